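"""CRISPR locus mining and guide design.

Detects repeat-spacer arrays and ORFs on contigs, searches the array
neighborhood for anti-repeat (tracrRNA candidate) regions, assembles sgRNA
scaffolds (spacer + truncated repeat + tetraloop linker + tracrRNA
fragment), enumerates PAM-constrained target sites, and builds recombineering
templates from homology arms.

Array detection is seeded with exact 12-mers recurring at admissible
periodicity, extended to a maximal repeat unit, then validated against the
geometry bounds; additional units are chained at the same period allowing up
to 2 substitutions.  The anti-repeat search is a substitution-only (gapless)
Hamming scan, which keeps it deterministic and oracle-checkable.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio.Seq import Seq

from .errors import UsageError
from .seq_io import IupacPattern, SeqRecord, iupac_match, revcomp


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class CrisprArray:
    """A detected repeat-spacer array (strand unknown at detection)."""

    repeat_consensus: str
    units: list[tuple[int, int]]
    spacers: list[tuple[str, int, int]]
    mismatch_total: int = 0  # summed unit-vs-consensus Hamming distance

    @property
    def start(self) -> int:
        return self.units[0][0]

    @property
    def end(self) -> int:
        return self.units[-1][1]

    @property
    def repeat_length(self) -> int:
        return len(self.repeat_consensus)

    @property
    def spacer_lengths(self) -> list[int]:
        return [e - s for _, s, e in self.spacers]


@dataclass
class TracrCandidate:
    """An approximate (anti-)repeat match near an array."""

    start: int
    end: int
    strand: str
    mismatches: int
    distance_to_array: int


@dataclass
class SgRNADesign:
    """A single-guide RNA scaffold with component coordinates.

    ``full_sequence`` = spacer + repeat_part + linker + tracr_part.
    ``duplex_mismatches`` counts mismatches between the retained repeat part
    and the anti-repeat region of the tracrRNA part when reverse-complement
    aligned.
    """

    spacer: str
    repeat_part: str
    linker: str
    tracr_part: str
    duplex_mismatches: int

    @property
    def full_sequence(self) -> str:
        return self.spacer + self.repeat_part + self.linker + self.tracr_part

    @property
    def components(self) -> dict[str, tuple[int, int]]:
        n1 = len(self.spacer)
        n2 = n1 + len(self.repeat_part)
        n3 = n2 + len(self.linker)
        n4 = n3 + len(self.tracr_part)
        return {"spacer": (0, n1), "repeat_part": (n1, n2),
                "linker": (n2, n3), "tracr_part": (n3, n4)}

    def __len__(self) -> int:
        return len(self.full_sequence)


@dataclass
class TargetSite:
    """A protospacer+PAM hit; coordinates are forward-strand, 0-based
    half-open, covering the protospacer."""

    protospacer: str
    pam_region: str
    strand: str
    start: int
    end: int
    pam_start: int
    pam_end: int


# ---------------------------------------------------------------------------
# array detection
# ---------------------------------------------------------------------------

def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _extend_pair(seq: str, i: int, j: int, k: int, max_len: int
                 ) -> tuple[int, int]:
    """Maximal exact extension of a k-mer match at positions i < j.

    Returns (start_offset_left, total_length) of the maximal equal substring
    around the seed, capped so the unit never reaches its partner (length <=
    min(j - i, max_len))."""
    left = 0
    while (i - left - 1 >= 0 and seq[i - left - 1] == seq[j - left - 1]
           and j - left - 1 >= i + 1):
        left += 1
    right = 0
    limit = min(j - i, max_len)
    while (j + k + right < len(seq)
           and seq[i + k + right] == seq[j + k + right]
           and left + k + right + 1 <= limit
           and i + k + right + 1 <= j):
        right += 1
    return left, left + k + right


def find_crispr_arrays(contig: SeqRecord, min_repeat: int = 18,
                       max_repeat: int = 45, min_spacer: int = 15,
                       max_spacer: int = 45, min_units: int = 2,
                       k: int = 12, max_unit_mismatch: int = 2
                       ) -> list[CrisprArray]:
    """Detect repeat-spacer arrays by periodic exact k-mer seeding.

    Every reported array has >= ``min_units`` repeat units whose pairwise
    mismatch to the first unit is <= ``max_unit_mismatch``, unit length in
    [min_repeat, max_repeat], and spacer lengths in [min_spacer, max_spacer].
    Arrays are reported 5'->3' by start; overlapping detections of the same
    array are merged (leftmost start, then longest, wins).
    """
    seq = contig.bases
    n = len(seq)
    if n < 2 * min_repeat + min_spacer:
        return []
    kmers: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        kmers.setdefault(seq[i:i + k], []).append(i)

    min_period = min_repeat + min_spacer
    max_period = max_repeat + max_spacer
    found: dict[tuple[int, ...], CrisprArray] = {}
    for positions in kmers.values():
        if len(positions) < 2 or len(positions) > 50:
            continue
        for a in range(len(positions) - 1):
            for b in range(a + 1, len(positions)):
                i, j = positions[a], positions[b]
                d = j - i
                if d < min_period:
                    continue
                if d > max_period:
                    break
                left, length = _extend_pair(seq, i, j, k, max_repeat)
                if not min_repeat <= length <= max_repeat:
                    continue
                if not min_spacer <= d - length <= max_spacer:
                    continue
                start = i - left
                unit_seq = seq[start:start + length]
                starts = _chain_units(seq, unit_seq, start, d,
                                      max_unit_mismatch)
                if len(starts) < min_units:
                    continue
                key = tuple(starts)
                if key not in found:
                    found[key] = _build_array(seq, unit_seq, starts, length)

    arrays = _dedup_overlaps(list(found.values()))
    return sorted(arrays, key=lambda arr: arr.start)


def _chain_units(seq: str, unit: str, start: int, period: int,
                 max_mm: int) -> list[int]:
    length = len(unit)
    starts = [start]
    s = start - period
    while s >= 0 and _hamming(seq[s:s + length], unit) <= max_mm:
        starts.insert(0, s)
        s -= period
    s = start + period
    while s + length <= len(seq) and _hamming(seq[s:s + length], unit) <= max_mm:
        starts.append(s)
        s += period
    return starts


def _build_array(seq: str, unit: str, starts: list[int], length: int
                 ) -> CrisprArray:
    units = [(s, s + length) for s in starts]
    # column-majority consensus over the units
    cols = []
    for j in range(length):
        col = [seq[s + j] for s in starts]
        cols.append(max(set(col), key=col.count))
    spacers = [(seq[units[t][1]:units[t + 1][0]], units[t][1], units[t + 1][0])
               for t in range(len(units) - 1)]
    consensus = "".join(cols)
    mm_total = sum(_hamming(seq[s:e], consensus) for s, e in units)
    return CrisprArray(consensus, units, spacers, mm_total)


def _dedup_overlaps(arrays: list[CrisprArray]) -> list[CrisprArray]:
    """Among overlapping detections keep the most consistent one.

    Preference: more repeat units, then fewer unit-vs-consensus mismatches
    (a boundary over-extension past the true repeat shows up as mismatches
    in at least one unit), then leftmost start, then longest."""
    kept: list[CrisprArray] = []
    for arr in sorted(arrays,
                      key=lambda a: (-len(a.units), a.mismatch_total,
                                     a.start, -(a.end - a.start))):
        if any(not (arr.end <= other.start or other.end <= arr.start)
               for other in kept):
            continue
        kept.append(arr)
    return kept


# ---------------------------------------------------------------------------
# ORF scan
# ---------------------------------------------------------------------------

def find_orfs(contig: SeqRecord, min_len_aa: int = 100,
              include_open: bool = False
              ) -> list[tuple[int, int, str, str]]:
    """Maximal ATG->stop ORFs in all six frames, >= ``min_len_aa`` residues.

    Returns (start, end, strand, protein) with forward-strand coordinates
    spanning start codon through stop codon (half-open).  ORFs running off
    the contig edge without a stop are excluded unless ``include_open``.
    """
    results = []
    n = len(contig.bases)
    for strand, seq in (("+", contig.bases), ("-", revcomp(contig.bases))):
        for frame in range(3):
            orf_start = None
            i = frame
            while i + 3 <= len(seq):
                codon = seq[i:i + 3]
                if orf_start is None:
                    if codon == "ATG":
                        orf_start = i
                elif codon in ("TAA", "TAG", "TGA"):
                    aa_len = (i - orf_start) // 3
                    if aa_len >= min_len_aa:
                        results.append(_orf_record(seq, orf_start, i + 3,
                                                   strand, n))
                    orf_start = None
                i += 3
            if orf_start is not None and include_open:
                end = i
                if (end - orf_start) // 3 >= min_len_aa:
                    results.append(_orf_record(seq, orf_start, end, strand, n))
    return sorted(results, key=lambda r: (r[0], r[1]))


def _orf_record(seq: str, s: int, e: int, strand: str, n: int
                ) -> tuple[int, int, str, str]:
    protein = str(Seq(seq[s:e]).translate()).rstrip("*")
    if strand == "+":
        return (s, e, strand, protein)
    return (n - e, n - s, strand, protein)


# ---------------------------------------------------------------------------
# anti-repeat (tracrRNA candidate) search
# ---------------------------------------------------------------------------

def find_anti_repeat(contig: SeqRecord, array: CrisprArray,
                     window: int = 2000, max_mismatch: int = 6
                     ) -> list[TracrCandidate]:
    """Gapless scan for degenerate repeat copies near the array.

    Both the repeat consensus (strand ``+``) and its reverse complement
    (strand ``-``) are slid over ``window`` nt on each side of the array;
    windows overlapping any array unit are excluded.  Candidates are sorted
    by mismatches, then distance to the array.
    """
    seq = contig.bases
    if array.end > len(seq):
        raise UsageError("array does not lie on the contig")
    repeat = array.repeat_consensus
    m = len(repeat)
    lo = max(0, array.start - window)
    hi = min(len(seq), array.end + window)
    probes = ((repeat, "+"), (revcomp(repeat), "-"))
    out: list[TracrCandidate] = []
    for p in range(lo, hi - m + 1):
        span = (p, p + m)
        if any(span[0] < ue and us < span[1] for us, ue in array.units):
            continue
        window_seq = seq[p:p + m]
        for probe, strand in probes:
            mm = _hamming(window_seq, probe)
            if mm <= max_mismatch:
                if p >= array.end:
                    dist = p - array.end
                elif p + m <= array.start:
                    dist = array.start - (p + m)
                else:
                    dist = 0
                out.append(TracrCandidate(p, p + m, strand, mm, dist))
    return sorted(out, key=lambda c: (c.mismatches, c.distance_to_array,
                                      c.start))


# ---------------------------------------------------------------------------
# sgRNA design
# ---------------------------------------------------------------------------

def design_sgrna(repeat: str, tracr: str, spacer: str = "",
                 keep_repeat: int = 18, linker: str = "GAAA",
                 keep_tracr: int = 73, repeat_from: str = "3prime"
                 ) -> SgRNADesign:
    """Assemble an sgRNA scaffold: spacer + truncated repeat + linker +
    tracrRNA fragment.

    With the defaults (18-nt repeat truncation, GAAA tetraloop, 73-nt
    tracrRNA fragment) and a 23-nt spacer the guide is 118 nt with a 95-nt
    constant backbone.  ``repeat_from='3prime'`` keeps the repeat's 3' end
    (the crRNA-retained portion adjoining the spacer-repeat junction); the
    tracrRNA fragment is taken from its 5' end, which begins with the
    anti-repeat.
    """
    repeat, tracr, spacer = repeat.upper(), tracr.upper(), spacer.upper()
    if keep_repeat > len(repeat):
        raise UsageError(f"keep_repeat {keep_repeat} exceeds repeat length "
                         f"{len(repeat)}")
    if keep_tracr > len(tracr):
        raise UsageError(f"keep_tracr {keep_tracr} exceeds tracrRNA length "
                         f"{len(tracr)}")
    if repeat_from not in ("3prime", "5prime"):
        raise UsageError("repeat_from must be '3prime' or '5prime'")
    repeat_part = (repeat[-keep_repeat:] if repeat_from == "3prime"
                   else repeat[:keep_repeat])
    tracr_part = tracr[:keep_tracr]
    anti_len = min(len(repeat_part), len(tracr_part))
    duplex_mm = _hamming(repeat_part[:anti_len],
                         revcomp(tracr_part[:anti_len]))
    return SgRNADesign(spacer, repeat_part, linker.upper(), tracr_part,
                       duplex_mm)


def eh_sgrna(spacer: str | None = None) -> SgRNADesign:
    """The packaged EH-architecture sgRNA (default-length random-free spacer
    taken from the preset array spacer's PAM-proximal end)."""
    from .synthetic_data import load_preset

    p = load_preset("eh")
    if spacer is None:
        spacer = p["array_spacer"][-p["guide_length"]:]
    return design_sgrna(p["repeat"], p["tracrrna"], spacer,
                        keep_repeat=p["sgrna"]["keep_repeat"],
                        linker=p["sgrna"]["linker"],
                        keep_tracr=p["sgrna"]["keep_tracr"],
                        repeat_from=p["sgrna"]["repeat_from"])


# ---------------------------------------------------------------------------
# target enumeration
# ---------------------------------------------------------------------------

def find_targets(genome: SeqRecord, pam: IupacPattern | str = "TGGN",
                 guide_len: int = 23) -> list[TargetSite]:
    """Enumerate protospacer+PAM sites on both strands.

    The protospacer is the ``guide_len`` nt immediately 5' of the PAM on the
    spacer-matching strand; reported coordinates are forward-strand 0-based
    half-open over the protospacer.
    """
    pam = IupacPattern(pam)
    seq = genome.bases
    n = len(seq)
    plen = len(pam)
    if n < guide_len + plen:
        raise UsageError("genome shorter than guide + PAM")
    hits: list[TargetSite] = []
    for i in range(n - guide_len - plen + 1):
        window = seq[i + guide_len:i + guide_len + plen]
        if "N" not in window and iupac_match(window, pam):
            hits.append(TargetSite(seq[i:i + guide_len], window, "+",
                                   i, i + guide_len,
                                   i + guide_len, i + guide_len + plen))
    rc = revcomp(seq)
    for i in range(n - guide_len - plen + 1):
        window = rc[i + guide_len:i + guide_len + plen]
        if "N" not in window and iupac_match(window, pam):
            # protospacer occupies rc[i, i+guide_len) -> forward coords below;
            # the PAM sits 5'-ward of it on the forward strand
            ps_start_f = n - (i + guide_len)
            ps_end_f = n - i
            hits.append(TargetSite(rc[i:i + guide_len], window, "-",
                                   ps_start_f, ps_end_f,
                                   ps_start_f - plen, ps_start_f))
    return sorted(hits, key=lambda t: (t.start, t.strand))


# ---------------------------------------------------------------------------
# recombineering templates
# ---------------------------------------------------------------------------

@dataclass
class RecombTemplate:
    """A linear recombination template: upstream arm + downstream arm."""

    upstream_arm: str
    downstream_arm: str

    @property
    def sequence(self) -> str:
        return self.upstream_arm + self.downstream_arm

    @property
    def arm_boundary(self) -> int:
        return len(self.upstream_arm)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def record(self) -> SeqRecord:
        return SeqRecord("recomb_template", self.sequence)


def build_recomb_template(upstream_arm: str, downstream_arm: str
                          ) -> RecombTemplate:
    """Concatenate homology arms into a linear recombination template."""
    if not upstream_arm or not downstream_arm:
        raise UsageError("both homology arms must be non-empty")
    return RecombTemplate(upstream_arm.upper(), downstream_arm.upper())


def apply_recombination(locus: str, template: RecombTemplate) -> str:
    """In silico homologous recombination: delete the segment between the
    two arm matches in ``locus``.

    Both arms must occur exactly once, upstream before downstream.
    """
    locus = locus.upper()
    up, down = template.upstream_arm, template.downstream_arm
    i = locus.find(up)
    j = locus.find(down)
    if i < 0 or j < 0:
        raise UsageError("homology arm not found in locus")
    if locus.find(up, i + 1) >= 0 or locus.find(down, j + 1) >= 0:
        raise UsageError("homology arm occurs more than once in locus")
    if j < i + len(up):
        raise UsageError("downstream arm precedes upstream arm")
    return locus[:i + len(up)] + locus[j:]


# ---------------------------------------------------------------------------
# tabular export
# ---------------------------------------------------------------------------

def features_to_tsv(contig_id: str, arrays: Sequence[CrisprArray],
                    orfs: Sequence[tuple[int, int, str, str]],
                    tracrs: Sequence[TracrCandidate], path: str | Path
                    ) -> Path:
    """BED-like feature table: contig, start, end, strand, score, name."""
    rows = []
    for idx, arr in enumerate(arrays):
        rows.append((contig_id, arr.start, arr.end, ".", len(arr.units),
                     f"crispr_array_{idx} repeat_len={arr.repeat_length}"))
        for us, ue in arr.units:
            rows.append((contig_id, us, ue, ".", 0, f"repeat_unit_{idx}"))
    for s, e, strand, prot in orfs:
        rows.append((contig_id, s, e, strand, len(prot), f"orf_{len(prot)}aa"))
    for idx, t in enumerate(tracrs):
        rows.append((contig_id, t.start, t.end, t.strand, t.mismatches,
                     f"tracr_candidate_{idx}"))
    df = pd.DataFrame(rows, columns=["contig", "start", "end", "strand",
                                     "score", "name"])
    df.to_csv(path, sep="\t", index=False)
    return Path(path)
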