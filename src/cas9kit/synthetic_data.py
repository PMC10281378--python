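"""Seeded generators for every input class the pipeline consumes.

Each generator is a pure function of (arguments, seed) and returns the
simulated data together with a :class:`GroundTruth` record sufficient to
score recovery by the corresponding analysis stage:

* PAM-randomized plasmid libraries (``TNNN`` in vivo, ``NNNNNNN`` in vitro),
* treatment/control screen read pools under a per-PAM survival model,
* adapter-ligated cleavage-fragment reads with a planted cut geometry,
* edited amplicons with a planted indel spectrum plus SNV noise,
* contigs carrying a repeat-spacer array, a long ORF, and a mismatched
  anti-repeat.

Sequencing error is substitution-only so indel calls are never confounded;
reads are single-end and fully cover the PAM region.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .errors import ConfigError, UsageError
from .pam_depletion import PamCountTable
from .pam_invitro import TargetContext
from .seq_io import IUPAC_CODES, IupacPattern, SeqRecord, iupac_match, revcomp

BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_B2I = {b: i for i, b in enumerate(BASES)}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class PamLibrarySpec:
    """A randomized-PAM plasmid library design.

    ``pattern`` is the IUPAC pattern of the PAM region (e.g. ``TNNN`` for the
    in vivo screen, ``NNNNNNN`` in vitro); ``anchor`` is the fixed protospacer
    sequence on the spacer-matching strand; the PAM region sits immediately
    3' of the anchor on that strand.
    """

    pattern: IupacPattern
    anchor: str
    pam_side: str = "3prime"
    label: str = "library"

    def __post_init__(self) -> None:
        self.pattern = IupacPattern(self.pattern)
        self.anchor = self.anchor.upper()
        if not self.anchor:
            raise UsageError("anchor must be non-empty")
        if self.pam_side != "3prime":
            raise UsageError("only 3'-of-protospacer PAM placement is modeled")


@dataclass
class ActivityModel:
    """Per-PAM probability that a plasmid molecule survives the nuclease.

    ``survival[v]`` is the probability that a molecule carrying PAM variant
    ``v`` yields a transformant (in vivo) or escapes cleavage (in vitro).
    """

    survival: dict[str, float]

    def __post_init__(self) -> None:
        bad = {v: p for v, p in self.survival.items() if not 0 <= p <= 1}
        if bad:
            raise UsageError(f"survival probabilities outside [0,1]: {bad}")

    @classmethod
    def from_rule(cls, pattern: str, active: str,
                  survival_active: float = 1e-4,
                  survival_inactive: float = 1.0) -> "ActivityModel":
        """Binary model: variants matching the IUPAC ``active`` rule get
        ``survival_active``, all others ``survival_inactive``."""
        return cls({v: survival_active if iupac_match(v, active)
                    else survival_inactive
                    for v in IupacPattern(pattern).expand()})

    @classmethod
    def from_cleavage_probs(cls, cleavage: Mapping[str, float]) -> "ActivityModel":
        """Survival = 1 - cleavage probability, variant-wise."""
        return cls({v: 1.0 - p for v, p in cleavage.items()})

    def require_all(self, variants: Sequence[str]) -> None:
        missing = [v for v in variants if v not in self.survival]
        if missing:
            raise ConfigError(
                f"activity model missing {len(missing)} variant(s), "
                f"e.g. {missing[:3]}")


class GroundTruth(dict):
    """Serializable record of what a generator planted."""

    def to_json(self, path: str | Path) -> Path:
        Path(path).write_text(json.dumps(self, indent=1, default=_jsonable))
        return Path(path)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(json.loads(Path(path).read_text()))


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def load_preset(name: str = "eh") -> dict:
    """Load a packaged system preset (sequences + geometry defaults).

    The ``eh`` preset carries the EH CRISPR-Cas9 architecture (36-bp repeat,
    29-bp spacer, 18+4+73-nt sgRNA backbone, TGGN editing PAM, blunt cut at
    offset 3); its repeat/spacer/tracrRNA sequences are synthetic stand-ins
    (see the preset file header).
    """
    from importlib.resources import files

    res = files("cas9kit.presets") / f"{name}_synthetic.yaml"
    if not res.is_file():
        raise ConfigError(f"unknown preset {name!r}")
    return yaml.safe_load(res.read_text())


# ---------------------------------------------------------------------------
# PAM library and screen reads
# ---------------------------------------------------------------------------

def gen_pam_library(spec: PamLibrarySpec, depth: int, skew: float = 0.0,
                    seed: int = 0) -> tuple[PamCountTable, GroundTruth]:
    """Sample a plasmid-library composition over every PAM variant.

    ``skew`` is a lognormal concentration parameter: 0 gives a uniform
    composition; larger values give increasingly uneven variant abundances.
    Counts are one multinomial draw of size ``depth``.
    """
    if depth <= 0:
        raise UsageError("depth must be positive")
    variants = spec.pattern.expand()
    v = len(variants)
    rng = np.random.default_rng(seed)
    if skew < 0:
        raise UsageError("skew must be >= 0")
    if skew == 0:
        probs = np.full(v, 1.0 / v)
    else:
        w = np.exp(skew * rng.standard_normal(v))
        probs = w / w.sum()
    counts = rng.multinomial(depth, probs)
    table = PamCountTable(dict(zip(variants, counts.tolist())), label=spec.label)
    truth = GroundTruth(probs=dict(zip(variants, probs.tolist())),
                        counts=dict(zip(variants, counts.tolist())),
                        depth=depth, skew=skew, seed=seed)
    return table, truth


def gen_treated_table(library: PamCountTable, activity: ActivityModel,
                      n: int, seed: int = 0) -> PamCountTable:
    """Counts-level screen: draw ``n`` reads from the library composition
    reweighted by per-variant survival and renormalized.

    Equivalent to the composition of :func:`gen_screen_reads`' treatment arm
    without materializing reads; used for large in vitro variant universes.
    """
    variants = library.variants
    activity.require_all(variants)
    rng = np.random.default_rng(seed)
    freq = np.array([library.counts[v] for v in variants], dtype=float)
    freq /= freq.sum()
    w = freq * np.array([activity.survival[v] for v in variants])
    if w.sum() == 0:
        raise ConfigError("no variant survives; treatment pool is empty")
    counts = rng.multinomial(n, w / w.sum())
    return PamCountTable(dict(zip(variants, counts.tolist())),
                         label=f"{library.label}_treated")


def _mutate_batch(mat: np.ndarray, error_rate: float,
                  rng: np.random.Generator) -> int:
    """In-place i.i.d. substitutions on a base-index matrix; returns the
    number of substituted positions."""
    if error_rate == 0:
        return 0
    mask = rng.random(mat.shape) < error_rate
    n = int(mask.sum())
    if n:
        mat[mask] = (mat[mask] + rng.integers(1, 4, size=n)) % 4
    return n


def _rows_to_records(mat: np.ndarray, prefix: str) -> list[SeqRecord]:
    ascii_codes = np.frombuffer(b"ACGT", dtype=np.uint8)[mat]
    return [SeqRecord(f"{prefix}_{i}", bytes(row).decode())
            for i, row in enumerate(ascii_codes)]


def gen_screen_reads(
    library: PamCountTable,
    activity: ActivityModel,
    n_reads: int,
    error_rate: float,
    flanks: tuple[str, str],
    spec: PamLibrarySpec,
    seed: int = 0,
) -> tuple[list[SeqRecord], list[SeqRecord], GroundTruth]:
    """Simulate treatment and control read pools of an in vivo PAM screen.

    Control reads are drawn from the library composition; treatment reads
    from the composition reweighted by survival and renormalized.  Each read
    is ``flank5 + anchor + PAM + flank3`` with i.i.d. substitution errors.
    """
    if not 0 <= error_rate <= 0.1:
        raise UsageError("error_rate must be in [0, 0.1]")
    variants = library.variants
    activity.require_all(variants)
    rng = np.random.default_rng(seed)
    f5, f3 = (f.upper() for f in flanks)
    freq = np.array([library.counts[v] for v in variants], dtype=float)
    freq /= freq.sum()
    surv = np.array([activity.survival[v] for v in variants])
    w = freq * surv
    if w.sum() == 0:
        raise ConfigError("no variant survives; treatment pool is empty")

    templates = np.array(
        [[_B2I[b] for b in f5 + spec.anchor + v + f3] for v in variants],
        dtype=np.int8)

    out: dict[str, list[SeqRecord]] = {}
    tallies: dict[str, dict[str, int]] = {}
    n_err: dict[str, int] = {}
    for arm, probs in (("control", freq), ("treatment", w / w.sum())):
        counts = rng.multinomial(n_reads, probs)
        idx = np.repeat(np.arange(len(variants)), counts)
        rng.shuffle(idx)
        mat = templates[idx].copy()
        n_err[arm] = _mutate_batch(mat, error_rate, rng)
        out[arm] = _rows_to_records(mat, arm)
        tallies[arm] = dict(zip(variants, counts.tolist()))
    truth = GroundTruth(treatment_counts=tallies["treatment"],
                        control_counts=tallies["control"],
                        survival=dict(activity.survival),
                        n_errors=n_err, flanks=[f5, f3], seed=seed)
    return out["treatment"], out["control"], truth


# ---------------------------------------------------------------------------
# cleavage fragments
# ---------------------------------------------------------------------------

def gen_cleavage_fragments(
    library: PamCountTable,
    activity: ActivityModel,
    cut_offset: int,
    overhang: int,
    adapter: str,
    n: int,
    spec: PamLibrarySpec,
    flanks: tuple[str, str] = ("GCTTAGCTGGTCAACGTACT", "CCAGTTGACTGATCGGAACT"),
    seed: int = 0,
) -> tuple[list[SeqRecord], TargetContext, GroundTruth]:
    """Simulate adapter-ligated reads from the ends of cleavage fragments.

    ``n`` molecules are drawn from the library composition; each is cleaved
    with probability ``1 - survival``.  Cleavage cuts the spacer-matching
    (top) strand ``cut_offset`` nt from the PAM-proximal protospacer end and
    the bottom strand ``cut_offset + overhang`` nt from it (``overhang`` 0 is
    a blunt cut).  Each cleaved molecule yields two reads, one per new 5'
    end, beginning with the adapter so that the first template base marks a
    cut terminus on its strand.
    """
    if cut_offset < 1:
        raise UsageError("cut_offset must be >= 1")
    if overhang < 0:
        raise UsageError("overhang must be >= 0")
    adapter = adapter.upper()
    if len(adapter) < 8:
        raise ConfigError("adapter shorter than 8 nt is unanchorable")
    variants = library.variants
    activity.require_all(variants)
    f5, f3 = (f.upper() for f in flanks)
    ps_start = len(f5)
    pam_start = len(f5) + len(spec.anchor)
    pam_end = pam_start + len(spec.pattern)
    t_top = pam_start - cut_offset
    t_bot = pam_start - cut_offset - overhang
    if t_bot <= 0 or t_top <= ps_start - len(spec.anchor):
        raise UsageError("cut geometry falls outside the target context")

    rng = np.random.default_rng(seed)
    freq = np.array([library.counts[v] for v in variants], dtype=float)
    freq /= freq.sum()
    surv = np.array([activity.survival[v] for v in variants])
    mol_counts = rng.multinomial(n, freq)
    cleaved = rng.binomial(mol_counts, 1.0 - surv)

    reads: list[SeqRecord] = []
    cleaved_tally: dict[str, int] = {}
    k = 0
    for v, c in zip(variants, cleaved):
        if c == 0:
            continue
        cleaved_tally[v] = int(c)
        context = f5 + spec.anchor + v + f3
        top = adapter + context[t_top:]
        bottom = adapter + revcomp(context[:t_bot])
        for _ in range(int(c)):
            reads.append(SeqRecord(f"frag_{k}_top", top))
            reads.append(SeqRecord(f"frag_{k}_bot", bottom))
            k += 1
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]

    masked = f5 + spec.anchor + "N" * len(spec.pattern) + f3
    ctx = TargetContext(sequence=masked, protospacer_start=ps_start,
                        pam_start=pam_start, pam_end=pam_end)
    truth = GroundTruth(cut_offset=cut_offset, overhang=overhang,
                        top_terminus=t_top, bottom_terminus=t_bot,
                        cleaved_counts=cleaved_tally,
                        molecule_counts=dict(zip(variants, mol_counts.tolist())),
                        n_molecules=n, seed=seed)
    return reads, ctx, truth


# ---------------------------------------------------------------------------
# edited amplicons
# ---------------------------------------------------------------------------

def parse_allele_label(label: str) -> tuple[int, int, str]:
    """Parse an allele label like ``-2:1D`` or ``+1:2I``.

    Returns (position relative to the cut site, event length, kind) with
    kind ``D`` (deletion) or ``I`` (insertion).  Position -1 is the base
    immediately 5' of the cut, +1 immediately 3'; 0 is invalid.
    """
    try:
        pos_s, rest = label.split(":")
        pos = int(pos_s)
        length = int(rest[:-1])
        kind = rest[-1].upper()
    except (ValueError, IndexError) as exc:
        raise UsageError(f"malformed allele label {label!r}") from exc
    if kind not in "DI" or length < 1 or pos == 0:
        raise UsageError(f"malformed allele label {label!r}")
    return pos, length, kind


def _label_to_index(pos: int, cut_pos: int) -> int:
    """Cut-relative label position -> 0-based reference index."""
    return cut_pos + pos if pos < 0 else cut_pos + pos - 1


def apply_allele(ref: str, cut_pos: int, label: str,
                 insert_seq: str | None = None) -> str:
    """Apply an allele label to a reference sequence.

    Deletions remove ``length`` bases starting at the labeled position;
    insertions place ``insert_seq`` immediately before the base at the
    labeled position (so ``+1:kI`` inserts exactly at the cut).
    """
    pos, length, kind = parse_allele_label(label)
    idx = _label_to_index(pos, cut_pos)
    if kind == "D":
        if idx < 0 or idx + length > len(ref):
            raise ConfigError(f"allele {label!r} falls outside the amplicon")
        return ref[:idx] + ref[idx + length:]
    if idx < 0 or idx > len(ref):
        raise ConfigError(f"allele {label!r} falls outside the amplicon")
    if insert_seq is None or len(insert_seq) != length:
        raise UsageError(f"allele {label!r} needs an insert of length {length}")
    return ref[:idx] + insert_seq + ref[idx:]


def normalize_label(ref: str, cut_pos: int, label: str,
                    insert_seq: str | None = None) -> str:
    """Leftmost-equivalent representation of an allele label.

    A deletion (or insertion) inside a repeat context has several equivalent
    placements; variant callers conventionally report the leftmost one.
    This shifts the event left while the edited sequence is unchanged and
    re-labels it, so planted alleles can be compared with called ones.
    """
    pos, length, kind = parse_allele_label(label)
    idx = _label_to_index(pos, cut_pos)
    if kind == "D":
        while idx > 0 and ref[idx - 1] == ref[idx + length - 1]:
            idx -= 1
    else:
        ins = insert_seq or ""
        while idx > 0 and ins and ref[idx - 1] == ins[-1]:
            ins = ref[idx - 1] + ins[:-1]
            idx -= 1
    new_pos = idx - cut_pos if idx < cut_pos else idx - cut_pos + 1
    sign = "+" if new_pos > 0 else ""
    return f"{sign}{new_pos}:{length}{kind}"


def gen_editing_amplicons(
    ref: SeqRecord,
    cut_pos: int,
    indel_rate: float,
    spectrum: Mapping[str, float],
    snv_rate: float,
    n: int,
    seed: int = 0,
) -> tuple[list[SeqRecord], GroundTruth]:
    """Simulate an editing amplicon pool with a planted indel spectrum.

    Each read carries a planted indel with probability ``indel_rate`` (allele
    drawn from ``spectrum``, probabilities summing to 1); all reads then
    receive i.i.d. substitutions at per-base rate ``snv_rate``.  Ground truth
    records each read's class and planted label.
    """
    if not 0 <= indel_rate <= 1 or not 0 <= snv_rate <= 1:
        raise UsageError("rates must be probabilities")
    if spectrum and abs(sum(spectrum.values()) - 1.0) > 1e-9:
        raise UsageError("spectrum probabilities must sum to 1")
    if indel_rate > 0 and not spectrum:
        raise UsageError("non-zero indel_rate requires a spectrum")
    if not 0 < cut_pos < len(ref.bases):
        raise UsageError("cut_pos must lie strictly inside the reference")
    rng = np.random.default_rng(seed)
    labels = list(spectrum)
    probs = np.array([spectrum[l] for l in labels]) if labels else None
    # validate labels up front so a bad spectrum fails before sampling
    for label in labels:
        pos, length, kind = parse_allele_label(label)
        apply_allele(ref.bases, cut_pos, label,
                     "A" * length if kind == "I" else None)

    reads: list[SeqRecord] = []
    per_read: list[dict] = []
    for i in range(n):
        planted = None
        if labels is not None and labels and rng.random() < indel_rate:
            planted = labels[rng.choice(len(labels), p=probs)]
        normalized = None
        if planted is None:
            seq = ref.bases
        else:
            _, length, kind = parse_allele_label(planted)
            ins = "".join(rng.choice(list(BASES), length)) if kind == "I" else None
            seq = apply_allele(ref.bases, cut_pos, planted, ins)
            normalized = normalize_label(ref.bases, cut_pos, planted, ins)
        mat = np.array([_B2I[b] for b in seq], dtype=np.int8)
        n_sub = _mutate_batch(mat[None, :], snv_rate, rng)
        if n_sub:
            seq = bytes(np.frombuffer(b"ACGT", dtype=np.uint8)[mat]).decode()
        cls = "indel" if planted else ("snv_only" if n_sub else "wt")
        reads.append(SeqRecord(f"amp_{i}", seq))
        per_read.append({"id": f"amp_{i}", "class": cls, "label": planted,
                         "label_normalized": normalized, "n_subs": n_sub})
    truth = GroundTruth(reads=per_read, cut_pos=cut_pos,
                        indel_rate=indel_rate, spectrum=dict(spectrum),
                        snv_rate=snv_rate, seed=seed)
    return reads, truth


# ---------------------------------------------------------------------------
# locus contigs
# ---------------------------------------------------------------------------

def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, n)])


def _base_not_in(forbidden) -> str:
    banned = set(forbidden)
    for b in BASES:
        if b not in banned:
            return b
    return "A"  # all four bases forbidden: boundary stays ambiguous


def _mutated_copy(seq: str, n_mut: int, rng: np.random.Generator) -> str:
    out = list(seq)
    for p in rng.choice(len(seq), size=n_mut, replace=False):
        out[p] = rng.choice([b for b in BASES if b != out[p]])
    return "".join(out)


def gen_locus_contig(
    repeat: str,
    spacers: Sequence[str],
    orf_len_aa: int,
    anti_repeat_mismatches: int = 4,
    seed: int = 0,
    pads: tuple[int, int, int, int] = (400, 150, 150, 200),
) -> tuple[SeqRecord, GroundTruth]:
    """Build a contig carrying an array, an anti-repeat, and a long ORF.

    Layout: background, repeat-spacer array (``len(spacers)+1`` exact repeat
    units), background, one copy of the repeat's reverse complement mutated
    at exactly ``anti_repeat_mismatches`` positions, background, an ORF of
    exactly ``orf_len_aa`` codons (ATG start, stop-terminated, preceded by an
    in-frame stop so it is maximal), background.  All coordinates are
    recorded in the ground truth (0-based, half-open).
    """
    repeat = repeat.upper()
    if len(repeat) < 18:
        raise UsageError("repeat must be >= 18 nt")
    if orf_len_aa < 100:
        raise UsageError("orf_len_aa must be >= 100")
    if not 0 <= anti_repeat_mismatches <= len(repeat):
        raise UsageError("anti_repeat_mismatches out of range")
    rng = np.random.default_rng(seed)

    parts: list[str] = []
    pos = 0

    def emit(s: str) -> tuple[int, int]:
        nonlocal pos
        parts.append(s)
        start, pos_end = pos, pos + len(s)
        pos = pos_end
        return start, pos_end

    spacers = [sp.upper() for sp in spacers]
    bg0 = _random_bases(rng, pads[0])
    bg1 = _random_bases(rng, pads[1])
    if spacers:
        # pin the two background bases flanking the array so the repeat
        # boundary is unambiguous (a chance match there would make the
        # maximal repeat extension overrun the planted unit)
        bg0 = bg0[:-1] + _base_not_in((sp[-1] for sp in spacers))
        bg1 = _base_not_in((sp[0] for sp in spacers)) + bg1[1:]
    emit(bg0)
    units: list[tuple[int, int]] = []
    spacer_coords: list[tuple[int, int]] = []
    units.append(emit(repeat))
    for sp in spacers:
        spacer_coords.append(emit(sp))
        units.append(emit(repeat))
    array_span = (units[0][0], units[-1][1])

    emit(bg1)
    anti_seq = _mutated_copy(revcomp(repeat), anti_repeat_mismatches, rng)
    anti_span = emit(anti_seq)

    emit(_random_bases(rng, pads[2]))
    emit("TAA")  # in-frame stop so the planted ORF is maximal
    non_stop = [a + b + c for a in BASES for b in BASES for c in BASES
                if a + b + c not in _STOPS]
    body = "".join(np.array(non_stop)[rng.integers(0, len(non_stop),
                                                   orf_len_aa - 1)])
    stop = rng.choice(sorted(_STOPS))
    orf_span = emit("ATG" + body + stop)
    emit(_random_bases(rng, pads[3]))

    contig = SeqRecord(f"synthetic_locus_seed{seed}", "".join(parts))
    from Bio.Seq import Seq

    protein = str(Seq(contig.bases[orf_span[0]:orf_span[1]]).translate())
    assert protein.endswith("*") and len(protein) - 1 == orf_len_aa
    truth = GroundTruth(
        repeat=repeat, spacers=[s.upper() for s in spacers],
        array=[list(array_span)], units=[list(u) for u in units],
        spacer_coords=[list(s) for s in spacer_coords],
        anti_repeat=list(anti_span), anti_repeat_strand="-",
        anti_repeat_mismatches=anti_repeat_mismatches,
        orf=list(orf_span), orf_strand="+", protein=protein[:-1],
        seed=seed)
    return contig, truth


def eh_locus_contig(seed: int = 0, orf_len_aa: int | None = None
                    ) -> tuple[SeqRecord, GroundTruth]:
    """EH-preset contig: 36-bp repeats, one 29-bp spacer, mismatched
    anti-repeat, and (by default) a 1070-codon ORF."""
    p = load_preset("eh")
    return gen_locus_contig(
        repeat=p["repeat"], spacers=[p["array_spacer"]],
        orf_len_aa=orf_len_aa if orf_len_aa is not None else p["orf_len_aa"],
        anti_repeat_mismatches=p["anti_repeat_mismatches"], seed=seed)
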