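"""In vitro cleavage-screen analysis.

After digestion of a PAM-randomized plasmid library, adapters are ligated to
the new fragment ends, so each sequencing read starts at a cut terminus.
This module:

* normalizes per-PAM occurrence for library composition:
  ``norm(v) = f_T(v) * mean(f_C) / f_C(v)`` (treatment frequency scaled by
  the average control frequency over its own),
* keeps the top fraction (default 10%) of PAMs by normalized occurrence,
* builds a (by default occurrence-weighted) position frequency matrix and
  calls required/preferred IUPAC consensus strings from it,
* infers the cut site from the most frequent read termini on each strand.

Offset convention: the cut offset is the distance in nt from the
PAM-proximal end of the protospacer to the scissile phosphate on that
strand, so a blunt cut between the 3rd and 4th protospacer positions from
the PAM is offset 3 on both strands::

    5'-. . . N N N | N N N>PAM . . .-3'   top (spacer-matching) strand
    3'-. . . N N N | N N N<PAM . . .-5'   bottom strand   (blunt, offset 3)
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError, UsageError
from .pam_depletion import BASES, LogoMatrix, PamCountTable, logo_matrix
from .seq_io import IUPAC_FROM_SET, IupacPattern, SeqRecord, revcomp


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class TargetContext:
    """The cleavage substrate region around the protospacer.

    ``sequence`` carries ``N`` at the randomized PAM positions so reads from
    any library variant map onto it; coordinates are 0-based half-open.  The
    protospacer occupies ``[protospacer_start, pam_start)`` and the PAM
    ``[pam_start, pam_end)`` on the spacer-matching strand.
    """

    sequence: str
    protospacer_start: int
    pam_start: int
    pam_end: int

    def to_json(self, path: str | Path) -> Path:
        Path(path).write_text(json.dumps(self.__dict__, indent=1))
        return Path(path)

    @classmethod
    def from_json(cls, path: str | Path) -> "TargetContext":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class NormalizedOccurrence:
    """Per-variant normalized PAM occurrence and its inputs."""

    norm: dict[str, float]
    treatment_freq: dict[str, float]
    control_freq: dict[str, float]
    mean_control_freq: float

    def to_tsv(self, path: str | Path) -> Path:
        df = pd.DataFrame({
            "variant": list(self.norm),
            "normalized": list(self.norm.values()),
            "treatment_freq": [self.treatment_freq[v] for v in self.norm],
            "control_freq": [self.control_freq[v] for v in self.norm],
        })
        df.to_csv(path, sep="\t", index=False)
        return Path(path)


@dataclass
class CutSiteProfile:
    """Per-strand terminus histograms and the inferred cut geometry.

    Histogram keys are offsets (nt from the PAM-proximal protospacer end);
    ``overhang`` is the absolute difference of the two modal offsets and
    ``end_type`` is ``blunt`` iff it is 0.  ``ambiguous`` flags a tie for
    the mode on either strand (the smallest modal offset is then reported).
    """

    hist_top: dict[int, int]
    hist_bottom: dict[int, int]
    modal_offset_top: int
    modal_offset_bottom: int
    overhang: int
    end_type: str
    ambiguous: bool = False
    n_unmapped: int = 0

    def to_json(self, path: str | Path) -> Path:
        d = dict(self.__dict__)
        d["hist_top"] = {str(k): v for k, v in self.hist_top.items()}
        d["hist_bottom"] = {str(k): v for k, v in self.hist_bottom.items()}
        Path(path).write_text(json.dumps(d, indent=1))
        return Path(path)


# ---------------------------------------------------------------------------
# normalization, selection, consensus
# ---------------------------------------------------------------------------

def normalize_occurrence(treatment: PamCountTable, control: PamCountTable,
                         pseudocount: float = 1.0) -> NormalizedOccurrence:
    """norm(v) = f_T(v) * mean(f_C) / f_C(v), variant-wise.

    ``mean(f_C)`` is the average control frequency over variants (exactly
    1/V for a complete library).  With a uniform control composition the
    normalized occurrence equals the treatment frequency.
    """
    if set(treatment.counts) != set(control.counts):
        raise UsageError("treatment and control tables cover different "
                         "variant universes")
    f_t = treatment.freqs(0.0) if pseudocount == 0 else treatment.freqs(pseudocount)
    f_c = control.freqs(pseudocount)
    zero = [v for v, f in f_c.items() if f == 0]
    if zero:
        raise DataError(f"control frequency is zero for variant {zero[0]!r} "
                        "(pseudocount 0)")
    mean_c = sum(f_c.values()) / len(f_c)
    norm = {v: f_t[v] * mean_c / f_c[v] for v in f_t}
    return NormalizedOccurrence(norm, f_t, f_c, mean_c)


def top_fraction(norm: NormalizedOccurrence, fraction: float = 0.10
                 ) -> list[str]:
    """The floor(fraction * V) variants with highest normalized occurrence.

    Ties at the cutoff are broken lexicographically (smaller string kept).
    Returned in rank order.
    """
    if not 0 < fraction <= 1:
        raise UsageError("fraction must be in (0, 1]")
    if not norm.norm:
        raise UsageError("empty normalized-occurrence table")
    k = max(1, math.floor(fraction * len(norm.norm)))
    ranked = sorted(norm.norm, key=lambda v: (-norm.norm[v], v))
    return ranked[:k]


def weighted_pfm(norm: NormalizedOccurrence, selected: Sequence[str]
                 ) -> LogoMatrix:
    """PFM over the selected PAMs weighted by normalized occurrence."""
    weights = {v: norm.norm[v] for v in selected}
    if all(w == 0 for w in weights.values()):
        # degenerate screen: fall back to unweighted to keep the PFM defined
        return logo_matrix(list(selected))
    return logo_matrix(weights)


def consensus_from_pfm(pfm: LogoMatrix, require_freq: float = 0.9,
                       exclude_freq: float = 0.05, prefer_freq: float = 0.5
                       ) -> tuple[IupacPattern, IupacPattern]:
    """Call (required, preferred) IUPAC consensus strings from a PFM.

    Required string: positions where a single base reaches ``require_freq``
    get that base, otherwise N.  Preferred string additionally excludes
    bases at or below ``exclude_freq`` (IUPAC code over the remaining bases)
    and restricts to bases at or above ``prefer_freq`` where any exist.
    """
    required = []
    preferred = []
    for _, row in pfm.pfm.iterrows():
        top_base = row.idxmax()
        required.append(top_base if row[top_base] >= require_freq else "N")
        if row[top_base] >= require_freq:
            preferred.append(top_base)
            continue
        allowed = {b for b in BASES if row[b] > exclude_freq}
        liked = {b for b in allowed if row[b] >= prefer_freq}
        chosen = liked or allowed or set(BASES)
        preferred.append(IUPAC_FROM_SET[frozenset(chosen)])
    return IupacPattern("".join(required)), IupacPattern("".join(preferred))


# ---------------------------------------------------------------------------
# junction mapping and cut-site inference
# ---------------------------------------------------------------------------

def _scan(fragment: str, context: str, anchor_len: int, max_mismatch: int,
          align: str) -> int | None:
    """Best placement of a fragment edge on the context by Hamming scan.

    ``align='start'`` matches the fragment's first ``anchor_len`` nt at every
    context position and returns the terminus (start) position; ``'end'``
    matches the last ``anchor_len`` nt and returns the exclusive end
    position.  Context ``N`` positions are excluded from the mismatch count.
    Returns None if no placement is within ``max_mismatch`` or the best
    placement is tied.
    """
    m = min(anchor_len, len(fragment))
    if m == 0:
        return None
    probe = fragment[:m] if align == "start" else fragment[-m:]
    best_mm, best_pos, tied = max_mismatch + 1, None, False
    for p in range(len(context) - m + 1):
        mm = 0
        window = context[p:p + m]
        for a, b in zip(window, probe):
            if a != "N" and a != b:
                mm += 1
                if mm > best_mm:
                    break
        else:
            if mm < best_mm:
                best_mm, best_pos, tied = mm, p, False
            elif mm == best_mm:
                tied = True
    if best_pos is None or tied:
        return None
    return best_pos if align == "start" else best_pos + m


def map_junction(read: SeqRecord, context: TargetContext, adapter: str,
                 anchor_len: int = 25, max_mismatch: int = 2
                 ) -> tuple[str, int, str | None] | None:
    """Map one adapter-ligated read onto the target context.

    Returns (strand, terminus, pam) or None if unmappable.  ``strand`` is
    ``+`` when the fragment reads the top strand 5'->3' from its cut (the
    terminus is the fragment start coordinate) and ``-`` when it reads the
    bottom strand (the terminus is the exclusive end coordinate of the
    covered region).  ``pam`` is the read-derived PAM window when the read
    covers it, else None.
    """
    adapter = adapter.upper()
    seq = read.bases
    if not seq.startswith(adapter):
        return None
    frag = seq[len(adapter):]
    if not frag:
        return None
    ctx = context.sequence
    t_top = _scan(frag, ctx, anchor_len, max_mismatch, "start")
    g = revcomp(frag)
    t_bot = _scan(g, ctx, anchor_len, max_mismatch, "end")
    # prefer the orientation that places the whole fragment consistently
    if t_top is not None and t_bot is None:
        strand, terminus, covered_start, oriented = "+", t_top, t_top, frag
    elif t_bot is not None and t_top is None:
        strand, terminus = "-", t_bot
        covered_start, oriented = t_bot - len(g), g
    elif t_top is None and t_bot is None:
        return None
    else:  # both orientations match: ambiguous, drop
        return None
    pam = None
    a, b = context.pam_start, context.pam_end
    lo = covered_start
    hi = covered_start + len(oriented)
    if lo <= a and b <= hi:
        pam = oriented[a - lo:b - lo]
    return strand, terminus, pam


def infer_cut_site(fragment_reads: Sequence[SeqRecord],
                   target_context: TargetContext, adapter: str,
                   anchor_len: int = 25, max_mismatch: int = 2
                   ) -> CutSiteProfile:
    """Infer the cut geometry from the most frequent read termini.

    Each mapped junction read contributes one terminus to its strand's
    histogram (offsets measured from the PAM-proximal protospacer end); the
    modal offset per strand gives the cut position, their absolute
    difference the overhang.
    """
    hist_top: Counter[int] = Counter()
    hist_bot: Counter[int] = Counter()
    unmapped = 0
    pam_start = target_context.pam_start
    for read in fragment_reads:
        hit = map_junction(read, target_context, adapter, anchor_len,
                           max_mismatch)
        if hit is None:
            unmapped += 1
            continue
        strand, terminus, _ = hit
        offset = pam_start - terminus
        (hist_top if strand == "+" else hist_bot)[offset] += 1
    if not hist_top or not hist_bot:
        raise DataError("no cleavage evidence: zero mappable junction reads "
                        "on at least one strand")

    def modal(hist: Counter[int]) -> tuple[int, bool]:
        best = max(hist.values())
        modes = sorted(k for k, v in hist.items() if v == best)
        return modes[0], len(modes) > 1

    mt, amb_t = modal(hist_top)
    mb, amb_b = modal(hist_bot)
    overhang = abs(mt - mb)
    return CutSiteProfile(
        hist_top=dict(sorted(hist_top.items())),
        hist_bottom=dict(sorted(hist_bot.items())),
        modal_offset_top=mt, modal_offset_bottom=mb,
        overhang=overhang,
        end_type="blunt" if overhang == 0 else "staggered",
        ambiguous=amb_t or amb_b, n_unmapped=unmapped)


def predict_fragment_sizes(substrate_len: int, cut_pos: int
                           ) -> tuple[int, int]:
    """Expected cleavage-fragment lengths for a linear substrate.

    A single duplex cut at ``cut_pos`` (0-based, from the substrate 5' end
    on the top strand) yields fragments of ``cut_pos`` and
    ``substrate_len - cut_pos`` bp, the band sizes expected on a gel.
    """
    if not 0 < cut_pos < substrate_len:
        raise UsageError("cut_pos must lie strictly inside the substrate")
    return cut_pos, substrate_len - cut_pos


def count_pams_from_fragments(fragment_reads: Sequence[SeqRecord],
                              target_context: TargetContext, adapter: str,
                              pattern: IupacPattern | str,
                              anchor_len: int = 25, max_mismatch: int = 2
                              ) -> PamCountTable:
    """Tabulate PAM variants carried by junction reads that cover the PAM.

    Only reads whose mapped span includes the whole randomized window
    contribute (for a 3'-of-protospacer PAM these are the PAM-proximal
    fragment's top-strand reads).
    """
    from .seq_io import iupac_match

    pattern = IupacPattern(pattern)
    table = PamCountTable.empty(pattern, label="fragments")
    unassigned = 0
    for read in fragment_reads:
        hit = map_junction(read, target_context, adapter, anchor_len,
                           max_mismatch)
        if hit is None or hit[2] is None:
            unassigned += 1
            continue
        pam = hit[2]
        if len(pam) == len(pattern) and iupac_match(pam, pattern):
            table.counts[pam] += 1
        else:
            unassigned += 1
    table.unassigned = unassigned
    return table
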