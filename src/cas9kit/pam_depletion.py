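"""In vivo PAM-depletion screen analysis.

A PAM-randomized plasmid library is transformed into cells expressing the
nuclease (treatment) or not (control); plasmids whose PAM licenses cleavage
are depleted among transformants.  This module extracts the PAM-region
variant from each read by anchoring on the fixed protospacer, tabulates
per-variant frequencies in both arms, scores depletion as

    log2fc(v) = log2( f_control(v) / f_treatment(v) )

with pseudocounted frequencies f = (count + c) / (total + c*V), selects
variants with log2fc strictly above a threshold (default 7), and summarizes
selected sets as a position frequency matrix with per-position information
content (bits) for sequence-logo rendering.

Sign convention: higher log2fc = more depleted in the treatment arm = more
nuclease-permissive PAM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, UsageError
from .seq_io import IupacPattern, SeqRecord, iupac_match

BASES = "ACGT"


# ---------------------------------------------------------------------------
# count tables
# ---------------------------------------------------------------------------

@dataclass
class PamCountTable:
    """Per-PAM-variant read counts for one sample.

    The variant universe is fixed at construction (every sequence the library
    pattern admits), so zero-count variants are represented explicitly.
    """

    counts: dict[str, int]
    label: str = ""
    unassigned: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def variants(self) -> list[str]:
        return list(self.counts)

    def freqs(self, pseudocount: float = 0.0) -> dict[str, float]:
        """Pseudocounted frequencies f = (count + c) / (total + c*V)."""
        v = len(self.counts)
        denom = self.total + pseudocount * v
        if denom == 0:
            raise UsageError(f"table {self.label!r} is empty and unpseudocounted")
        return {k: (c + pseudocount) / denom for k, c in self.counts.items()}

    @classmethod
    def empty(cls, pattern: IupacPattern | str, label: str = "") -> "PamCountTable":
        return cls({v: 0 for v in IupacPattern(pattern).expand()}, label=label)

    def to_tsv(self, path: str | Path) -> Path:
        df = pd.DataFrame({"variant": list(self.counts),
                           "count": list(self.counts.values())})
        df["frequency"] = df["count"] / max(self.total, 1)
        df.to_csv(path, sep="\t", index=False)
        return Path(path)

    @classmethod
    def from_tsv(cls, path: str | Path, label: str = "") -> "PamCountTable":
        df = pd.read_csv(path, sep="\t")
        return cls(dict(zip(df["variant"], df["count"].astype(int))), label=label)


@dataclass
class DepletionScores:
    """Per-variant log2 fold-change (control over treatment)."""

    scores: dict[str, float]
    pseudocount: float
    treatment_label: str = ""
    control_label: str = ""

    def to_tsv(self, path: str | Path) -> Path:
        df = pd.DataFrame({"variant": list(self.scores),
                           "log2fc": list(self.scores.values())})
        df.to_csv(path, sep="\t", index=False)
        return Path(path)


@dataclass
class LogoMatrix:
    """Position frequency matrix plus per-position information content.

    ``pfm`` is positions x {A,C,G,T} with columns summing to 1 per position;
    ``ic`` is 2 - H(position) in bits, in [0, 2].
    """

    pfm: pd.DataFrame
    ic: pd.Series

    def __post_init__(self) -> None:
        sums = self.pfm.sum(axis=1).to_numpy()
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise UsageError("PFM rows must each sum to 1")

    def to_tsv(self, path: str | Path) -> Path:
        out = self.pfm.copy()
        out["IC_bits"] = self.ic
        out.to_csv(path, sep="\t", index_label="position")
        return Path(path)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def _hamming_find(read: str, anchor: str, max_mismatch: int) -> int:
    """Leftmost position where ``anchor`` matches ``read`` with <= max_mismatch
    substitutions, or -1."""
    la, lr = len(anchor), len(read)
    best = -1
    for i in range(lr - la + 1):
        mm = 0
        window = read[i:i + la]
        for a, b in zip(window, anchor):
            if a != b:
                mm += 1
                if mm > max_mismatch:
                    break
        else:
            return i
    return best


def count_pams(reads: Sequence[SeqRecord], spec, max_anchor_mismatch: int = 1
               ) -> PamCountTable:
    """Tabulate PAM-region variants by anchoring each read on the protospacer.

    ``spec`` is a :class:`~cas9kit.synthetic_data.PamLibrarySpec` (pattern +
    anchor).  The variant is the pattern-length window immediately 3' of the
    anchor on the spacer-matching strand.  Reads whose anchor cannot be
    located within ``max_anchor_mismatch`` substitutions, or whose extracted
    window does not match the library pattern, are counted unassigned.
    """
    pattern = IupacPattern(spec.pattern)
    anchor = spec.anchor.upper()
    if not anchor:
        raise ConfigError("library spec has an empty anchor")
    plen = len(pattern)
    table = PamCountTable.empty(pattern, label=getattr(spec, "label", "sample"))
    unassigned = 0
    for read in reads:
        seq = read.bases
        i = seq.find(anchor)
        if i < 0 and max_anchor_mismatch > 0:
            i = _hamming_find(seq, anchor, max_anchor_mismatch)
        if i < 0:
            unassigned += 1
            continue
        window = seq[i + len(anchor): i + len(anchor) + plen]
        if len(window) == plen and iupac_match(window, pattern):
            table.counts[window] += 1
        else:
            unassigned += 1
    table.unassigned = unassigned
    return table


def depletion_log2fc(treatment: PamCountTable, control: PamCountTable,
                     pseudocount: float = 1.0) -> DepletionScores:
    """log2(f_control / f_treatment) per variant, pseudocounted.

    With ``pseudocount`` 0, variants with a zero count in either arm yield
    +/-inf; the default of 1 read per variant keeps every score finite.
    """
    if set(treatment.counts) != set(control.counts):
        raise UsageError("treatment and control tables cover different "
                         "variant universes")
    f_t = treatment.freqs(pseudocount)
    f_c = control.freqs(pseudocount)
    scores = {}
    for v in treatment.counts:
        if f_t[v] == 0 and f_c[v] == 0:
            scores[v] = 0.0
        elif f_t[v] == 0:
            scores[v] = math.inf
        elif f_c[v] == 0:
            scores[v] = -math.inf
        else:
            scores[v] = math.log2(f_c[v] / f_t[v])
    return DepletionScores(scores, pseudocount,
                           treatment.label, control.label)


def sum_tables(tables: Sequence[PamCountTable], label: str = "pooled"
               ) -> PamCountTable:
    """Pool replicate count tables by summing per-variant counts."""
    if not tables:
        raise UsageError("no tables to pool")
    universe = set(tables[0].counts)
    if any(set(t.counts) != universe for t in tables):
        raise UsageError("replicate tables cover different variant universes")
    pooled = {v: sum(t.counts[v] for t in tables) for v in tables[0].counts}
    return PamCountTable(pooled, label=label)


def depletion_by_replicate(treatments: Sequence[PamCountTable],
                           controls: Sequence[PamCountTable],
                           pseudocount: float = 1.0) -> list[DepletionScores]:
    """Per-replicate depletion scores (default analysis pools replicates)."""
    if len(treatments) != len(controls):
        raise UsageError("unequal numbers of treatment and control replicates")
    return [depletion_log2fc(t, c, pseudocount)
            for t, c in zip(treatments, controls)]


def select_depleted(scores: DepletionScores, threshold: float = 7.0) -> set[str]:
    """Variants with log2 fold-change strictly greater than ``threshold``."""
    return {v for v, s in scores.scores.items() if s > threshold}


def logo_matrix(variants: Iterable[str] | Mapping[str, float]) -> LogoMatrix:
    """PFM and information content from a set (or weighted table) of variants.

    IC per position is 2 - H in bits where H is the Shannon entropy of the
    column; no small-sample correction is applied.
    """
    if isinstance(variants, Mapping):
        items = [(v, w) for v, w in variants.items() if w > 0]
    else:
        items = [(v, 1.0) for v in variants]
    if not items:
        raise UsageError("logo_matrix requires a non-empty variant set")
    lengths = {len(v) for v, _ in items}
    if len(lengths) != 1:
        raise UsageError(f"variants have unequal lengths {sorted(lengths)}")
    (length,) = lengths
    counts = np.zeros((length, 4))
    idx = {b: i for i, b in enumerate(BASES)}
    for v, w in items:
        for j, b in enumerate(v):
            counts[j, idx[b]] += w
    freqs = counts / counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    ic = 2.0 + plogp.sum(axis=1)
    positions = pd.RangeIndex(1, length + 1, name="position")
    return LogoMatrix(pd.DataFrame(freqs, columns=list(BASES), index=positions),
                      pd.Series(ic, index=positions, name="IC_bits"))
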