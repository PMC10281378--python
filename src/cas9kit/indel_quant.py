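"""Amplicon-sequencing INDEL quantification.

Reads are globally aligned to the reference amplicon with affine gap
penalties, classified as indel / SNV-only / wild-type by the variants that
overlap a window around the expected cut site, and summarized as an editing
efficiency (the fraction of reads with indels, excluding reads carrying only
substitutions) plus an allele table in cut-relative notation: ``-2:1D`` is a
1-nt deletion starting 2 nt 5' of the cut, ``+1:2I`` a 2-nt insertion at the
cut.  The cut-relative coordinates match the convention of
:mod:`cas9kit.pam_invitro` (offset from the PAM-proximal protospacer end),
so a cut position derived there can be used here directly.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import Align

from .errors import UsageError
from .seq_io import SeqRecord

#: Default global-alignment scoring (affine gaps; a length-k gap costs
#: open + (k-1) * extend).
DEFAULT_SCORING = {"match": 2, "mismatch": -4, "gap_open": -6, "gap_extend": -1}


@dataclass
class Alignment:
    """A gapped global alignment of read against reference."""

    aligned_ref: str
    aligned_read: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_ref) != len(self.aligned_read):
            raise UsageError("gapped rows must be equal length")


@dataclass
class AlleleCall:
    """Per-read classification around the cut site.

    ``labels`` lists cut-window indel events in cut-relative notation;
    ``class_`` is ``indel`` iff at least one such event exists, ``snv_only``
    if the read carries substitutions (or only out-of-window indels) but no
    in-window indel, and ``wt`` otherwise.  Out-of-window indels are kept in
    ``out_of_window`` for inspection but do not count toward editing.
    """

    read_id: str
    class_: str
    labels: list[str]
    score: float
    n_substitutions: int = 0
    out_of_window: list[str] = field(default_factory=list)

    @property
    def allele(self) -> str:
        return ";".join(self.labels) if self.labels else ""


@dataclass
class EditingSummary:
    """Editing efficiency and the top alleles of one (or pooled) sample(s)."""

    n_reads: int
    n_indel: int
    percent_indel: float
    allele_table: list[tuple[str, int, float]]  # (allele, count, frequency)
    n_dropped: int = 0

    def to_json(self, path: str | Path) -> Path:
        d = {"n_reads": self.n_reads, "n_indel": self.n_indel,
             "percent_indel": self.percent_indel, "n_dropped": self.n_dropped,
             "alleles": [{"allele": a, "count": c, "frequency": f}
                         for a, c, f in self.allele_table]}
        Path(path).write_text(json.dumps(d, indent=1))
        return Path(path)

    def allele_tsv(self, path: str | Path) -> Path:
        df = pd.DataFrame(self.allele_table,
                          columns=["allele", "count", "frequency"])
        df.to_csv(path, sep="\t", index=False)
        return Path(path)


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def _make_aligner(scoring: dict) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring["match"]
    aligner.mismatch_score = scoring["mismatch"]
    aligner.open_gap_score = scoring["gap_open"]
    aligner.extend_gap_score = scoring["gap_extend"]
    return aligner


def _left_normalize_events(ref_row: str, read_row: str) -> tuple[str, str]:
    """Left-align indels by rebuilding the alignment from its event list."""
    ref = ref_row.replace("-", "")
    read = read_row.replace("-", "")
    events = []  # (ref_pos, kind, length, inserted_seq)
    r = q = 0
    i = 0
    n = len(ref_row)
    while i < n:
        if ref_row[i] == "-":
            j = i
            while j < n and ref_row[j] == "-":
                j += 1
            events.append([r, "I", j - i, read_row[i:j]])
            q += j - i
            i = j
        elif read_row[i] == "-":
            j = i
            while j < n and read_row[j] == "-":
                j += 1
            events.append([r, "D", j - i, ""])
            r += j - i
            i = j
        else:
            r += 1
            q += 1
            i += 1
    # shift each event left while the deleted block / insertion context allows
    for ev in events:
        pos, kind, length, ins = ev
        if kind == "D":
            while pos > 0 and ref[pos - 1] == ref[pos + length - 1]:
                pos -= 1
            ev[0] = pos
        else:
            while pos > 0 and ref[pos - 1] == ins[-1]:
                ins = ref[pos - 1] + ins[:-1]
                pos -= 1
            ev[0], ev[3] = pos, ins
    events.sort(key=lambda e: e[0])
    # rebuild rows
    out_ref, out_read = [], []
    r = q = 0
    for pos, kind, length, ins in events:
        while r < pos:
            out_ref.append(ref[r])
            out_read.append(read[q])
            r += 1
            q += 1
        if kind == "D":
            out_ref.append(ref[r:r + length])
            out_read.append("-" * length)
            r += length
        else:
            out_ref.append("-" * length)
            out_read.append(read[q:q + length])
            q += length
    out_ref.append(ref[r:])
    out_read.append(read[q:])
    return "".join(out_ref), "".join(out_read)


def align_amplicon(read: SeqRecord, ref: SeqRecord,
                   scoring: dict | None = None) -> Alignment:
    """Global affine-gap alignment of a read to the reference amplicon.

    Deterministic: the highest-scoring alignment is taken and its gaps are
    then shifted to their leftmost equal-score placement.
    """
    scoring = scoring or DEFAULT_SCORING
    if read.bases == ref.bases:
        return Alignment(ref.bases, read.bases,
                         scoring["match"] * len(ref.bases))
    aligner = _make_aligner(scoring)
    aln = aligner.align(ref.bases, read.bases)[0]
    ref_row, read_row = str(aln[0]), str(aln[1])
    ref_row, read_row = _left_normalize_events(ref_row, read_row)
    return Alignment(ref_row, read_row, float(aln.score))


# ---------------------------------------------------------------------------
# allele calling
# ---------------------------------------------------------------------------

def _format_label(ref_idx: int, cut_pos: int, length: int, kind: str) -> str:
    pos = ref_idx - cut_pos if ref_idx < cut_pos else ref_idx - cut_pos + 1
    sign = "+" if pos > 0 else ""
    return f"{sign}{pos}:{length}{kind}"


def call_allele(alignment: Alignment, cut_pos: int, window: int = 5,
                read_id: str = "") -> AlleleCall:
    """Classify one aligned read by the variants around the cut site.

    Indel events whose span touches cut-relative positions -window..+window
    are labeled (deletions by their leftmost deleted base, insertions by the
    position of the base they precede, so ``+1`` is an insertion exactly at
    the cut).  Reads with no in-window indel but any substitution are
    ``snv_only``; reads with neither are ``wt``.
    """
    ref_len = len(alignment.aligned_ref.replace("-", ""))
    if not 0 <= cut_pos <= ref_len:
        raise UsageError("cut_pos outside the reference")
    lo_idx = cut_pos - window       # smallest in-window ref index
    hi_idx = cut_pos + window - 1   # largest in-window ref index
    labels: list[str] = []
    outside: list[str] = []
    n_sub = 0
    r = 0
    i = 0
    n = len(alignment.aligned_ref)
    while i < n:
        a, b = alignment.aligned_ref[i], alignment.aligned_read[i]
        if a == "-":
            j = i
            while j < n and alignment.aligned_ref[j] == "-":
                j += 1
            length = j - i
            label = _format_label(r, cut_pos, length, "I")
            # insertion sits between ref[r-1] and ref[r]
            if lo_idx <= r <= hi_idx:
                labels.append(label)
            else:
                outside.append(label)
            i = j
        elif b == "-":
            j = i
            while j < n and alignment.aligned_read[j] == "-":
                j += 1
            length = j - i
            label = _format_label(r, cut_pos, length, "D")
            if r <= hi_idx and r + length - 1 >= lo_idx:
                labels.append(label)
            else:
                outside.append(label)
            r += length
            i = j
        else:
            if a != b:
                n_sub += 1
            r += 1
            i += 1
    if labels:
        cls = "indel"
    elif n_sub or outside:
        cls = "snv_only" if n_sub else "wt"
    else:
        cls = "wt"
    return AlleleCall(read_id, cls, labels, alignment.score, n_sub, outside)


# ---------------------------------------------------------------------------
# summary
# ---------------------------------------------------------------------------

def summarize_editing(calls: Sequence[AlleleCall] | Sequence[Sequence[AlleleCall]],
                      top_k: int = 10) -> EditingSummary:
    """Editing efficiency and allele table from per-read calls.

    ``percent_indel`` counts only reads of class ``indel``; SNV-only reads
    are excluded from the numerator but kept in the denominator.  Passing a
    list of per-replicate call lists averages percent and allele frequencies
    over replicates; counts are summed.
    """
    if not calls:
        raise UsageError("no allele calls to summarize")
    replicates: list[Sequence[AlleleCall]]
    if isinstance(calls[0], AlleleCall):
        replicates = [calls]  # type: ignore[list-item]
    else:
        replicates = list(calls)  # type: ignore[assignment]
        if any(not rep for rep in replicates):
            raise UsageError("empty replicate in call set")

    percents = []
    freq_acc: Counter[str] = Counter()
    count_acc: Counter[str] = Counter()
    n_reads = n_indel = 0
    for rep in replicates:
        n = len(rep)
        indels = [c for c in rep if c.class_ == "indel"]
        percents.append(100.0 * len(indels) / n)
        n_reads += n
        n_indel += len(indels)
        rep_counts = Counter(c.allele for c in indels)
        for allele, cnt in rep_counts.items():
            count_acc[allele] += cnt
            freq_acc[allele] += cnt / n / len(replicates)
    percent = sum(percents) / len(percents)
    table = sorted(((a, count_acc[a], freq_acc[a]) for a in freq_acc),
                   key=lambda t: (-t[2], t[0]))[:top_k]
    return EditingSummary(n_reads, n_indel, percent, table)


def subtract_background(sample: EditingSummary, control: EditingSummary
                        ) -> float:
    """Editing efficiency with a non-transfected control subtracted.

    Returns ``max(0, sample.percent_indel - control.percent_indel)``: the
    control pool estimates the rate of spontaneous/artifactual indels.  The
    default analysis excludes SNV-only reads without subtraction; this is
    the optional control-subtraction mode.
    """
    return max(0.0, sample.percent_indel - control.percent_indel)


def quantify_amplicons(reads: Sequence[SeqRecord], ref: SeqRecord,
                       cut_pos: int, window: int = 5,
                       scoring: dict | None = None, min_score: float = 0.0,
                       top_k: int = 10
                       ) -> tuple[EditingSummary, list[AlleleCall]]:
    """Align, call and summarize one amplicon pool.

    Reads whose alignment score falls below ``min_score`` are dropped (and
    counted in the summary) rather than classified.
    """
    calls: list[AlleleCall] = []
    dropped = 0
    for read in reads:
        aln = align_amplicon(read, ref, scoring)
        if aln.score < min_score:
            dropped += 1
            continue
        calls.append(call_allele(aln, cut_pos, window, read.id))
    if not calls:
        raise UsageError("all reads were dropped; nothing to summarize")
    summary = summarize_editing(calls, top_k=top_k)
    summary.n_dropped = dropped
    return summary, calls
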