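"""Sequence I/O, IUPAC pattern matching, and barcode demultiplexing.

All other stages consume the :class:`SeqRecord` type defined here.  FASTA and
FASTQ (Phred+33) parsing is delegated to Biopython; records are validated and
uppercased on load.  Qualities are carried through round trips but never used
for filtering.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from .errors import ConfigError, ParseError, UsageError

#: Expansion of each IUPAC nucleotide code into the plain bases it admits.
IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

#: Inverse map: frozenset of admitted bases -> IUPAC code.
IUPAC_FROM_SET: dict[frozenset, str] = {
    frozenset(v): k for k, v in IUPAC_CODES.items()
}

_VALID_BASES = set("ACGTN")
_RC = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware)."""
    return seq.translate(_RC)[::-1]


@dataclass
class SeqRecord:
    """A nucleotide sequence with optional Phred-scale qualities.

    Invariants: ``bases`` is uppercase over {A,C,G,T,N}; when ``quals`` is
    present its length equals ``len(bases)``.
    """

    id: str
    bases: str
    quals: list[int] | None = None

    def __post_init__(self) -> None:
        if self.quals is not None and len(self.quals) != len(self.bases):
            raise UsageError(
                f"record {self.id!r}: {len(self.quals)} qualities for "
                f"{len(self.bases)} bases"
            )

    def __len__(self) -> int:
        return len(self.bases)


class IupacPattern(str):
    """A degenerate nucleotide pattern over the 15 IUPAC codes.

    Behaves as a string; construction validates every symbol.
    """

    def __new__(cls, symbols: str) -> "IupacPattern":
        symbols = str(symbols).upper()
        bad = [s for s in symbols if s not in IUPAC_CODES]
        if bad:
            raise UsageError(f"invalid IUPAC symbol(s) {bad!r} in pattern {symbols!r}")
        if not symbols:
            raise UsageError("empty IUPAC pattern")
        return super().__new__(cls, symbols)

    def expand(self) -> list[str]:
        """Enumerate every plain-base sequence the pattern admits (lexicographic)."""
        return ["".join(t) for t in itertools.product(
            *(sorted(IUPAC_CODES[s]) for s in self))]

    def n_variants(self) -> int:
        n = 1
        for s in self:
            n *= len(IUPAC_CODES[s])
        return n


def iupac_match(seq: str, pattern: str) -> bool:
    """True iff every base of ``seq`` is admitted by the matching pattern symbol.

    ``seq`` must be over {A,C,G,T} and equal in length to ``pattern``.
    """
    if len(seq) != len(pattern):
        raise UsageError(
            f"sequence length {len(seq)} != pattern length {len(pattern)}")
    return all(b in IUPAC_CODES[p] for b, p in zip(seq, pattern))


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_FORMATS = ("fasta", "fastq")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".fa", ".fasta", ".fna"):
        return "fasta"
    if suffix in (".fq", ".fastq"):
        return "fastq"
    raise UsageError(f"cannot infer sequence format from {path.name!r}; "
                     "pass format='fasta' or 'fastq'")


def read_seq_file(path: str | Path, format: str | None = None) -> list[SeqRecord]:
    """Read a FASTA or FASTQ file into a list of :class:`SeqRecord`.

    Bases are uppercased; characters outside the IUPAC alphabet are a
    :class:`ParseError` naming the record and line.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise UsageError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
    if not path.exists():
        raise UsageError(f"no such file: {path}")
    records: list[SeqRecord] = []
    lines_per_record = 4 if fmt == "fastq" else None
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), fmt)):
            bases = str(rec.seq).upper()
            bad = set(bases) - set(IUPAC_CODES)
            if bad:
                line = 1 + i * lines_per_record + 1 if lines_per_record else None
                where = f" (near line {line})" if line else ""
                raise ParseError(
                    f"{path}: record {rec.id!r}{where} contains invalid "
                    f"characters {sorted(bad)!r}")
            quals = None
            if fmt == "fastq":
                quals = list(rec.letter_annotations["phred_quality"])
            records.append(SeqRecord(rec.id, bases, quals))
    except ParseError:
        raise
    except ValueError as exc:  # Biopython's malformed-record errors
        raise ParseError(f"{path}: malformed {fmt} record "
                         f"(after record {len(records)}): {exc}") from exc
    return records


def write_seq_file(records: Iterable[SeqRecord], path: str | Path,
                   format: str | None = None) -> Path:
    """Write records as FASTA or FASTQ (Phred+33).

    FASTQ records lacking qualities are written with Q40 throughout.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    bio = []
    for r in records:
        b = _BioRecord(Seq(r.bases), id=r.id, description="")
        if fmt == "fastq":
            b.letter_annotations["phred_quality"] = (
                r.quals if r.quals is not None else [40] * len(r.bases))
        bio.append(b)
    SeqIO.write(bio, str(path), fmt)
    return path


# ---------------------------------------------------------------------------
# demultiplexing
# ---------------------------------------------------------------------------

def read_barcode_tsv(path: str | Path) -> dict[str, str]:
    """Two-column TSV (label, barcode sequence) -> mapping."""
    barcodes: dict[str, str] = {}
    for n, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(f"{path}: line {n}: expected 2 tab-separated "
                             f"columns, got {len(parts)}")
        barcodes[parts[0]] = parts[1].upper()
    return barcodes


def demultiplex(
    reads: Sequence[SeqRecord], barcodes: Mapping[str, str]
) -> tuple[dict[str, list[SeqRecord]], list[SeqRecord]]:
    """Assign reads to bins by exact barcode prefix match.

    Barcodes must be equal-length and mutually distinct.  A read is assigned
    iff its prefix equals exactly one barcode; others land in the unassigned
    bin.  Bin sizes plus unassigned always sum to the input size.
    """
    seqs = list(barcodes.values())
    if len(set(seqs)) != len(seqs):
        raise ConfigError("duplicate barcode sequences")
    if len(set(map(len, seqs))) > 1:
        raise ConfigError("barcodes must be equal length")
    by_seq = {v: k for k, v in barcodes.items()}
    width = len(seqs[0]) if seqs else 0
    bins: dict[str, list[SeqRecord]] = {label: [] for label in barcodes}
    unassigned: list[SeqRecord] = []
    for read in reads:
        label = by_seq.get(read.bases[:width]) if width else None
        if label is None:
            unassigned.append(read)
        else:
            bins[label].append(read)
    return bins, unassigned
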