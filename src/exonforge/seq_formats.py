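"""Core coordinate types, design parameters and readers/writers.

All internal coordinates are 0-based half-open; conversion to/from the
1-based inclusive convention of GFF3 happens only at the I/O boundary.
Soft-masking state travels both as lowercase letters inside sequence
strings and as explicit interval records; the interval records are
authoritative for overlap arithmetic.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "Read",
    "GenomicInterval",
    "DesignParams",
    "FormatError",
    "read_fasta_qual",
    "write_fasta_qual",
    "read_gff3_track",
    "write_gff3",
    "read_bed",
    "write_bed",
    "write_tsv_ledger",
    "read_tsv_ledger",
]

#: IUPAC nucleotide one-letter codes (upper and lower case both legal;
#: lowercase denotes soft-masked positions).
IUPAC_NT = set("ACGTURYSWKMBDHVN") | set("acgturyswkmbdhvn")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class Read:
    """A named nucleotide sequence with optional per-base phred qualities.

    ``tags`` is a free-form set of status labels used by the cleaning
    cascade and by synthetic-truth bookkeeping.  Case of ``bases`` is
    preserved: lowercase marks soft-masked positions.
    """

    id: str
    bases: str
    quals: Optional[List[int]] = None
    tags: set = field(default_factory=set)

    def __post_init__(self) -> None:
        bad = set(self.bases) - IUPAC_NT
        if bad:
            raise FormatError(
                f"record {self.id!r}: non-IUPAC characters {sorted(bad)!r}"
            )
        if self.quals is not None and len(self.quals) != len(self.bases):
            raise FormatError(
                f"record {self.id!r}: {len(self.quals)} quality values for "
                f"{len(self.bases)} bases"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a named sequence.

    ``strand`` is ``+``, ``-`` or ``?`` (unknown / unstranded).
    """

    seq_id: str
    start: int
    end: int
    strand: str = "?"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.seq_id}"
            )
        if self.strand not in ("+", "-", "?"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )

    def shifted(self, offset: int) -> "GenomicInterval":
        return replace(self, start=self.start + offset, end=self.end + offset)


@dataclass(frozen=True)
class DesignParams:
    """Every numeric threshold of the array-design pipeline in one place.

    Defaults are the published design rules: reads shorter than 100 bp or
    with more than 3% undetermined bases are discarded, 60 bp are trimmed
    from each read end, exonic regions must be at least 60 bp and are
    penalized below 100 bp, EST ORFs must reach 150 bp, redundancy is
    called at 98% identity, regions more than 25% covered by repeats are
    dropped, and each exon receives four 25-mer probes.
    """

    min_read_len: int = 100
    max_ambiguity_frac: float = 0.03
    end_trim: int = 60
    min_exon_len: int = 60
    short_exon_penalty_len: int = 100
    min_orf_len: int = 150
    redundancy_identity: float = 0.98
    max_repeat_overlap_frac: float = 0.25
    probes_per_exon: int = 4
    probe_len: int = 25

    def __post_init__(self) -> None:
        for name in (
            "min_read_len",
            "end_trim",
            "min_exon_len",
            "short_exon_penalty_len",
            "min_orf_len",
            "probes_per_exon",
            "probe_len",
        ):
            v = getattr(self, name)
            if not (isinstance(v, int) and v > 0):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        for name in ("max_ambiguity_frac", "redundancy_identity", "max_repeat_overlap_frac"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v!r}")


# ---------------------------------------------------------------------------
# FASTA / QUAL


def read_fasta_qual(
    fasta_path, qual_path=None
) -> List[Read]:
    """Read a FASTA file, optionally pairing it with a phred ``.qual`` file.

    When both files are given their records must appear in the same order
    with identical ids; a mismatch raises :class:`FormatError` naming the
    offending records.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    quals: Dict[int, List[int]] = {}
    if qual_path is not None:
        qrecords = list(SeqIO.parse(str(qual_path), "qual"))
        if len(qrecords) != len(records):
            raise FormatError(
                f"{len(records)} fasta records but {len(qrecords)} qual records"
            )
        for i, (fr, qr) in enumerate(zip(records, qrecords)):
            if fr.id != qr.id:
                raise FormatError(
                    f"fasta/qual id mismatch at record {i}: {fr.id!r} vs {qr.id!r}"
                )
            quals[i] = list(qr.letter_annotations["phred_quality"])
    reads = []
    for i, rec in enumerate(records):
        reads.append(Read(id=rec.id, bases=str(rec.seq), quals=quals.get(i)))
    return reads


def write_fasta_qual(reads: Sequence[Read], fasta_path, qual_path=None) -> None:
    """Write reads as FASTA (and, when requested, a matching ``.qual``)."""
    with open(fasta_path, "w") as fh:
        for r in reads:
            fh.write(f">{r.id}\n{r.bases}\n")
    if qual_path is not None:
        with open(qual_path, "w") as fh:
            for r in reads:
                if r.quals is None:
                    raise ValueError(f"read {r.id!r} has no qualities to write")
                fh.write(f">{r.id}\n")
                fh.write(" ".join(str(q) for q in r.quals) + "\n")


# ---------------------------------------------------------------------------
# GFF3

_GFF3_COLS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes",
]


def read_gff3_track(path, source_label: Optional[str] = None) -> List[GenomicInterval]:
    """Read a GFF3 file as a flat evidence track of intervals.

    GFF3 coordinates (1-based, inclusive) are converted to the internal
    0-based half-open convention; strand ``.`` becomes ``?``.  The file's
    feature types and attributes are ignored — a track is just intervals.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None, names=_GFF3_COLS,
            dtype={"seqid": str, "strand": str}, na_filter=False,
        )
    except pd.errors.EmptyDataError:
        return []
    intervals: List[GenomicInterval] = []
    for row in df.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        if end < start:
            raise FormatError(
                f"{path.name}: end < start ({end} < {start}) on {row.seqid}"
            )
        strand = row.strand if row.strand in ("+", "-") else "?"
        intervals.append(
            GenomicInterval(seq_id=str(row.seqid), start=start - 1, end=end, strand=strand)
        )
    return intervals


def write_gff3(
    intervals: Iterable[GenomicInterval],
    path,
    source: str = "exonforge",
    feature_type: str = "region",
    attributes: Optional[Sequence[str]] = None,
) -> None:
    """Write intervals as GFF3 (converting back to 1-based inclusive)."""
    intervals = list(intervals)
    if attributes is None:
        attributes = ["." for _ in intervals]
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for iv, attr in zip(intervals, attributes):
            strand = iv.strand if iv.strand in ("+", "-") else "."
            fh.write(
                f"{iv.seq_id}\t{source}\t{feature_type}\t{iv.start + 1}\t{iv.end}"
                f"\t.\t{strand}\t.\t{attr}\n"
            )


# ---------------------------------------------------------------------------
# BED


def write_bed(intervals: Iterable[GenomicInterval], path, names=None) -> None:
    """Write 0-based half-open BED (3 or 6 columns, 6 when any strand known)."""
    intervals = list(intervals)
    if names is None:
        names = [f"iv{i}" for i in range(len(intervals))]
    stranded = any(iv.strand in ("+", "-") for iv in intervals)
    with open(path, "w") as fh:
        for iv, name in zip(intervals, names):
            if stranded:
                strand = iv.strand if iv.strand in ("+", "-") else "."
                fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{name}\t0\t{strand}\n")
            else:
                fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\n")


def read_bed(path) -> List[GenomicInterval]:
    intervals: List[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"BED line with {len(fields)} fields: {line!r}")
            strand = "?"
            if len(fields) >= 6 and fields[5] in ("+", "-"):
                strand = fields[5]
            intervals.append(
                GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand)
            )
    return intervals


# ---------------------------------------------------------------------------
# TSV ledgers


def write_tsv_ledger(ledger: Dict[str, int], path) -> None:
    """Write a category→count mapping as a two-column TSV (lossless)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["category", "count"])
        for key, value in ledger.items():
            w.writerow([key, value])


def read_tsv_ledger(path) -> Dict[str, int]:
    out: Dict[str, int] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != ["category", "count"]:
            raise FormatError(f"unexpected ledger header {header!r}")
        for row in reader:
            out[row[0]] = int(row[1])
    return out
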