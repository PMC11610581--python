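"""Shared coordinate types and plain-text genomics I/O.

All coordinates are 0-based half-open (BED/PAF convention) everywhere in the
package; any 1-based representation is display formatting only.  Minus-strand
intervals store coordinates on the forward strand of ``seq_name`` — the strand
is orientation metadata, matching PAF semantics.

Supported formats: FASTA / FASTQ (Phred+33), BED (3/4/6 columns), PAF
(12 mandatory columns plus optional typed tags), and TSV result tables.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger("tandemdup")


class ParseError(ValueError):
    """A malformed line in an input file; the message names the line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval on a named sequence.

    ``strand`` is orientation metadata: coordinates always refer to the
    forward strand of ``seq_name``.
    """

    seq_name: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.seq_name}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def __len__(self) -> int:
        return self.length

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_name == other.seq_name
            and self.start < other.end
            and other.start < self.end
        )

    def shifted(self, offset: int) -> "GenomicInterval":
        return replace(self, start=self.start + offset, end=self.end + offset)


@dataclass(frozen=True)
class AlignmentRecord:
    """One pairwise alignment in PAF terms.

    The relative orientation of query vs target lives on ``query.strand``
    (the target interval is always '+').  ``score`` defaults to the package's
    declared scoring scheme (match +1, mismatch -2) when no score tag is
    present in the input; ``mismatches`` likewise defaults to
    ``aln_len - matches`` when no NM tag is present.
    """

    query: GenomicInterval
    target: GenomicInterval
    query_len: int
    target_len: int
    matches: int
    aln_len: int
    mapq: int = 60
    score: Optional[int] = None
    mismatches: Optional[int] = None

    def __post_init__(self) -> None:
        if self.matches > self.aln_len:
            raise ValueError("matches exceed alignment length")
        if self.query.length > self.query_len:
            raise ValueError("query interval exceeds query length")
        if self.target.length > self.target_len:
            raise ValueError("target interval exceeds target length")
        if self.mismatches is None:
            object.__setattr__(self, "mismatches", self.aln_len - self.matches)
        if self.score is None:
            object.__setattr__(self, "score", self.matches - 2 * self.mismatches)


@dataclass
class SequenceRecord:
    """A named sequence with optional per-base Phred qualities."""

    name: str
    bases: str
    qualities: Optional[tuple[int, ...]] = None

    def __post_init__(self) -> None:
        if self.qualities is not None and len(self.qualities) != len(self.bases):
            raise ValueError(
                f"record {self.name}: {len(self.qualities)} qualities for "
                f"{len(self.bases)} bases"
            )

    def __len__(self) -> int:
        return len(self.bases)

    def mean_accuracy(self) -> Optional[float]:
        """Read accuracy as 1 - mean per-base error probability.

        This is the mean of error probabilities converted back from Phred,
        not the mean of Phred values, so a read advertised at Q30 throughout
        has accuracy exactly 0.999.
        """
        if self.qualities is None:
            return None
        q = np.asarray(self.qualities, dtype=float)
        return float(1.0 - np.mean(10.0 ** (-q / 10.0)))


# ---------------------------------------------------------------------------
# PAF

_PAF_MIN_COLS = 12


def read_paf(path: str | Path) -> list[AlignmentRecord]:
    """Read a PAF file into AlignmentRecords.

    Optional typed tags ``AS:i`` (score) and ``NM:i`` (per-base differences)
    are honoured when present; otherwise score and mismatches are derived
    (score = matches - 2*mismatches, mismatches = aln_len - matches).
    """
    records: list[AlignmentRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < _PAF_MIN_COLS:
                raise ParseError(
                    f"{path}: line {lineno}: expected >= {_PAF_MIN_COLS} "
                    f"columns, got {len(cols)}"
                )
            try:
                qname, qlen, qstart, qend = cols[0], int(cols[1]), int(cols[2]), int(cols[3])
                strand = cols[4]
                tname, tlen, tstart, tend = cols[5], int(cols[6]), int(cols[7]), int(cols[8])
                matches, aln_len, mapq = int(cols[9]), int(cols[10]), int(cols[11])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            if min(qlen, qstart, tlen, tstart, matches, aln_len, mapq) < 0:
                raise ParseError(f"{path}: line {lineno}: negative field")
            score: Optional[int] = None
            mismatches: Optional[int] = None
            for tag in cols[_PAF_MIN_COLS:]:
                parts = tag.split(":", 2)
                if len(parts) != 3:
                    continue
                name, typ, value = parts
                if name == "AS" and typ == "i":
                    score = int(value)
                elif name == "NM" and typ == "i":
                    mismatches = int(value)
            try:
                rec = AlignmentRecord(
                    query=GenomicInterval(qname, qstart, qend, strand),
                    target=GenomicInterval(tname, tstart, tend, "+"),
                    query_len=qlen,
                    target_len=tlen,
                    matches=matches,
                    aln_len=aln_len,
                    mapq=mapq,
                    score=score,
                    mismatches=mismatches,
                )
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            records.append(rec)
    logger.info("read_paf: %d records from %s", len(records), path)
    return records


def write_paf(records: Iterable[AlignmentRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            cols = [
                r.query.seq_name,
                str(r.query_len),
                str(r.query.start),
                str(r.query.end),
                r.query.strand,
                r.target.seq_name,
                str(r.target_len),
                str(r.target.start),
                str(r.target.end),
                str(r.matches),
                str(r.aln_len),
                str(r.mapq),
                f"NM:i:{r.mismatches}",
                f"AS:i:{r.score}",
            ]
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# FASTA / FASTQ

def read_fastx(path: str | Path) -> list[SequenceRecord]:
    """Read FASTA or FASTQ; the dialect is detected from the first character.

    FASTQ records carry Phred+33 qualities; FASTA records carry none.
    """
    with open(path) as fh:
        first = fh.read(1)
    if first == "":
        return []
    if first == ">":
        fmt = "fasta"
    elif first == "@":
        fmt = "fastq"
    else:
        raise ParseError(f"{path}: line 1: not FASTA or FASTQ (starts {first!r})")
    out: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), fmt):
        quals = None
        if fmt == "fastq":
            quals = tuple(rec.letter_annotations["phred_quality"])
        out.append(SequenceRecord(rec.id, str(rec.seq), quals))
    logger.info("read_fastx: %d records from %s (%s)", len(out), path, fmt)
    return out


def write_fastx(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write FASTQ if every record has qualities, else FASTA."""
    records = list(records)
    fmt = "fastq" if records and all(r.qualities is not None for r in records) else "fasta"
    bio = []
    for r in records:
        b = _BioSeqRecord(Seq(r.bases), id=r.name, description="")
        if fmt == "fastq":
            b.letter_annotations["phred_quality"] = list(r.qualities)
        bio.append(b)
    SeqIO.write(bio, str(path), fmt)


# ---------------------------------------------------------------------------
# BED

def read_bed(path: str | Path) -> list[tuple[GenomicInterval, str]]:
    """Read 3/4/6-column BED into (interval, label) pairs.

    Overlapping intervals are preserved, never merged.  The label is the 4th
    column when present, else ``""``; a 6th column sets the strand.
    """
    out: list[tuple[GenomicInterval, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ParseError(f"{path}: line {lineno}: fewer than 3 columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            strand = cols[5] if len(cols) >= 6 else "+"
            if strand in ("−",):  # tolerate unicode minus
                strand = "-"
            try:
                iv = GenomicInterval(cols[0], start, end, strand)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            label = cols[3] if len(cols) >= 4 else ""
            out.append((iv, label))
    logger.info("read_bed: %d intervals from %s", len(out), path)
    return out


def write_bed(
    entries: Iterable[tuple[GenomicInterval, str]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for iv, label in entries:
            fh.write(
                f"{iv.seq_name}\t{iv.start}\t{iv.end}\t{label or '.'}\t0\t{iv.strand}\n"
            )


def phred_string(qualities: Sequence[int]) -> str:
    return "".join(chr(33 + q) for q in qualities)


def accuracy_to_phred(accuracy: float, cap: int = 60) -> int:
    """Phred score whose error probability equals 1 - accuracy (capped)."""
    err = max(1.0 - accuracy, 10.0 ** (-cap / 10.0))
    return min(cap, int(round(-10.0 * math.log10(err))))
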