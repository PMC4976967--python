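"""Readers and writers for the external representations the pipeline touches.

All other modules exchange the domain types defined here (``SequenceRecord``,
``Interval``, ``TaxonomyRow``, ``ReadPair``); no downstream code parses files.

Coordinate convention: 0-based, half-open everywhere. BED is native; SAM
positions are converted on read.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd
import pysam

DNA_ALPHABET = frozenset("ACGTN")


class FormatError(ValueError):
    """Raised for malformed input files."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named sequence with optional phred33 quality string."""

    id: str
    sequence: str
    quality: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise FormatError(
                f"record {self.id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Interval:
    """0-based half-open interval on a named sequence."""

    seq_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise FormatError(
                f"invalid interval {self.seq_id}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class TaxonomyRow:
    seq_id: str
    superkingdom: str
    genus: str


@dataclass
class ReadPair:
    """Two mates of a paired-end fragment; the unit of classification."""

    id: str
    mate1: SequenceRecord
    mate2: SequenceRecord
    expected_read_length: int = 0
    # (mean, tolerance) of the library fragment size, in bp
    expected_fragment: tuple[float, float] = (0.0, 0.0)


@dataclass(frozen=True)
class Anchor:
    """Reference placement of the mapped mate of a half-mapped pair."""

    interval: Interval
    strand: str  # '+' or '-'
    mapped_mate: int = 1  # 1 or 2: which mate of the pair carries the anchor


COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def read_fastq(path: str | os.PathLike) -> Iterator[SequenceRecord]:
    """Stream 4-line FASTQ records, qualities preserved byte-exact.

    Malformed records raise :class:`FormatError` naming the offending line.
    """
    with open(path, "rt") as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lineno += 1
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise FormatError(f"{path}: line {lineno}: expected '@' header")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline().rstrip("\n")
            qual = fh.readline().rstrip("\n")
            if not plus.startswith("+"):
                raise FormatError(f"{path}: line {lineno + 2}: missing '+' line")
            if len(qual) != len(seq):
                raise FormatError(
                    f"{path}: line {lineno + 3}: quality length {len(qual)} "
                    f"!= sequence length {len(seq)}"
                )
            lineno += 3
            rid = header[1:].split()[0] if len(header) > 1 else ""
            yield SequenceRecord(rid, seq.upper(), qual)


def write_fastq(records: Iterable[SequenceRecord], path: str | os.PathLike) -> None:
    with open(path, "wt") as fh:
        for rec in records:
            if rec.quality is None:
                raise FormatError(f"record {rec.id!r} has no quality; cannot write FASTQ")
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{rec.quality}\n")


def read_fastq_pairs(
    r1_path: str | os.PathLike,
    r2_path: str | os.PathLike,
    expected_read_length: int = 0,
    expected_fragment: tuple[float, float] = (0.0, 0.0),
) -> Iterator[ReadPair]:
    """Pair two FASTQ files by record order, checking id prefixes agree.

    Ids may carry ``/1`` ``/2`` suffixes; the shared prefix must match.
    """
    it1, it2 = read_fastq(r1_path), read_fastq(r2_path)
    for i, (m1, m2) in enumerate(zip(it1, it2)):
        p1 = m1.id.split("/")[0]
        p2 = m2.id.split("/")[0]
        if p1 != p2:
            raise FormatError(
                f"record {i}: mate ids {m1.id!r} / {m2.id!r} do not share a prefix"
            )
        yield ReadPair(p1, m1, m2, expected_read_length, expected_fragment)
    for leftover in (it1, it2):
        try:
            next(leftover)
        except StopIteration:
            continue
        raise FormatError("paired FASTQ files have unequal record counts")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(
    path: str | os.PathLike, allow_n: bool = False
) -> Iterator[SequenceRecord]:
    """Stream FASTA records; sequences uppercased and alphabet-checked.

    ``allow_n=False`` rejects N so reference sequences feeding k-mer indexes
    stay unambiguous.
    """
    allowed = DNA_ALPHABET if allow_n else frozenset("ACGT")
    seen: set[str] = set()
    rid: Optional[str] = None
    chunks: list[str] = []

    def finish() -> SequenceRecord:
        seq = "".join(chunks).upper()
        bad = set(seq) - allowed
        if bad:
            raise FormatError(
                f"{path}: record {rid!r} has characters outside alphabet: "
                f"{sorted(bad)}"
            )
        return SequenceRecord(rid, seq)

    with open(path, "rt") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if rid is not None:
                    yield finish()
                rid = line[1:].split()[0]
                if rid in seen:
                    raise FormatError(f"{path}: duplicate sequence id {rid!r}")
                seen.add(rid)
                chunks = []
            elif line:
                if rid is None:
                    raise FormatError(f"{path}: sequence data before first header")
                chunks.append(line)
    if rid is not None:
        yield finish()


def write_fasta(
    records: Iterable[SequenceRecord], path: str | os.PathLike, width: int = 80
) -> None:
    with open(path, "wt") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

def extract_unmapped_pairs(
    sam_path: str | os.PathLike,
) -> tuple[list[ReadPair], list[tuple[ReadPair, Anchor]]]:
    """Partition primary SAM pairs into both-unmapped and half-mapped sets.

    Fully mapped pairs are dropped. Secondary/supplementary records are
    ignored. The half-mapped anchor reports the mapped mate's reference
    interval and strand. A QNAME with other than two primary records is an
    error.
    """
    by_name: dict[str, list[pysam.AlignedSegment]] = {}
    with pysam.AlignmentFile(os.fspath(sam_path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary:
                continue
            by_name.setdefault(rec.query_name, []).append(rec)

        both_unmapped: list[ReadPair] = []
        half_mapped: list[tuple[ReadPair, Anchor]] = []
        for qname, recs in by_name.items():
            if len(recs) != 2:
                raise FormatError(
                    f"{sam_path}: QNAME {qname!r} has {len(recs)} primary records"
                )
            first = next((r for r in recs if r.is_read1), recs[0])
            second = recs[1] if recs[0] is first else recs[0]
            mates = []
            for r in (first, second):
                seq = r.query_sequence or ""
                qual = (
                    "".join(chr(q + 33) for q in r.query_qualities)
                    if r.query_qualities is not None
                    else "I" * len(seq)
                )
                if r.is_mapped and r.is_reverse:
                    # store mate in sequencing (original read) orientation
                    seq, qual = revcomp(seq), qual[::-1]
                mates.append(SequenceRecord(qname, seq, qual))
            pair = ReadPair(qname, mates[0], mates[1])
            unmapped = [r.is_unmapped for r in (first, second)]
            if all(unmapped):
                both_unmapped.append(pair)
            elif any(unmapped):
                mapped = second if unmapped[0] else first
                anchor = Anchor(
                    Interval(
                        fh.get_reference_name(mapped.reference_id),
                        mapped.reference_start,
                        mapped.reference_end,
                    ),
                    "-" if mapped.is_reverse else "+",
                    mapped_mate=2 if unmapped[0] else 1,
                )
                half_mapped.append((pair, anchor))
            # fully mapped pairs dropped
    return both_unmapped, half_mapped


def write_half_mapped_sam(
    pairs: Sequence[tuple[ReadPair, Anchor]],
    reference_lengths: dict[str, int],
    path: str | os.PathLike,
) -> None:
    """Write half-mapped pairs as minimal SAM text (mapped mate anchored)."""
    with open(path, "wt") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, length in reference_lengths.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for pair, anchor in pairs:
            seq1, qual1 = pair.mate1.sequence, pair.mate1.quality or "I" * len(pair.mate1)
            seq2, qual2 = pair.mate2.sequence, pair.mate2.quality or "I" * len(pair.mate2)
            # convention: mate1 mapped (anchor), mate2 unmapped
            flag1 = 0x1 | 0x8 | 0x40 | (0x10 if anchor.strand == "-" else 0)
            if anchor.strand == "-":
                seq1, qual1 = revcomp(seq1), qual1[::-1]
            cigar = f"{len(seq1)}M"
            fh.write(
                f"{pair.id}\t{flag1}\t{anchor.interval.seq_id}\t"
                f"{anchor.interval.start + 1}\t60\t{cigar}\t*\t0\t0\t{seq1}\t{qual1}\n"
            )
            flag2 = 0x1 | 0x4 | 0x80
            fh.write(f"{pair.id}\t{flag2}\t*\t0\t0\t*\t*\t0\t0\t{seq2}\t{qual2}\n")


# ---------------------------------------------------------------------------
# BED / taxonomy / TSV
# ---------------------------------------------------------------------------

def read_bed(path: str | os.PathLike) -> list[Interval]:
    """Read 3-column BED (0-based half-open)."""
    out: list[Interval] = []
    with open(path, "rt") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: expected 3 BED columns")
            seq_id, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise FormatError(
                    f"{path}: line {lineno}: start {start} >= end {end}"
                )
            out.append(Interval(seq_id, start, end))
    return out


def write_bed(intervals: Iterable[Interval], path: str | os.PathLike) -> None:
    with open(path, "wt") as fh:
        for iv in intervals:
            fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\n")


def read_taxonomy(path: str | os.PathLike) -> list[TaxonomyRow]:
    """Read a TSV (header: seq_id, superkingdom, genus)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"seq_id", "superkingdom", "genus"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: taxonomy TSV must have columns {sorted(required)}")
    if df["seq_id"].duplicated().any():
        dup = df.loc[df["seq_id"].duplicated(), "seq_id"].iloc[0]
        raise FormatError(f"{path}: duplicate taxonomy row for {dup!r}")
    return [
        TaxonomyRow(r.seq_id, r.superkingdom, r.genus) for r in df.itertuples()
    ]


def write_taxonomy(rows: Iterable[TaxonomyRow], path: str | os.PathLike) -> None:
    pd.DataFrame(
        [(r.seq_id, r.superkingdom, r.genus) for r in rows],
        columns=["seq_id", "superkingdom", "genus"],
    ).to_csv(path, sep="\t", index=False)


def write_tsv(table: pd.DataFrame, path: str | os.PathLike) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def write_newick(tree, path: str | os.PathLike) -> None:
    """Write a dendropy Tree as Newick (labels kept verbatim, no quoting)."""
    tree.write(
        path=os.fspath(path),
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )


def read_newick(path: str | os.PathLike):
    import dendropy

    return dendropy.Tree.get(
        path=os.fspath(path), schema="newick", preserve_underscores=True
    )


def newick_string(tree) -> str:
    return tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip()
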