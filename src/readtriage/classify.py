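"""Mapping-based origin classification of QC-passing unmapped pairs.

Each pair is tested for *in-pair* placement (both mates on one sequence, FR
orientation, insert size near the library expectation, bounded mismatches)
against three databases: the alternative assembly, Y contigs, and a
contaminant set. Alternative hits are subdivided by a coverage annotation
(regions of the alternative supported by primary-strain data: hits there point
at sequence missing from the primary reference; hits elsewhere at
strain-divergent sequence). Rat-derived databases take precedence over the
contaminant database so homologous material is never discarded as
contamination. The result is a per-sample origin tally and a genus-level
contaminant report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import _kmers
from ._align import count_mismatches
from .formats import Interval, ReadPair, SequenceRecord, TaxonomyRow
from .qc import QcSummary

ORIGIN_CATEGORIES = (
    "low_qc",
    "variation",
    "alt_missing_region",
    "alt_other",
    "alt_and_y",
    "y_only",
    "contamination",
    "remaining",
)


@dataclass(frozen=True)
class MapParams:
    k_seed: int = 17
    max_mismatch: int = 5  # per mate
    insert_tolerance: Optional[float] = None  # default: the pair's own tolerance


@dataclass
class ReferenceSet:
    """Named reference collections with roles, plus coverage and taxonomy."""

    primary: list[SequenceRecord] = field(default_factory=list)
    alternative: list[SequenceRecord] = field(default_factory=list)
    y_contigs: list[SequenceRecord] = field(default_factory=list)
    contaminant: list[SequenceRecord] = field(default_factory=list)
    coverage: list[Interval] = field(default_factory=list)
    taxonomy: list[TaxonomyRow] = field(default_factory=list)


class KmerIndex:
    """Complete canonical k-mer index over a set of sequences.

    Every position with a valid (ACGT-only) k-mer is indexed under the
    canonical form (lexicographic min of the k-mer and its reverse
    complement), recording whether the forward k-mer is the canonical one.
    """

    def __init__(self, sequences: Sequence[SequenceRecord], k_seed: int = 17):
        if not sequences:
            raise ValueError("cannot index an empty sequence set")
        shortest = min(len(s) for s in sequences)
        if k_seed > shortest:
            raise ValueError(
                f"k_seed {k_seed} exceeds shortest sequence length {shortest}"
            )
        self.k = k_seed
        self.names = [s.id for s in sequences]
        self.seqs = [_kmers.encode(s.sequence) for s in sequences]
        self.lens = [len(s) for s in self.seqs]
        table: dict[int, object] = {}
        for sidx, codes in enumerate(self.seqs):
            canon, valid, is_fwd = _kmers.canonical_kmer_codes(codes, k_seed)
            packed_base = sidx << 33
            for pos in np.nonzero(valid)[0].tolist():
                entry = packed_base | (pos << 1) | int(is_fwd[pos])
                cur = table.get(canon[pos])
                if cur is None:
                    table[canon[pos]] = entry
                elif isinstance(cur, list):
                    cur.append(entry)
                else:
                    table[canon[pos]] = [cur, entry]
        self._table = table

    def lookup(self, canonical: int) -> list[tuple[int, int, bool]]:
        """Placements of a canonical k-mer: (seq_idx, position, is_forward)."""
        cur = self._table.get(int(canonical))
        if cur is None:
            return []
        entries = cur if isinstance(cur, list) else [cur]
        return [((e >> 33), (e >> 1) & 0xFFFFFFFF, bool(e & 1)) for e in entries]

    def __len__(self) -> int:
        return len(self._table)


def build_index(sequences: Sequence[SequenceRecord], k_seed: int = 17) -> KmerIndex:
    """Build a complete canonical k-mer index over reference sequences."""
    return KmerIndex(sequences, k_seed)


@dataclass
class MapResult:
    maps_in_pair: bool
    # (seq_id, mate1 interval, mate2 interval, mate1 strand, total mismatches,
    #  observed insert)
    best_placement: Optional[
        tuple[str, Interval, Interval, str, int, int]
    ] = None


class _PreparedMate:
    """Per-mate precomputation shared across index queries."""

    __slots__ = ("codes", "rc_codes", "canon", "valid", "is_fwd", "length")

    def __init__(self, seq: str, k: int):
        self.codes = _kmers.encode(seq)
        self.rc_codes = _kmers.revcomp_codes(self.codes)
        self.canon, self.valid, self.is_fwd = _kmers.canonical_kmer_codes(
            self.codes, k
        )
        self.length = len(self.codes)


def _mate_placements(
    mate: _PreparedMate,
    index: KmerIndex,
    max_mismatch: int,
    offsets: Iterable[int],
) -> dict[tuple[int, str, int], int]:
    """Verified placements (seq_idx, strand, start) → mismatch count."""
    placements: dict[tuple[int, str, int], int] = {}
    k, L = index.k, mate.length
    seen: set[tuple[int, str, int]] = set()
    for off in offsets:
        if off >= len(mate.canon) or not mate.valid[off]:
            continue
        read_fwd = bool(mate.is_fwd[off])
        for sidx, pos, ref_fwd in index.lookup(mate.canon[off]):
            if read_fwd == ref_fwd:
                strand, start = "+", pos - off
            else:
                strand, start = "-", pos - (L - off - k)
            key = (sidx, strand, start)
            if key in seen:
                continue
            seen.add(key)
            query = mate.codes if strand == "+" else mate.rc_codes
            mm = count_mismatches(query, index.seqs[sidx], start, max_mismatch)
            if mm <= max_mismatch:
                placements[key] = int(mm)
    return placements


def _map_prepared(
    m1: _PreparedMate,
    m2: _PreparedMate,
    index: KmerIndex,
    max_mismatch: int,
    insert_mean: float,
    insert_tol: float,
) -> MapResult:
    k = index.k

    def offsets(mate: _PreparedMate, full: bool):
        n = mate.length - k + 1
        if n <= 0:
            return []
        if full:
            return range(n)
        offs = list(range(0, n, k))
        if offs[-1] != n - 1:
            offs.append(n - 1)
        return offs

    for full in (False, True):
        p1 = _mate_placements(m1, index, max_mismatch, offsets(m1, full))
        p2 = _mate_placements(m2, index, max_mismatch, offsets(m2, full))
        best = None
        for (s1, st1, a1), mm1 in p1.items():
            for (s2, st2, a2), mm2 in p2.items():
                if s1 != s2 or st1 == st2:
                    continue
                if st1 == "+":
                    fwd_start, rev_start, rev_len = a1, a2, m2.length
                else:
                    fwd_start, rev_start, rev_len = a2, a1, m1.length
                if rev_start < fwd_start:
                    continue  # not FR
                insert = rev_start + rev_len - fwd_start
                if abs(insert - insert_mean) > insert_tol:
                    continue
                key = (mm1 + mm2, index.names[s1], min(a1, a2))
                if best is None or key < best[0]:
                    best = (
                        key,
                        (
                            index.names[s1],
                            Interval(index.names[s1], a1, a1 + m1.length),
                            Interval(index.names[s2], a2, a2 + m2.length),
                            st1,
                            mm1 + mm2,
                            int(insert),
                        ),
                    )
        if best is not None:
            return MapResult(True, best[1])
        if full:
            break
    return MapResult(False, None)


def map_pair(
    pair: ReadPair, index: KmerIndex, params: MapParams = MapParams()
) -> MapResult:
    """Best in-pair placement of a read pair against one database.

    Seed k-mers anchor candidate placements; ungapped extension counts
    mismatches. ``maps_in_pair`` requires both mates on one sequence in FR
    orientation, each with at most ``max_mismatch`` mismatches, and an
    observed insert within tolerance of the expected fragment mean. Ties are
    broken by total mismatches, then (seq_id, leftmost position).
    """
    mean, tol = pair.expected_fragment
    if params.insert_tolerance is not None:
        tol = params.insert_tolerance
    m1 = _PreparedMate(pair.mate1.sequence, index.k)
    m2 = _PreparedMate(pair.mate2.sequence, index.k)
    return _map_prepared(m1, m2, index, params.max_mismatch, mean, tol)


# ---------------------------------------------------------------------------
# Coverage annotation
# ---------------------------------------------------------------------------

class CoverageMap:
    """Point-in-interval queries over a coverage annotation."""

    def __init__(self, intervals: Sequence[Interval]):
        self._by_seq: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        per_seq: dict[str, list[Interval]] = {}
        for iv in intervals:
            per_seq.setdefault(iv.seq_id, []).append(iv)
        for seq_id, ivs in per_seq.items():
            ivs.sort(key=lambda iv: iv.start)
            self._by_seq[seq_id] = (
                np.array([iv.start for iv in ivs]),
                np.array([iv.end for iv in ivs]),
            )

    def covers(self, seq_id: str, pos: int) -> bool:
        if seq_id not in self._by_seq:
            return False
        starts, ends = self._by_seq[seq_id]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        return i >= 0 and pos < ends[i]


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_pair(
    pair: ReadPair,
    alt_index: KmerIndex,
    y_index: Optional[KmerIndex],
    contam_index: Optional[KmerIndex],
    coverage: CoverageMap,
    params: MapParams = MapParams(),
) -> tuple[str, Optional[MapResult]]:
    """Origin category of one pair, with the supporting placement.

    Precedence: rat-derived databases (alternative, Y) beat the contaminant
    database; a pair hitting both alternative and Y is the joint category.
    Returns ``(category, placement)`` where the placement is the alternative
    hit for alt categories and the contaminant hit for contamination.
    """
    mean, tol = pair.expected_fragment
    if params.insert_tolerance is not None:
        tol = params.insert_tolerance
    k = alt_index.k
    m1 = _PreparedMate(pair.mate1.sequence, k)
    m2 = _PreparedMate(pair.mate2.sequence, k)

    alt_res = _map_prepared(m1, m2, alt_index, params.max_mismatch, mean, tol)
    y_res = (
        _map_prepared(m1, m2, y_index, params.max_mismatch, mean, tol)
        if y_index is not None
        else MapResult(False)
    )
    if alt_res.maps_in_pair and y_res.maps_in_pair:
        return "alt_and_y", alt_res
    if y_res.maps_in_pair:
        return "y_only", y_res
    if alt_res.maps_in_pair:
        seq_id, iv1, iv2, *_ = alt_res.best_placement
        if coverage.covers(seq_id, iv1.midpoint) or coverage.covers(
            seq_id, iv2.midpoint
        ):
            return "alt_missing_region", alt_res
        return "alt_other", alt_res
    if contam_index is not None:
        c_res = _map_prepared(m1, m2, contam_index, params.max_mismatch, mean, tol)
        if c_res.maps_in_pair:
            return "contamination", c_res
    return "remaining", None


@dataclass
class OriginTally:
    """Per-sample counts/percentages over the origin partition (Table-1 row shape)."""

    sample: str
    counts: dict[str, int]
    total: int

    @property
    def percentages(self) -> dict[str, float]:
        if self.total == 0:
            return {c: 0.0 for c in ORIGIN_CATEGORIES}
        return {c: 100.0 * self.counts.get(c, 0) / self.total for c in ORIGIN_CATEGORIES}

    def to_row(self) -> dict[str, object]:
        row: dict[str, object] = {"sample": self.sample, "total_pairs": self.total}
        for c in ORIGIN_CATEGORIES:
            row[c] = self.counts.get(c, 0)
        for c, p in self.percentages.items():
            row[f"{c}_pct"] = round(p, 3)
        return row


@dataclass
class GenusReport:
    sample: str
    genus_counts: dict[str, int]
    superkingdom_counts: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.genus_counts.items()),
            columns=["genus", "pairs"],
        ).assign(sample=self.sample)


def classify_sample(
    pairs: Sequence[ReadPair],
    qc_summary: QcSummary,
    refs: ReferenceSet,
    params: MapParams = MapParams(),
    sample: str = "sample",
) -> tuple[OriginTally, GenusReport, list[ReadPair]]:
    """Classify every QC-passing pair of one sample and merge the tallies.

    Returns the Table-1-shaped origin tally (over the full QC input), the
    genus-level contaminant report, and the remaining pairs for downstream
    stages.
    """
    alt_index = KmerIndex(refs.alternative, params.k_seed)
    y_index = KmerIndex(refs.y_contigs, params.k_seed) if refs.y_contigs else None
    contam_index = (
        KmerIndex(refs.contaminant, params.k_seed) if refs.contaminant else None
    )
    return classify_sample_with_indexes(
        pairs, qc_summary, alt_index, y_index, contam_index,
        CoverageMap(refs.coverage), refs.taxonomy, params, sample,
    )


def classify_sample_with_indexes(
    pairs: Sequence[ReadPair],
    qc_summary: QcSummary,
    alt_index: KmerIndex,
    y_index: Optional[KmerIndex],
    contam_index: Optional[KmerIndex],
    coverage: CoverageMap,
    taxonomy: Sequence[TaxonomyRow],
    params: MapParams = MapParams(),
    sample: str = "sample",
) -> tuple[OriginTally, GenusReport, list[ReadPair]]:
    """Same as :func:`classify_sample` but with prebuilt indexes (multi-sample runs)."""
    tax_by_id = {row.seq_id: row for row in taxonomy}
    counts = {c: 0 for c in ORIGIN_CATEGORIES}
    counts["low_qc"] = qc_summary.low_qc
    counts["variation"] = qc_summary.variation
    genus_counts: dict[str, int] = {}
    kingdom_counts: dict[str, int] = {}
    remaining: list[ReadPair] = []

    for pair in pairs:
        category, res = classify_pair(
            pair, alt_index, y_index, contam_index, coverage, params
        )
        counts[category] += 1
        if category == "remaining":
            remaining.append(pair)
        elif category == "contamination":
            seq_id = res.best_placement[0]
            row = tax_by_id.get(seq_id)
            if row is None:
                raise ValueError(
                    f"contaminant sequence {seq_id!r} has no taxonomy row"
                )
            genus_counts[row.genus] = genus_counts.get(row.genus, 0) + 1
            kingdom_counts[row.superkingdom] = (
                kingdom_counts.get(row.superkingdom, 0) + 1
            )

    tally = OriginTally(sample, counts, qc_summary.input)
    report = GenusReport(sample, genus_counts, kingdom_counts)
    return tally, report, remaining


def tallies_to_frame(tallies: Iterable[OriginTally]) -> pd.DataFrame:
    """Merge per-sample tallies into one table, one row per sample."""
    return pd.DataFrame([t.to_row() for t in tallies])


def gc_shift(
    all_reads: Sequence[SequenceRecord], retained_reads: Sequence[SequenceRecord]
) -> tuple[float, bool]:
    """Absolute GC% difference between a retained read set and the full set.

    A shift above 2 percentage points flags the sample as assembly-hostile.
    """
    if not all_reads or not retained_reads:
        raise ValueError("gc_shift requires non-empty read sets")

    def mean_gc(reads: Sequence[SequenceRecord]) -> float:
        fracs = []
        for r in reads:
            n = len(r.sequence)
            if n == 0:
                continue
            gc = r.sequence.count("G") + r.sequence.count("C")
            fracs.append(gc / n)
        if not fracs:
            raise ValueError("gc_shift requires reads with sequence")
        return 100.0 * float(np.mean(fracs))

    delta = abs(mean_gc(retained_reads) - mean_gc(all_reads))
    return delta, delta > 2.0
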