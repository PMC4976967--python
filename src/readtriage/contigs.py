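"""Strain-specific versus common classification of assembled contigs.

Contigs of sufficient length are aligned across strain groups: a contig is
*common* when some contig from a different strain group aligns with more than
``min_match`` matching columns at more than ``min_identity`` identity, and
*strain-specific* otherwise. Substrains collapse into strain groups by name
(the part before the slash) and/or small genetic distance. Common contigs can
be greedily clustered (longest-first, CD-HIT-like), contig novelty screened by
reciprocal overlap against an archive, and whole assemblies compared by an
alignment-coverage distance suitable for the same hierarchical clustering as
the read-similarity matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import _kmers
from ._align import smith_waterman
from .formats import Interval, SequenceRecord
from .similarity import SimilarityMatrix


@dataclass(frozen=True)
class ContigRecord:
    id: str
    strain: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class LocalHit:
    """Best local alignment between two contigs.

    ``match_length`` counts aligned columns; ``identity`` is identical columns
    over aligned columns.
    """

    query_id: str
    target_id: str
    query_interval: Optional[Interval]
    target_interval: Optional[Interval]
    match_length: int
    identity: float
    score: int


@dataclass
class ClassificationParams:
    min_len: int = 500
    min_match: int = 100        # aligned columns, strict >
    min_identity: float = 0.80  # strict >
    length_strictly_greater: bool = False  # True: "longer than 500bp" reading
    seed_k: int = 12            # candidate prefilter seed length


# ---------------------------------------------------------------------------
# Substrain grouping
# ---------------------------------------------------------------------------

@dataclass
class StrainGrouping:
    """Equivalence of substrain names into strain groups."""

    group_of: dict[str, str]

    def same_group(self, a: str, b: str) -> bool:
        return self.group_of[a] == self.group_of[b]

    @property
    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for name, gid in self.group_of.items():
            out.setdefault(gid, []).append(name)
        for members in out.values():
            members.sort()
        return out


def group_substrains(
    names: Sequence[str],
    distance_table: Optional[dict[tuple[str, str], float]] = None,
    max_distance: float = 0.02,
) -> StrainGrouping:
    """Union of the name-prefix and small-genetic-distance relations.

    Substrains share a group when the name before the first ``/`` matches
    and/or their genetic distance is strictly below ``max_distance``; the
    union is closed transitively.
    """
    if not names:
        raise ValueError("group_substrains requires at least one name")
    names = list(dict.fromkeys(names))
    parent = {n: n for n in names}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    by_prefix: dict[str, str] = {}
    for n in names:
        prefix = n.split("/")[0]
        if prefix in by_prefix:
            union(by_prefix[prefix], n)
        else:
            by_prefix[prefix] = n

    if distance_table:
        for (a, b), d in distance_table.items():
            rev = distance_table.get((b, a))
            if rev is not None and not np.isclose(rev, d):
                raise ValueError(
                    f"asymmetric distance table: d({a},{b})={d} != d({b},{a})={rev}"
                )
            if a in parent and b in parent and d < max_distance:
                union(a, b)

    return StrainGrouping({n: find(n) for n in names})


# ---------------------------------------------------------------------------
# Local alignment
# ---------------------------------------------------------------------------

_SW_CELL_LIMIT = 30_000_000  # full-DP cutoff; larger pairs are seed-windowed


def local_align(query: SequenceRecord | ContigRecord, target: SequenceRecord | ContigRecord) -> LocalHit:
    """Best local alignment (match +1, mismatch -2, gap -3) between two contigs.

    Sequences within the DP budget get the exact Smith–Waterman optimum; very
    large pairs are restricted to a window around the densest shared-seed
    diagonal before the same DP runs.
    """
    q_codes = _kmers.encode(query.sequence)
    t_codes = _kmers.encode(target.sequence)
    q_off = t_off = 0
    if len(q_codes) * len(t_codes) > _SW_CELL_LIMIT:
        window = _seed_window(q_codes, t_codes)
        if window is None:
            return LocalHit(query.id, target.id, None, None, 0, 0.0, 0)
        (qs, qe), (ts, te) = window
        q_codes, t_codes = q_codes[qs:qe], t_codes[ts:te]
        q_off, t_off = qs, ts
    score, (qs, qe), (ts, te), cols, ident = smith_waterman(q_codes, t_codes)
    if score <= 0:
        return LocalHit(query.id, target.id, None, None, 0, 0.0, 0)
    return LocalHit(
        query.id,
        target.id,
        Interval(query.id, q_off + qs, q_off + qe),
        Interval(target.id, t_off + ts, t_off + te),
        cols,
        ident / cols if cols else 0.0,
        score,
    )


def _seed_window(
    q: np.ndarray, t: np.ndarray, k: int = 12, pad: int = 400
) -> Optional[tuple[tuple[int, int], tuple[int, int]]]:
    qk, qv = _kmers.kmer_codes(q, k)
    tk, tv = _kmers.kmer_codes(t, k)
    t_index: dict[int, list[int]] = {}
    for pos in np.nonzero(tv)[0].tolist():
        t_index.setdefault(int(tk[pos]), []).append(pos)
    spans: dict[int, list[int]] = {}  # diagonal band -> q positions
    hits = []
    for qpos in np.nonzero(qv)[0].tolist():
        for tpos in t_index.get(int(qk[qpos]), ()):
            hits.append((qpos, tpos))
    if not hits:
        return None
    bands: dict[int, list[tuple[int, int]]] = {}
    for qpos, tpos in hits:
        bands.setdefault((tpos - qpos) // 200, []).append((qpos, tpos))
    best = max(bands.values(), key=len)
    qs = max(0, min(h[0] for h in best) - pad)
    qe = min(len(q), max(h[0] for h in best) + k + pad)
    ts = max(0, min(h[1] for h in best) - pad)
    te = min(len(t), max(h[1] for h in best) + k + pad)
    return (qs, qe), (ts, te)


def _shares_seed(
    a_kmers: set[int], b_kmers: set[int]
) -> bool:
    if len(a_kmers) > len(b_kmers):
        a_kmers, b_kmers = b_kmers, a_kmers
    return any(k in b_kmers for k in a_kmers)


def _forward_seed_set(seq: str, k: int) -> set[int]:
    # both strands stored so reverse-complement homology is also caught
    codes = _kmers.encode(seq)
    canon, valid, _ = _kmers.canonical_kmer_codes(codes, k)
    return set(canon[valid].tolist())


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

@dataclass
class ClassifiedContigs:
    labels: dict[str, str]                 # contig id -> strain_specific | common
    hits: list[LocalHit]                   # qualifying cross-group hits
    contigs: dict[str, ContigRecord]
    params: ClassificationParams

    def summary(self) -> pd.DataFrame:
        """Per strain and label: total bp, contig counts above 1/10 kb, N50."""
        rows = []
        per: dict[tuple[str, str], list[int]] = {}
        for cid, label in self.labels.items():
            c = self.contigs[cid]
            per.setdefault((c.strain, label), []).append(c.length)
        for (strain, label), lengths in sorted(per.items()):
            rows.append(
                dict(
                    strain=strain,
                    label=label,
                    contigs=len(lengths),
                    total_bp=sum(lengths),
                    over_1kb=sum(1 for x in lengths if x > 1000),
                    over_10kb=sum(1 for x in lengths if x > 10_000),
                    n50=n50(lengths),
                )
            )
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                dict(
                    contig=cid,
                    strain=self.contigs[cid].strain,
                    label=label,
                    length=self.contigs[cid].length,
                )
                for cid, label in sorted(self.labels.items())
            ]
        )


def _qualifies(hit: LocalHit, params: ClassificationParams) -> bool:
    return hit.match_length > params.min_match and hit.identity > params.min_identity


def classify_contigs(
    contigs: Sequence[ContigRecord],
    grouping: Optional[StrainGrouping] = None,
    params: ClassificationParams = ClassificationParams(),
) -> ClassifiedContigs:
    """Label length-filtered contigs strain-specific or common.

    A contig is common iff a contig from a *different* strain group aligns
    with match_length > min_match and identity > min_identity; hits within one
    strain group never confer commonness. With a single group every retained
    contig is strain-specific (warned).
    """
    if params.length_strictly_greater:
        kept = [c for c in contigs if c.length > params.min_len]
    else:
        kept = [c for c in contigs if c.length >= params.min_len]
    if grouping is None:
        grouping = group_substrains(sorted({c.strain for c in kept})) if kept else StrainGrouping({})

    by_id = {c.id: c for c in kept}
    if len(by_id) != len(kept):
        raise ValueError("duplicate contig ids")
    groups = {c.id: grouping.group_of[c.strain] for c in kept}
    if len(set(groups.values())) < 2 and kept:
        warnings.warn("all contigs belong to one strain group; everything is strain-specific")

    labels = {c.id: "strain_specific" for c in kept}
    qualifying: list[LocalHit] = []
    seeds = {c.id: _forward_seed_set(c.sequence, params.seed_k) for c in kept}
    ordered = sorted(kept, key=lambda c: (-c.length, c.id))
    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            if groups[a.id] == groups[b.id]:
                continue
            if labels[a.id] == "common" and labels[b.id] == "common":
                continue
            if not _shares_seed(seeds[a.id], seeds[b.id]):
                continue
            hit = local_align(a, b)
            if _qualifies(hit, params):
                labels[a.id] = "common"
                labels[b.id] = "common"
                qualifying.append(hit)
    return ClassifiedContigs(labels, qualifying, by_id, params)


# ---------------------------------------------------------------------------
# Clustering of common contigs
# ---------------------------------------------------------------------------

@dataclass
class ContigCluster:
    representative: ContigRecord
    members: list[ContigRecord]


def cluster_common(
    common: Sequence[ContigRecord],
    identity_threshold: float = 0.90,
    coverage_fraction: float = 0.80,
    seed_k: int = 12,
) -> list[ContigCluster]:
    """Greedy longest-first clustering of common contigs.

    Each contig joins the first existing cluster whose representative aligns
    at >= identity_threshold over >= coverage_fraction of the shorter
    sequence, else founds a new cluster; the representative is always the
    longest (first) member. Deterministic by (length desc, id) ordering.
    """
    clusters: list[ContigCluster] = []
    rep_seeds: list[set[int]] = []
    for contig in sorted(common, key=lambda c: (-c.length, c.id)):
        cseeds = _forward_seed_set(contig.sequence, seed_k)
        placed = False
        for cluster, rseeds in zip(clusters, rep_seeds):
            if not _shares_seed(cseeds, rseeds):
                continue
            rep = cluster.representative
            hit = local_align(contig, rep)
            shorter = min(contig.length, rep.length)
            if (
                hit.identity >= identity_threshold
                and hit.match_length >= coverage_fraction * shorter
            ):
                cluster.members.append(contig)
                placed = True
                break
        if not placed:
            clusters.append(ContigCluster(contig, [contig]))
            rep_seeds.append(cseeds)
    return clusters


# ---------------------------------------------------------------------------
# Archive overlap, N50, assembly distance
# ---------------------------------------------------------------------------

def reciprocal_overlap(
    contig: ContigRecord | SequenceRecord,
    archive: Sequence[SequenceRecord],
    min_fraction: float = 0.66,
) -> bool:
    """True iff some archive sequence shares a local hit covering at least
    ``min_fraction`` of BOTH the contig and the archive sequence."""
    n_q = len(contig.sequence)
    for arch in archive:
        hit = local_align(contig, arch)
        if hit.query_interval is None:
            continue
        q_cov = len(hit.query_interval) / n_q
        t_cov = len(hit.target_interval) / len(arch.sequence)
        if q_cov >= min_fraction and t_cov >= min_fraction:
            return True
    return False


def n50(contigs: Sequence) -> int:
    """Length at which the cumulative sum of descending lengths reaches half
    the total (the weighted median of contig sizes)."""
    lengths = sorted(
        (c if isinstance(c, (int, np.integer)) else len(c.sequence) for c in contigs),
        reverse=True,
    )
    if not lengths:
        raise ValueError("n50 of an empty contig set")
    half = sum(lengths) / 2
    acc = 0
    for length in lengths:
        acc += length
        if acc >= half:
            return int(length)
    return int(lengths[-1])


def assembly_distance(
    assembly_a: Sequence[ContigRecord],
    assembly_b: Sequence[ContigRecord],
    params: ClassificationParams = ClassificationParams(min_len=0),
) -> float:
    """Alignment-coverage distance between two assemblies in [0, 1].

    1 - (bp of A covered by qualifying hits onto B + bp of B covered onto A)
    / (total bp of A + total bp of B): the size-weighted mean of the two
    aligned fractions. Weighting by assembly size keeps one small assembly
    from dominating the score (an unweighted mean misplaces size outliers in
    the clustering). Qualifying hits use the same match-length/identity
    thresholds as contig classification; symmetric by construction. This is a
    surrogate coverage-based score, named as such in output metadata.
    """
    if not assembly_a or not assembly_b:
        raise ValueError("assembly_distance requires non-empty assemblies")
    cov_a, tot_a = _aligned_fraction(assembly_a, assembly_b, params)
    cov_b, tot_b = _aligned_fraction(assembly_b, assembly_a, params)
    return 1.0 - (cov_a + cov_b) / (tot_a + tot_b)


def _aligned_fraction(
    queries: Sequence[ContigRecord],
    targets: Sequence[ContigRecord],
    params: ClassificationParams,
) -> tuple[int, int]:
    """(bp covered by qualifying hits, total bp) of the query assembly."""
    t_seeds = [(_forward_seed_set(t.sequence, params.seed_k), t) for t in targets]
    total = sum(q.length for q in queries)
    covered = 0
    for q in queries:
        qseeds = _forward_seed_set(q.sequence, params.seed_k)
        intervals: list[tuple[int, int]] = []
        for tseeds, t in t_seeds:
            if not _shares_seed(qseeds, tseeds):
                continue
            hit = local_align(q, t)
            if _qualifies(hit, params) and hit.query_interval is not None:
                intervals.append((hit.query_interval.start, hit.query_interval.end))
        covered += _union_length(intervals)
    return covered, total


def _union_length(intervals: list[tuple[int, int]]) -> int:
    if not intervals:
        return 0
    intervals.sort()
    out = 0
    cur_s, cur_e = intervals[0]
    for s, e in intervals[1:]:
        if s > cur_e:
            out += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    out += cur_e - cur_s
    return out


def assembly_distance_matrix(
    assemblies: dict[str, Sequence[ContigRecord]],
    params: ClassificationParams = ClassificationParams(min_len=0),
) -> SimilarityMatrix:
    """Pairwise assembly distances as a matrix ready for cluster_matrix."""
    names = sorted(assemblies)
    n = len(names)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = assembly_distance(assemblies[names[i]], assemblies[names[j]], params)
            values[i, j] = values[j, i] = d
    return SimilarityMatrix(names, values)
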