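"""Between-sample read similarity via shared non-overlapping k-mer blocks.

A read pair of sample A is *similar in* sample B when at least
``required_blocks`` k-mers of the pair (k = 40% of the read length by
default), pairwise non-overlapping in read coordinates and never spanning the
mate boundary, are present in B's pooled canonical k-mer set. The percentage
of A's pairs similar in B, over all ordered sample pairs, forms a (generally
asymmetric) similarity matrix; Euclidean distances between its rows drive
average-linkage hierarchical clustering, and the resulting dendrogram can be
scored against a known phylogeny by Robinson–Foulds distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from . import _kmers
from .formats import ReadPair


def block_size(read_length: int, kmer_fraction: float = 0.4) -> int:
    """Similarity block length: floor(kmer_fraction x read_length)."""
    k = int(kmer_fraction * read_length)
    if k < 1:
        raise ValueError("read_length too short for the requested k-mer fraction")
    return k


@dataclass
class SampleKmerSet:
    """Pooled canonical k-mers over all remaining reads of one sample."""

    sample: str
    k: int
    kmers: set[int]

    @classmethod
    def from_pairs(cls, sample: str, pairs: Sequence[ReadPair], k: int) -> "SampleKmerSet":
        seqs: list[str] = []
        for p in pairs:
            seqs.append(p.mate1.sequence)
            seqs.append(p.mate2.sequence)
        return cls(sample, k, _kmers.canonical_kmer_set(seqs, k))


def _mate_canon(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    canon, valid, _ = _kmers.canonical_kmer_codes(_kmers.encode(seq), k)
    return canon, valid


def _greedy_blocks(
    canon: np.ndarray, valid: np.ndarray, k: int, target: set[int], needed: int
) -> int:
    """Greedy left-to-right count of non-overlapping target k-mers (capped)."""
    count = 0
    i = 0
    n = len(canon)
    while i < n and count < needed:
        if valid[i] and int(canon[i]) in target:
            count += 1
            i += k
        else:
            i += 1
    return count


def pair_similar(
    pair: ReadPair, target: SampleKmerSet, required_blocks: int = 2
) -> bool:
    """True iff the pair shares >= required_blocks non-overlapping k-mer
    blocks with the target sample's pooled set.

    Blocks may be distributed across the two mates but no k-mer spans the
    mate boundary; k-mers containing N are skipped; a mate shorter than k
    contributes nothing. Greedy left-to-right selection decides existence
    (equivalent to exhaustive search for fixed-length blocks).
    """
    k = target.k
    needed = required_blocks
    for mate in (pair.mate1, pair.mate2):
        if len(mate.sequence) < k:
            continue
        canon, valid = _mate_canon(mate.sequence, k)
        needed -= _greedy_blocks(canon, valid, k, target.kmers, needed)
        if needed <= 0:
            return True
    return False


@dataclass
class SimilarityMatrix:
    """Sample x sample percentages; entry (A,B) = % of A's pairs similar in B."""

    samples: list[str]
    values: np.ndarray  # percentages in [0, 100]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.samples)

    def entry(self, a: str, b: str) -> float:
        return float(self.values[self.samples.index(a), self.samples.index(b)])


def similarity_matrix(
    samples: dict[str, Sequence[ReadPair]],
    kmer_fraction: float = 0.4,
    required_blocks: int = 2,
    read_length: Optional[int] = None,
) -> SimilarityMatrix:
    """Ordered-pair similarity percentages over all samples.

    ``read_length`` defaults to the median mate length over all samples and
    fixes one k for the whole comparison.
    """
    if len(samples) < 2:
        raise ValueError("similarity_matrix needs at least 2 samples")
    for name, pairs in samples.items():
        if not pairs:
            raise ValueError(f"sample {name!r} is empty")
    if read_length is None:
        lengths = [
            len(m.sequence)
            for pairs in samples.values()
            for p in pairs
            for m in (p.mate1, p.mate2)
        ]
        read_length = int(np.median(lengths))
    k = block_size(read_length, kmer_fraction)

    names = sorted(samples)
    sets = {name: SampleKmerSet.from_pairs(name, samples[name], k) for name in names}
    # per-pair k-mer arrays computed once per source sample
    prepared: dict[str, list[list[tuple[np.ndarray, np.ndarray]]]] = {}
    for name in names:
        rows = []
        for p in samples[name]:
            mates = []
            for mate in (p.mate1, p.mate2):
                if len(mate.sequence) >= k:
                    mates.append(_mate_canon(mate.sequence, k))
            rows.append(mates)
        prepared[name] = rows

    n = len(names)
    values = np.zeros((n, n))
    for i, a in enumerate(names):
        rows = prepared[a]
        for j, b in enumerate(names):
            target = sets[b].kmers
            hits = 0
            for mates in rows:
                needed = required_blocks
                for canon, valid in mates:
                    needed -= _greedy_blocks(canon, valid, k, target, needed)
                    if needed <= 0:
                        break
                if needed <= 0:
                    hits += 1
            values[i, j] = 100.0 * hits / len(rows)
    return SimilarityMatrix(names, values)


def screen_samples(
    samples: dict[str, Sequence[ReadPair]],
    kmer_fraction: float = 0.4,
    min_pairs: int = 30_000,
    gc_shift_flags: Optional[dict[str, bool]] = None,
    read_length: Optional[int] = None,
) -> tuple[dict[str, Sequence[ReadPair]], list[str]]:
    """Usability screens before the similarity comparison.

    Excludes (with a warning) samples whose median read length is below 2k —
    where k is the block size of the comparison, derived from ``read_length``
    (default: the median mate length over all samples) — with fewer than
    ``min_pairs`` pairs, or flagged for GC shift. ``min_pairs`` defaults to
    the screen used on the real study's scale; desk-scale runs pass a smaller
    value.
    """
    if read_length is None:
        lengths = [
            len(m.sequence)
            for pairs in samples.values()
            for p in pairs
            for m in (p.mate1, p.mate2)
        ]
        read_length = int(np.median(lengths)) if lengths else 0
    k = max(1, int(kmer_fraction * read_length))
    usable: dict[str, Sequence[ReadPair]] = {}
    excluded: list[str] = []
    for name in sorted(samples):
        pairs = samples[name]
        reasons = []
        if len(pairs) < min_pairs:
            reasons.append(f"only {len(pairs)} pairs (<{min_pairs})")
        if pairs:
            med_len = int(
                np.median([len(m.sequence) for p in pairs for m in (p.mate1, p.mate2)])
            )
            if med_len < 2 * k:
                reasons.append(f"median read length {med_len} < 2x block size {k}")
        else:
            reasons.append("no pairs")
        if gc_shift_flags and gc_shift_flags.get(name):
            reasons.append("GC shift > 2%")
        if reasons:
            warnings.warn(f"sample {name} excluded from similarity: {'; '.join(reasons)}")
            excluded.append(name)
        else:
            usable[name] = pairs
    return usable, excluded


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

@dataclass
class Dendrogram:
    """Average-linkage merge tree over samples, serializable to Newick."""

    samples: list[str]
    linkage: np.ndarray

    def to_newick(self) -> str:
        n = len(self.samples)
        heights = {i: 0.0 for i in range(n)}
        labels = {i: self.samples[i] for i in range(n)}
        for idx, (a, b, h, _cnt) in enumerate(self.linkage):
            a, b = int(a), int(b)
            node = n + idx
            parts = []
            for child in (a, b):
                bl = max(0.0, float(h) - heights[child])
                parts.append(f"{labels[child]}:{bl:.6f}")
            labels[node] = f"({','.join(parts)})"
            heights[node] = float(h)
        return labels[2 * n - 2] + ";"

    def to_tree(self) -> dendropy.Tree:
        return dendropy.Tree.get(
            data=self.to_newick(), schema="newick", preserve_underscores=True
        )

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def cluster_matrix(matrix: SimilarityMatrix) -> Dendrogram:
    """Agglomerative average-linkage clustering of the matrix rows.

    The distance between two samples is the Euclidean distance between their
    rows; input rows are ordered by sample name so ties break
    deterministically.
    """
    values = np.asarray(matrix.values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("cluster_matrix expects a square matrix")
    order = np.argsort(np.array(matrix.samples))
    samples = [matrix.samples[i] for i in order]
    rows = values[order]
    with warnings.catch_warnings():
        # scipy guesses a vector matrix that happens to be square/symmetric
        # might be a distance matrix; here rows are genuinely feature vectors
        warnings.simplefilter("ignore", hierarchy.ClusterWarning)
        Z = hierarchy.linkage(rows, method="average", metric="euclidean")
    return Dendrogram(samples, Z)


def _as_tree(obj) -> dendropy.Tree:
    if isinstance(obj, Dendrogram):
        return obj.to_tree()
    if isinstance(obj, dendropy.Tree):
        return obj
    raise TypeError(f"expected Dendrogram or dendropy.Tree, got {type(obj)!r}")


def _nontrivial_splits(tree: dendropy.Tree, n_leaves: int) -> int:
    count = 0
    for bip in tree.encode_bipartitions():
        size = bin(bip.leafset_bitmask).count("1")
        if 1 < size < n_leaves - 1:
            count += 1
    return count


def tree_recovery_score(dendrogram, true_tree) -> tuple[int, float]:
    """Robinson–Foulds distance to a reference topology, raw and normalized.

    Both trees are compared unrooted; normalization divides by the total
    number of non-trivial bipartitions in the two trees, so identical
    topologies give 0 and maximally conflicting ones give 1.
    """
    t1 = _as_tree(dendrogram)
    t2 = _as_tree(true_tree)
    ns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(
        data=t1.as_string(schema="newick", unquoted_underscores=True),
        schema="newick",
        taxon_namespace=ns,
        preserve_underscores=True,
    )
    t2 = dendropy.Tree.get(
        data=t2.as_string(schema="newick", unquoted_underscores=True),
        schema="newick",
        taxon_namespace=ns,
        preserve_underscores=True,
    )
    leaves1 = {lf.taxon.label for lf in t1.leaf_node_iter()}
    leaves2 = {lf.taxon.label for lf in t2.leaf_node_iter()}
    if leaves1 != leaves2:
        raise ValueError(
            f"leaf sets differ: {sorted(leaves1 ^ leaves2)} not shared"
        )
    for t in (t1, t2):
        t.is_rooted = False
        t.update_bipartitions()
    rf = int(dendropy.calculate.treecompare.symmetric_difference(t1, t2))
    n = len(leaves1)
    denom = _nontrivial_splits(t1, n) + _nontrivial_splits(t2, n)
    return rf, (rf / denom if denom else 0.0)
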