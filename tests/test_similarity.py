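"""k-mer block similarity, matrix, clustering, and tree scoring."""

import dendropy
import numpy as np
import pytest

from readtriage import _kmers
from readtriage.formats import ReadPair, SequenceRecord, revcomp
from readtriage.similarity import (
    Dendrogram,
    SampleKmerSet,
    SimilarityMatrix,
    block_size,
    cluster_matrix,
    pair_similar,
    screen_samples,
    similarity_matrix,
    tree_recovery_score,
)


def _seq(rng, n):
    return "".join("ACGT"[b] for b in rng.integers(0, 4, n))


def _pair(pid, m1, m2):
    return ReadPair(
        pid,
        SequenceRecord(f"{pid}/1", m1, "I" * len(m1)),
        SequenceRecord(f"{pid}/2", m2, "I" * len(m2)),
        expected_read_length=len(m1),
    )


def _random_pairs(rng, n, length=100):
    return [_pair(f"p{i}", _seq(rng, length), _seq(rng, length)) for i in range(n)]


# ---------------------------------------------------------------------------
# Block size and pair similarity
# ---------------------------------------------------------------------------

def test_block_size_is_forty_percent_of_read_length():
    assert block_size(85, 0.4) == 34
    assert block_size(100, 0.4) == 40


def test_pair_is_similar_to_its_own_sample():
    rng = np.random.default_rng(0)
    pairs = _random_pairs(rng, 20, 85)
    own = SampleKmerSet.from_pairs("s", pairs, block_size(85))
    assert all(pair_similar(p, own) for p in pairs)


def test_single_shared_kmer_is_not_enough():
    rng = np.random.default_rng(1)
    k = 40
    shared = _seq(rng, k)
    # target knows exactly one k-mer of the pair
    target = SampleKmerSet("t", k, _kmers.canonical_kmer_set([shared], k))
    pair = _pair("p", shared + _seq(rng, 60), _seq(rng, 100))
    assert not pair_similar(pair, target, required_blocks=2)
    assert pair_similar(pair, target, required_blocks=1)


def test_blocks_may_split_across_mates_but_not_span_the_boundary():
    rng = np.random.default_rng(2)
    k = 40
    b1, b2 = _seq(rng, k), _seq(rng, k)
    target = SampleKmerSet("t", k, _kmers.canonical_kmer_set([b1, b2], k))
    # one block in each mate
    pair = _pair("p", b1 + _seq(rng, 60), _seq(rng, 60) + b2)
    assert pair_similar(pair, target)
    # the two blocks joined across the mate boundary do not count
    joint = b1 + b2
    pair2 = _pair("q", joint[:50], joint[50:] + _seq(rng, 20))
    # mate1 holds b1's first 50bp only (one whole k-mer of b1 at offset 0..10)
    target_b1_only = SampleKmerSet("t", k, _kmers.canonical_kmer_set([b1], k))
    assert not pair_similar(pair2, target_b1_only, required_blocks=2)


def exhaustive_two_blocks(pair, target, k):
    """Oracle: enumerate all non-overlapping k-mer pairs per mate combination."""
    hits_per_mate = []
    for mate in (pair.mate1, pair.mate2):
        canon, valid, _ = _kmers.canonical_kmer_codes(_kmers.encode(mate.sequence), k)
        hits = [i for i in range(len(canon)) if valid[i] and int(canon[i]) in target.kmers]
        hits_per_mate.append(hits)
    h1, h2 = hits_per_mate
    if h1 and h2:
        return True  # one block in each mate never overlaps
    for hits in (h1, h2):
        for i in range(len(hits)):
            for j in range(i + 1, len(hits)):
                if hits[j] >= hits[i] + k:
                    return True
    return False


def test_greedy_block_finding_matches_exhaustive_search():
    rng = np.random.default_rng(3)
    k = 34
    vocab = [_seq(rng, k) for _ in range(8)]
    target = SampleKmerSet("t", k, _kmers.canonical_kmer_set(vocab, k))
    agree = disagreements = 0
    for trial in range(1000):
        L = int(rng.integers(k, 121))
        mates = []
        for _ in range(2):
            s = list(_seq(rng, L))
            # plant 0-2 vocabulary k-mers (possibly overlapping, possibly RC)
            for _ in range(int(rng.integers(0, 3))):
                at = int(rng.integers(0, L - k + 1))
                word = vocab[int(rng.integers(0, len(vocab)))]
                if rng.random() < 0.5:
                    word = revcomp(word)
                s[at : at + k] = word
            mates.append("".join(s))
        pair = _pair(f"t{trial}", mates[0], mates[1])
        expected = exhaustive_two_blocks(pair, target, k)
        assert pair_similar(pair, target) == expected
        agree += 1
    assert agree == 1000


# ---------------------------------------------------------------------------
# Matrix
# ---------------------------------------------------------------------------

def test_identical_samples_have_all_entries_100():
    rng = np.random.default_rng(4)
    pairs = _random_pairs(rng, 50)
    m = similarity_matrix({"a": pairs, "b": list(pairs)})
    assert np.allclose(m.values, 100.0)


def test_unrelated_samples_have_near_zero_entries_and_full_diagonal():
    rng = np.random.default_rng(5)
    m = similarity_matrix(
        {"a": _random_pairs(rng, 1000), "b": _random_pairs(rng, 1000)}
    )
    assert m.entry("a", "a") == 100.0 and m.entry("b", "b") == 100.0
    assert m.entry("a", "b") < 1.0 and m.entry("b", "a") < 1.0


def test_entries_invariant_under_read_order_permutation():
    rng = np.random.default_rng(6)
    a = _random_pairs(rng, 100)
    b = _random_pairs(rng, 100)
    m1 = similarity_matrix({"a": a, "b": b})
    m2 = similarity_matrix({"a": a[::-1], "b": b[::-1]})
    assert np.allclose(m1.values, m2.values)


def test_empty_sample_is_an_error_naming_it():
    rng = np.random.default_rng(7)
    with pytest.raises(ValueError, match="bad"):
        similarity_matrix({"a": _random_pairs(rng, 5), "bad": []})


def test_screen_excludes_short_and_small_samples():
    rng = np.random.default_rng(8)
    ok = _random_pairs(rng, 50, 100)
    few = _random_pairs(rng, 3, 100)
    short = _random_pairs(rng, 50, 50)  # below 2k = 80 for the 100bp comparison
    with pytest.warns(UserWarning):
        usable, excluded = screen_samples(
            {"ok": ok, "few": few, "short": short}, min_pairs=10, read_length=100
        )
    assert set(usable) == {"ok"}
    assert sorted(excluded) == ["few", "short"]
    # GC-shift flag also excludes
    with pytest.warns(UserWarning):
        usable2, excluded2 = screen_samples(
            {"ok": ok, "shifted": list(ok)},
            min_pairs=10,
            gc_shift_flags={"shifted": True},
        )
    assert set(usable2) == {"ok"} and excluded2 == ["shifted"]


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def test_identical_rows_merge_first_at_height_zero():
    values = np.array(
        [
            [100.0, 90.0, 10.0],
            [100.0, 90.0, 10.0],
            [10.0, 10.0, 100.0],
        ]
    )
    d = cluster_matrix(SimilarityMatrix(["a", "b", "c"], values))
    assert d.linkage[0, 2] == 0.0  # first merge at height 0
    assert "(a:0.000000,b:0.000000)" in d.to_newick()


def test_three_sample_hand_geometry():
    # rows of a and b are 3 apart; c is ~127 away from both
    values = np.array(
        [
            [100.0, 90.0, 0.0],
            [90.0, 100.0, 0.0],
            [0.0, 0.0, 100.0],
        ]
    )
    d = cluster_matrix(SimilarityMatrix(["a", "b", "c"], values))
    h1, h2 = d.linkage[0, 2], d.linkage[1, 2]
    assert h1 == pytest.approx(np.sqrt(2 * 10.0**2))
    assert h2 > h1  # average-linkage heights are non-decreasing


def test_cluster_matrix_is_invariant_to_sample_order():
    rng = np.random.default_rng(9)
    values = rng.random((4, 4)) * 100
    names = ["s1", "s2", "s3", "s4"]
    m1 = SimilarityMatrix(names, values)
    perm = [2, 0, 3, 1]
    m2 = SimilarityMatrix(
        [names[i] for i in perm], values[np.ix_(perm, perm)]
    )
    t1, t2 = cluster_matrix(m1), cluster_matrix(m2)
    rf, _ = tree_recovery_score(t1, t2)
    assert rf == 0


def test_cluster_matrix_rejects_non_square():
    with pytest.raises(ValueError):
        cluster_matrix(SimilarityMatrix(["a", "b"], np.zeros((2, 3))))


# ---------------------------------------------------------------------------
# Tree recovery score
# ---------------------------------------------------------------------------

def _tree(newick):
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


def newick_splits(newick):
    """Independent split enumerator: parse nesting by hand, collect non-trivial
    bipartitions as frozensets of the smaller side (by min-containing rule)."""
    newick = newick.strip().rstrip(";")
    clades = []

    def parse(s, i):
        leaves = []
        assert s[i] == "("
        i += 1
        while True:
            if s[i] == "(":
                sub, i = parse(s, i)
                leaves.extend(sub)
            else:
                j = i
                while s[j] not in ",()":
                    j += 1
                name = s[i:j].split(":")[0]
                if name:
                    leaves.append(name)
                i = j
            if s[i] == ",":
                i += 1
                continue
            assert s[i] == ")"
            i += 1
            while i < len(s) and s[i] not in ",()":
                i += 1
            clades.append(frozenset(leaves))
            return leaves, i

    all_leaves, _ = parse(newick, 0)
    n = len(all_leaves)
    universe = frozenset(all_leaves)
    splits = set()
    for c in clades:
        if 1 < len(c) < n - 1:
            splits.add(min(c, universe - c, key=lambda x: (len(x), sorted(x))))
    return splits


def test_identical_topologies_score_zero():
    t = "((a,b),(c,d));"
    rf, norm = tree_recovery_score(_tree(t), _tree(t))
    assert rf == 0 and norm == 0.0


def test_star_versus_resolved_is_maximal():
    rf, norm = tree_recovery_score(_tree("(a,b,c,d);"), _tree("((a,b),(c,d));"))
    assert rf == 1 and norm == 1.0


def test_caterpillar_versus_balanced_matches_split_enumeration():
    cat = "(((((a,b),c),d),e),f);"
    bal = "((a,b),((c,d),(e,f)));"
    s1, s2 = newick_splits(cat), newick_splits(bal)
    expected = len(s1 ^ s2)
    rf, norm = tree_recovery_score(_tree(cat), _tree(bal))
    assert rf == expected
    assert norm == pytest.approx(expected / (len(s1) + len(s2)))


def test_leaf_set_mismatch_is_an_error():
    with pytest.raises(ValueError, match="leaf"):
        tree_recovery_score(_tree("((a,b),c);"), _tree("((a,b),d);"))


# ---------------------------------------------------------------------------
# Signal properties on the full simulated study
# ---------------------------------------------------------------------------

def test_similarity_decreases_with_tree_distance(full_study, full_analysis):
    """Spearman rho < 0 between matrix entries and patristic distances."""
    from scipy.stats import spearmanr

    matrix = full_analysis.matrix
    assert matrix is not None
    pdm = full_study.tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in full_study.tree.taxon_namespace}
    sims, dists = [], []
    for i, a in enumerate(matrix.samples):
        for j, b in enumerate(matrix.samples):
            if a == b:
                continue
            sims.append(matrix.values[i, j])
            dists.append(pdm.path_edge_count(taxa[a], taxa[b]))
    rho, _p = spearmanr(sims, dists)
    assert rho < -0.5
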