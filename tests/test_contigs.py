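"""Contig classification: grouping, local alignment, thresholds, clustering,
reciprocal overlap, N50, assembly distance."""

import numpy as np
import pytest
from Bio import Align

from readtriage.contigs import (
    ClassificationParams,
    ContigRecord,
    assembly_distance,
    assembly_distance_matrix,
    classify_contigs,
    cluster_common,
    group_substrains,
    local_align,
    n50,
    reciprocal_overlap,
)
from readtriage.formats import SequenceRecord


def _seq(rng, n):
    return "".join("ACGT"[b] for b in rng.integers(0, 4, n))


def _mutate(rng, seq, n_subs):
    s = list(seq)
    for pos in rng.choice(len(s), n_subs, replace=False):
        s[pos] = "ACGT"[("ACGT".index(s[pos]) + int(rng.integers(1, 4))) % 4]
    return "".join(s)


# ---------------------------------------------------------------------------
# Substrain grouping
# ---------------------------------------------------------------------------

def test_grouping_by_name_prefix():
    g = group_substrains(["F344/NCrl", "F344/NHsd", "WAG/Rij"])
    assert g.same_group("F344/NCrl", "F344/NHsd")
    assert not g.same_group("F344/NCrl", "WAG/Rij")
    assert len(g.groups) == 2


def test_grouping_by_small_distance_despite_names():
    g = group_substrains(
        ["X/a", "Y/b"], distance_table={("X/a", "Y/b"): 0.01}
    )
    assert g.same_group("X/a", "Y/b")


def test_distance_exactly_at_threshold_does_not_merge():
    g = group_substrains(
        ["X/a", "Y/b"], distance_table={("X/a", "Y/b"): 0.02}
    )
    assert not g.same_group("X/a", "Y/b")


def test_grouping_is_transitively_closed():
    g = group_substrains(
        ["A/1", "B/1", "C/1"],
        distance_table={("A/1", "B/1"): 0.01, ("B/1", "C/1"): 0.01},
    )
    assert g.same_group("A/1", "C/1")


def test_asymmetric_distance_table_is_an_error():
    with pytest.raises(ValueError, match="asymmetric"):
        group_substrains(
            ["X/a", "Y/b"],
            distance_table={("X/a", "Y/b"): 0.01, ("Y/b", "X/a"): 0.5},
        )


# ---------------------------------------------------------------------------
# Local alignment vs Smith–Waterman oracle
# ---------------------------------------------------------------------------

def _oracle_aligner():
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -3
    aligner.extend_gap_score = -3
    return aligner


def test_identical_contigs_align_fully():
    rng = np.random.default_rng(0)
    seq = _seq(rng, 600)
    hit = local_align(ContigRecord("a", "s1", seq), ContigRecord("b", "s2", seq))
    assert hit.match_length == 600 and hit.identity == 1.0
    assert (hit.query_interval.start, hit.query_interval.end) == (0, 600)


def test_ten_percent_divergent_copy_matches_dp_oracle():
    rng = np.random.default_rng(1)
    seq = _seq(rng, 600)
    other = _mutate(rng, seq, 60)
    hit = local_align(ContigRecord("a", "s1", seq), ContigRecord("b", "s2", other))
    oracle = _oracle_aligner().score(seq, other)
    assert hit.score == int(oracle)
    assert hit.identity == pytest.approx(0.90, abs=0.03)


def test_random_contigs_share_no_long_match():
    rng = np.random.default_rng(2)
    for _ in range(30):
        hit = local_align(
            ContigRecord("a", "s1", _seq(rng, 600)),
            ContigRecord("b", "s2", _seq(rng, 600)),
        )
        assert hit.match_length < 100


def test_local_align_score_equals_smith_waterman_on_mixed_pairs():
    """Exact score agreement with an independent DP on 60 random/homologous pairs
    up to 2 kb (the full 200-pair sweep runs in the acceptance suite)."""
    rng = np.random.default_rng(3)
    aligner = _oracle_aligner()
    for trial in range(60):
        n1 = int(rng.integers(50, 2001))
        a = _seq(rng, n1)
        if trial % 2:
            b = _seq(rng, int(rng.integers(50, 2001)))  # unrelated
        else:
            window = a[int(rng.integers(0, n1 // 2)) :]
            b = _mutate(rng, window, int(0.1 * len(window)))
        hit = local_align(ContigRecord("a", "s1", a), ContigRecord("b", "s2", b))
        assert hit.score == int(aligner.score(a, b))


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def _planted_contigs(rng):
    """Two strain groups; one true common segment, the rest private."""
    common_seq = _seq(rng, 800)
    return [
        ContigRecord("c_a", "A/1", common_seq),
        ContigRecord("c_b", "B/1", _mutate(rng, common_seq, 8)),
        ContigRecord("s_a", "A/1", _seq(rng, 700)),
        ContigRecord("s_b", "B/1", _seq(rng, 900)),
        ContigRecord("tiny", "A/1", _seq(rng, 300)),  # below the length filter
    ]


def test_classify_contigs_planted_common_and_specific():
    rng = np.random.default_rng(4)
    result = classify_contigs(_planted_contigs(rng))
    assert result.labels == {
        "c_a": "common",
        "c_b": "common",
        "s_a": "strain_specific",
        "s_b": "strain_specific",
    }
    assert "tiny" not in result.labels  # filtered by min_len


def test_same_group_hits_never_confer_commonness():
    rng = np.random.default_rng(5)
    seq = _seq(rng, 800)
    contigs = [
        ContigRecord("x", "F344/NCrl", seq),
        ContigRecord("y", "F344/NHsd", _mutate(rng, seq, 5)),
    ]
    with pytest.warns(UserWarning):
        result = classify_contigs(contigs)
    assert set(result.labels.values()) == {"strain_specific"}


def test_short_or_weak_foreign_hit_keeps_contig_specific():
    rng = np.random.default_rng(6)
    shared = _seq(rng, 90)  # 90 bp at high identity: match rule fails
    contigs = [
        ContigRecord("a", "A/1", shared + _seq(rng, 510)),
        ContigRecord("b", "B/1", shared + _seq(rng, 510)),
    ]
    result = classify_contigs(contigs)
    assert set(result.labels.values()) == {"strain_specific"}


def test_threshold_monotonicity_over_parameter_grid():
    rng = np.random.default_rng(7)
    base = [_seq(rng, 800) for _ in range(6)]
    contigs = []
    for i, seq in enumerate(base):
        contigs.append(ContigRecord(f"a{i}", "A/1", seq))
        # foreign copies at varying divergence: 2%..30%
        div = [10, 40, 80, 130, 180, 240][i]
        contigs.append(ContigRecord(f"b{i}", "B/1", _mutate(rng, seq, div)))
    grid = {}
    for min_match in (50, 100, 200):
        for min_identity in (0.70, 0.80, 0.90):
            params = ClassificationParams(min_match=min_match, min_identity=min_identity)
            labels = classify_contigs(contigs, params=params).labels
            grid[(min_match, min_identity)] = sum(
                v == "strain_specific" for v in labels.values()
            )
    for mm in (50, 100, 200):
        col = [grid[(mm, i)] for i in (0.70, 0.80, 0.90)]
        assert col == sorted(col)
    for ident in (0.70, 0.80, 0.90):
        row = [grid[(m, ident)] for m in (50, 100, 200)]
        assert row == sorted(row)


def test_planted_study_contigs_label_perfectly(full_study, full_analysis):
    """Every truth contig from an internal-branch insert is common; every
    terminal-branch insert is strain-specific."""
    result = full_analysis.contig_result
    assert result is not None
    registry = full_study.registry
    checked = 0
    for cid, label in result.labels.items():
        iid = int(cid.rsplit("ins", 1)[1])
        rec = registry[iid]
        expected = "common" if rec.kind == "novel_shared" else "strain_specific"
        assert label == expected, cid
        checked += 1
    assert checked > 50


def test_commonness_is_symmetric(full_analysis):
    result = full_analysis.contig_result
    for hit in result.hits:
        assert result.labels[hit.query_id] == "common"
        assert result.labels[hit.target_id] == "common"


# ---------------------------------------------------------------------------
# Clustering of common contigs
# ---------------------------------------------------------------------------

def test_three_identical_contigs_form_one_cluster():
    rng = np.random.default_rng(8)
    seq = _seq(rng, 700)
    clusters = cluster_common(
        [ContigRecord(f"c{i}", f"s{i}", seq) for i in range(3)]
    )
    assert len(clusters) == 1 and len(clusters[0].members) == 3


def test_distinct_contigs_stay_singletons():
    rng = np.random.default_rng(9)
    clusters = cluster_common(
        [ContigRecord(f"c{i}", f"s{i}", _seq(rng, 700)) for i in range(5)]
    )
    assert len(clusters) == 5


def test_cluster_representative_is_the_longest_member():
    rng = np.random.default_rng(10)
    seq = _seq(rng, 900)
    contigs = [
        ContigRecord("long", "s1", seq),
        ContigRecord("short", "s2", seq[:750]),
    ]
    clusters = cluster_common(contigs)
    assert len(clusters) == 1
    assert clusters[0].representative.id == "long"


# ---------------------------------------------------------------------------
# Reciprocal overlap / N50 / assembly distance
# ---------------------------------------------------------------------------

def test_reciprocal_overlap_identical_sequence():
    rng = np.random.default_rng(11)
    seq = _seq(rng, 1000)
    contig = ContigRecord("c", "s", seq)
    archive = [SequenceRecord("arch", seq)]
    assert reciprocal_overlap(contig, archive, 0.66)
    assert reciprocal_overlap(contig, archive, 0.85)


def test_reciprocal_overlap_requires_both_sides():
    rng = np.random.default_rng(12)
    inner = _seq(rng, 1000)
    archive = [SequenceRecord("arch", _seq(rng, 4500) + inner + _seq(rng, 4500))]
    contig = ContigRecord("c", "s", inner)  # fully contained, archive side 10%
    assert not reciprocal_overlap(contig, archive, 0.66)


def test_novel_contig_does_not_overlap_reference_archive(full_study):
    name = full_study.strain_names[0]
    contigs = full_study.contigs()[name]
    archive = full_study.references.refs.alternative
    c = contigs[0]
    assert not reciprocal_overlap(
        ContigRecord(c.id, name, c.sequence), archive, 0.66
    )


@pytest.mark.parametrize(
    "lengths, expected",
    [([5, 4, 3, 2, 1], 4), ([7], 7), ([3, 3, 3, 3], 3)],
)
def test_n50_examples(lengths, expected):
    assert n50(lengths) == expected


def test_n50_rejects_empty_input():
    with pytest.raises(ValueError):
        n50([])


def test_assembly_distance_identity_and_disjoint():
    rng = np.random.default_rng(13)
    a = [ContigRecord(f"a{i}", "A", _seq(rng, 800)) for i in range(4)]
    b = [ContigRecord(f"b{i}", "B", _seq(rng, 800)) for i in range(4)]
    assert assembly_distance(a, a) == 0.0
    assert assembly_distance(a, b) > 0.95
    with pytest.raises(ValueError):
        assembly_distance(a, [])


def test_assembly_distance_matrix_is_symmetric(full_analysis):
    m = full_analysis.assembly_matrix
    assert m is not None
    assert np.allclose(m.values, m.values.T)
    assert np.allclose(np.diag(m.values), 0.0)
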