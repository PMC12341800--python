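import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.cluster.hierarchy import cophenet, linkage as scipy_linkage
from scipy.spatial.distance import squareform

from consig import (
    CellClass,
    ConsensusParams,
    CountingUnit,
    DistanceMethod,
    FCScale,
    FilterParams,
    Linkage,
    SimilarityMetric,
    ValidationError,
    consensus_signature,
    exclusive_intersections,
    filter_markers,
    gene_lists_by_class,
    hierarchical_cluster,
    pairwise_similarity,
    similarity_to_distance,
)
from conftest import make_marker_table


# ---------------------------------------------------------------- oracles

def brute_consensus(lists, k):
    """Independent per-gene membership count over the plain sets."""
    union = set().union(*lists.values())
    return {g for g in union if sum(g in s for s in lists.values()) >= k}


def brute_patterns(lists):
    """Enumerate all 2^n - 1 membership patterns directly."""
    units = list(lists)
    out = {}
    for r in range(1, len(units) + 1):
        for combo in itertools.combinations(units, r):
            exclusive = set.intersection(*(set(lists[u]) for u in combo))
            for u in units:
                if u not in combo:
                    exclusive -= lists[u]
            if exclusive:
                out[frozenset(combo)] = exclusive
    return out


def random_lists(rng, max_lists=6, max_genes=50):
    n = rng.integers(2, max_lists + 1)
    pool = [f"g{i}" for i in range(max_genes)]
    return {f"L{i}": frozenset(rng.choice(pool,
                                          size=rng.integers(1, max_genes + 1),
                                          replace=False))
            for i in range(n)}


# ---------------------------------------------------------------- filtering

@pytest.mark.parametrize("scale,fc,padj,kept", [
    (FCScale.LINEAR, 1.6, 0.01, True),    # passes both thresholds
    (FCScale.LINEAR, 1.5, 0.01, False),   # FC boundary is strict
    (FCScale.LOG2, 0.7, 0.01, True),      # 2**0.7 ~ 1.62 > 1.5
    (FCScale.LOG2, 0.5, 0.01, False),     # 2**0.5 ~ 1.41
    (FCScale.LINEAR, 2.0, 0.05, False),   # p boundary is strict
    (FCScale.LN, 0.30, 0.01, True),       # ln threshold applied directly
    (FCScale.LN, 0.25, 0.01, False),
    (FCScale.LINEAR, 2.0, np.nan, False),  # missing p_adj fails
])
def test_filter_thresholds(scale, fc, padj, kept):
    table = make_marker_table(
        [("s1", "RGL", CellClass.NSC, "Fabp7", fc, scale, padj)])
    out = filter_markers(table, FilterParams())
    assert (len(out) == 1) == kept


def test_filter_preserves_order_and_empty_output_is_legal():
    rows = [("s1", "RGL", CellClass.NSC, g, fc, FCScale.LINEAR, 0.01)
            for g, fc in [("a", 3.0), ("b", 1.2), ("c", 2.0), ("d", 1.1)]]
    out = filter_markers(make_marker_table(rows))
    assert list(out.records["gene"]) == ["a", "c"]
    empty = filter_markers(make_marker_table(
        [("s1", "RGL", CellClass.NSC, "x", 1.0, FCScale.LINEAR, 0.9)]))
    assert len(empty) == 0


# ----------------------------------------------------------- gene lists

def test_gene_lists_by_class_units():
    rows = [("s1", "RGL", CellClass.NSC, g, 2.0, FCScale.LINEAR, 0.01)
            for g in "AB"] + \
           [("s1", "qNSC", CellClass.NSC, g, 2.0, FCScale.LINEAR, 0.01)
            for g in "BC"]
    table = make_marker_table(rows)
    by_study = gene_lists_by_class(table, CellClass.NSC, CountingUnit.STUDY)
    assert by_study == {"s1": frozenset("ABC")}
    by_cluster = gene_lists_by_class(table, CellClass.NSC, CountingUnit.CLUSTER)
    assert len(by_cluster) == 2
    assert gene_lists_by_class(table, CellClass.NEUROBLAST) == {}


def test_gene_lists_merge_symbol_case_variants():
    rows = [("s1", "RGL", CellClass.NSC, "Fabp7", 2.0, FCScale.LINEAR, 0.01),
            ("s2", "NSC", CellClass.NSC, "FABP7", 2.0, FCScale.LINEAR, 0.01)]
    lists = gene_lists_by_class(make_marker_table(rows), CellClass.NSC)
    # first-seen spelling wins in both units
    assert lists["s1"] == lists["s2"] == frozenset({"Fabp7"})


# ----------------------------------------------------------- similarity

def test_similarity_metric_values():
    lists = {"a": frozenset("ABC"), "b": frozenset("BCD")}
    assert pairwise_similarity(lists, SimilarityMetric.COMMON_COUNT).values[0, 1] == 2
    assert pairwise_similarity(lists, SimilarityMetric.JACCARD).values[0, 1] == 0.5
    same = {"a": frozenset("ABC"), "b": frozenset("ABC")}
    assert pairwise_similarity(same, SimilarityMetric.JACCARD).values[0, 1] == 1.0
    disjoint = {"a": frozenset("AB"), "b": frozenset("CD")}
    for metric in SimilarityMetric:
        assert pairwise_similarity(disjoint, metric).values[0, 1] == 0.0


def test_similarity_diagonals():
    lists = {"a": frozenset("ABC"), "b": frozenset("BCDE")}
    cc = pairwise_similarity(lists, SimilarityMetric.COMMON_COUNT)
    assert np.allclose(np.diag(cc.values), [3, 4])
    jc = pairwise_similarity(lists, SimilarityMetric.JACCARD)
    assert np.allclose(np.diag(jc.values), 1.0)


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 10_000))
def test_similarity_permutation_equivariance(seed):
    rng = np.random.default_rng(seed)
    lists = random_lists(rng, max_lists=5, max_genes=20)
    S = pairwise_similarity(lists, SimilarityMetric.JACCARD)
    order = list(lists)
    perm = [order[i] for i in rng.permutation(len(order))]
    S2 = pairwise_similarity({k: lists[k] for k in perm}, SimilarityMetric.JACCARD)
    df, df2 = S.to_frame(), S2.to_frame()
    assert np.allclose(df.loc[order, order], df2.loc[order, order])
    assert np.allclose(S.values, S.values.T)


def test_distance_conversion():
    lists = {"a": frozenset("ABC"), "b": frozenset("BCD")}
    jc = pairwise_similarity(lists, SimilarityMetric.JACCARD)
    D = similarity_to_distance(jc, DistanceMethod.ONE_MINUS)
    assert D[0, 1] == 0.5 and D[0, 0] == 0.0
    cc = pairwise_similarity(lists, SimilarityMetric.COMMON_COUNT)
    D2 = similarity_to_distance(cc, DistanceMethod.MAX_MINUS)
    assert D2[0, 1] == cc.values.max() - 2
    assert np.allclose(np.diag(D2), 0.0)
    with pytest.raises(ValidationError):
        similarity_to_distance(cc, DistanceMethod.ONE_MINUS)


# ----------------------------------------------------------- clustering

def test_cluster_three_leaves_by_hand():
    D = np.array([[0, 1, 5], [1, 0, 5], [5, 5, 0]], dtype=float)
    dend = hierarchical_cluster(D, ["x", "y", "z"], Linkage.COMPLETE)
    (a, b, h1), (c, d, h2) = dend.merges
    assert {a, b} == {0, 1} and h1 == 1.0
    assert h2 == 5.0


def test_cluster_identical_lists_merge_at_zero():
    n = 4
    D = np.zeros((n, n))
    dend = hierarchical_cluster(D, [f"l{i}" for i in range(n)], Linkage.AVERAGE)
    assert all(h == 0.0 for _, _, h in dend.merges)


def test_cluster_requires_two_leaves_and_valid_matrix():
    with pytest.raises(ValidationError):
        hierarchical_cluster(np.zeros((1, 1)), ["a"])
    with pytest.raises(ValidationError):
        hierarchical_cluster(np.array([[0, 1], [2, 0.0]]), ["a", "b"])


def test_cluster_tie_break_is_deterministic():
    # equilateral: all three merges tie at 1; lexicographically smallest pair first
    D = np.ones((3, 3)) - np.eye(3)
    dend = hierarchical_cluster(D, ["c", "a", "b"], Linkage.COMPLETE)
    a, b, _ = dend.merges[0]
    assert {dend.labels[a], dend.labels[b]} == {"a", "b"}
    assert dend.to_newick() == hierarchical_cluster(
        D, ["c", "a", "b"], Linkage.COMPLETE).to_newick()


@pytest.mark.parametrize("link,scipy_name", [
    (Linkage.SINGLE, "single"),
    (Linkage.COMPLETE, "complete"),
    (Linkage.AVERAGE, "average"),
])
def test_cluster_matches_scipy_on_tie_free_instances(link, scipy_name):
    """Cophenetic distances agree with scipy's hclust on random matrices
    with distinct entries (where tie-break policy cannot matter)."""
    rng = np.random.default_rng(7)
    for _ in range(5):
        n = int(rng.integers(4, 9))
        cond = rng.permutation(np.arange(1, n * (n - 1) // 2 + 1)).astype(float)
        D = squareform(cond)
        dend = hierarchical_cluster(D, [f"l{i}" for i in range(n)], link)
        ours = cophenet(dend.to_linkage())
        ref = cophenet(scipy_linkage(cond, method=scipy_name))
        assert np.allclose(ours, ref)


def test_cluster_heights_non_decreasing_and_newick_leaves():
    rng = np.random.default_rng(3)
    D = squareform(rng.uniform(0.1, 2.0, size=15))
    labels = [f"pop {i}" for i in range(6)]
    dend = hierarchical_cluster(D, labels, Linkage.COMPLETE)
    heights = [h for _, _, h in dend.merges]
    assert all(a <= b + 1e-12 for a, b in zip(heights, heights[1:]))
    nwk = dend.to_newick()
    assert nwk.endswith(";") and all(f"'pop {i}'" in nwk for i in range(6))


# ------------------------------------------------------- intersections

def test_exclusive_intersections_small_example():
    lists = {"1": frozenset("AB"), "2": frozenset("BC")}
    table = exclusive_intersections(lists)
    counts = {tuple(sorted(p)): c for p, c in table.counts().items()}
    assert counts == {("1",): 1, ("1", "2"): 1, ("2",): 1}


@settings(max_examples=40, deadline=None)
@given(st.integers(0, 10_000))
def test_exclusive_intersections_match_bruteforce(seed):
    rng = np.random.default_rng(seed)
    lists = random_lists(rng, max_lists=4, max_genes=30)
    table = exclusive_intersections(lists)
    expected = brute_patterns(lists)
    got = {p: set(genes) for p, genes in table.rows}
    assert got == expected
    assert table.total == len(set().union(*lists.values()))


# ------------------------------------------------------------ consensus

def test_consensus_threshold_boundary():
    lists = {f"s{i}": frozenset({"core"} if i < 5 else {"other"})
             for i in range(7)}
    assert "core" in consensus_signature(lists, ConsensusParams(5)).genes
    with pytest.raises(ValidationError):
        # nothing reaches 6 studies
        consensus_signature(lists, ConsensusParams(6))


def test_consensus_min1_is_union():
    lists = {"a": frozenset("AB"), "b": frozenset("BC")}
    sig = consensus_signature(lists, ConsensusParams(1))
    assert set(sig.genes) == set("ABC")
    assert sig.genes[0] == "B"  # highest unit count sorts first


def test_consensus_errors_when_k_exceeds_units():
    with pytest.raises(ValidationError):
        consensus_signature({"a": frozenset("A")}, ConsensusParams(2))


@settings(max_examples=40, deadline=None)
@given(st.integers(0, 10_000))
def test_consensus_matches_bruteforce_and_nests(seed):
    rng = np.random.default_rng(seed)
    lists = random_lists(rng, max_lists=8, max_genes=100)
    previous = None
    for k in range(1, len(lists) + 1):
        expected = brute_consensus(lists, k)
        if expected:
            got = set(consensus_signature(lists, ConsensusParams(k)).genes)
            assert got == expected
        else:
            with pytest.raises(ValidationError):
                consensus_signature(lists, ConsensusParams(k))
        if previous is not None:
            assert expected <= previous  # monotone nesting
        previous = expected
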