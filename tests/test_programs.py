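"""Normalization, prominence, fold-changes, clustering, enrichment."""

import itertools
from fractions import Fraction
from math import comb, log2

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from switchtome import programs as pr
from switchtome.model import GeneAnnotation, ValidationError

from conftest import toy_counts, toy_expression


def _genes(lengths, rrna=()):
    out = []
    for i, ln in enumerate(lengths):
        gid = f"g{i + 1}"
        flags = frozenset({"rRNA"}) if gid in rrna else frozenset()
        out.append(GeneAnnotation(gid, i * 2000, i * 2000 + ln, "+", ln,
                                  flags=flags))
    return out


class TestNormalize:
    def test_single_library_rpkm(self):
        counts = toy_counts([[100]], [0.0], library_sizes=[1e6])
        expr = pr.normalize_expression(counts, _genes([1000]))
        assert expr.values.iloc[0, 0] == pytest.approx(100.0)

    def test_proportional_libraries_identical_after_uq(self):
        c = np.array([[10, 20], [40, 80], [160, 320]])
        counts = toy_counts(c, [0.0, 1.0], library_sizes=[1e6, 1e6])
        expr = pr.normalize_expression(counts, _genes([1000] * 3))
        np.testing.assert_allclose(expr.values.iloc[:, 0],
                                   expr.values.iloc[:, 1])

    def test_three_gene_hand_computation(self):
        counts = toy_counts([[10], [20], [40]], [0.0], library_sizes=[1e6])
        expr = pr.normalize_expression(counts, _genes([1000] * 3))
        # RPKM = counts; single library: UQ factor is 1 by construction
        np.testing.assert_allclose(expr.values.iloc[:, 0], [10.0, 20.0, 40.0])
        # two libraries, second twice as deep with identical counts:
        counts2 = toy_counts([[10, 10], [20, 20], [40, 40]], [0.0, 1.0],
                             library_sizes=[1e6, 2e6])
        expr2 = pr.normalize_expression(counts2, _genes([1000] * 3))
        # RPKM: lib2 = lib1/2; UQ factors sqrt(2) apart restore equality
        np.testing.assert_allclose(expr2.values.iloc[:, 0],
                                   expr2.values.iloc[:, 1])

    def test_rrna_masked_before_quartiles(self):
        counts = toy_counts([[1000], [10], [20]], [0.0], library_sizes=[1e6])
        expr = pr.normalize_expression(counts, _genes([1000] * 3,
                                                      rrna=("g1",)))
        assert "g1" not in expr.values.index
        assert len(expr.values) == 2

    def test_all_zero_library_raises(self):
        counts = toy_counts([[0, 5], [0, 5]], [0.0, 1.0],
                            library_sizes=[1e6, 1e6])
        with pytest.raises(ValidationError, match="all-zero"):
            pr.normalize_expression(counts, _genes([1000] * 2))


class TestProminence:
    def test_top_half_by_maximum(self):
        expr = toy_expression([[5, 5], [1, 1], [10, 2], [3, 3]], [0.0, 1.0])
        assert set(pr.prominent_genes(expr)) == {"g3", "g1"}

    def test_ceil_at_odd_count(self):
        expr = toy_expression([[5], [1], [10], [3], [2]], [0.0])
        assert len(pr.prominent_genes(expr)) == 3

    def test_boundary_ties_broken_lexicographically(self):
        expr = toy_expression([[5], [5], [5], [5]], [0.0])
        assert pr.prominent_genes(expr) == ["g1", "g2"]


class TestFoldChanges:
    def test_pseudocount_fold_change(self):
        expr = toy_expression([[10, 40], [10, 40]], [1.0, 2.0])
        out = pr.switch_fold_changes(expr, 1.0, 2.0)
        assert out["log2fc"]["g1"] == pytest.approx(log2(40.5 / 10.5))
        assert out["changed_fraction"] == 1.0

    def test_unchanged_genes(self):
        expr = toy_expression([[10, 10], [3, 3]], [1.0, 2.0])
        assert pr.switch_fold_changes(expr, 1.0, 2.0)["changed_fraction"] == 0.0

    def test_same_timepoint_raises(self):
        expr = toy_expression([[10, 10]], [1.0, 2.0])
        with pytest.raises(ValidationError):
            pr.switch_fold_changes(expr, 1.0, 1.0)


def _brute_force_complete_linkage(X):
    """O(n^3) agglomerative complete linkage under Pearson distance.

    Returns the sorted list of merge heights and the 3-group partition.
    """
    X = np.asarray(X, dtype=float)
    n = len(X)
    Xc = X - X.mean(axis=1, keepdims=True)

    def dist(i, j):
        r = np.corrcoef(X[i], X[j])[0, 1]
        return 1 - r

    D = {(i, j): dist(i, j) for i in range(n) for j in range(i + 1, n)}
    clusters = {i: {i} for i in range(n)}
    heights = []
    partitions = {}
    while len(clusters) > 1:
        best, bd = None, np.inf
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = max(D[(min(i, j), max(i, j))]
                    for i in clusters[a] for j in clusters[b])
            if d < bd:
                bd, best = d, (a, b)
        a, b = best
        clusters[a] = clusters[a] | clusters.pop(b)
        heights.append(bd)
        partitions[len(clusters)] = [frozenset(m) for m in clusters.values()]
    return heights, partitions


class TestClusterPhases:
    def _phase_map(self):
        return {1.0: "exponential", 2.0: "transitional", 3.0: "stationary"}

    def test_identical_profiles_share_cluster(self):
        expr = toy_expression([[1, 5, 2], [1, 5, 2], [9, 1, 1]],
                              [1.0, 2.0, 3.0])
        out = pr.cluster_phases(expr, self._phase_map(), n_clusters=2)
        a = out.assignments
        assert a.loc["g1", "cluster"] == a.loc["g2", "cluster"]
        assert a.loc["g1", "cluster"] != a.loc["g3", "cluster"]

    def test_anticorrelated_profiles_at_maximal_distance(self):
        from scipy.spatial.distance import pdist
        X = np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        d = pdist(X - X.mean(axis=1, keepdims=True), metric="correlation")
        assert d[0] == pytest.approx(2.0)

    def test_zero_variance_profiles_excluded(self):
        expr = toy_expression([[2, 2, 2], [1, 5, 2], [9, 1, 1]],
                              [1.0, 2.0, 3.0])
        out = pr.cluster_phases(expr, self._phase_map(), n_clusters=2)
        assert out.excluded == ["g1"]
        assert "g1" not in out.assignments.index

    def test_phase_from_centroid_peak(self):
        expr = toy_expression([[9, 1, 1], [8, 2, 1], [1, 1, 9], [1, 2, 8]],
                              [1.0, 2.0, 3.0])
        out = pr.cluster_phases(expr, self._phase_map(), n_clusters=2)
        assert out.phase_of("g1") == "exponential"
        assert out.phase_of("g3") == "stationary"

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_tree_matches_bruteforce_enumeration(self, seed):
        """scipy complete linkage equals an O(n^3) re-derivation on 6-8 gene
        toys: same merge heights and the same 3-group partition."""
        from scipy.cluster.hierarchy import linkage
        rng = np.random.default_rng(seed)
        n = rng.integers(6, 9)
        X = rng.normal(0, 1, (int(n), 5))
        heights, partitions = _brute_force_complete_linkage(X)
        Xc = X - X.mean(axis=1, keepdims=True)
        Z = linkage(Xc, method="complete", metric="correlation")
        np.testing.assert_allclose(sorted(Z[:, 2]), sorted(heights),
                                   atol=1e-10)
        expr = toy_expression(X, list(range(5)))
        out = pr.cluster_phases(expr, {float(t): "exponential"
                                       for t in range(5)}, n_clusters=3)
        got = {frozenset(out.assignments.index[out.assignments["cluster"] == c])
               for c in out.assignments["cluster"].unique()}
        want = {frozenset(f"g{i + 1}" for i in m) for m in partitions[3]}
        assert got == want

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(data=st.data())
    def test_affine_invariance_of_clustering(self, data):
        """Per-gene affine rescaling of profiles never changes the clusters
        (Pearson distance property)."""
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        X = rng.normal(0, 1, (8, 5))
        a = rng.uniform(0.2, 5.0, size=(8, 1))
        b = rng.uniform(-10, 10, size=(8, 1))
        pmap = {float(t): "exponential" for t in range(5)}
        out1 = pr.cluster_phases(toy_expression(X, range(5)), pmap)
        out2 = pr.cluster_phases(toy_expression(a * X + b, range(5)), pmap)
        groups = lambda o: {frozenset(
            o.assignments.index[o.assignments["cluster"] == c])
            for c in o.assignments["cluster"].unique()}
        assert groups(out1) == groups(out2)


def _exact_fisher_tail(a, b, c, d):
    """Hypergeometric upper-tail P(X >= a) in exact rational arithmetic."""
    M, n, N = a + b + c + d, a + c, a + b
    denom = comb(M, N)
    num = sum(comb(n, x) * comb(M - n, N - x)
              for x in range(a, min(n, N) + 1))
    return Fraction(num, denom)


class TestCategoryEnrichment:
    def test_complete_overlap_small_universe(self):
        universe = [f"g{i}" for i in range(10)]
        cat = {g: ("A" if i < 5 else "B") for i, g in enumerate(universe)}
        res = pr.category_enrichment(universe[:5], universe, cat)
        byname = {r.category: r for r in res}
        assert byname["A"].p == pytest.approx(1 / 252)

    def test_overlap_at_expectation_fold_one(self):
        universe = [f"g{i}" for i in range(20)]
        cat = {g: ("A" if i < 10 else "B") for i, g in enumerate(universe)}
        res = pr.category_enrichment(universe[:5] + universe[10:15],
                                     universe, cat)
        assert all(r.fold_enrichment == pytest.approx(1.0) for r in res)

    def test_set_equal_universe_p_one(self):
        universe = [f"g{i}" for i in range(12)]
        cat = {g: ("A" if i % 2 else "B") for i, g in enumerate(universe)}
        res = pr.category_enrichment(universe, universe, cat)
        assert all(r.p == pytest.approx(1.0) for r in res)

    def test_fisher_matches_exact_rational_spot_checks(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 13, size=4)
            p = pr.fisher_one_sided(int(a), int(b), int(c), int(d))
            exact = float(_exact_fisher_tail(int(a), int(b), int(c), int(d)))
            assert p == pytest.approx(exact, rel=1e-10)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_q_values_monotone_in_p_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        universe = [f"g{i}" for i in range(40)]
        cats = rng.integers(0, 5, size=40)
        cat_map = {g: f"C{c}" for g, c in zip(universe, cats)}
        gene_set = [g for g in universe if rng.random() < 0.4]
        res = pr.category_enrichment(gene_set, universe, cat_map)
        res.sort(key=lambda r: r.p)
        qs = [r.q for r in res]
        assert all(a <= b + 1e-12 for a, b in zip(qs, qs[1:]))
        assert all(r.q <= 1.0 + 1e-12 and r.q >= r.p - 1e-12 for r in res)
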