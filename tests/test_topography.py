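"""Genome-scale topography statistics."""

import itertools
import math

import numpy as np
import pytest

from switchtome.model import (ChromosomeModel, GeneAnnotation, RegionPartition,
                              ValidationError)
from switchtome import topography as topo

from conftest import make_track, toy_expression


class TestTranscribedFraction:
    def test_single_position_each_metric(self):
        tr = make_track([1, 0], [0, 0])
        out = topo.transcribed_fraction([tr], 1)
        assert out["either_strand"] == 0.5
        assert out["unstranded"] == 0.5
        assert out["singleton_fraction"] == 1.0

    def test_saturated_coverage(self):
        tr = make_track([2, 2], [2, 2])
        out = topo.transcribed_fraction([tr], 1)
        assert out["either_strand"] == 1.0
        assert out["singleton_fraction"] == 0.0

    def test_min_cov_threshold_and_monotonicity(self):
        tr = make_track([1, 2, 3], [0, 0, 0])
        assert topo.transcribed_fraction([tr], 3)["unstranded"] == pytest.approx(1 / 3)
        fracs = [topo.transcribed_fraction([tr], mc)["unstranded"]
                 for mc in (1, 2, 3, 4)]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))

    def test_empty_track_set_raises(self):
        with pytest.raises(ValidationError, match="empty"):
            topo.transcribed_fraction([], 1)


class TestStrandPreference:
    def test_replichore_one_preference(self):
        chrom = ChromosomeModel("chr", 200, origin=0)   # terminus 100
        tr = make_track(np.full(200, 30.0), np.full(200, 10.0))
        stat = topo.strand_preference(tr, chrom, bin_size=100)
        assert stat.values[0] == pytest.approx(0.5)     # leading = plus there
        assert stat.values[1] == pytest.approx(-0.5)    # leading = minus there

    def test_antisymmetry_under_strand_swap(self):
        chrom = ChromosomeModel("chr", 300, origin=0)
        rng = np.random.default_rng(0)
        plus, minus = rng.random(300) * 5, rng.random(300) * 5
        a = topo.strand_preference(make_track(plus, minus), chrom, 50).values
        b = topo.strand_preference(make_track(minus, plus), chrom, 50).values
        np.testing.assert_allclose(a, -b)

    def test_zero_bins_are_missing(self):
        chrom = ChromosomeModel("chr", 100, origin=0)
        plus = np.zeros(100)
        plus[:50] = 2.0
        stat = topo.strand_preference(make_track(plus, np.zeros(100)), chrom, 50)
        assert np.isnan(stat.values[1])

    def test_unstranded_raises(self):
        chrom = ChromosomeModel("chr", 100)
        with pytest.raises(ValidationError):
            topo.strand_preference(make_track(np.ones(100)), chrom, 50)

    def test_leading_bias_recovered_from_simulation(self, default_bundle):
        """The generator puts ~75% of high-expression genes on the leading
        strand; the genome-median bin preference must come out positive."""
        cfg = default_bundle["truth"].config
        pooled = topo.pool_tracks(default_bundle["tracks"].values())
        stat = topo.strand_preference(pooled, default_bundle["chrom"], 10_000)
        assert np.nanmedian(stat.values) > 0.1

    def test_invariant_under_bin_refinement_piecewise_constant(self):
        chrom = ChromosomeModel("chr", 400, origin=0)
        plus = np.repeat([4.0, 1.0, 3.0, 2.0], 100)
        minus = np.repeat([1.0, 2.0, 1.0, 5.0], 100)
        coarse = topo.strand_preference(make_track(plus, minus), chrom, 100).values
        fine = topo.strand_preference(make_track(plus, minus), chrom, 50).values
        np.testing.assert_allclose(np.repeat(coarse, 2), fine)


def _uniform_partition(L, half):
    return RegionPartition([(0, half, "core"), (half, L, "noncore")], L)


class TestRegionEnrichment:
    def test_uniform_expression_zero_enrichment(self):
        part = _uniform_partition(200, 100)
        tracks = {0.0: make_track(np.ones(200), np.zeros(200))}
        enr = topo.region_enrichment(tracks, part, bin_size=10)
        assert np.allclose(enr.table["log2_enrichment"], 0.0)

    def test_known_region_means(self):
        part = _uniform_partition(200, 100)
        plus = np.concatenate([np.full(100, 20.0), np.full(100, 5.0)])
        tracks = {0.0: make_track(plus, np.zeros(200))}
        enr = topo.region_enrichment(tracks, part, bin_size=10)
        assert enr.enrichment(0.0, "noncore") == pytest.approx(
            math.log2(5 / 12.5))
        assert enr.enrichment(0.0, "core") == pytest.approx(math.log2(20 / 12.5))

    def test_label_permutation_has_no_mean_enrichment(self):
        """Randomly permuted region labels must show no systematic enrichment
        (expectation over 100 permutations)."""
        rng = np.random.default_rng(7)
        L, b = 2000, 10
        plus = rng.lognormal(0, 1, L)
        tracks = {0.0: make_track(plus, np.zeros(L))}
        es = []
        for _ in range(100):
            labels = np.array(["core"] * (L // (2 * b)) +
                              ["noncore"] * (L // (2 * b)))
            rng.shuffle(labels)
            ivs = [(i * b, (i + 1) * b, labels[i]) for i in range(L // b)]
            part = RegionPartition(ivs, L)
            enr = topo.region_enrichment(tracks, part, bin_size=b)
            es.append(enr.enrichment(0.0, "noncore"))
        assert abs(np.mean(es)) < 0.05

    def test_switch_detection_polarity(self):
        part = _uniform_partition(200, 100)
        hi = np.concatenate([np.full(100, 5.0), np.full(100, 20.0)])
        lo = np.concatenate([np.full(100, 20.0), np.full(100, 5.0)])
        tracks = {1.0: make_track(hi, np.zeros(200)),
                  2.0: make_track(lo, np.zeros(200))}
        enr = topo.region_enrichment(tracks, part, 10, switch_timepoint=2.0)
        assert enr.switch_detected and enr.switch_sign == -1
        flipped = topo.region_enrichment(
            {1.0: tracks[2.0], 2.0: tracks[1.0]}, part, 10,
            switch_timepoint=2.0)
        assert flipped.switch_detected and flipped.switch_sign == +1

    def test_empty_region_raises(self):
        part = _uniform_partition(200, 100)
        tracks = {0.0: make_track(np.ones(200), np.zeros(200))}
        with pytest.raises(ValidationError):
            topo.region_enrichment(tracks, part, bin_size=200)


def _toy_border_setup(n_genes=100, n_tr=5, fc_tr=3.0, L=100_000):
    """Genes on a 100 kb chromosome; ``n_tr`` transposons packed tightly at
    the core/noncore border, the rest spread over the first replichore."""
    part = RegionPartition([(0, L // 2, "core"), (L // 2, L, "noncore")], L)
    genes, vals_pre, vals_post, ids = [], [], [], []
    border = L // 2
    for i in range(n_genes):
        gid = f"g{i + 1:03d}"
        is_tr = i < n_tr
        if is_tr:
            start = border - 300 * n_tr + 600 * i    # straddles the border
        else:
            start = 1000 + (i - n_tr) * ((border - 6000) // max(1, n_genes - n_tr))
        flag = frozenset({"transposon"}) if is_tr else frozenset()
        genes.append(GeneAnnotation(gid, start, start + 500, "+", 500,
                                    flags=flag))
        ids.append(gid)
        vals_pre.append(100.0)
        vals_post.append(100.0 * (2 ** fc_tr if is_tr else 1.0))
    expr = toy_expression(np.column_stack([vals_pre, vals_post]), [1.0, 2.0],
                          gene_ids=ids)
    return expr, genes, part


class TestBorderInduction:
    def test_no_signal_gives_null_statistics(self):
        expr, genes, part = _toy_border_setup(fc_tr=0.0)
        out = topo.border_induction(expr, genes, part, (1.0, 2.0),
                                    window=2_500, n_perm=200, seed=0)
        assert out["fold"] == pytest.approx(1.0)
        assert out["p_mw"] >= 0.3 and out["p_perm"] >= 0.3

    def test_exhaustive_permutation_matches_bruteforce(self):
        """On a 20-gene instance the permutation p equals exact enumeration."""
        expr, genes, part = _toy_border_setup(n_genes=20, n_tr=5)
        out = topo.border_induction(expr, genes, part, (1.0, 2.0),
                                    window=2_500, seed=0)
        fc = np.log2((expr.at_timepoint(2.0) + 0.5)
                     / (expr.at_timepoint(1.0) + 0.5))
        k = out["n_set"]
        obs = out["median_log2fc"]
        hits = total = 0
        for subset in itertools.combinations(range(len(fc)), k):
            total += 1
            if np.median(fc.to_numpy()[list(subset)]) >= obs:
                hits += 1
        assert out["p_perm"] == pytest.approx(hits / total)

    def test_monte_carlo_agrees_with_exact(self):
        expr, genes, part = _toy_border_setup(n_genes=20, n_tr=5)
        exact = topo.border_induction(expr, genes, part, (1.0, 2.0),
                                      window=2_500, seed=0)["p_perm"]
        mc = topo.border_induction(expr, genes, part, (1.0, 2.0),
                                   window=2_500, seed=0, exact_limit=0,
                                   n_perm=20_000)["p_perm"]
        sd = math.sqrt(exact * (1 - exact) / 20_000)
        assert abs(mc - exact) < 4 * sd + 1e-4

    def test_no_qualifying_genes_raises(self):
        expr, genes, part = _toy_border_setup(n_tr=0)
        with pytest.raises(ValidationError, match="bp of a region border"):
            topo.border_induction(expr, genes, part, (1.0, 2.0), window=2_500)

    def test_default_simulation_detects_border_induction(self, default_bundle,
                                                         default_expr):
        cfg = default_bundle["truth"].config
        out = topo.border_induction(default_expr, default_bundle["genes"],
                                    default_bundle["partition"],
                                    (40.0, cfg.switch_timepoint), seed=0)
        assert out["p_perm"] < 0.01
        assert out["p_mw"] < 0.01
        assert out["fold"] > 2


class TestAntisense:
    def _gene(self, start, end, strand="+", gid="g"):
        return GeneAnnotation(gid, start, end, strand, end - start)

    def test_simple_ratio(self):
        tr = make_track(np.full(100, 97.0), np.full(100, 3.0))
        out = topo.antisense_fraction([tr], [self._gene(0, 100)])
        assert out["overall"] == pytest.approx(0.03)

    def test_no_antisense_zero_profile(self):
        tr = make_track(np.full(100, 5.0), np.zeros(100))
        out = topo.antisense_fraction([tr], [self._gene(0, 100)])
        assert out["overall"] == 0.0
        assert np.all(out["positional_profile"] == 0.0)

    def test_minus_strand_orientation_flips_profile(self):
        """A 3'-skewed antisense signal must land in the last deciles
        regardless of gene strand."""
        plus = np.zeros(100)
        minus = np.full(100, 10.0)
        plus[:10] = 5.0                      # genomic left end
        out = topo.antisense_fraction([make_track(plus, minus)],
                                      [self._gene(0, 100, "-")])
        profile = out["positional_profile"]
        assert profile[-1] > 0 and profile[0] == 0.0

    def test_simulation_profile_rises_at_three_prime(self, default_bundle):
        out = topo.antisense_fraction(default_bundle["tracks"].values(),
                                      default_bundle["genes"])
        prof = out["positional_profile"]
        assert prof[7] < prof[8] < prof[9]
        assert out["overall"] == pytest.approx(0.03, abs=0.005)


class TestIntergenicCandidates:
    def _setup(self, L=1000):
        chrom = ChromosomeModel("chr", L)
        gene = GeneAnnotation("g1", 0, 300, "+", 300)
        return chrom, [gene]

    def test_expressed_block_called(self):
        chrom, genes = self._setup()
        plus = np.zeros(1000)
        plus[500:600] = 10.0
        tr = make_track(plus, np.zeros(1000), library_size=1e6)
        out = topo.intergenic_candidates([tr], genes, chrom)
        assert len(out) == 1
        assert (out.loc[0, "start"], out.loc[0, "end"]) == (500, 600)

    def test_same_strand_gene_overlap_suppresses(self):
        chrom, genes = self._setup()
        plus = np.zeros(1000)
        plus[250:350] = 10.0                # overlaps the gene on + strand
        tr = make_track(plus, np.zeros(1000), library_size=1e6)
        out = topo.intergenic_candidates([tr], genes, chrom)
        assert len(out) == 1 and out.loc[0, "start"] == 300   # clipped, not called inside

    def test_short_gap_runs_are_merged(self):
        chrom, genes = self._setup()
        plus = np.zeros(1000)
        plus[500:560] = 10.0
        plus[570:630] = 10.0                # 10 bp gap < 20 bp
        tr = make_track(plus, np.zeros(1000), library_size=1e6)
        out = topo.intergenic_candidates([tr], genes, chrom)
        assert len(out) == 1
        assert out.loc[0, "end"] - out.loc[0, "start"] == 130

    def test_length_window_enforced(self):
        chrom, genes = self._setup()
        plus = np.zeros(1000)
        plus[500:530] = 10.0                # 30 nt < min_len 50
        tr = make_track(plus, np.zeros(1000), library_size=1e6)
        assert len(topo.intergenic_candidates([tr], genes, chrom)) == 0

    def test_bad_length_window_raises(self):
        chrom, genes = self._setup()
        tr = make_track(np.zeros(1000), np.zeros(1000), library_size=1e6)
        with pytest.raises(ValidationError):
            topo.intergenic_candidates([tr], genes, chrom, min_len=100,
                                       max_len=50)

    def test_fragment_support_flag(self):
        chrom, genes = self._setup()
        plus = np.zeros(1000)
        plus[500:600] = 10.0
        tr = make_track(plus, np.zeros(1000), library_size=1e6)
        fplus = np.zeros(1000)
        fplus[500:580] = 3.0                # 80% covered
        ftr = make_track(fplus, np.zeros(1000), library_size=1e6)
        out = topo.intergenic_candidates([tr], genes, chrom,
                                         fragment_tracks=[ftr])
        assert bool(out.loc[0, "supported"])

    def test_planted_ncrnas_recovered(self, default_bundle):
        """Planted intergenic elements with adequate expression are found."""
        truth = default_bundle["truth"]
        out = topo.intergenic_candidates(
            default_bundle["tracks"].values(), default_bundle["genes"],
            default_bundle["chrom"],
            fragment_tracks=default_bundle["frag_tracks"].values())
        pooled = topo.pool_tracks(default_bundle["tracks"].values())
        found = 0
        expressed = 0
        for _, row in truth.ncrna.iterrows():
            vec = pooled.strand_vector(row["strand"])
            mean_cov = float(vec[int(row["start"]):int(row["end"])].mean())
            # require a comfortably expressed element in the pooled signal
            if mean_cov * 1e6 / pooled.library_size < 3.0:
                continue
            expressed += 1
            hit = ((out["strand"] == row["strand"])
                   & (out["start"] <= row["start"])
                   & (out["end"] >= row["end"]))
            found += bool(hit.any())
        assert expressed >= 10
        assert found >= 0.8 * expressed
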