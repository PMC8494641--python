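"""DMS permutation test, DMR assembly/filtering, correlations, enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from methylatlas.dmr import (
    DmrRecord,
    _rms_stat,
    assemble_dmrs,
    call_dms,
    dmr_gene_correlation,
    dmr_sample_fractions,
    gradient_dmr,
    region_gene_enrichment,
    robust_mean_filter,
)
from methylatlas.simulate import PlantedDmr, generate_gradient_population


def _dms_frame(positions, significant=None, chrom="chrS"):
    n = len(positions)
    sig = np.ones(n, dtype=bool) if significant is None else np.asarray(significant)
    return pd.DataFrame(
        {"chrom": chrom, "pos": positions, "stat": 1.0, "p": 0.001,
         "p_adj": 0.001, "tested": True, "significant": sig}
    )


class TestCallDms:
    def test_clear_difference_is_significant(self):
        mc = np.array([[10], [0]])
        cov = np.array([[10], [10]])
        tab = call_dms(mc, cov, np.array([100]), n_perm=999, seed=0)
        assert tab.p[0] <= 0.01

    def test_identical_fractions_stat_zero_p_one(self):
        mc = np.array([[5, 2], [5, 2]])
        cov = np.array([[10, 4], [10, 4]])
        tab = call_dms(mc, cov, np.array([10, 20]), n_perm=199, seed=0)
        assert np.allclose(tab.stat, 0.0)
        assert np.allclose(tab.p, 1.0)

    def test_matches_exhaustive_enumeration_oracle(self):
        # 2 samples, cov (3,3), total mc 3: the permutation null is
        # mc_1 ~ Hypergeometric(6, 3, 3); exact tail vs empirical p
        covs = np.array([3, 3])
        support = np.arange(4)
        pmf = hypergeom.pmf(support, 6, 3, 3)
        stats = np.array([_rms_stat(np.array([m, 3 - m]), covs) for m in support])
        tab = call_dms(
            np.array([[3], [0]]), np.array([[3], [3]]),
            np.array([100]), n_perm=30_000, seed=1,
        )
        exact = pmf[stats >= tab.stat[0] - 1e-12].sum()
        assert tab.p[0] == pytest.approx(exact, abs=0.01)

    def test_more_coverage_at_same_fractions_strengthens_evidence(self):
        mc1 = np.array([[8], [2]])
        cov1 = np.array([[10], [10]])
        p_small = call_dms(mc1, cov1, np.array([1]), n_perm=999, seed=0).p[0]
        p_large = call_dms(4 * mc1, 4 * cov1, np.array([1]), n_perm=999, seed=0).p[0]
        assert p_large < p_small

    def test_type_one_error_calibrated(self, rng):
        n_sites, n_samples = 400, 8
        p = rng.beta(5, 5, size=n_sites)
        cov = rng.poisson(50, size=(n_samples, n_sites)) + 1
        mc = rng.binomial(cov, p[None, :])
        tab = call_dms(mc, cov, np.arange(n_sites), n_perm=199, seed=2)
        rate = np.mean(tab.p[tab.tested] <= 0.05)
        assert 0.02 < rate < 0.08

    def test_undercovered_sites_skipped(self):
        mc = np.array([[1, 1], [0, 0]])
        cov = np.array([[2, 2], [0, 2]])
        tab = call_dms(mc, cov, np.array([1, 2]), n_perm=99, seed=0)
        assert not tab.tested[0] and tab.tested[1]

    def test_requires_two_samples(self):
        with pytest.raises(ValueError):
            call_dms(np.array([[1]]), np.array([[2]]), np.array([1]))


class TestAssembleDmrs:
    def test_gap_rule(self):
        dms = _dms_frame([100, 300, 600])
        regions = assemble_dmrs(dms, max_gap=250)
        assert [(r.start, r.end) for r in regions] == [(100, 301), (600, 601)]

    def test_gap_of_exactly_250_merges(self):
        dms = _dms_frame([100, 350])
        regions = assemble_dmrs(dms, max_gap=250)
        assert len(regions) == 1

    def test_only_significant_sites_used(self):
        dms = _dms_frame([100, 200, 300], significant=[True, False, True])
        regions = assemble_dmrs(dms)
        assert len(regions) == 1
        assert list(regions[0].sites) == [100, 300]

    def test_empty_input(self):
        assert assemble_dmrs(_dms_frame([], significant=[])) == []


class TestRobustMeanFilter:
    def test_hand_example_low_sample_assigned_hypo(self):
        # nine samples at 0.8, one at 0.1 with site evidence -> hypo
        dmr = DmrRecord("chrS", 0, 100, np.array([50]))
        fracs = np.array([[0.8] * 9 + [0.1]])
        hypo = np.zeros((1, 10), dtype=bool)
        hypo[0, 9] = True
        hyper = np.zeros((1, 10), dtype=bool)
        kept = robust_mean_filter([dmr], fracs, hypo, hyper)
        assert kept[0].hypo_samples == [9]
        assert kept[0].robust_mean == pytest.approx(0.8)

    def test_all_within_band_excluded(self):
        dmr = DmrRecord("chrS", 0, 100, np.array([50]))
        fracs = np.array([[0.5, 0.55, 0.6, 0.65, 0.7]])
        flags = np.ones((1, 5), dtype=bool)
        assert robust_mean_filter([dmr], fracs, flags, flags) == []

    def test_boundary_exactly_delta_below_not_hypo(self):
        dmr = DmrRecord("chrS", 0, 100, np.array([50]))
        fracs = np.array([[0.8] * 9 + [0.5]])  # 0.5 == m - 0.3 exactly
        flags = np.ones((1, 10), dtype=bool)
        kept = robust_mean_filter([dmr], fracs, flags, np.zeros((1, 10), bool))
        assert kept == []

    def test_few_samples_median_fallback_warns(self):
        dmr = DmrRecord("chrS", 0, 100, np.array([50]))
        fracs = np.array([[0.9, 0.85, 0.1]])
        flags = np.ones((1, 3), dtype=bool)
        with pytest.warns(UserWarning, match="median"):
            kept = robust_mean_filter([dmr], fracs, flags, np.zeros((1, 3), bool))
        assert kept[0].robust_mean == pytest.approx(0.85)


class TestDmrGeneCorrelation:
    # ~100 subtype profiles: chance covariate alignment (the main erosion of
    # residual correlations) scales as 1/sqrt(n_subtypes)
    def _planted(self, rng, n_subtypes=100, n_dmr=40, n_gene=40, n_linked=5):
        shared = rng.normal(0, 1, (n_subtypes, n_linked))
        dmr = rng.normal(0, 1, (n_subtypes, n_dmr))
        gene = rng.normal(0, 1, (n_subtypes, n_gene))
        dmr[:, :n_linked] = shared + rng.normal(0, 0.05, shared.shape)
        gene[:, :n_linked] = shared + rng.normal(0, 0.05, shared.shape)
        centers = rng.integers(0, 3_000_000, n_dmr)
        tss = centers.copy()[:n_gene]  # linked pairs colocate
        return dmr, gene, centers, tss

    def test_planted_pairs_recovered_with_high_r(self, rng):
        dmr, gene, centers, tss = self._planted(rng)
        # measured global levels are independent covariates; regressing them
        # out must not erode the planted DMR-gene correlation
        out = dmr_gene_correlation(
            dmr, gene, centers, tss,
            global_mcg=rng.normal(0.75, 0.02, dmr.shape[0]),
            global_mch=rng.normal(0.03, 0.005, dmr.shape[0]),
            n_perm=50, seed=0,
        )
        linked = out[(out.dmr == out.gene) & (out.dmr < 5)]
        assert (linked.r > 0.9).all()
        assert linked.reported.all()

    def test_pairs_beyond_window_not_tested(self, rng):
        dmr = rng.normal(0, 1, (12, 1))
        gene = rng.normal(0, 1, (12, 1))
        out = dmr_gene_correlation(
            dmr, gene, np.array([0]), np.array([1_200_000]), n_perm=10, seed=0
        )
        assert len(out) == 0

    def test_chromosome_mismatch_not_tested(self, rng):
        dmr = rng.normal(0, 1, (12, 1))
        gene = rng.normal(0, 1, (12, 1))
        out = dmr_gene_correlation(
            dmr, gene, np.array([0]), np.array([0]),
            dmr_chrom=np.array(["chr1"]), gene_chrom=np.array(["chr2"]),
            n_perm=10, seed=0,
        )
        assert len(out) == 0

    def test_null_inputs_report_near_nominal_rate(self, rng):
        n_subtypes = 40
        dmr = rng.normal(0, 1, (n_subtypes, 60))
        gene = rng.normal(0, 1, (n_subtypes, 60))
        centers = rng.integers(0, 2_000_000, 60)
        tss = rng.integers(0, 2_000_000, 60)
        out = dmr_gene_correlation(dmr, gene, centers, tss, n_perm=100, seed=3)
        assert out.reported.mean() <= 0.007


class TestGradientDmr:
    def test_planted_signs_classified(self):
        dmrs = [
            PlantedDmr(0, 3_000, +1),
            PlantedDmr(10_000, 13_000, +1),
            PlantedDmr(20_000, 23_000, -1),
        ]
        counts, truth = generate_gradient_population(
            400, (0.005, 0.02), dmrs, n_sites=400, site_spacing=100,
            site_cov_mean=2.0, seed=8,
        )
        res = gradient_dmr(
            counts, truth.cell_global["CH"], cells_per_group=80,
            n_control_groups=5, n_perm=999, seed=1,
        )
        assert len(res.gradient_dmrs) > 0
        # every classified DMR's sign matches its planted interval
        for rec, sign in zip(res.gradient_dmrs, res.classification):
            if sign == 0:
                continue
            planted = [d.sign for d in dmrs if d.start < rec.end and rec.start < d.end]
            assert planted and planted[0] == sign
        assert set(res.classification) >= {1, -1}

    def test_insufficient_cells_error_states_minimum(self):
        counts, truth = generate_gradient_population(
            50, (0.005, 0.02), [], n_sites=20, seed=0
        )
        with pytest.raises(ValueError, match="1600"):
            gradient_dmr(counts, truth.cell_global["CH"])

    def test_degenerate_flat_dmr_unclassified(self):
        seq_r = np.std([0.5, 0.5, 0.5, 0.5])
        assert seq_r == 0  # pearson undefined -> classification 0 by construction


class TestRegionGeneEnrichment:
    genes = pd.DataFrame(
        {"chrom": ["chrS"], "start": [1_000_000], "end": [1_010_000],
         "name": ["g"], "strand": ["+"]}
    )

    def _positions(self, rng, body_dms, body_sites, flank_dms, flank_sites):
        body = rng.integers(1_000_000, 1_010_000, body_sites)
        flank = rng.integers(0, 1_000_000, flank_sites)
        dms = np.concatenate([body[:body_dms], flank[:flank_dms]])
        return np.sort(dms), np.sort(np.concatenate([body, flank]))

    def test_dense_gene_enriched_with_large_odds_ratio(self, rng):
        dms, sites = self._positions(rng, 25, 100, 50, 20_000)
        out = region_gene_enrichment(dms, sites, self.genes)
        assert out.enriched[0]
        assert out.odds_ratio[0] > 50

    def test_uniform_density_not_enriched(self, rng):
        dms, sites = self._positions(rng, 30, 100, 6000, 20_000)
        out = region_gene_enrichment(dms, sites, self.genes)
        assert out.odds_ratio[0] == pytest.approx(1.0, rel=0.5)
        assert not out.enriched[0]

    def test_exactly_twenty_dms_not_enriched(self, rng):
        dms, sites = self._positions(rng, 20, 100, 10, 20_000)
        out = region_gene_enrichment(dms, sites, self.genes)
        assert not out.enriched[0]

    def test_short_genes_excluded(self, rng):
        short = self.genes.assign(end=self.genes.start + 4_000)
        dms, sites = self._positions(rng, 25, 100, 50, 20_000)
        out = region_gene_enrichment(dms, sites, short)
        assert len(out) == 0


class TestDmrSampleFractions:
    def test_pooled_fraction_and_flags(self):
        dms = _dms_frame([100, 200])
        for s, fr, cv in [(0, [0.9, 0.8], [10, 10]), (1, [0.1, 0.2], [10, 10])]:
            dms[f"frac_{s}"] = fr
            dms[f"cov_{s}"] = cv
        dmrs = assemble_dmrs(dms)
        fracs, hypo, hyper = dmr_sample_fractions(dmrs, dms, 2)
        assert fracs[0, 0] == pytest.approx(0.85)
        assert fracs[0, 1] == pytest.approx(0.15)
        assert hyper[0, 0] and hypo[0, 1]
        assert not hypo[0, 0] and not hyper[0, 1]
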