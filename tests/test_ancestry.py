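"""Ancestry posteriors, correlation analyses and the classification test."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from apiscan import ancestry


def row(**kw):
    r = {f"p{s}": 0.0 for s in ancestry.STATES}
    for k, v in kw.items():
        r[f"p{k}"] = v
    return [r[f"p{s}"] for s in ancestry.STATES]


def fisher_enumeration_oracle(table):
    """Two-sided Fisher p by full enumeration over the free cell."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    N = r1 + r2

    def prob(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(N, c1)

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


class TestCombinePosterior:
    def test_pure_AA_gives_one(self):
        assert ancestry.combine_posterior_A(row(AA=1.0)) == pytest.approx(1.0)

    def test_MA_gives_half(self):
        assert ancestry.combine_posterior_A(row(MA=1.0)) == pytest.approx(0.5)

    def test_printed_arithmetic_case(self):
        r = row(AA=0.5, CA=0.2, MA=0.1, MM=0.2)
        assert ancestry.combine_posterior_A(r) == pytest.approx(0.65)

    def test_not_normalized_raises(self):
        with pytest.raises(ValueError):
            ancestry.combine_posterior_A(row(AA=0.7))

    def test_three_ancestries_sum_to_one(self):
        rng = np.random.default_rng(0)
        probs = rng.dirichlet(np.ones(6), size=200)
        out = ancestry.combine_posterior_all(probs)
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(out[:, 2], ancestry.combine_posterior_A(probs))


class TestAncestryTrack:
    def _posteriors(self, pa_by_pop, n_snps=50):
        rows = []
        for sample, pa in pa_by_pop:
            for s in range(n_snps):
                rows.append({"snp": s, "sample": sample,
                             **dict(zip([f"p{x}" for x in ancestry.STATES],
                                        row(AA=pa, MM=1 - pa)))})
        return pd.DataFrame(rows)

    def test_identical_posteriors_delta_zero(self):
        post = self._posteriors([("l1", 0.8), ("l2", 0.8), ("h1", 0.8), ("h2", 0.8)])
        pops = {"l1": "lowland", "l2": "lowland", "h1": "highland", "h2": "highland"}
        track = ancestry.population_ancestry_track(post, pops)
        assert np.allclose(track["delta"], 0.0)

    def test_configured_population_difference_recovered(self):
        post = self._posteriors([("l1", 0.847), ("h1", 0.686)])
        track = ancestry.population_ancestry_track(
            post, {"l1": "lowland", "h1": "highland"})
        assert track["delta"].mean() == pytest.approx(0.161, abs=1e-9)

    def test_empty_population_raises(self):
        post = self._posteriors([("l1", 0.8)])
        with pytest.raises(ValueError):
            ancestry.population_ancestry_track(post, {"l1": "lowland"})

    def test_generator_truth_recovered(self, default_panels):
        # genome-mean delta ~ 0.847 - 0.686 = 0.161 on default panels
        from apiscan import simdata

        cfg, _, mat, truth = default_panels[0]
        post, _ = simdata.generate_posteriors_and_clines(truth, cfg)
        pops = dict(zip(mat.samples, mat.populations))
        track = ancestry.population_ancestry_track(post, pops)
        n = cfg.n_snps
        se = 3 * 0.5 / np.sqrt(n * 29)
        assert abs(track["delta"].mean() - 0.161) < 0.01
        # selected loci shifted well above the genome mean
        sel = track.loc[np.isin(track.index.to_numpy(), truth.selected_index)]
        assert sel["delta"].mean() > track["delta"].mean() + 0.25


class TestCorrelations:
    def test_spearman_perfect_ordering(self):
        wf = pd.DataFrame({
            "chrom": ["chr1"] * 10, "start": np.arange(10) * 10_000 + 1,
            "end": (np.arange(10) + 1) * 10_000,
            "value": np.linspace(0.01, 0.1, 10),
        })
        track = pd.DataFrame({
            "snp": np.arange(10),
            "delta": np.linspace(0.0, 0.9, 10),
        }).set_index("snp")
        positions = pd.DataFrame({
            "snp": np.arange(10), "chrom": ["chr1"] * 10,
            "pos": np.arange(10) * 10_000 + 5_000,
        })
        rho, p = ancestry.correlate_fst_ancestry(wf, track, positions)
        assert rho == pytest.approx(1.0)

    def test_independent_tracks_uncorrelated(self):
        rng = np.random.default_rng(5)
        n = 400
        wf = pd.DataFrame({
            "chrom": ["chr1"] * n, "start": np.arange(n) * 10_000 + 1,
            "end": (np.arange(n) + 1) * 10_000,
            "value": rng.random(n),
        })
        track = pd.DataFrame({
            "snp": np.arange(n), "delta": rng.random(n),
        }).set_index("snp")
        positions = pd.DataFrame({
            "snp": np.arange(n), "chrom": ["chr1"] * n,
            "pos": np.arange(n) * 10_000 + 5_000,
        })
        rho, _ = ancestry.correlate_fst_ancestry(wf, track, positions)
        assert abs(rho) < 3 / np.sqrt(n)

    def test_pearson_proportional_steepness(self):
        track = pd.DataFrame({
            "snp": np.arange(20), "delta": np.linspace(0, 1, 20),
        }).set_index("snp")
        steep = pd.DataFrame({"snp": np.arange(20),
                              "steepness": np.linspace(0, 2, 20)})
        r, p, n = ancestry.correlate_clines(track, steep)
        assert r == pytest.approx(1.0)
        assert n == 20

    def test_permuted_steepness_uncorrelated(self):
        rng = np.random.default_rng(7)
        n = 1000
        delta = rng.random(n)
        track = pd.DataFrame({"snp": np.arange(n), "delta": delta}).set_index("snp")
        steep = pd.DataFrame({"snp": np.arange(n),
                              "steepness": rng.permutation(delta)})
        r, _, _ = ancestry.correlate_clines(track, steep)
        assert abs(r) < 3 / np.sqrt(n)

    def test_cline_strength_recovered_at_scale(self):
        # correlation strength 0.1 at 100,000 SNPs recovered within 0.02
        from apiscan import simdata

        cfg = simdata.SimConfig(n_snps=100_000, cline_correlation=0.1, seed=3,
                                n_selected_loci=200)
        n = cfg.n_snps
        rng = np.random.default_rng(99)
        sel = np.sort(rng.choice(n, 200, replace=False))
        truth = simdata.SimTruth(
            ancestral_freq=np.full(n, np.nan),
            lineage_freqs=pd.DataFrame(),
            a_dosage=np.zeros((n, 0), dtype=np.int8),
            admixed_samples=[],
            selected_index=sel,
            centromeres={},
            admix_A_lowland=0.847, admix_A_highland=0.686,
        )
        _, clines = simdata.generate_posteriors_and_clines(truth, cfg)
        shift = np.zeros(n)
        shift[sel] = cfg.selection_ancestry_shift
        r = np.corrcoef(shift, clines["steepness"])[0, 1]
        assert abs(r - 0.1) < 0.02

    def test_zero_strength_uncorrelated(self):
        from apiscan import simdata

        cfg = simdata.SimConfig(n_snps=20_000, cline_correlation=0.0, seed=4)
        rng = np.random.default_rng(1)
        sel = np.sort(rng.choice(cfg.n_snps, 60, replace=False))
        truth = simdata.SimTruth(
            ancestral_freq=np.full(cfg.n_snps, np.nan),
            lineage_freqs=pd.DataFrame(),
            a_dosage=np.zeros((cfg.n_snps, 0), dtype=np.int8),
            admixed_samples=[], selected_index=sel, centromeres={},
            admix_A_lowland=0.847, admix_A_highland=0.686,
        )
        _, clines = simdata.generate_posteriors_and_clines(truth, cfg)
        shift = np.zeros(cfg.n_snps)
        shift[sel] = cfg.selection_ancestry_shift
        r = np.corrcoef(shift, clines["steepness"])[0, 1]
        assert abs(r) < 3 / np.sqrt(cfg.n_snps)


class TestDependentCorrelations:
    def test_equal_correlations_z_zero(self):
        out = ancestry.compare_dependent_correlations(0.4, 0.4, 0.2, 100)
        assert out.z == pytest.approx(0.0)
        assert out.p == pytest.approx(1.0)

    def test_antisymmetry(self):
        a = ancestry.compare_dependent_correlations(0.5, 0.3, 0.6, 100)
        b = ancestry.compare_dependent_correlations(0.3, 0.5, 0.6, 100)
        assert a.z == pytest.approx(-b.z)

    def test_matches_independent_transcription(self):
        # independent re-derivation of Dunn & Clark's z with the
        # backtransformed-average covariance term
        r_jk, r_jh, r_kh, n = 0.5, 0.3, 0.6, 100
        z1 = 0.5 * math.log((1 + r_jk) / (1 - r_jk))
        z2 = 0.5 * math.log((1 + r_jh) / (1 - r_jh))
        zm = (z1 + z2) / 2
        rm = (math.exp(2 * zm) - 1) / (math.exp(2 * zm) + 1)
        c = (r_kh * (1 - 2 * rm ** 2)
             - 0.5 * rm ** 2 * (1 - 2 * rm ** 2 - r_kh ** 2)) / (1 - rm ** 2) ** 2
        z_expected = (z1 - z2) * math.sqrt((n - 3) / (2 - 2 * c))
        out = ancestry.compare_dependent_correlations(r_jk, r_jh, r_kh, n)
        assert out.z == pytest.approx(z_expected, abs=1e-10)

    def test_degenerate_raises(self):
        with pytest.raises(ValueError):
            ancestry.compare_dependent_correlations(1.0, 0.3, 0.2, 50)

    def test_type_one_error_controlled(self):
        # trivariate normal null: all pairwise correlations equal, so the
        # two overlapping correlations share the same population value
        rng = np.random.default_rng(42)
        n, reps, alpha = 200, 2000, 0.05
        cov = np.array([[1, 0.3, 0.3], [0.3, 1, 0.4], [0.3, 0.3, 1.0]])
        cov[2, 1] = cov[1, 2] = 0.4
        cov[0, 1] = cov[1, 0] = 0.3
        cov[0, 2] = cov[2, 0] = 0.3
        L = np.linalg.cholesky(cov)
        rejections = 0
        for _ in range(reps):
            x = rng.standard_normal((n, 3)) @ L.T
            r = np.corrcoef(x, rowvar=False)
            out = ancestry.compare_dependent_correlations(
                r[0, 1], r[0, 2], r[1, 2], n)
            rejections += out.p < alpha
        assert rejections / reps <= 1.5 * alpha


class TestClassifyAndTest:
    def test_published_table_significant(self):
        p = ancestry.fisher_exact_two_sided(np.array([[11, 6], [0, 4]]))
        assert p == pytest.approx(0.0351, abs=0.0005)
        assert p < 0.05

    def test_balanced_diagonal_table(self):
        p = ancestry.fisher_exact_two_sided(np.array([[5, 0], [0, 5]]))
        assert p == pytest.approx(2 / math.comb(10, 5), rel=1e-9)

    def test_identical_row_proportions_p_one(self):
        p = ancestry.fisher_exact_two_sided(np.array([[4, 4], [4, 4]]))
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("case", range(60))
    def test_matches_enumeration_oracle(self, case):
        rng = np.random.default_rng(200 + case)
        table = rng.integers(0, 16, size=(2, 2))
        if table.sum() == 0:
            table[0, 0] = 1
        got = ancestry.fisher_exact_two_sided(table)
        assert got == pytest.approx(fisher_enumeration_oracle(table), rel=1e-9)

    def test_classification_pipeline(self):
        comparisons = pd.DataFrame({
            "A_ancestry": [0.5] * 17 + [0.75] * 4 + [0.9],
            "z": [3.5] * 11 + [0.1] * 6 + [0.2] * 4 + [5.0],
            "p": [1e-5] * 11 + [0.9] * 6 + [0.8] * 4 + [1e-9],
        })
        table, p, df = ancestry.classify_and_test(
            comparisons, hl_level=0.686, ll_level=0.847, alpha=0.001)
        assert table.tolist() == [[11, 6], [0, 4]]
        assert p < 0.05
        assert (df["cls"] == "excluded").sum() == 1


class TestExternalPopulationCorrelations:
    def test_highland_correlates_more_with_similar_ancestry_population(self):
        # an external population at A = 0.6 experiencing the same selection
        # targets correlates more strongly with the highland track than one
        # at A = 0.8 without them, across 20 seeded replicates
        n_snps, m_ext, shift = 30_000, 10, 0.5
        n_high = 14
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            sel = np.zeros(n_snps, dtype=bool)
            sel[rng.integers(0, n_snps - 60):][:60] = True

            def track(alpha, m, shifted):
                a = np.full(n_snps, alpha)
                if shifted:
                    a[sel] = alpha - shift
                return rng.binomial(2 * m, a) / (2 * m)

            high = track(0.686, n_high, True)
            ext_low = track(0.6, m_ext, True)    # similar climate: same targets
            ext_high = track(0.8, m_ext, False)  # lowland-like: no targets
            r_sim = np.corrcoef(high, ext_low)[0, 1]
            r_dis = np.corrcoef(high, ext_high)[0, 1]
            wins += r_sim > r_dis
        assert wins == 20
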