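"""Diversity and divergence statistics against hand computations,
brute-force formula transcriptions and simulation oracles."""

import numpy as np
import pandas as pd
import pytest

from apiscan import popgen
from conftest import make_matrix


# ---------------------------------------------------------------------------
# independent oracle: direct transcription of the Weir & Cockerham (1984)
# two-population variance components for one bi-allelic site
# ---------------------------------------------------------------------------

def wc84_site_oracle(genos_a, genos_b):
    """genos_x: list of (allele, allele) diploid genotype pairs (no
    missing).  Returns (a, a+b+c)."""
    def summarize(genos):
        n = len(genos)
        alleles = [x for g in genos for x in g]
        p = sum(alleles) / (2 * n)
        h = sum(1 for g in genos if g[0] != g[1]) / n
        return n, p, h

    n1, p1, h1 = summarize(genos_a)
    n2, p2, h2 = summarize(genos_b)
    r = 2
    nbar = (n1 + n2) / r
    nc = (n1 + n2 - (n1 ** 2 + n2 ** 2) / (n1 + n2)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    hbar = (n1 * h1 + n2 * h2) / (n1 + n2)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, a + b + c


class TestPairHaploids:
    def _drone_matrix(self, n_drones, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for _ in range(20):
            rows.append([(int(rng.integers(2)), -1) for _ in range(n_drones)])
        return make_matrix(rows, ["M"] * n_drones, ploidy=[1] * n_drones)

    def test_deterministic_pairing(self):
        m = self._drone_matrix(4)
        ids = m.samples
        _, pairs1, _ = popgen.pair_haploids(m, ids, seed=7)
        _, pairs2, _ = popgen.pair_haploids(m, ids, seed=7)
        assert pairs1 == pairs2
        assert len(pairs1) == 2

    def test_85_drones_give_42_pairs_one_dropped(self):
        m = self._drone_matrix(85)
        out, pairs, dropped = popgen.pair_haploids(m, m.samples, seed=1)
        assert len(pairs) == 42
        assert len(dropped) == 1
        assert out.n_samples == 42

    def test_identical_haploids_pair_homozygous(self):
        rows = [[(1, -1), (1, -1)], [(0, -1), (0, -1)]]
        m = make_matrix(rows, ["M", "M"], ploidy=[1, 1])
        out, _, _ = popgen.pair_haploids(m, m.samples, seed=0)
        assert not out.is_het().any()

    def test_fewer_than_two_raises(self):
        m = self._drone_matrix(2)
        with pytest.raises(ValueError):
            popgen.pair_haploids(m, m.samples[:1], seed=0)


class TestNucleotideDiversity:
    def test_monomorphic_window_is_zero(self):
        m = make_matrix([[(0, 0), (0, 0)]], ["p", "p"], pos=[5])
        windows, genome = popgen.nucleotide_diversity_windows(m, window_bp=10_000)
        assert windows[0].value == 0.0
        assert genome == 0.0

    def test_single_snp_half_frequency_hand_value(self):
        # one SNP, p = 0.5 over n = 2 chromosomes, 10-kbp window:
        # pi = 2*0.5*0.5*2/1 / 10000 = 1e-4
        m = make_matrix([[(0, 1)]], ["p"], pos=[5])
        windows, genome = popgen.nucleotide_diversity_windows(m, window_bp=10_000)
        assert genome == pytest.approx(1e-4)

    def test_relabeling_invariance(self, default_panels):
        _, _, mat, _ = default_panels[0]
        sub = mat.take_samples(mat.sample_indices("A"))
        _, g1 = popgen.nucleotide_diversity_windows(sub)
        perm = np.random.default_rng(0).permutation(sub.n_samples)
        _, g2 = popgen.nucleotide_diversity_windows(sub.take_samples(perm))
        assert g1 == pytest.approx(g2)

    def test_window_tiling_counts_every_snp_once(self, default_panels):
        cfg, _, mat, _ = default_panels[0]
        windows, _ = popgen.nucleotide_diversity_windows(
            mat, "lowland", 50_000, cfg.chrom_lengths)
        assert sum(w.n_snps for w in windows) == mat.n_sites

    def test_balding_nichols_diversity_matches_closed_form(self, default_panels):
        # expected per-bp pi for the A-like lineage: SNP density times the
        # mixture over SNP classes of E[2p(1-p)] under the generator's
        # frequency model (shared Balding-Nichols + low-frequency privates)
        cfg, freqs, mat, _ = default_panels[0]
        density = cfg.n_snps / sum(cfg.chrom_lengths.values())
        e_pq_shared = 0.1825  # E[p(1-p)], p ~ U(0.05, 0.95)
        lo, hi = cfg.private_freq_range
        ep = (lo + hi) / 2
        ep2 = ep ** 2 + (hi - lo) ** 2 / 12
        w = cfg.snp_class_weights
        fA = cfg.lineage_divergence["A"]
        expect = density * 2 * (
            w["shared"] * e_pq_shared * (1 - fA) + w["A"] * (ep - ep2)
        )
        _, gA = popgen.nucleotide_diversity_windows(
            mat, "A", 50_000, cfg.chrom_lengths)
        assert gA == pytest.approx(expect, rel=0.10)

    def test_diversity_ordering_reproduced(self, default_panels):
        # qualitative ranking: A-like > admixed > M-like > C-like
        for cfg, _, mat, _ in default_panels[:3]:
            pi = {
                pop: popgen.nucleotide_diversity_windows(
                    mat, pop, 50_000, cfg.chrom_lengths)[1]
                for pop in ("A", "C", "M", "lowland", "highland")
            }
            assert pi["A"] > pi["lowland"] > pi["M"] > pi["C"]
            assert pi["A"] > pi["highland"] > pi["M"]


class TestWattersonTheta:
    def test_no_segregating_sites(self):
        m = make_matrix([[(0, 0), (0, 0)]], ["p", "p"])
        assert popgen.watterson_theta(m, 1000) == 0.0

    def test_hand_value(self):
        # S=11 segregating sites, n=4 chromosomes, L=1000:
        # a_3 = 1 + 1/2 + 1/3 = 1.8333, theta = 11/1833.3 = 0.006
        rows = [[(0, 1), (0, 0)]] * 11
        m = make_matrix(rows, ["p", "p"])
        assert popgen.watterson_theta(m, 1000) == pytest.approx(0.006, abs=1e-4)

    def test_recovers_simulated_theta(self):
        # infinite-sites coalescent panel at theta = 0.0047/bp via msprime
        import msprime

        L = 200_000
        theta = 0.0047
        n = 20
        ts = msprime.sim_ancestry(
            samples=n, ploidy=1, sequence_length=L,
            population_size=1.0, recombination_rate=0.0005, random_seed=5)
        mts = msprime.sim_mutations(ts, rate=theta / 4, random_seed=6,
                                    model=msprime.BinaryMutationModel())
        S = mts.num_sites
        an = sum(1.0 / i for i in range(1, n))
        est = S / (an * L)
        # 3 SE of S under the Watterson model
        var_s = an * theta * L + sum(1.0 / i ** 2 for i in range(1, n)) * (theta * L) ** 2
        se = 3 * np.sqrt(var_s) / (an * L)
        assert abs(est - theta) < se


class TestWcFst:
    def test_fixed_difference_is_one(self):
        row = [(0, 0)] * 10 + [(1, 1)] * 10
        m = make_matrix([row], ["a"] * 10 + ["b"] * 10)
        res = popgen.wc_fst_components(m, "a", "b")
        assert res["fst"].iloc[0] == pytest.approx(1.0)

    def test_identical_populations_nonpositive(self):
        row = [(0, 1)] * 5 + [(0, 1)] * 5
        m = make_matrix([row], ["a"] * 5 + ["b"] * 5)
        res = popgen.wc_fst_components(m, "a", "b")
        assert res["a"].iloc[0] <= 0
        assert res["fst"].iloc[0] <= 0

    def test_matches_brute_force_transcription(self):
        rng = np.random.default_rng(42)
        rows, oracle = [], []
        for _ in range(50):
            ga = [tuple(rng.integers(0, 2, 2)) for _ in range(3)]
            gb = [tuple(rng.integers(0, 2, 2)) for _ in range(3)]
            rows.append(ga + gb)
            oracle.append(wc84_site_oracle(ga, gb))
        m = make_matrix(rows, ["a"] * 3 + ["b"] * 3)
        res = popgen.wc_fst_components(m, "a", "b")
        for i, (a, d) in enumerate(oracle):
            assert res["a"].iloc[i] == pytest.approx(a, abs=1e-12)
            assert res["d"].iloc[i] == pytest.approx(d, abs=1e-12)

    def test_fst_never_exceeds_one(self, default_panels):
        _, _, mat, _ = default_panels[0]
        res = popgen.wc_fst_components(mat, "highland", "lowland")
        f = res["fst"].dropna()
        assert (f <= 1.0 + 1e-12).all()


class TestWcFstWindowed:
    def test_single_snp_window_equals_ratio(self):
        per = pd.DataFrame({
            "chrom": ["chr1"], "pos": [5000], "a": [0.3], "d": [0.6],
            "fst": [0.5],
        })
        w = popgen.wc_fst_windowed(per, 10_000)
        assert w[0].value == pytest.approx(0.5)
        assert w[0].n_snps == 1

    def test_equal_denominators_give_mean_of_ratios(self):
        ratios = np.array([0.1, 0.4, 0.25])
        per = pd.DataFrame({
            "chrom": ["chr1"] * 3, "pos": [100, 200, 300],
            "a": ratios * 2.0, "d": [2.0] * 3, "fst": ratios,
        })
        w = popgen.wc_fst_windowed(per, 10_000)
        assert w[0].value == pytest.approx(ratios.mean())

    def test_tiling_covers_each_snp_once(self, default_panels):
        cfg, _, mat, _ = default_panels[0]
        per = popgen.wc_fst_components(mat, "highland", "lowland")
        wins = popgen.wc_fst_windowed(per, 10_000, cfg.chrom_lengths)
        assert sum(w.n_snps for w in wins) == int(np.isfinite(per["d"]).sum())

    def test_windowed_in_unit_interval_band(self, default_panels):
        cfg, _, mat, _ = default_panels[0]
        per = popgen.wc_fst_components(mat, "highland", "lowland")
        wins = popgen.wc_fst_windowed(per, 10_000, cfg.chrom_lengths)
        vals = np.array([w.value for w in wins])
        vals = vals[np.isfinite(vals)]
        assert (vals <= 1.0 + 1e-9).all()
        assert (vals >= -0.5).all()


class TestReynolds:
    def test_identical_populations_near_zero(self):
        rng = np.random.default_rng(3)
        rows = []
        for _ in range(2000):
            p = rng.uniform(0.1, 0.9)
            rows.append([(int(rng.random() < p), int(rng.random() < p))
                         for _ in range(20)])
        m = make_matrix(rows, ["a"] * 10 + ["b"] * 10)
        fst = popgen.reynolds_fst_genomewide(m, "a", "b")
        assert abs(fst) < 0.01

    def test_fixed_difference_is_one(self):
        rows = [[(0, 0)] * 5 + [(1, 1)] * 5] * 10
        m = make_matrix(rows, ["a"] * 5 + ["b"] * 5)
        assert popgen.reynolds_fst_genomewide(m, "a", "b") == pytest.approx(1.0)

    def test_split_model_recovers_design_fst(self):
        # two-deme split at T (2N units) has F_ST = 1 - exp(-2T); Reynolds
        # ratio-of-sums over simulated SNPs should recover it.  Split time
        # 0.0301 in 4N units corresponds to F_ST ~ 0.0584.
        from apiscan.coalescent import SplitModel, simulate_snp_panel

        panel = simulate_snp_panel(SplitModel(t_split=0.0301, n_loci=60_000, seed=9))
        n1, n2 = 28, 30
        p1 = panel.derived1 / n1
        p2 = panel.derived2 / n2
        num, den = popgen.reynolds_terms(
            np.full(p1.shape, n1 / 2), np.full(p2.shape, n2 / 2), p1, p2)
        est = np.nansum(num) / np.nansum(den)
        assert est == pytest.approx(0.0584, abs=0.006)


class TestKingKinship:
    def test_self_kinship_half(self):
        rng = np.random.default_rng(1)
        rows = [[(int(rng.integers(2)), int(rng.integers(2)))] * 2
                for _ in range(300)]
        m = make_matrix(rows, ["p", "p"])
        kin = popgen.king_kinship(m, [("s0", "s1")])
        assert kin[0].phi == pytest.approx(0.5)

    def test_unrelated_mean_near_zero(self):
        rng = np.random.default_rng(2)
        n_ind, n_sites = 10, 4000
        p = rng.uniform(0.2, 0.8, n_sites)
        rows = [
            [tuple(rng.random(2) < p[i]) for _ in range(n_ind)]
            for i in range(n_sites)
        ]
        m = make_matrix(np.array(rows, dtype=int), ["p"] * n_ind)
        kin = popgen.king_kinship(m)
        phis = np.array([k.phi for k in kin])
        se = phis.std() / np.sqrt(len(phis))
        assert abs(phis.mean()) < 3 * se + 0.01

    def test_parent_offspring_quarter(self):
        rng = np.random.default_rng(4)
        n_sites = 5000
        p = rng.uniform(0.2, 0.8, n_sites)
        pa = (rng.random((n_sites, 2)) < p[:, None]).astype(int)
        pb = (rng.random((n_sites, 2)) < p[:, None]).astype(int)
        # child: one allele from each parent
        child = np.stack([
            np.where(rng.random(n_sites) < 0.5, pa[:, 0], pa[:, 1]),
            np.where(rng.random(n_sites) < 0.5, pb[:, 0], pb[:, 1]),
        ], axis=1)
        rows = np.stack([pa, pb, child], axis=1)
        m = make_matrix(rows, ["p"] * 3)
        kin = popgen.king_kinship(m, [("s0", "s2")])
        assert kin[0].phi == pytest.approx(0.25, abs=0.03)
        assert kin[0].flagged  # 0.25 > 0.044 relatedness threshold
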