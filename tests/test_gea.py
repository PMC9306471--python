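"""Association engines: population frequencies, Omega, XtX, BF, LMM, Meff."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import linregress

from islegea.config import InvalidConfigError, SimulationConfig
from islegea.gea import (
    bayes_factor_scan,
    effective_tests,
    estimate_omega,
    kinship,
    lmm_gwa,
    population_allele_frequencies,
    variance_explained,
    xtx_scan,
)
from islegea.simulate import (
    PopulationFrequencyTable,
    simulate_allele_frequencies,
    simulate_population_tree,
    simulate_site_table,
)

from conftest import make_matrix


def _labels(samples, pops):
    return pd.Series(pops, index=samples, name="population")


class TestPopulationFrequencies:
    def test_fixed_cluster_frequency_one(self):
        d = np.full((5, 6), 2, dtype=np.int8)
        m = make_matrix(d)
        labels = _labels(m.samples, ["a"] * 3 + ["b"] * 3)
        t = population_allele_frequencies(m, labels, min_size=3)
        assert np.allclose(t.freqs, 1.0)

    def test_small_clusters_dropped(self):
        d = np.zeros((4, 10), dtype=np.int8)
        m = make_matrix(d)
        labels = _labels(m.samples, ["a"] * 2 + ["b"] * 3 + ["c"] * 5)
        t = population_allele_frequencies(m, labels, min_size=3)
        assert t.populations == ["b", "c"]

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(0)
        d = rng.integers(-1, 3, size=(50, 12)).astype(np.int8)
        m = make_matrix(d)
        pops = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        labels = _labels(m.samples, pops)
        t = population_allele_frequencies(m, labels, min_size=3)
        for k, pop in enumerate(t.populations):
            cols = [i for i, p in enumerate(pops) if p == pop]
            for i in range(50):
                vals = [d[i, j] for j in cols if d[i, j] >= 0]
                expect = np.mean(vals) / 2 if vals else np.nan
                got = t.freqs[i, k]
                assert (np.isnan(got) and np.isnan(expect)) or got == pytest.approx(expect)


def _table_from_freqs(freqs, pi=None):
    n, P = freqs.shape
    return PopulationFrequencyTable(
        chrom=np.array(["chr1"] * n, dtype=object),
        pos=np.arange(1, n + 1),
        pi_anc=pi if pi is not None else freqs.mean(axis=1),
        freqs=freqs,
        populations=[f"pop{i}" for i in range(P)],
    )


class TestOmega:
    def test_iid_populations_near_diagonal(self):
        rng = np.random.default_rng(1)
        n, P, c = 20_000, 5, 0.02
        pi = rng.uniform(0.2, 0.8, n)
        freqs = pi[:, None] + np.sqrt(pi * (1 - pi))[:, None] * (
            np.sqrt(c) * rng.standard_normal((n, P))
        )
        om = estimate_omega(_table_from_freqs(np.clip(freqs, 0.001, 0.999), pi),
                            subset_size=n)
        off = om.omega[~np.eye(P, dtype=bool)]
        assert np.abs(off).max() < 0.2 * c
        assert np.allclose(np.diag(om.omega), c, rtol=0.2)

    def test_duplicated_population_column(self):
        rng = np.random.default_rng(2)
        n, P = 5_000, 4
        pi = rng.uniform(0.3, 0.7, n)
        freqs = np.clip(
            pi[:, None] + 0.1 * rng.standard_normal((n, P)), 0.01, 0.99
        )
        freqs[:, 1] = freqs[:, 0]
        om = estimate_omega(_table_from_freqs(freqs, pi), subset_size=n)
        assert om.omega[0, 1] == pytest.approx(om.omega[0, 0], rel=0.05)

    def test_simulator_truth_recovery(self):
        cfg = SimulationConfig(n_snvs=10_000, n_adaptive_loci=0, seed=21)
        rng = np.random.default_rng(21)
        omega_true = simulate_population_tree(cfg, rng)
        st = simulate_site_table(cfg, rng)
        table, _ = simulate_allele_frequencies(cfg, omega_true, st, rng)
        om = estimate_omega(table, subset_size=10_000, rng=rng)
        iu = np.triu_indices_from(omega_true)
        r = np.corrcoef(om.omega[iu], omega_true[iu])[0, 1]
        assert r >= 0.9

    def test_too_few_snvs_rejected(self):
        from islegea.gea import OmegaEstimationError

        freqs = np.full((100, 3), 0.5)
        with pytest.raises(OmegaEstimationError):
            estimate_omega(_table_from_freqs(freqs), subset_size=100)


class TestXtX:
    def test_no_differentiation_zero(self):
        pi = np.full(10, 0.4)
        freqs = np.tile(pi[:, None], (1, 6))
        table = _table_from_freqs(freqs, pi)
        from islegea.gea import OmegaMatrix

        om = OmegaMatrix(omega=np.eye(6) * 0.05, n_snvs=10, shrinkage=0.0)
        scan = xtx_scan(table, om)
        assert np.allclose(scan.xtx, 0.0)

    def test_neutral_mean_near_p(self):
        cfg = SimulationConfig(n_snvs=20_000, n_adaptive_loci=0, seed=22)
        rng = np.random.default_rng(22)
        omega_true = simulate_population_tree(cfg, rng)
        st = simulate_site_table(cfg, rng)
        table, _ = simulate_allele_frequencies(cfg, omega_true, st, rng)
        om = estimate_omega(table, subset_size=5_000, rng=rng)
        scan = xtx_scan(table, om)
        P = cfg.n_populations
        assert 0.9 * P <= np.nanmean(scan.xtx) <= 1.1 * P

    def test_planted_outlier_flagged(self):
        rng = np.random.default_rng(3)
        n, P = 5_000, 8
        pi = rng.uniform(0.3, 0.7, n)
        freqs = np.clip(
            pi[:, None] + 0.15 * rng.standard_normal((n, P)), 0.01, 0.99
        )
        freqs[0] = [0.05, 0.95] * 4  # strongly differentiated locus
        pi[0] = 0.5
        table = _table_from_freqs(freqs, pi)
        om = estimate_omega(table, subset_size=n, rng=rng)
        scan = xtx_scan(table, om, quantile=0.999)
        assert scan.flagged[0]

    def test_allele_relabeling_invariance(self):
        rng = np.random.default_rng(4)
        n, P = 200, 5
        pi = rng.uniform(0.3, 0.7, n)
        freqs = np.clip(pi[:, None] + 0.1 * rng.standard_normal((n, P)), 0.01, 0.99)
        om = estimate_omega(_pad(freqs, pi, rng), subset_size=5_000)
        s1 = xtx_scan(_table_from_freqs(freqs, pi), om)
        s2 = xtx_scan(_table_from_freqs(1 - freqs, 1 - pi), om)
        assert np.allclose(s1.xtx, s2.xtx, rtol=1e-9)


def _pad(freqs, pi, rng):
    """Pad a small frequency set to enough SNVs for Omega estimation."""
    n, P = freqs.shape
    reps = int(np.ceil(600 / n))
    big = np.vstack([np.clip(freqs + 0.01 * rng.standard_normal(freqs.shape), 0.01, 0.99) for _ in range(reps)])
    big_pi = np.tile(pi, reps)
    return _table_from_freqs(big, big_pi)


class TestBayesFactor:
    def _setup(self, seed=5, n=2_000, P=10, effect=0.0):
        rng = np.random.default_rng(seed)
        pi = rng.uniform(0.2, 0.8, n)
        z = rng.standard_normal(P)
        z = (z - z.mean()) / z.std()
        freqs = pi[:, None] + np.sqrt(pi * (1 - pi))[:, None] * (
            0.2 * rng.standard_normal((n, P))
        )
        if effect:
            freqs[0] += effect * np.sqrt(pi[0] * (1 - pi[0])) * 0.2 * z
        table = _table_from_freqs(np.clip(freqs, 0.001, 0.999), pi)
        cov = pd.DataFrame({"v": z}, index=table.populations)
        om = estimate_omega(table, subset_size=n, rng=rng)
        return table, om, cov

    def test_orthogonal_covariate_negative_db(self):
        rng = np.random.default_rng(6)
        n, P = 600, 6
        pi = np.full(n, 0.5)
        freqs = np.clip(0.5 + 0.1 * rng.standard_normal((n, P)), 0.01, 0.99)
        table = _table_from_freqs(freqs, pi)
        om = estimate_omega(table, subset_size=n, rng=rng)
        # covariate exactly orthogonal to the whitened deviation of marker 0
        L = om.cholesky
        a0 = (freqs[0] - 0.5) / 0.5
        y = np.linalg.solve(L, a0)
        x = rng.standard_normal(P)
        x -= (x @ y) / (y @ y) * y
        z = L @ x
        cov = pd.DataFrame({"v": z}, index=table.populations)
        scan = bayes_factor_scan(table, om, cov)
        assert scan.bf_db[0, 0] < 0

    def test_null_flag_rate_bounded(self):
        table, om, cov = self._setup(seed=7, n=20_000)
        scan = bayes_factor_scan(table, om, cov)
        assert scan.flagged.mean() <= 0.002

    def test_covariate_scaling_invariance(self):
        table, om, cov = self._setup(seed=8, n=1_000)
        s1 = bayes_factor_scan(table, om, cov)
        s2 = bayes_factor_scan(table, om, cov * 37.5)
        assert np.allclose(s1.bf_db, s2.bf_db, rtol=1e-9)

    def test_constant_covariate_skipped(self):
        table, om, cov = self._setup(seed=9, n=1_000)
        cov["const"] = 1.0
        scan = bayes_factor_scan(table, om, cov)
        assert scan.covariates == ["v"]


class TestKinship:
    def test_identical_samples_match_diagonal(self):
        rng = np.random.default_rng(10)
        d = (rng.random((400, 8)) < rng.uniform(0.2, 0.8, (400, 1))).astype(np.int8) * 2
        d[:, 1] = d[:, 0]
        m = make_matrix(d)
        kin = kinship(m, loco=False)
        assert kin.full[0, 1] == pytest.approx(kin.full[0, 0], rel=1e-9)

    def test_unrelated_samples_low_offdiagonal(self):
        # off-diagonals carry only the -1/(n-1) centering bias plus noise
        rng = np.random.default_rng(11)
        n = 100
        p = rng.uniform(0.2, 0.8, (5_000, 1))
        d = ((rng.random((5_000, n)) < p).astype(np.int8)
             + (rng.random((5_000, n)) < p).astype(np.int8))
        kin = kinship(make_matrix(d), loco=False)
        off = kin.full[~np.eye(n, dtype=bool)]
        assert np.abs(off.mean()) < 0.02

    def test_loco_excludes_own_chromosome(self):
        rng = np.random.default_rng(12)
        n = 600
        chrom = np.array(["chr1"] * 300 + ["chr2"] * 300, dtype=object)
        d = (rng.random((n, 10)) < 0.5).astype(np.int8) * 2
        pos = np.concatenate([np.arange(1, 301), np.arange(1, 301)])
        m = make_matrix(d, chrom=chrom, pos=pos)
        kin1 = kinship(m, loco=True)
        # scrambling chr1's genotypes must not change chr1's LOCO matrix
        d2 = d.copy()
        d2[:300] = (rng.random((300, 10)) < 0.5).astype(np.int8) * 2
        m2 = make_matrix(d2, chrom=chrom, pos=pos)
        kin2 = kinship(m2, loco=True)
        assert np.allclose(kin1.loco["chr1"], kin2.loco["chr1"], atol=1e-12)


class TestLMM:
    def test_identity_kinship_matches_ols(self):
        from islegea.gea import KinshipSet

        rng = np.random.default_rng(13)
        n_samp, n_mark = 30, 150
        d = (rng.random((n_mark, n_samp)) < rng.uniform(0.2, 0.8, (n_mark, 1))).astype(np.int8) * 2
        m = make_matrix(d)
        y = pd.Series(rng.standard_normal(n_samp), index=m.samples)
        kin = KinshipSet(full=np.eye(n_samp), loco={}, samples=m.samples)
        res = lmm_gwa(m, y, kin)
        for i in range(0, n_mark, 7):
            if np.std(d[i]) == 0:
                continue
            ols = linregress(d[i].astype(float), y.to_numpy())
            assert res.p[i] == pytest.approx(ols.pvalue, abs=1e-6)
            assert res.beta[i] == pytest.approx(ols.slope, rel=1e-6)

    def test_planted_marker_attains_minimum_p(self):
        rng = np.random.default_rng(14)
        n_samp, n_mark = 40, 200
        d = (rng.random((n_mark, n_samp)) < 0.5).astype(np.int8) * 2
        m = make_matrix(d)
        y = pd.Series(
            2.0 * d[17].astype(float) + 0.3 * rng.standard_normal(n_samp),
            index=m.samples,
        )
        kin = kinship(m, loco=False)
        from islegea.gea import KinshipSet

        res = lmm_gwa(m, y, KinshipSet(full=kin.full, loco={}, samples=m.samples))
        assert np.nanargmin(res.p) == 17

    def test_null_pvalues_uniform(self):
        from islegea.gea import lmm_null_uniformity
        from islegea.simulate import simulate_dataset

        cfg = SimulationConfig(
            n_snvs=5_000, n_adaptive_loci=0, n_hyperdivergent_blocks=0,
            failing_site_fraction=0.0, seed=23,
        )
        m, _, _ = simulate_dataset(cfg)
        rng = np.random.default_rng(24)
        y = pd.Series(rng.standard_normal(m.n_samples), index=m.samples)
        kin = kinship(m, loco=True)
        res = lmm_gwa(m, y, kin)
        assert lmm_null_uniformity(res.p) > 0.01

    def test_constant_phenotype_rejected(self):
        from islegea.gea import KinshipSet

        m = make_matrix(np.zeros((5, 4), dtype=np.int8))
        y = pd.Series(np.ones(4), index=m.samples)
        with pytest.raises(InvalidConfigError):
            lmm_gwa(m, y, KinshipSet(full=np.eye(4), loco={}, samples=m.samples))


class TestEffectiveTests:
    def test_independent_markers(self):
        rng = np.random.default_rng(15)
        d = (rng.random((50, 2_000)) < rng.uniform(0.2, 0.8, (50, 1))).astype(np.int8) * 2
        meff, thr = effective_tests(make_matrix(d))
        assert meff == pytest.approx(50, rel=0.1)
        assert thr == pytest.approx(0.05 / meff)

    def test_identical_markers_one(self):
        col = (np.random.default_rng(16).random(200) < 0.5).astype(np.int8) * 2
        d = np.tile(col, (20, 1))
        meff, _ = effective_tests(make_matrix(d))
        assert meff == pytest.approx(1.0)

    def test_block_diagonal_counts_blocks(self):
        # exactly orthogonal block patterns (Hadamard rows) so the marker
        # correlation is exactly block-diagonal: Meff equals the block count
        from scipy.linalg import hadamard

        b, per = 5, 4
        h = hadamard(8)[1: 1 + b]  # orthogonal, zero-mean +/-1 rows
        cols = [((row + 1)).astype(np.int8) for row in h for _ in range(per)]
        meff, _ = effective_tests(make_matrix(np.array(cols)))
        assert meff == pytest.approx(b, abs=1e-6)


class TestVarianceExplained:
    def test_affine_phenotype_is_one(self):
        d = np.array([0, 0, 2, 2, 0, 2], dtype=float)
        assert variance_explained(d, 3.0 * d - 1.0) == pytest.approx(1.0)

    def test_independent_near_zero(self):
        rng = np.random.default_rng(18)
        d = (rng.random(2_000) < 0.5) * 2.0
        y = rng.standard_normal(2_000)
        assert variance_explained(d, y) < 0.01

    def test_equals_regression_identity(self):
        rng = np.random.default_rng(19)
        d = (rng.random(100) < 0.5) * 2.0
        y = 0.5 * d + rng.standard_normal(100)
        got = variance_explained(d, y)
        ols = linregress(d, y)
        rss = np.sum((y - ols.intercept - ols.slope * d) ** 2)
        tss = np.sum((y - y.mean()) ** 2)
        assert got == pytest.approx(1 - rss / tss, rel=1e-9)
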