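"""Genotype-environment association engines.

Two complementary scans:

* A differentiation / covariate scan in the drift-covariance model family:
  per-SNV population allele-frequency deviations are standardized against
  an estimated population covariance matrix Omega.  The XtX statistic (an
  FST analogue) is the Omega-whitened squared norm of the deviation vector,
  distributed ~ chi-square(P) under neutrality; covariate evidence is a
  conjugate-linear-model Bayes factor (Zellner g-prior, g = P) between the
  whitened deviations and the whitened standardized covariate, reported in
  decibans (10 log10 BF), with 20 dB the "decisive" cutoff.  Omega is
  estimated by a shrunk moment estimator rather than MCMC.

* A linear mixed-model GWA with leave-one-chromosome-out (LOCO) kinship:
  per chromosome the variance ratio is REML-estimated once on the
  eigendecomposed model, then every marker gets a GLS Wald test.
  Significance uses the Li-Ji effective number of independent tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import kstest, t as t_dist

from .config import InvalidConfigError
from .genotypes import GenotypeMatrix
from .simulate import PopulationFrequencyTable

logger = logging.getLogger(__name__)


class OmegaEstimationError(RuntimeError):
    pass


@dataclass
class OmegaMatrix:
    omega: np.ndarray
    n_snvs: int
    shrinkage: float

    @property
    def cholesky(self) -> np.ndarray:
        return np.linalg.cholesky(self.omega)


# ---------------------------------------------------------------------------
# population frequencies and Omega
# ---------------------------------------------------------------------------

def population_allele_frequencies(
    matrix: GenotypeMatrix,
    cluster_labels: pd.Series,
    min_size: int = 3,
) -> PopulationFrequencyTable:
    """Per-SNV alternate-allele frequency per sampling-cluster population.

    Clusters below ``min_size`` samples are dropped (logged).  The ancestral
    frequency estimate is the sample-size-weighted mean across clusters.
    SNVs missing in an entire cluster carry NaN there and are excluded from
    Omega estimation downstream.
    """
    counts = cluster_labels.value_counts()
    keep_pops = sorted(counts.index[counts >= min_size])
    dropped = sorted(set(counts.index) - set(keep_pops))
    if dropped:
        logger.info("dropped %d clusters below min_size=%d", len(dropped), min_size)
    if len(keep_pops) < 2:
        raise InvalidConfigError("fewer than 2 clusters meet min_size")
    d = matrix.dosage.astype(float)
    d[d < 0] = np.nan
    sample_index = {s: i for i, s in enumerate(matrix.samples)}
    freqs = np.full((matrix.n_sites, len(keep_pops)), np.nan)
    sizes = np.zeros((matrix.n_sites, len(keep_pops)))
    for k, pop in enumerate(keep_pops):
        members = [sample_index[s] for s in cluster_labels.index[cluster_labels == pop]
                   if s in sample_index]
        sub = d[:, members]
        n_nm = (~np.isnan(sub)).sum(axis=1)
        with np.errstate(invalid="ignore"):
            freqs[:, k] = np.nanmean(sub, axis=1) / 2.0
        sizes[:, k] = n_nm
    wsum = sizes.sum(axis=1)
    pi = np.nansum(np.where(np.isnan(freqs), 0.0, freqs) * sizes, axis=1) / np.where(
        wsum > 0, wsum, np.nan
    )
    return PopulationFrequencyTable(
        chrom=matrix.chrom,
        pos=matrix.pos,
        pi_anc=pi,
        freqs=freqs,
        populations=keep_pops,
        sample_sizes=sizes,
    )


def scaled_deviations(table: PopulationFrequencyTable) -> tuple[np.ndarray, np.ndarray]:
    """Standardized deviation vectors a_i = (p_i - pi_i) / sqrt(pi_i(1-pi_i)).

    Returns (a, usable_mask); rows with any missing population frequency or
    a degenerate ancestral frequency are masked out.
    """
    pi = table.pi_anc
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.sqrt(pi * (1.0 - pi))
        a = (table.freqs - pi[:, None]) / scale[:, None]
    usable = (
        np.isfinite(a).all(axis=1)
        & np.isfinite(pi)
        & (pi > 0.0)
        & (pi < 1.0)
    )
    return a, usable


def estimate_omega(
    table: PopulationFrequencyTable,
    subset_size: int = 5_000,
    rng: Optional[np.random.Generator] = None,
    max_condition: float = 1e6,
) -> OmegaMatrix:
    """Moment estimator of the population covariance matrix Omega.

    Averages a_i a_i^T over a random subset of usable SNVs and shrinks the
    estimate toward its diagonal with the smallest weight that brings the
    condition number at or below ``max_condition``.
    """
    a, usable = scaled_deviations(table)
    idx = np.flatnonzero(usable)
    if len(idx) < 500:
        raise OmegaEstimationError(f"only {len(idx)} usable SNVs (<500)")
    if subset_size and len(idx) > subset_size:
        rng = rng or np.random.default_rng(0)
        idx = np.sort(rng.choice(idx, size=subset_size, replace=False))
    av = a[idx]
    raw = av.T @ av / len(idx)
    diag = np.diag(np.diag(raw))
    for w in np.concatenate([[0.0], np.geomspace(1e-8, 1.0, 60)]):
        omega = (1.0 - w) * raw + w * diag
        eig = np.linalg.eigvalsh(omega)
        if eig.min() > 0 and eig.max() / eig.min() <= max_condition:
            return OmegaMatrix(omega=omega, n_snvs=len(idx), shrinkage=float(w))
    raise OmegaEstimationError("omega singular even after full shrinkage")


# ---------------------------------------------------------------------------
# XtX and Bayes-factor scans
# ---------------------------------------------------------------------------

@dataclass
class XtXScan:
    chrom: np.ndarray
    pos: np.ndarray
    xtx: np.ndarray  # NaN where the marker was skipped
    threshold: float
    flagged: np.ndarray  # bool


def xtx_scan(
    table: PopulationFrequencyTable,
    omega: OmegaMatrix,
    quantile: float = 0.999,
) -> XtXScan:
    """Omega-whitened differentiation statistic per marker.

    XtX_i = a_i^T Omega^-1 a_i; under pure drift it behaves like a
    chi-square with ~P degrees of freedom.  Markers above the empirical
    ``quantile`` of the genome-wide distribution are flagged.
    """
    a, usable = scaled_deviations(table)
    n_skip = int((~usable).sum())
    if n_skip:
        logger.info("xtx_scan skipped %d markers with missing frequencies", n_skip)
    xtx = np.full(len(table.pos), np.nan)
    sol = np.linalg.solve(omega.omega, a[usable].T)
    xtx[usable] = np.einsum("ij,ji->i", a[usable], sol)
    thr = float(np.nanquantile(xtx, quantile))
    flagged = np.where(np.isnan(xtx), False, xtx > thr)
    return XtXScan(chrom=table.chrom, pos=table.pos, xtx=xtx, threshold=thr,
                   flagged=flagged)


@dataclass
class BFScan:
    chrom: np.ndarray
    pos: np.ndarray
    covariates: list
    bf_db: np.ndarray  # (n_snvs, n_cov)
    beta: np.ndarray  # (n_snvs, n_cov) whitened-regression effect
    cut_db: float

    @property
    def flagged(self) -> np.ndarray:
        return np.where(np.isnan(self.bf_db), False, self.bf_db > self.cut_db)


def bayes_factor_scan(
    table: PopulationFrequencyTable,
    omega: OmegaMatrix,
    covariates: pd.DataFrame,
    cut_db: float = 20.0,
) -> BFScan:
    """Conjugate Bayes factor for each (marker, covariate), in decibans.

    Covariates (one row per population) are standardized across populations;
    both the deviation vector and the covariate are whitened by the
    Cholesky factor of Omega, and the BF compares the one-regressor linear
    model under a Zellner g-prior (g = P) against the null:

        BF = (1 + g)^(-1/2) * (1 - g/(1+g) R^2)^(-P/2)

    Constant covariates are skipped with a warning.
    """
    P = omega.omega.shape[0]
    g = float(P)
    a, usable = scaled_deviations(table)
    L = omega.cholesky
    y = np.linalg.solve(L, a[usable].T)  # (P, n_usable)
    yy = np.einsum("ji,ji->i", y, y)
    cov_names = []
    bf_cols, beta_cols = [], []
    cov = covariates.loc[list(table.populations)]
    for name in cov.columns:
        z = cov[name].to_numpy(dtype=float)
        if np.nanstd(z) == 0:
            logger.warning("covariate %s is constant; skipped", name)
            continue
        z = (z - z.mean()) / z.std()
        x = np.linalg.solve(L, z)
        xx = float(x @ x)
        xy = x @ y
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = np.where(yy > 0, xy**2 / (xx * yy), 0.0)
        r2 = np.clip(r2, 0.0, 1.0 - 1e-12)
        log10_bf = -0.5 * np.log10(1.0 + g) - (P / 2.0) * np.log10(
            1.0 - (g / (1.0 + g)) * r2
        )
        bf = np.full(len(table.pos), np.nan)
        bf[usable] = 10.0 * log10_bf
        beta = np.full(len(table.pos), np.nan)
        beta[usable] = xy / xx
        cov_names.append(name)
        bf_cols.append(bf)
        beta_cols.append(beta)
    return BFScan(
        chrom=table.chrom,
        pos=table.pos,
        covariates=cov_names,
        bf_db=np.column_stack(bf_cols) if bf_cols else np.zeros((len(table.pos), 0)),
        beta=np.column_stack(beta_cols) if beta_cols else np.zeros((len(table.pos), 0)),
        cut_db=cut_db,
    )


# ---------------------------------------------------------------------------
# kinship and LMM GWA
# ---------------------------------------------------------------------------

@dataclass
class KinshipSet:
    full: np.ndarray
    loco: dict  # chrom -> kinship excluding that chromosome
    samples: list


def kinship(matrix: GenotypeMatrix, loco: bool = True) -> KinshipSet:
    """Realized-relationship matrices K = A A^T / m on normalized dosages."""
    from .structure import _normalize_markers

    x, _ = _normalize_markers(matrix.dosage)  # n x m (monomorphic dropped)
    d = matrix.dosage.astype(float).T
    d[d < 0] = np.nan
    p = np.nanmean(d, axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    chrom_poly = matrix.chrom[poly]
    m = x.shape[1]
    full = x @ x.T / m
    loco_mats = {}
    if loco:
        for c in matrix.chromosomes():
            on = chrom_poly == c
            m_c = int(on.sum())
            if m - m_c == 0:
                raise InvalidConfigError(
                    f"no markers left after excluding chromosome {c}"
                )
            xc = x[:, on]
            loco_mats[c] = (full * m - xc @ xc.T) / (m - m_c)
    return KinshipSet(full=full, loco=loco_mats, samples=list(matrix.samples))


def _reml_loglik(log_delta, lam, yr, xr):
    """REML log-likelihood of the eigendecomposed null model at delta."""
    delta = 10.0**log_delta
    w = 1.0 / (lam + delta)
    xtwx = (xr * w) @ xr.T if xr.ndim > 1 else float((xr**2 * w).sum())
    xtwx = np.atleast_2d(xtwx)
    xtwy = (xr * w) @ yr
    beta = np.linalg.solve(xtwx, np.atleast_1d(xtwy))
    resid = yr - beta @ np.atleast_2d(xr)
    rss = float((w * resid**2).sum())
    n, p = len(yr), xtwx.shape[0]
    if rss <= 0:
        return -np.inf
    sign, logdet_xtwx = np.linalg.slogdet(xtwx)
    if sign <= 0:
        return -np.inf
    return -0.5 * (
        (n - p) * np.log(rss / (n - p))
        + np.log(lam + delta).sum()
        + logdet_xtwx
    )


def _fit_delta(lam, yr, xr, grid_lo=-5.0, grid_hi=5.0, grid_n=101):
    """Grid search plus golden-section refinement over log10 variance ratio."""
    grid = np.linspace(grid_lo, grid_hi, grid_n)
    ll = np.array([_reml_loglik(g, lam, yr, xr) for g in grid])
    if not np.isfinite(ll).any():
        raise RuntimeError("REML likelihood not finite anywhere on the grid")
    k = int(np.nanargmax(ll))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, grid_n - 1)]
    phi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c, d = b - phi * (b - a), a + phi * (b - a)
    fc, fd = _reml_loglik(c, lam, yr, xr), _reml_loglik(d, lam, yr, xr)
    for _ in range(40):
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - phi * (b - a)
            fc = _reml_loglik(c, lam, yr, xr)
        else:
            a, c, fc = c, d, fd
            d = a + phi * (b - a)
            fd = _reml_loglik(d, lam, yr, xr)
    return 10.0 ** ((a + b) / 2.0)


@dataclass
class GWAResult:
    chrom: np.ndarray
    pos: np.ndarray
    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray
    delta_by_chrom: dict = field(default_factory=dict)


def lmm_gwa(
    matrix: GenotypeMatrix,
    phenotype: pd.Series,
    kinship_set: KinshipSet,
) -> GWAResult:
    """Mixed-model association with LOCO kinship.

    Model y = mu + g beta + u + e with u ~ N(0, sg^2 K_loco).  The variance
    ratio delta = se^2/sg^2 is REML-estimated once per chromosome on the
    intercept-only model, then each marker is tested by GLS Wald t with
    n - 2 degrees of freedom.
    """
    y = phenotype.loc[kinship_set.samples].to_numpy(dtype=float)
    if np.nanstd(y) == 0:
        raise InvalidConfigError("phenotype is constant")
    n = len(y)
    beta = np.full(matrix.n_sites, np.nan)
    se = np.full(matrix.n_sites, np.nan)
    pval = np.full(matrix.n_sites, np.nan)
    deltas = {}
    d_all = matrix.dosage.astype(float).T
    d_all[d_all < 0] = np.nan
    col_mean = np.nanmean(d_all, axis=0)
    inds = np.where(np.isnan(d_all))
    d_all[inds] = np.take(col_mean, inds[1])
    for c in matrix.chromosomes():
        K = kinship_set.loco.get(c, kinship_set.full)
        lam, U = np.linalg.eigh(K)
        lam = np.clip(lam, 0.0, None)
        yr = U.T @ y
        ones_r = U.T @ np.ones(n)
        try:
            delta = _fit_delta(lam, yr, ones_r)
        except RuntimeError:
            logger.warning("REML failed on %s; markers skipped", c)
            continue
        deltas[c] = delta
        w = 1.0 / (lam + delta)
        on = matrix.chrom == c
        G = d_all[:, on]  # n x m_c
        Gr = U.T @ G
        a11 = float((w * ones_r**2).sum())
        a12 = ((w * ones_r)[:, None] * Gr).sum(axis=0)
        a22 = (w[:, None] * Gr**2).sum(axis=0)
        b1 = float((w * ones_r * yr).sum())
        b2 = (w[:, None] * Gr * yr[:, None]).sum(axis=0)
        det = a11 * a22 - a12**2
        ok = det > 1e-12
        bg = np.where(ok, (a11 * b2 - a12 * b1) / np.where(ok, det, 1.0), np.nan)
        b0 = np.where(ok, (a22 * b1 - a12 * b2) / np.where(ok, det, 1.0), np.nan)
        yy = float((w * yr**2).sum())
        rss = yy - (b0 * b1 + bg * b2)
        rss = np.clip(rss, 1e-300, None)
        sigma2 = rss / (n - 2)
        var_bg = sigma2 * a11 / np.where(ok, det, np.nan)
        se_c = np.sqrt(var_bg)
        tstat = bg / se_c
        beta[on] = bg
        se[on] = se_c
        pval[on] = 2.0 * t_dist.sf(np.abs(tstat), df=n - 2)
    return GWAResult(chrom=matrix.chrom, pos=matrix.pos, beta=beta, se=se,
                     p=pval, delta_by_chrom=deltas)


def lmm_null_uniformity(pvals: np.ndarray) -> float:
    """KS test p-value of GWA p-values against Uniform(0, 1)."""
    p = pvals[np.isfinite(pvals)]
    return float(kstest(p, "uniform").pvalue)


# ---------------------------------------------------------------------------
# multiple testing and effect size
# ---------------------------------------------------------------------------

def effective_tests(matrix: GenotypeMatrix, alpha: float = 0.05) -> tuple[float, float]:
    """Li-Ji effective number of independent tests and its threshold.

    Meff sums, over eigenvalues of the marker correlation matrix,
    ``1(lambda >= 1) + (lambda - floor(lambda))``; the genome-wide
    significance threshold is ``alpha / Meff``.
    """
    if matrix.n_sites < 2:
        raise InvalidConfigError("need at least 2 markers")
    from .structure import _fill_standardize

    z, _ = _fill_standardize(matrix.dosage)  # n x m, unit-variance columns
    n, m = z.shape
    # eigenvalues of the m x m correlation matrix via SVD of the n x m data
    svals = np.linalg.svd(z, compute_uv=False)
    lam = np.zeros(m)
    lam[: len(svals)] = svals**2 / n
    lam *= m / lam.sum()  # trace of a correlation matrix is m
    # round before flooring: the floor step is discontinuous at integers and
    # exact block structures land eigenvalues there up to float error
    lam = np.round(lam, 10)
    meff = float(np.sum((lam >= 1.0).astype(float) + (lam - np.floor(lam))))
    return meff, alpha / meff


def variance_explained(dosage: np.ndarray, phenotype: np.ndarray) -> float:
    """Squared Pearson correlation between peak-marker dosage and phenotype."""
    d = np.asarray(dosage, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    ok = np.isfinite(d) & np.isfinite(y) & (d >= 0)
    if ok.sum() < 3:
        raise InvalidConfigError("need >= 3 paired observations")
    d, y = d[ok], y[ok]
    if np.std(d) == 0:
        return float("nan")
    r = np.corrcoef(d, y)[0, 1]
    return float(r * r)
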