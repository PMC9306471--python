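"""Population structure: LD pruning, PCA with Tracy-Widom significance,
hierarchical genetic-group assignment, and PC-environment correlation.

PCA follows the classic population-genetics recipe: markers normalized by
the binomial standard deviation sqrt(2 p (1 - p)), eigendecomposition of
the sample covariance, and per-eigenvalue Tracy-Widom tests with the
moment-matched effective marker count.  Optional iterative outlier removal
drops samples more than ``outlier_sigma`` SDs out along any top PC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import gamma as gamma_dist
from scipy.stats import pearsonr

from .config import InvalidConfigError
from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)

# Gamma approximation to the Tracy-Widom TW1 distribution (shape, scale,
# shift); accurate to ~1e-2 in CDF over the relevant tail.
_TW1_GAMMA = (46.44604884518764, 0.18605402228279682, 9.848007781128567)


def tracy_widom_sf(x: np.ndarray) -> np.ndarray:
    """Upper-tail probability of the TW1 (beta = 1) distribution."""
    k, theta, shift = _TW1_GAMMA
    return gamma_dist.sf(np.asarray(x, dtype=float) + shift, a=k, scale=theta)


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def _fill_standardize(dosage: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean-impute missing calls and column-standardize; returns (Z, maf)."""
    d = dosage.astype(float).T  # samples x markers
    miss = d < 0
    d[miss] = np.nan
    mean = np.nanmean(d, axis=0)
    inds = np.where(np.isnan(d))
    d[inds] = np.take(mean, inds[1])
    p = mean / 2.0
    maf = np.minimum(p, 1.0 - p)
    sd = d.std(axis=0)
    sd[sd == 0] = 1.0
    return (d - mean) / sd, maf


def ld_prune(
    matrix: GenotypeMatrix,
    window: int = 50,
    step: int = 10,
    r2_max: float = 0.8,
    maf_min: float = 0.0,
) -> np.ndarray:
    """Window-based LD pruning; returns indices of retained markers.

    Within each ``window``-marker window (advanced by ``step`` markers),
    while any retained pair has squared dosage correlation above ``r2_max``
    the member with the lower minor-allele frequency is removed (ties break
    toward the later position).  An optional MAF filter runs first.  The
    retained set is guaranteed to contain no co-windowed pair above the
    threshold.
    """
    if step <= 0:
        raise InvalidConfigError("step must be positive")
    m = matrix.n_sites
    if m == 0:
        return np.array([], dtype=int)
    z, maf = _fill_standardize(matrix.dosage)
    candidates = np.arange(m)
    if maf_min > 0:
        candidates = candidates[maf[candidates] >= maf_min]
    alive = np.zeros(m, dtype=bool)
    alive[candidates] = True

    chrom = matrix.chrom
    n = z.shape[0]
    # precompute r^2 for all within-chromosome pairs at lag < window
    pairs: list[tuple[int, int, float]] = []
    for lag in range(1, window):
        if lag >= m:
            break
        i = np.arange(m - lag)
        same = chrom[i] == chrom[i + lag]
        r = np.einsum("ij,ij->j", z[:, i], z[:, i + lag]) / n
        r2 = r * r
        hit = same & (r2 > r2_max)
        for ii in np.flatnonzero(hit):
            pairs.append((ii, ii + lag, r2[ii]))
    # process pairs in window order (left to right, as windows advance)
    for i, j, _ in sorted(pairs):
        if not (alive[i] and alive[j]):
            continue
        if not _co_windowed(i, j, window, step, m):
            continue
        # remove the lower-MAF member; tie -> later position
        drop = j if maf[j] <= maf[i] else i
        alive[drop] = False
    return np.flatnonzero(alive)


def _co_windowed(i: int, j: int, window: int, step: int, m: int) -> bool:
    """True if markers i < j fall together in at least one pruning window."""
    lo = max(0, j - window + 1)  # window must start at or after this
    first = ((lo + step - 1) // step) * step
    return first <= i and first < m


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    eigenvalues: np.ndarray
    scores: pd.DataFrame  # samples x PCs (projections)
    tw_stats: np.ndarray
    tw_p: np.ndarray
    n_significant: int
    removed_outliers: list = field(default_factory=list)  # (sample, iteration)
    n_markers: int = 0


def _normalize_markers(dosage: np.ndarray) -> tuple[np.ndarray, int]:
    """Patterson normalization (g - 2p) / sqrt(2p(1-p)); drops monomorphic."""
    d = dosage.astype(float).T  # n x m
    d[d < 0] = np.nan
    p = np.nanmean(d, axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    n_dropped = int((~poly).sum())
    d = d[:, poly]
    p = p[poly]
    x = (d - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    x[np.isnan(x)] = 0.0
    return x, n_dropped


def _tw_tests(eigenvalues: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Successive Tracy-Widom tests with the moment-matched marker count."""
    lam = np.asarray(eigenvalues, dtype=float)
    stats = np.full(len(lam), np.nan)
    pvals = np.full(len(lam), np.nan)
    for i in range(len(lam) - 2):
        rest = lam[i:]
        nn = len(rest)
        s1, s2 = rest.sum(), (rest**2).sum()
        denom = (nn - 1) * s2 - s1 * s1
        if denom <= 0 or s1 <= 0:
            break
        m_eff = (nn + 1) * s1 * s1 / denom
        if m_eff <= 1:
            break
        ell = nn * rest[0] / s1
        sq_m = np.sqrt(m_eff - 1.0)
        sq_n = np.sqrt(float(nn))
        mu = (sq_m + sq_n) ** 2 / m_eff
        sigma = (sq_m + sq_n) / m_eff * (1.0 / sq_m + 1.0 / sq_n) ** (1.0 / 3.0)
        stats[i] = (ell - mu) / sigma
        pvals[i] = tracy_widom_sf(stats[i])
    return stats, pvals


def pca(
    matrix: GenotypeMatrix,
    n_components: int = 50,
    outlier_iterations: int = 0,
    outlier_sigma: float = 6.0,
    tw_alpha: float = 0.05,
) -> PCAResult:
    """PCA of normalized genotypes with TW significance and outlier removal.

    Scores are eigenvector projections scaled by sqrt(eigenvalue), with the
    sign of each PC canonicalized so its largest-magnitude entry is
    positive.  Outlier iterations remove samples more than ``outlier_sigma``
    SDs from the mean along any of the top 10 PCs, then recompute.
    """
    if matrix.n_samples < 3:
        raise InvalidConfigError("need at least 3 samples for PCA")
    keep = np.arange(matrix.n_samples)
    removed: list[tuple[str, int]] = []
    for iteration in range(max(outlier_iterations, 0) + 1):
        sub = matrix.take_samples(keep) if len(keep) < matrix.n_samples else matrix
        x, n_dropped = _normalize_markers(sub.dosage)
        if n_dropped:
            logger.info("dropped %d monomorphic markers", n_dropped)
        n, m = x.shape
        if m < 1:
            raise InvalidConfigError("no polymorphic markers")
        cov = x @ x.T / m
        lam, vec = np.linalg.eigh(cov)
        order = np.argsort(lam)[::-1]
        lam, vec = lam[order], vec[:, order]
        lam = np.clip(lam, 0.0, None)
        ncomp = min(n_components, n)
        if iteration >= outlier_iterations:
            break
        top = vec[:, : min(10, n)]
        sd = top.std(axis=0)
        sd[sd == 0] = 1.0
        zscore = np.abs(top - top.mean(axis=0)) / sd
        out_rows = np.flatnonzero((zscore > outlier_sigma).any(axis=1))
        if len(out_rows) == 0:
            break
        for r in out_rows:
            removed.append((sub.samples[r], iteration + 1))
        keep = keep[np.setdiff1d(np.arange(len(keep)), out_rows)]
        if len(keep) < 3:
            raise InvalidConfigError("outlier removal left <3 samples")

    scores = vec[:, :ncomp] * np.sqrt(lam[:ncomp])
    # canonical sign: largest-magnitude loading positive
    for k in range(scores.shape[1]):
        col = scores[:, k]
        if len(col) and col[np.argmax(np.abs(col))] < 0:
            scores[:, k] = -col
    tw_stats, tw_p = _tw_tests(lam[: max(ncomp, 10)])
    n_sig = 0
    for p in tw_p:
        if np.isnan(p) or p >= tw_alpha:
            break
        n_sig += 1
    sample_names = [matrix.samples[i] for i in keep]
    score_df = pd.DataFrame(
        scores, index=sample_names,
        columns=[f"PC{k + 1}" for k in range(scores.shape[1])],
    )
    return PCAResult(
        eigenvalues=lam[:ncomp],
        scores=score_df,
        tw_stats=tw_stats[:ncomp],
        tw_p=tw_p[:ncomp],
        n_significant=n_sig,
        removed_outliers=removed,
        n_markers=m,
    )


# ---------------------------------------------------------------------------
# genetic groups
# ---------------------------------------------------------------------------

def assign_genetic_groups(scores: pd.DataFrame, k: int = 7) -> pd.Series:
    """Average-linkage hierarchical clustering of PC scores into k groups.

    Group labels are canonicalized by descending group size (label 1 is the
    largest group; ties break on the smallest member id).
    """
    if k > len(scores):
        raise InvalidConfigError(f"k={k} exceeds {len(scores)} samples")
    if k == 1:
        return pd.Series(1, index=scores.index, name="group")
    z = linkage(scores.to_numpy(), method="average", metric="euclidean")
    raw = fcluster(z, t=k, criterion="maxclust")
    sizes = pd.Series(raw).value_counts()
    order = sorted(
        sizes.index,
        key=lambda lbl: (-sizes[lbl], min(scores.index[raw == lbl])),
    )
    remap = {lbl: i + 1 for i, lbl in enumerate(order)}
    return pd.Series([remap[l] for l in raw], index=scores.index, name="group")


def pc_environment_correlation(
    scores: pd.DataFrame, env: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Pearson r between each PC and each environmental variable.

    Returns a long frame with r, raw p, and a Bonferroni-adjusted
    significance flag across the full PC x variable matrix.  Constant
    variables yield NaN r and are flagged undefined.
    """
    common = scores.index.intersection(env.index)
    if len(common) < 3:
        raise InvalidConfigError("need >= 3 paired observations")
    s = scores.loc[common]
    e = env.loc[common]
    rows = []
    n_tests = s.shape[1] * e.shape[1]
    for pc in s.columns:
        for var in e.columns:
            pair = pd.concat([s[pc], e[var]], axis=1).dropna()
            if len(pair) < 3 or pair[var].nunique() == 1 or pair[pc].nunique() == 1:
                rows.append({"pc": pc, "variable": var, "r": np.nan,
                             "p": np.nan, "significant": False})
                continue
            r, p = pearsonr(pair[pc], pair[var])
            rows.append(
                {"pc": pc, "variable": var, "r": float(r), "p": float(p),
                 "significant": bool(p * n_tests < alpha)}
            )
    return pd.DataFrame(rows)
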