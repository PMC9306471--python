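"""Ecological analyses: spatial clustering, enrichment, niche comparison.

Sampling sites are grouped into populations by average-linkage hierarchical
clustering of great-circle distances cut at 3 km.  Habitat/land-cover
enrichment uses two-sided Fisher's exact tests; species niche comparisons
use Kruskal-Wallis with Dunn's post-hoc z tests (Bonferroni-adjusted) and a
compact letter display; collinear environmental variables are pruned at
|r| > 0.7.
"""

from __future__ import annotations

import itertools
import logging
import string
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import fisher_exact, kruskal, norm, rankdata

logger = logging.getLogger(__name__)

EARTH_RADIUS_M = 6_371_000.0

HABITAT_CLASSES = ("native", "introduced", "disturbed", "bare")


def geodesic_distance(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Great-circle (haversine) distance in meters between (lat, lon) pairs."""
    for lat, _ in (a, b):
        if not -90.0 <= lat <= 90.0:
            raise ValueError(f"latitude {lat} outside [-90, 90]")
    la1, lo1, la2, lo2 = map(np.radians, (a[0], a[1], b[0], b[1]))
    h = (
        np.sin((la2 - la1) / 2.0) ** 2
        + np.cos(la1) * np.cos(la2) * np.sin((lo2 - lo1) / 2.0) ** 2
    )
    return float(2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0))))


def geodesic_distance_matrix(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    la = np.radians(np.asarray(lat, dtype=float))
    lo = np.radians(np.asarray(lon, dtype=float))
    dlat = la[:, None] - la[None, :]
    dlon = lo[:, None] - lo[None, :]
    h = (
        np.sin(dlat / 2.0) ** 2
        + np.cos(la)[:, None] * np.cos(la)[None, :] * np.sin(dlon / 2.0) ** 2
    )
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def cluster_sampling_sites(
    coords: pd.DataFrame, cut: float = 3_000.0
) -> pd.Series:
    """Cluster samples into populations by geodesic distance.

    Average-linkage hierarchical clustering of the haversine distance
    matrix, cut at ``cut`` meters.  Samples with missing coordinates are
    excluded (logged).  Labels are canonicalized as the minimum sample id in
    each cluster, so they are stable under input reordering.

    Parameters
    ----------
    coords:
        Frame with columns ``sample``, ``latitude``, ``longitude``.
    """
    ok = coords[["latitude", "longitude"]].notna().all(axis=1)
    if (~ok).any():
        logger.warning("%d samples lack coordinates; excluded", int((~ok).sum()))
    sub = coords.loc[ok].reset_index(drop=True)
    if len(sub) == 0:
        return pd.Series(dtype=object, name="population")
    if len(sub) == 1:
        return pd.Series(
            {sub["sample"].iloc[0]: sub["sample"].iloc[0]}, name="population"
        )
    dmat = geodesic_distance_matrix(
        sub["latitude"].to_numpy(), sub["longitude"].to_numpy()
    )
    z = linkage(squareform(dmat, checks=False), method="average")
    raw = fcluster(z, t=cut, criterion="distance")
    rep = {}
    for lbl in np.unique(raw):
        members = sub["sample"][raw == lbl]
        rep[lbl] = min(members)
    return pd.Series(
        {s: rep[lbl] for s, lbl in zip(sub["sample"], raw)}, name="population"
    )


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    table: np.ndarray  # 2x2: rows = categories, cols = (positive, negative)
    odds_ratio: float
    p_value: float
    label: str = ""


def enrichment_test(
    positives: tuple[int, int], totals: tuple[int, int], label: str = ""
) -> EnrichmentResult:
    """Two-sided Fisher's exact test of positives/totals in two categories.

    The odds ratio is the sample (cross-product) OR with Haldane's 0.5
    correction when any cell is zero; the p-value sums all hypergeometric
    tables at most as probable as the observed one.
    """
    a, c = positives
    n1, n2 = totals
    if n1 <= 0 or n2 <= 0:
        raise ValueError("totals must be positive")
    if not (0 <= a <= n1 and 0 <= c <= n2):
        raise ValueError("positives must lie within totals")
    b, d = n1 - a, n2 - c
    table = np.array([[a, b], [c, d]])
    _, p = fisher_exact(table, alternative="two-sided")
    if min(a, b, c, d) == 0:
        orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        orr = (a * d) / (b * c)
    return EnrichmentResult(table=table, odds_ratio=float(orr), p_value=float(p),
                            label=label)


# ---------------------------------------------------------------------------
# niche comparison: Kruskal-Wallis + Dunn's test + letters
# ---------------------------------------------------------------------------

@dataclass
class NicheComparison:
    h_statistic: float
    kw_p: float
    pairwise: pd.DataFrame  # group_a, group_b, z, p_raw, p_adj
    letters: dict  # group -> letter string
    group_sizes: dict


def _dunn_pairwise(values: list[np.ndarray], names: list[str]) -> pd.DataFrame:
    """Dunn's z statistics on the pooled ranks, with tie correction."""
    pooled = np.concatenate(values)
    ranks = rankdata(pooled)
    n = len(pooled)
    # tie correction term for the rank variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n - 1))
    offs = np.cumsum([0] + [len(v) for v in values])
    mean_ranks = [ranks[offs[i]: offs[i + 1]].mean() for i in range(len(values))]
    rows = []
    for i, j in itertools.combinations(range(len(values)), 2):
        ni, nj = len(values[i]), len(values[j])
        se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / ni + 1.0 / nj))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p = 2.0 * norm.sf(abs(z))
        rows.append({"group_a": names[i], "group_b": names[j], "z": z, "p_raw": p})
    df = pd.DataFrame(rows)
    m = len(df)
    df["p_adj"] = np.minimum(df["p_raw"] * m, 1.0)
    return df


def _letter_display(names: list[str], pairwise: pd.DataFrame, alpha: float) -> dict:
    """Compact letter display: groups sharing a letter are not distinguishable."""
    differ = {
        frozenset((r.group_a, r.group_b))
        for r in pairwise.itertuples()
        if r.p_adj < alpha
    }
    letters: dict[str, str] = {g: "" for g in names}
    assigned: list[set[str]] = []  # groups carrying each letter
    for g in names:
        placed = False
        for members in assigned:
            if all(frozenset((g, m)) not in differ for m in members):
                members.add(g)
                placed = True
        if not placed and not any(g in m for m in assigned):
            assigned.append({g})
    for idx, members in enumerate(assigned):
        for g in members:
            letters[g] += string.ascii_lowercase[idx]
    return letters


def niche_compare(
    env_by_group: dict[str, np.ndarray], alpha: float = 0.05
) -> NicheComparison:
    """Compare one environmental variable across species.

    Kruskal-Wallis H (tie-corrected) followed by Dunn's pairwise z tests
    with Bonferroni adjustment within this variable's family, and a compact
    letter display at the given alpha.  Groups with fewer than 2
    observations are excluded (logged).
    """
    groups = {}
    for name, vals in env_by_group.items():
        vals = np.asarray(vals, dtype=float)
        vals = vals[~np.isnan(vals)]
        if len(vals) < 2:
            logger.warning("group %s has <2 observations; excluded", name)
            continue
        groups[name] = vals
    if len(groups) < 2:
        raise ValueError("need at least 2 groups with >= 2 observations")
    names = list(groups)
    values = [groups[g] for g in names]
    h, kw_p = kruskal(*values)
    pairwise = _dunn_pairwise(values, names)
    letters = _letter_display(names, pairwise, alpha)
    return NicheComparison(
        h_statistic=float(h),
        kw_p=float(kw_p),
        pairwise=pairwise,
        letters=letters,
        group_sizes={g: len(v) for g, v in groups.items()},
    )


# ---------------------------------------------------------------------------
# environmental-variable pruning
# ---------------------------------------------------------------------------

def env_correlation_prune(
    env: pd.DataFrame, r_max: float = 0.7
) -> tuple[list[str], pd.DataFrame]:
    """Iteratively drop one of each over-correlated variable pair.

    Pearson correlations are computed on pairwise-complete observations.
    While any pair has |r| > r_max, the pair with the largest |r| loses the
    member with more missing values (ties: the later column).  Variables
    that are entirely missing are removed first (logged).  Returns retained
    column names and the final correlation matrix.
    """
    cols = [c for c in env.columns]
    for c in list(cols):
        if env[c].notna().sum() == 0:
            logger.warning("variable %s all-missing; removed first", c)
            cols.remove(c)
    while True:
        corr = env[cols].corr(method="pearson")
        best, best_r = None, r_max
        for i, a in enumerate(cols):
            for j in range(i + 1, len(cols)):
                b = cols[j]
                r = abs(corr.loc[a, b])
                if not np.isnan(r) and r > best_r:
                    best_r, best = r, (a, b)
        if best is None:
            return cols, corr
        a, b = best
        na, nb = env[a].isna().sum(), env[b].isna().sum()
        drop = b if nb >= na else a  # tie -> later column
        cols.remove(drop)


# ---------------------------------------------------------------------------
# cohabitation
# ---------------------------------------------------------------------------

def cohabitation_frequency(
    collections: pd.DataFrame, species_pair: tuple[str, str]
) -> tuple[float, int, int]:
    """Fraction of first-species-positive collections also holding the second.

    ``collections`` needs a ``species`` column holding a set/list of species
    detected per collection.  Returns (fraction, co-positive, denominator),
    the denominator being collections positive for the first-named species.
    """
    first, second = species_pair
    has_first = collections["species"].apply(lambda s: first in s)
    denom = int(has_first.sum())
    if denom == 0:
        raise ValueError(f"no collections positive for {first}")
    both = collections["species"].apply(lambda s: first in s and second in s)
    num = int(both.sum())
    return num / denom, num, denom
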