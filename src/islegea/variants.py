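"""Variant QC, heterozygote polarization, isotype calling, and diversity.

The QC stage mirrors a hard-filter pipeline for a selfing species: per-call
depth, site-quality and strand-bias thresholds (all boundary-exclusive),
then missingness and residual-heterozygosity site filters.  Strains sharing
more than 99.97% of SNVs collapse into a single "isotype" — effectively one
genome-wide haplotype — and diversity statistics (windowed pi, Tajima's D)
are computed on the diploid haplotype convention (2 haplotypes per sample).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .config import InvalidConfigError
from .genotypes import GenotypeMatrix, load_vcf  # noqa: F401  (re-exported)

logger = logging.getLogger(__name__)


class UndefinedConcordanceError(ValueError):
    """No jointly genotyped site between the two strains."""


# ---------------------------------------------------------------------------
# heterozygote polarization
# ---------------------------------------------------------------------------

def polarize_heterozygotes(
    matrix: GenotypeMatrix, llr_threshold: float = 2.0
) -> GenotypeMatrix:
    """Convert confident heterozygous calls to the more likely homozygote.

    PL fields are phred-scaled likelihood deficits, so the log10 likelihood
    ratio of hom-ref to hom-alt is ``(PL_alt - PL_ref) / 10``.  Calls with
    |LLR| above the threshold become the favoured homozygote; the rest stay
    heterozygous.  Heterozygotes without PL are left unchanged with a
    warning.
    """
    out = matrix.take_sites(np.arange(matrix.n_sites))
    dosage = out.dosage
    het = dosage == 1
    if not het.any():
        return out
    if matrix.pl is None:
        logger.warning("no PL fields present; heterozygotes left unchanged")
        return out
    pl_ref = matrix.pl[..., 0].astype(float)
    pl_alt = matrix.pl[..., 2].astype(float)
    has_pl = (matrix.pl[..., 0] >= 0) & (matrix.pl[..., 2] >= 0)
    n_missing_pl = int((het & ~has_pl).sum())
    if n_missing_pl:
        logger.warning("%d heterozygous calls lack PL; left unchanged", n_missing_pl)
    llr = (pl_alt - pl_ref) / 10.0  # log10 L(hom-ref) - log10 L(hom-alt)
    to_ref = het & has_pl & (llr > llr_threshold)
    to_alt = het & has_pl & (llr < -llr_threshold)
    dosage[to_ref] = 0
    dosage[to_alt] = 2
    logger.info(
        "polarized %d heterozygotes to reference, %d to alternative",
        int(to_ref.sum()), int(to_alt.sum()),
    )
    return out


# ---------------------------------------------------------------------------
# site / genotype filtering
# ---------------------------------------------------------------------------

@dataclass
class FilterLog:
    """Counts removed per rule, for provenance."""

    dp_calls_set_missing: int = 0
    removed: dict = field(default_factory=dict)

    def total_sites_removed(self) -> int:
        return sum(self.removed.values())


def filter_sites(
    matrix: GenotypeMatrix,
    dp_min: int = 5,
    qual_min: float = 30.0,
    qd_min: float = 20.0,
    fs_max: float = 100.0,
    sor_max: float = 5.0,
    max_missing_frac: float = 0.95,
    max_het_frac: float = 0.10,
) -> tuple[GenotypeMatrix, FilterLog]:
    """Apply the hard QC filters; thresholds are boundary-exclusive.

    Genotype calls with DP <= dp_min are set missing; sites failing
    QUAL/QD/FS/SOR are removed; then sites missing in more than
    ``max_missing_frac`` of samples or heterozygous in more than
    ``max_het_frac`` are removed.  Multiallelic sites are always removed.
    A rule whose annotation is absent is skipped with a warning, never
    silently passed.
    """
    out = matrix.take_sites(np.arange(matrix.n_sites))
    log = FilterLog()
    if out.dp is not None:
        low = (out.dp >= 0) & (out.dp <= dp_min) & (out.dosage >= 0)
        log.dp_calls_set_missing = int(low.sum())
        out.dosage[low] = -1
    else:
        logger.warning("DP absent; depth rule skipped")

    n = out.n_sites
    keep = np.ones(n, dtype=bool)

    def site_rule(name, values, passes):
        nonlocal keep
        if values is None or (isinstance(values, np.ndarray) and np.isnan(values).all()):
            logger.warning("%s absent; rule skipped", name)
            return
        ok = np.where(np.isnan(values), True, passes(values))
        log.removed[name] = int((keep & ~ok).sum())
        keep &= ok

    site_rule("QUAL", out.qual, lambda v: v > qual_min)
    site_rule("QD", out.qd, lambda v: v > qd_min)
    site_rule("FS", out.fs, lambda v: v < fs_max)
    site_rule("SOR", out.sor, lambda v: v < sor_max)

    multi = out.multiallelic
    log.removed["multiallelic"] = int((keep & multi).sum())
    keep &= ~multi

    n_samples = out.n_samples
    missing_frac = (out.dosage == -1).sum(axis=1) / n_samples
    het_frac = (out.dosage == 1).sum(axis=1) / n_samples
    ok = missing_frac <= max_missing_frac
    log.removed["missingness"] = int((keep & ~ok).sum())
    keep &= ok
    ok = het_frac <= max_het_frac
    log.removed["heterozygosity"] = int((keep & ~ok).sum())
    keep &= ok
    logger.info("filter_sites removed %d of %d sites", int((~keep).sum()), n)
    return out.take_sites(keep), log


# ---------------------------------------------------------------------------
# isotype calling
# ---------------------------------------------------------------------------

@dataclass
class IsotypeAssignment:
    assignment: pd.Series  # strain -> isotype label (representative strain id)
    concordance: pd.DataFrame  # strain_a, strain_b, concordance

    @property
    def n_isotypes(self) -> int:
        return self.assignment.nunique()


def pairwise_concordance(matrix: GenotypeMatrix, pair: tuple[str, str]) -> float:
    """Fraction of jointly non-missing sites with identical dosage."""
    ia = matrix.samples.index(pair[0])
    ib = matrix.samples.index(pair[1])
    a, b = matrix.dosage[:, ia], matrix.dosage[:, ib]
    both = (a >= 0) & (b >= 0)
    n = int(both.sum())
    if n == 0:
        raise UndefinedConcordanceError(f"no jointly genotyped site for {pair}")
    return float((a[both] == b[both]).sum() / n)


def cluster_isotypes(
    matrix: GenotypeMatrix, threshold: float = 0.9997
) -> IsotypeAssignment:
    """Group strains into isotypes by concordance above the threshold.

    Strains are nodes; edges join pairs with concordance strictly above the
    threshold; isotypes are connected components (transitive closure), each
    represented by its lexicographically smallest strain id.
    """
    S = matrix.n_samples
    d = matrix.dosage
    nonmiss = d >= 0
    # joint non-missing counts and agreement counts, vectorized over pairs
    nm = nonmiss.astype(np.float32)
    joint = nm.T @ nm
    agree = np.zeros((S, S), dtype=np.float32)
    for g in (0, 1, 2):
        ind = ((d == g)).astype(np.float32)
        agree += ind.T @ ind
    with np.errstate(invalid="ignore", divide="ignore"):
        conc = np.where(joint > 0, agree / joint, np.nan)
    adj = np.triu(conc > threshold, k=1)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    reps = {}
    for comp in range(n_comp):
        members = [matrix.samples[i] for i in np.flatnonzero(labels == comp)]
        reps[comp] = min(members)
    assignment = pd.Series(
        {matrix.samples[i]: reps[labels[i]] for i in range(S)}, name="isotype"
    )
    iu = np.triu_indices(S, k=1)
    conc_df = pd.DataFrame(
        {
            "strain_a": [matrix.samples[i] for i in iu[0]],
            "strain_b": [matrix.samples[j] for j in iu[1]],
            "concordance": conc[iu],
        }
    )
    return IsotypeAssignment(assignment=assignment, concordance=conc_df)


# ---------------------------------------------------------------------------
# diversity statistics
# ---------------------------------------------------------------------------

def _site_pairwise_terms(dosage: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site mean pairwise difference and haplotype counts.

    Diploid convention: every non-missing genotype contributes 2 haplotypes;
    a heterozygote contributes one of each allele.  The per-site term is
    ``n_alt * n_ref / C(n, 2)``.
    """
    nonmiss = dosage >= 0
    n_chr = 2 * nonmiss.sum(axis=1)
    n_alt = np.where(nonmiss, dosage, 0).sum(axis=1)
    n_ref = n_chr - n_alt
    pairs = n_chr * (n_chr - 1) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        term = np.where(pairs > 0, n_alt * n_ref / pairs, 0.0)
    return term, n_chr


def _iter_windows(length: int, window: int, step: int):
    """1-based inclusive windows tiling [1, length]; terminal window clipped."""
    start = 1
    while start <= length:
        yield start, min(start + window - 1, length)
        start += step


def windowed_pi(
    matrix: GenotypeMatrix, window: int = 10_000, step: int = 1_000
) -> pd.DataFrame:
    """Sliding-window nucleotide diversity per chromosome.

    pi is the sum of per-site pairwise-difference terms over variant sites
    in the window, divided by the window length (the terminal partial
    window uses its true length).
    """
    if window <= 0 or step <= 0 or step > window:
        raise InvalidConfigError("need 0 < step <= window")
    term, _ = _site_pairwise_terms(matrix.dosage)
    rows = []
    for c in matrix.chromosomes():
        on = matrix.chrom == c
        pos = matrix.pos[on]
        t = term[on]
        csum = np.concatenate([[0.0], np.cumsum(t)])
        length = matrix.chrom_lengths.get(c, int(pos.max()) if len(pos) else window)
        for lo, hi in _iter_windows(length, window, step):
            i = np.searchsorted(pos, lo, side="left")
            j = np.searchsorted(pos, hi, side="right")
            rows.append(
                {
                    "chrom": c,
                    "start": lo,
                    "end": hi,
                    "pi": (csum[j] - csum[i]) / (hi - lo + 1),
                    "n_variants": j - i,
                }
            )
    return pd.DataFrame(rows)


def _tajima_constants(n: int) -> dict[str, float]:
    """Tajima (1989) normalization constants for n haplotypes."""
    a1 = np.sum(1.0 / np.arange(1, n))
    a2 = np.sum(1.0 / np.arange(1, n) ** 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2,
            "e1": e1, "e2": e2}


def tajimas_d(matrix: GenotypeMatrix, window: int = 10_000) -> pd.DataFrame:
    """Tajima's D in non-overlapping windows.

    D = (pi_total - S/a1) / sqrt(e1 S + e2 S (S-1)), with pi_total the
    window sum of per-site pairwise-difference terms (not per-bp) and the
    constants from the modal haplotype count n in the window.  Windows with
    S = 0, or with fewer than 4 haplotypes, are flagged undefined (NaN).
    """
    if window <= 0:
        raise InvalidConfigError("window must be positive")
    term, n_chr = _site_pairwise_terms(matrix.dosage)
    seg = (term > 0).astype(int)
    rows = []
    for c in matrix.chromosomes():
        on = matrix.chrom == c
        pos = matrix.pos[on]
        t, s, nh = term[on], seg[on], n_chr[on]
        length = matrix.chrom_lengths.get(c, int(pos.max()) if len(pos) else window)
        for lo, hi in _iter_windows(length, window, window):
            i = np.searchsorted(pos, lo, side="left")
            j = np.searchsorted(pos, hi, side="right")
            S = int(s[i:j].sum())
            pi_total = float(t[i:j].sum())
            d_val = np.nan
            n_used = 0
            if S > 0:
                n_used = int(np.median(nh[i:j][s[i:j] > 0]))
                if n_used >= 4:
                    k = _tajima_constants(n_used)
                    var = k["e1"] * S + k["e2"] * S * (S - 1)
                    if var > 0:
                        d_val = (pi_total - S / k["a1"]) / np.sqrt(var)
            rows.append(
                {"chrom": c, "start": lo, "end": hi, "pi_total": pi_total,
                 "S": S, "D": d_val, "n": n_used}
            )
    return pd.DataFrame(rows)
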