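"""Configuration objects for the simulator and the end-to-end pipeline.

Defaults mirror the field study this package models: 13 sampling-cluster
populations of a selfing nematode, eight environmental covariates, and the
variant-filter / scan parameters used throughout the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from typing import Optional

import numpy as np

#: Environmental variables carried in the site table, in canonical order.
ENV_VARS = (
    "elevation",
    "air_temp",
    "surface_temp",
    "rainfall",
    "soil_moisture",
    "lai",
)

#: Covariates used in the genotype-environment scans: the six environmental
#: variables plus geographic position.
GEA_COVARIATES = ENV_VARS + ("latitude", "longitude")

# Means and SDs used to map latent standard-normal gradients onto physically
# plausible values (m, deg C, mm/yr, volumetric fraction, m2/m2).
ENV_SCALES = {
    "elevation": (800.0, 400.0),
    "air_temp": (18.0, 3.0),
    "surface_temp": (20.0, 3.0),
    "rainfall": (2000.0, 800.0),
    "soil_moisture": (0.30, 0.10),
    "lai": (3.0, 1.0),
}


def default_env_correlation() -> np.ndarray:
    """Default target correlation among the six environmental variables.

    Built from a single latent altitude gradient (loadings ``lam``) plus
    independent residuals, so the matrix is positive semi-definite by
    construction.  Elevation and the two temperatures are almost collinear
    (|r| > 0.95), as observed on volcanic island transects; moisture-related
    variables are only moderately coupled.
    """
    lam = np.array([0.98, -0.99, -0.97, 0.30, 0.50, 0.60])
    corr = np.outer(lam, lam)
    np.fill_diagonal(corr, 1.0)
    return corr


class InvalidConfigError(ValueError):
    """Raised when a configuration violates a documented invariant."""


@dataclass
class SimulationConfig:
    """Parameters of the selfing-metapopulation generator.

    Attributes
    ----------
    n_populations:
        Number of sampling-cluster populations (tips of the drift tree).
    samples_per_population:
        Strains sampled per population.
    n_snvs:
        Neutral biallelic SNVs placed uniformly over the chromosomes
        (hyper-divergent blocks add their own variants on top).
    n_chromosomes, chromosome_length:
        Genome layout in base pairs.
    tree_depth:
        Root-to-tip drift on the population tree, in variance units of the
        scaled allele-frequency deviation (the diagonal of the population
        covariance matrix Omega).
    selfing_rate:
        Probability a site is emitted homozygous; ``1 - selfing_rate`` of
        calls are residual heterozygotes.
    n_adaptive_loci, adaptive_effect:
        Number of planted environment-coupled loci and their effect, in
        drift standard deviations of population allele frequency per SD of
        the coupled covariate.
    env_correlation_target:
        Target Pearson correlation matrix among the six environmental
        variables (symmetric PSD, unit diagonal).
    n_hyperdivergent_blocks, block_length:
        High-diversity blocks of two deeply diverged haplotype classes.
    failing_site_fraction:
        Fraction of sites emitted with annotations that deliberately fail
        the QC filters.
    mean_depth, base_error:
        Read-depth model for PL emission: depth ~ Poisson(mean_depth),
        per-base error rate ``base_error``.
    """

    n_populations: int = 13
    samples_per_population: int = 11
    n_snvs: int = 20_000
    n_chromosomes: int = 6
    chromosome_length: int = 1_000_000
    tree_depth: float = 0.1
    selfing_rate: float = 0.995
    n_adaptive_loci: int = 20
    adaptive_effect: float = 1.5
    env_correlation_target: Optional[np.ndarray] = None
    n_hyperdivergent_blocks: int = 6
    block_length: int = 20_000
    failing_site_fraction: float = 0.05
    mean_depth: float = 27.0
    base_error: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_populations",
            "samples_per_population",
            "n_snvs",
            "n_chromosomes",
            "chromosome_length",
        ):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be positive")
        if self.n_populations < 2:
            raise InvalidConfigError("n_populations must be at least 2")
        if self.tree_depth <= 0:
            raise InvalidConfigError("tree_depth must be positive")
        if not 0.0 <= self.selfing_rate <= 1.0:
            raise InvalidConfigError("selfing_rate must lie in [0, 1]")
        if self.n_adaptive_loci < 0 or self.n_hyperdivergent_blocks < 0:
            raise InvalidConfigError("counts must be non-negative")
        if not 0.0 <= self.failing_site_fraction < 1.0:
            raise InvalidConfigError("failing_site_fraction must lie in [0, 1)")
        if self.env_correlation_target is None:
            self.env_correlation_target = default_env_correlation()
        c = np.asarray(self.env_correlation_target, dtype=float)
        if c.shape != (len(ENV_VARS), len(ENV_VARS)):
            raise InvalidConfigError(
                f"env_correlation_target must be {len(ENV_VARS)}x{len(ENV_VARS)}"
            )
        if not np.allclose(c, c.T):
            raise InvalidConfigError("env_correlation_target must be symmetric")
        if not np.allclose(np.diag(c), 1.0):
            raise InvalidConfigError("env_correlation_target needs unit diagonal")
        if np.linalg.eigvalsh(c).min() < -1e-8:
            raise InvalidConfigError("env_correlation_target must be PSD")
        self.env_correlation_target = c

    @property
    def n_samples(self) -> int:
        return self.n_populations * self.samples_per_population

    @property
    def chromosomes(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]


@dataclass
class PipelineConfig:
    """End-to-end pipeline parameters, with the study's defaults.

    ``vcf`` etc. may be file paths, or ``mode='simulate'`` to drive the whole
    analysis from :class:`SimulationConfig`.
    """

    mode: str = "simulate"  # "simulate" or "files"
    vcf: Optional[str] = None
    site_table: Optional[str] = None
    hyperdivergent_bed: Optional[str] = None
    outdir: str = "islegea_out"
    seed: int = 0

    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    # variant QC (boundary-exclusive, DP > 5 keeps DP = 6)
    dp_min: int = 5
    qual_min: float = 30.0
    qd_min: float = 20.0
    fs_max: float = 100.0
    sor_max: float = 5.0
    max_missing_frac: float = 0.95
    max_het_frac: float = 0.10
    llr_threshold: float = 2.0
    concordance_threshold: float = 0.9997

    # diversity windows
    pi_window: int = 10_000
    pi_step: int = 1_000
    tajima_window: int = 10_000

    # spatial clustering
    cluster_cut_m: float = 3_000.0

    # LD pruning for the GEA marker set
    prune_window: int = 50
    prune_step: int = 1
    prune_r2: float = 0.8
    maf_min: float = 0.1

    # LD pruning ahead of PCA (separate, stricter r2)
    pca_prune_window: int = 50
    pca_prune_step: int = 10
    pca_prune_r2: float = 0.1

    # population structure
    pca_components: int = 50
    outlier_iterations: int = 0
    outlier_sigma: float = 6.0
    k_groups: int = 7

    # GEA scans
    min_cluster_size: int = 3
    omega_subset_size: int = 5_000
    xtx_quantile: float = 0.999
    bf_cut_db: float = 20.0

    # region building
    region_gap: int = 1_000
    region_flank: int = 150

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "files"):
            raise InvalidConfigError("mode must be 'simulate' or 'files'")
        if self.mode == "files" and self.vcf is None:
            raise InvalidConfigError("files mode requires a vcf path")
        if self.pi_step > self.pi_window or self.pi_window <= 0:
            raise InvalidConfigError("need 0 < pi_step <= pi_window")
        if self.prune_step <= 0:
            raise InvalidConfigError("prune_step must be positive")
        if not 0.0 < self.xtx_quantile < 1.0:
            raise InvalidConfigError("xtx_quantile must lie in (0, 1)")
        if not 0.0 < self.concordance_threshold <= 1.0:
            raise InvalidConfigError("concordance_threshold must lie in (0, 1]")
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig(**self.simulation)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        sim = d["simulation"]
        sim["env_correlation_target"] = np.asarray(
            sim["env_correlation_target"]
        ).tolist()
        return d


def validate_config(raw: dict | PipelineConfig) -> PipelineConfig:
    """Normalize a raw mapping into a :class:`PipelineConfig`.

    Fills defaults, rejects unknown keys and cross-field violations.
    Idempotent: validating an already-validated config returns an equal one.
    """
    if isinstance(raw, PipelineConfig):
        return PipelineConfig.from_dict(raw.to_dict())
    return PipelineConfig.from_dict(dict(raw))
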