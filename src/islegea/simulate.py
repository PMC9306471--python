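"""Selfing-metapopulation simulator.

Generates the statistical structure the downstream analysis assumes:

* a random bifurcating population tree whose shared branch lengths define
  the population allele-frequency covariance matrix Omega;
* per-sample site metadata with environment drawn from a target correlation
  matrix, constant within each sampling-cluster population;
* per-SNV population allele frequencies under the multivariate-normal drift
  model, with environment-coupled adaptive loci planted at known positions;
* near-homozygous diploid genotypes with PL/DP fields from a Poisson
  read-depth model and site annotations calibrated against the QC filters;
* hyper-divergent blocks of two deeply diverged haplotype classes that
  raise local nucleotide diversity several-fold.

All randomness flows from a single ``numpy`` Generator seeded from the
config, so a fixed seed yields byte-identical outputs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .config import ENV_SCALES, ENV_VARS, InvalidConfigError, SimulationConfig
from .genotypes import GenotypeMatrix, write_vcf

# Frequencies are clipped (not redrawn) after truncation of the normal draw;
# the bias at extreme ancestral frequencies is documented in the methods note.
_FREQ_CLIP = (0.001, 0.999)

# Extra class-defining SNVs inserted per background-density unit inside a
# hyper-divergent block (total block density = 1 + _BLOCK_DENSITY_MULT).
_BLOCK_DENSITY_MULT = 4


@dataclass
class PopulationFrequencyTable:
    """Per-SNV population alternate-allele frequencies."""

    chrom: np.ndarray
    pos: np.ndarray
    pi_anc: np.ndarray  # ancestral-frequency used to generate (or estimate)
    freqs: np.ndarray  # (n_snvs, P)
    populations: list
    sample_sizes: Optional[np.ndarray] = None


@dataclass
class TruthTables:
    """Ground truth emitted alongside the synthetic data."""

    omega_true: np.ndarray
    adaptive_loci: pd.DataFrame  # chrom, pos, variable, effect
    hyperdivergent_truth: pd.DataFrame  # chrom, start, end (0-based half-open)
    population_assignment: pd.Series  # sample -> population label
    qc_fail_sites: pd.DataFrame  # chrom, pos of deliberately failing sites


def omega_from_tree(
    n_tips: int, joins: list[tuple[frozenset, frozenset, float]], depth: float
) -> np.ndarray:
    """Drift covariance from an ultrametric tree given as a join schedule.

    Each join records the two tip sets merged and the height (from the
    tips) at which they coalesce.  Omega[i, j] is the branch length shared
    by tips i and j from the root down: ``depth - mrca_height(i, j)``.
    """
    omega = np.full((n_tips, n_tips), np.nan)
    np.fill_diagonal(omega, depth)
    for a, b, h in joins:
        for i in a:
            for j in b:
                omega[i, j] = omega[j, i] = depth - h
    if np.isnan(omega).any():
        raise InvalidConfigError("join schedule does not connect all tips")
    return omega


def simulate_population_tree(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Build Omega from a random ultrametric bifurcating population tree.

    Join heights are uniform on (0, tree_depth); Omega[i, j] is the branch
    length shared by tips i and j measured from the root, so the diagonal
    equals ``tree_depth`` and the matrix is positive definite whenever all
    heights are distinct and positive.
    """
    P = config.n_populations
    if config.tree_depth <= 0:
        raise InvalidConfigError("tree_depth must be positive")
    heights = np.sort(rng.uniform(0.0, config.tree_depth, size=P - 1))
    clusters: list[frozenset] = [frozenset([i]) for i in range(P)]
    joins = []
    for h in heights:
        ia, ib = sorted(rng.choice(len(clusters), size=2, replace=False))
        a, b = clusters[ia], clusters[ib]
        joins.append((a, b, float(h)))
        clusters[ia] = a | b
        del clusters[ib]
    return omega_from_tree(P, joins, config.tree_depth)


def simulate_site_table(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Sample metadata: coordinates and environmental covariates.

    Populations sit on a ~11 km grid (well beyond the 3 km clustering cut);
    samples jitter < 500 m around their population centre.  Environmental
    values are drawn once per population from a multivariate normal with the
    configured correlation target and held constant within the population.
    """
    P = config.n_populations
    corr = np.asarray(config.env_correlation_target, dtype=float)
    try:
        L = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(corr)
        if w.min() < -1e-8:
            raise InvalidConfigError("env_correlation_target is not PSD")
        L = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    z = rng.standard_normal((P, len(ENV_VARS))) @ L.T

    side = int(np.ceil(np.sqrt(P)))
    base_lat, base_lon, spacing = 19.5, -155.5, 0.1  # deg; 0.1 deg ~ 11 km
    records = []
    for p in range(P):
        lat_c = base_lat + spacing * (p // side)
        lon_c = base_lon + spacing * (p % side)
        env = {
            var: ENV_SCALES[var][0] + ENV_SCALES[var][1] * z[p, k]
            for k, var in enumerate(ENV_VARS)
        }
        for s in range(config.samples_per_population):
            records.append(
                {
                    "sample": f"S{p:02d}_{s:02d}",
                    "population": f"pop{p:02d}",
                    "latitude": lat_c + rng.uniform(-0.002, 0.002),
                    "longitude": lon_c + rng.uniform(-0.002, 0.002),
                    **env,
                }
            )
    return pd.DataFrame(records)


def _snv_positions(config: SimulationConfig, rng: np.random.Generator):
    """Uniform SNV placement: unique sorted positions per chromosome."""
    per_chrom = np.full(config.n_chromosomes, config.n_snvs // config.n_chromosomes)
    per_chrom[: config.n_snvs % config.n_chromosomes] += 1
    chroms, positions = [], []
    for c, n in zip(config.chromosomes, per_chrom):
        pos = np.sort(rng.choice(np.arange(1, config.chromosome_length + 1), size=n, replace=False))
        chroms += [c] * n
        positions.append(pos)
    return np.array(chroms, dtype=object), np.concatenate(positions)


def simulate_allele_frequencies(
    config: SimulationConfig,
    omega: np.ndarray,
    site_table: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[PopulationFrequencyTable, pd.DataFrame]:
    """Draw per-SNV population frequencies under the drift-covariance model.

    For SNV i with ancestral frequency pi_i ~ U(0.05, 0.95), the population
    frequency vector is pi_i + sqrt(pi_i (1 - pi_i)) * MVN(0, Omega),
    truncated to the open unit interval.  Adaptive loci shift the mean of
    population j on the logit-frequency scale:
    ``logistic(logit(pi) + adaptive_effect * z_j)`` with z_j the coupled
    covariate standardized across populations, so the effect is a
    logit-slope per covariate SD.
    """
    eigmin = np.linalg.eigvalsh(omega).min()
    if eigmin <= 0:
        raise InvalidConfigError("omega must be positive definite")
    P = omega.shape[0]
    chrom, pos = _snv_positions(config, rng)
    n = len(pos)
    pi = rng.uniform(0.05, 0.95, size=n)
    L = np.linalg.cholesky(omega)
    scale = np.sqrt(pi * (1.0 - pi))
    noise = rng.standard_normal((n, P)) @ L.T
    freqs = pi[:, None] + scale[:, None] * noise

    pop_env = (
        site_table.drop_duplicates("population")
        .set_index("population")[list(ENV_VARS)]
        .sort_index()
    )
    populations = list(pop_env.index)
    records = []
    if config.n_adaptive_loci > 0:
        idx = np.sort(rng.choice(n, size=config.n_adaptive_loci, replace=False))
        for k, i in enumerate(idx):
            var = ENV_VARS[k % len(ENV_VARS)]
            z = pop_env[var].to_numpy()
            z = (z - z.mean()) / z.std()
            logit = np.log(pi[i] / (1.0 - pi[i]))
            mean_j = 1.0 / (1.0 + np.exp(-(logit + config.adaptive_effect * z)))
            freqs[i] += mean_j - pi[i]
            records.append(
                {"chrom": chrom[i], "pos": int(pos[i]), "variable": var,
                 "effect": config.adaptive_effect}
            )
    np.clip(freqs, *_FREQ_CLIP, out=freqs)
    table = PopulationFrequencyTable(
        chrom=chrom, pos=pos, pi_anc=pi, freqs=freqs, populations=populations
    )
    adaptive = pd.DataFrame(records, columns=["chrom", "pos", "variable", "effect"])
    return table, adaptive


def _emit_pl(dosage: np.ndarray, dp: np.ndarray, err: float, rng: np.random.Generator) -> np.ndarray:
    """Phred-scaled genotype likelihoods from a binomial read model.

    Alt-read counts are binomial in the true genotype's alt probability
    (err, 1/2, 1-err); PLs are the usual -10 log10 likelihood deficits
    rounded to integers, with the most likely genotype at 0.
    """
    p_alt = np.select([dosage == 0, dosage == 1, dosage == 2], [err, 0.5, 1.0 - err])
    k = rng.binomial(dp, p_alt)
    probs = np.array([err, 0.5, 1.0 - err])
    loglik = (
        k[..., None] * np.log10(probs)
        + (dp - k)[..., None] * np.log10(1.0 - probs)
    )
    pl = np.rint(-10.0 * (loglik - loglik.max(axis=-1, keepdims=True)))
    return pl.astype(np.int32)


def simulate_genotypes(
    popfreqs: PopulationFrequencyTable,
    site_table: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Emit near-homozygous diploid genotypes with QC annotations.

    Each sample draws a single founder allele per SNV from its population
    frequency (dosage 0 or 2); a fraction ``1 - selfing_rate`` of calls are
    flipped to residual heterozygotes.  Site annotations pass the QC filters
    except for ``failing_site_fraction`` of sites, which draw one failing
    annotation; those truth rows are returned for filter validation.
    """
    pop_index = {p: i for i, p in enumerate(popfreqs.populations)}
    sample_pop = site_table.set_index("sample")["population"]
    samples = list(site_table["sample"])
    n, S = len(popfreqs.pos), len(samples)
    cols = np.array([pop_index[sample_pop[s]] for s in samples])
    p = popfreqs.freqs[:, cols]  # (n, S)
    dosage = (rng.random((n, S)) < p).astype(np.int8) * 2
    if config.selfing_rate < 1.0:
        het = rng.random((n, S)) < (1.0 - config.selfing_rate)
        dosage[het] = 1
    dp = rng.poisson(config.mean_depth, size=(n, S)).astype(np.int32)
    pl = _emit_pl(dosage, dp, config.base_error, rng)

    qual = rng.uniform(100.0, 2000.0, size=n)
    qd = rng.uniform(25.0, 40.0, size=n)
    fs = rng.uniform(0.0, 20.0, size=n)
    sor = rng.uniform(0.5, 3.0, size=n)
    n_fail = int(round(config.failing_site_fraction * n))
    fail_idx = np.sort(rng.choice(n, size=n_fail, replace=False)) if n_fail else np.array([], int)
    which = rng.integers(0, 4, size=n_fail)
    qual[fail_idx[which == 0]] = rng.uniform(1.0, 30.0, size=(which == 0).sum())
    qd[fail_idx[which == 1]] = rng.uniform(1.0, 20.0, size=(which == 1).sum())
    fs[fail_idx[which == 2]] = rng.uniform(100.0, 200.0, size=(which == 2).sum())
    sor[fail_idx[which == 3]] = rng.uniform(5.0, 9.0, size=(which == 3).sum())

    bases = np.array(list("ACGT"), dtype=object)
    ref = bases[rng.integers(0, 4, size=n)]
    alt = np.array([bases[(b + 1) % 4] for b in rng.integers(0, 4, size=n)], dtype=object)
    alt_fix = alt == ref
    alt[alt_fix] = [("A" if r != "A" else "C") for r in ref[alt_fix]]

    matrix = GenotypeMatrix(
        samples=samples,
        chrom=popfreqs.chrom,
        pos=popfreqs.pos,
        ref=ref,
        alt=alt,
        dosage=dosage,
        pl=pl,
        dp=dp,
        qual=qual,
        qd=qd,
        fs=fs,
        sor=sor,
        chrom_lengths={c: config.chromosome_length for c in config.chromosomes},
    )
    qc_fail = pd.DataFrame(
        {"chrom": popfreqs.chrom[fail_idx], "pos": popfreqs.pos[fail_idx]}
    )
    return matrix, qc_fail


def plant_hyperdivergent_blocks(
    matrix: GenotypeMatrix,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Insert blocks of two deeply diverged haplotype classes.

    Each block assigns every sample to one of two haplotype classes (each
    class carried at ~50% frequency); all block SNVs — pre-existing ones and
    extra inserted variants at several times the background density — become
    class-defining homozygous alleles.  Per-site heterozygosity at those
    sites is ~0.5 versus ~0.37 genome-wide, and the density boost raises
    windowed diversity well over four-fold.  Blocks never overlap: they are
    laid round-robin over chromosomes, one per equal-length segment.
    """
    B = config.n_hyperdivergent_blocks
    if B == 0:
        return matrix, pd.DataFrame(columns=["chrom", "start", "end"])
    chroms = config.chromosomes
    per_chrom: dict[str, int] = {}
    for b in range(B):
        c = chroms[b % len(chroms)]
        per_chrom[c] = per_chrom.get(c, 0) + 1
    for c, nb in per_chrom.items():
        if nb * config.block_length > config.chromosome_length:
            raise InvalidConfigError(f"blocks do not fit on {c} without overlap")

    bg_density = matrix.n_sites / (config.n_chromosomes * config.chromosome_length)
    intervals = []
    new_site_rows = []
    dosage = matrix.dosage.copy()
    S = matrix.n_samples
    placed: dict[str, int] = {c: 0 for c in per_chrom}
    for b in range(B):
        c = chroms[b % len(chroms)]
        seg_len = config.chromosome_length // per_chrom[c]
        k = placed[c]
        placed[c] += 1
        lo = k * seg_len
        start = int(rng.integers(lo, lo + seg_len - config.block_length + 1))
        end = start + config.block_length
        intervals.append({"chrom": c, "start": start, "end": end})
        classes = rng.integers(0, 2, size=S).astype(np.int8)  # per-sample haplotype class
        inside = (matrix.chrom == c) & (matrix.pos > start) & (matrix.pos <= end)
        dosage[inside] = classes[None, :] * 2
        n_extra = int(round(_BLOCK_DENSITY_MULT * bg_density * config.block_length))
        taken = set(matrix.pos[inside].tolist())
        extra_pos = []
        candidates = rng.permutation(np.arange(start + 1, end + 1))
        for pp in candidates:
            if len(extra_pos) >= n_extra:
                break
            if pp not in taken:
                extra_pos.append(int(pp))
                taken.add(int(pp))
        for pp in sorted(extra_pos):
            new_site_rows.append((c, pp, classes))

    n_new = len(new_site_rows)
    if n_new == 0:
        out = GenotypeMatrix(**{**matrix.__dict__, "dosage": dosage})
        return out, pd.DataFrame(intervals)

    new_chrom = np.array([r[0] for r in new_site_rows], dtype=object)
    new_pos = np.array([r[1] for r in new_site_rows], dtype=np.int64)
    new_dosage = np.stack([r[2] * 2 for r in new_site_rows]).astype(np.int8)
    new_dp = rng.poisson(config.mean_depth, size=(n_new, S)).astype(np.int32)
    new_pl = _emit_pl(new_dosage, new_dp, config.base_error, rng)
    bases = np.array(list("ACGT"), dtype=object)
    new_ref = bases[rng.integers(0, 4, size=n_new)]
    new_alt = np.array(
        [("A" if r != "A" else "C") for r in new_ref], dtype=object
    )

    def cat(a, b):
        return None if a is None else np.concatenate([a, b])

    merged = GenotypeMatrix(
        samples=list(matrix.samples),
        chrom=np.concatenate([matrix.chrom, new_chrom]),
        pos=np.concatenate([matrix.pos, new_pos]),
        ref=np.concatenate([matrix.ref, new_ref]),
        alt=np.concatenate([matrix.alt, new_alt]),
        dosage=np.concatenate([dosage, new_dosage]),
        pl=cat(matrix.pl, new_pl),
        dp=cat(matrix.dp, new_dp),
        qual=cat(matrix.qual, rng.uniform(100.0, 2000.0, n_new)),
        qd=cat(matrix.qd, rng.uniform(25.0, 40.0, n_new)),
        fs=cat(matrix.fs, rng.uniform(0.0, 20.0, n_new)),
        sor=cat(matrix.sor, rng.uniform(0.5, 3.0, n_new)),
        multiallelic=cat(matrix.multiallelic, np.zeros(n_new, dtype=bool)),
        chrom_lengths=dict(matrix.chrom_lengths),
    ).sort_sites()
    return merged, pd.DataFrame(intervals)


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, pd.DataFrame, TruthTables]:
    """Run the full generator: tree, sites, frequencies, genotypes, blocks."""
    rng = np.random.default_rng(config.seed)
    omega = simulate_population_tree(config, rng)
    site_table = simulate_site_table(config, rng)
    popfreqs, adaptive = simulate_allele_frequencies(config, omega, site_table, rng)
    matrix, qc_fail = simulate_genotypes(popfreqs, site_table, config, rng)
    matrix, hdr = plant_hyperdivergent_blocks(matrix, config, rng)
    truth = TruthTables(
        omega_true=omega,
        adaptive_loci=adaptive,
        hyperdivergent_truth=hdr,
        population_assignment=site_table.set_index("sample")["population"],
        qc_fail_sites=qc_fail,
    )
    return matrix, site_table, truth


def write_dataset(
    matrix: GenotypeMatrix,
    site_table: pd.DataFrame,
    truth: TruthTables,
    outdir: str,
) -> dict[str, str]:
    """Write VCF, site CSV, truth CSV/BED; returns the path map."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "vcf": os.path.join(outdir, "simulated.vcf"),
        "site_table": os.path.join(outdir, "site_table.csv"),
        "adaptive_truth": os.path.join(outdir, "adaptive_truth.csv"),
        "hyperdivergent_bed": os.path.join(outdir, "hyperdivergent_truth.bed"),
        "omega_true": os.path.join(outdir, "omega_true.tsv"),
    }
    write_vcf(matrix, paths["vcf"])
    site_table.to_csv(paths["site_table"], index=False)
    truth.adaptive_loci.to_csv(paths["adaptive_truth"], index=False)
    with open(paths["hyperdivergent_bed"], "w") as fh:
        for _, row in truth.hyperdivergent_truth.iterrows():
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\n")
    np.savetxt(paths["omega_true"], truth.omega_true, delimiter="\t")
    return paths
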