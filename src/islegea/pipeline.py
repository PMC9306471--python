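"""End-to-end orchestration: simulate/load -> QC -> isotypes -> diversity ->
spatial clustering -> structure -> GEA scans -> consensus regions.

``analyze`` is the pure in-memory engine; ``run_pipeline`` wraps it with
file input/output and a hashed provenance manifest, so a fixed seed yields
an identical manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import ecology, gea, regions as regions_mod, structure, variants
from .config import GEA_COVARIATES, PipelineConfig, validate_config
from .genotypes import GenotypeMatrix, load_vcf
from .simulate import TruthTables, simulate_dataset, write_dataset

logger = logging.getLogger(__name__)


@dataclass
class AnalysisResult:
    """All stage outputs of one pipeline run."""

    filter_log: variants.FilterLog
    isotypes: variants.IsotypeAssignment
    isotype_matrix: GenotypeMatrix
    population_labels: pd.Series
    pi_windows: pd.DataFrame
    tajima_windows: pd.DataFrame
    pca: structure.PCAResult
    groups: pd.Series
    pc_env: pd.DataFrame
    omega: Optional[gea.OmegaMatrix]
    xtx: Optional[gea.XtXScan]
    bf: Optional[gea.BFScan]
    gwa: dict  # covariate -> GWAResult
    meff: float
    gwa_threshold: float
    tracks: dict  # provenance -> list[Region] (xtx) or variable -> list
    gea_regions: list = field(default_factory=list)
    distinct: list = field(default_factory=list)
    hdr_flags: list = field(default_factory=list)
    hdr_fraction: float = 0.0


def _population_covariates(
    site_table: pd.DataFrame, labels: pd.Series
) -> pd.DataFrame:
    """Per-population covariate table: mean over member isotypes' sites."""
    cols = [c for c in GEA_COVARIATES if c in site_table.columns]
    st = site_table.set_index("sample")
    st = st.loc[st.index.intersection(labels.index)]
    st = st.assign(_pop=labels.loc[st.index])
    return st.groupby("_pop")[cols].mean()


def analyze(
    matrix: GenotypeMatrix,
    site_table: pd.DataFrame,
    hdr_bed: pd.DataFrame,
    cfg: PipelineConfig,
) -> AnalysisResult:
    """Run every analysis stage on an in-memory dataset."""
    rng = np.random.default_rng(cfg.seed + 1_000_003)

    # --- variant QC ---
    mat = variants.polarize_heterozygotes(matrix, cfg.llr_threshold)
    mat, flog = variants.filter_sites(
        mat,
        dp_min=cfg.dp_min,
        qual_min=cfg.qual_min,
        qd_min=cfg.qd_min,
        fs_max=cfg.fs_max,
        sor_max=cfg.sor_max,
        max_missing_frac=cfg.max_missing_frac,
        max_het_frac=cfg.max_het_frac,
    )

    # --- isotype calling; analyses continue at the isotype level ---
    iso = variants.cluster_isotypes(mat, cfg.concordance_threshold)
    reps = sorted(set(iso.assignment))
    rep_idx = [mat.samples.index(s) for s in reps]
    iso_mat = mat.take_samples(rep_idx)

    # --- diversity ---
    pi_windows = variants.windowed_pi(iso_mat, cfg.pi_window, cfg.pi_step)
    tajima = variants.tajimas_d(iso_mat, cfg.tajima_window)

    # --- spatial clustering of isotype sampling sites ---
    coords = site_table[site_table["sample"].isin(reps)][
        ["sample", "latitude", "longitude"]
    ]
    labels = ecology.cluster_sampling_sites(coords, cut=cfg.cluster_cut_m)

    # --- population structure ---
    pca_keep = structure.ld_prune(
        iso_mat,
        window=cfg.pca_prune_window,
        step=cfg.pca_prune_step,
        r2_max=cfg.pca_prune_r2,
    )
    pca_res = structure.pca(
        iso_mat.take_sites(pca_keep),
        n_components=cfg.pca_components,
        outlier_iterations=cfg.outlier_iterations,
        outlier_sigma=cfg.outlier_sigma,
    )
    n_pcs = max(pca_res.n_significant, 1)
    sig_scores = pca_res.scores.iloc[:, :n_pcs]
    k = min(cfg.k_groups, len(sig_scores))
    groups = structure.assign_genetic_groups(sig_scores, k=k)
    env_by_sample = site_table.set_index("sample")[
        [c for c in GEA_COVARIATES if c in site_table.columns]
    ]
    pc_env = structure.pc_environment_correlation(pca_res.scores, env_by_sample)

    # --- GEA marker set ---
    gea_keep = structure.ld_prune(
        iso_mat,
        window=cfg.prune_window,
        step=cfg.prune_step,
        r2_max=cfg.prune_r2,
        maf_min=cfg.maf_min,
    )
    gmat = iso_mat.take_sites(gea_keep)

    omega = xtx = bf = None
    gwa_results: dict = {}
    meff = float("nan")
    gwa_thr = float("nan")
    tracks: dict = {"xtx": [], "baypass": {}, "gwa": {}}
    gea_regs: list = []
    distinct: list = []
    hdr_flags: list = []
    hdr_frac = 0.0

    counts = labels.value_counts()
    n_big = int((counts >= cfg.min_cluster_size).sum())
    if n_big >= 2 and gmat.n_sites >= 2:
        freqs = gea.population_allele_frequencies(
            gmat, labels, min_size=cfg.min_cluster_size
        )
        omega = gea.estimate_omega(freqs, subset_size=cfg.omega_subset_size, rng=rng)
        xtx = gea.xtx_scan(freqs, omega, quantile=cfg.xtx_quantile)
        pop_cov = _population_covariates(site_table, labels).loc[freqs.populations]
        bf = gea.bayes_factor_scan(freqs, omega, pop_cov, cut_db=cfg.bf_cut_db)

        kin = gea.kinship(gmat, loco=True)
        meff, gwa_thr = gea.effective_tests(gmat)
        env_iso = site_table.set_index("sample")
        for cov_name in bf.covariates:
            pheno = env_iso[cov_name].loc[gmat.samples]
            if pheno.std() == 0:
                continue
            gwa_results[cov_name] = gea.lmm_gwa(gmat, pheno, kin)

        # --- region building ---
        tested = pd.DataFrame({"chrom": gmat.chrom, "pos": gmat.pos})
        xtx_sig = pd.DataFrame(
            {"chrom": xtx.chrom[xtx.flagged], "pos": xtx.pos[xtx.flagged],
             "stat": xtx.xtx[xtx.flagged]}
        )
        tracks["xtx"] = regions_mod.build_regions(
            xtx_sig, tested, gap=cfg.region_gap, flank=cfg.region_flank,
            provenance="xtx",
        )
        flagged_bf = bf.flagged
        for j, cov_name in enumerate(bf.covariates):
            on = flagged_bf[:, j]
            bp_sig = pd.DataFrame(
                {"chrom": bf.chrom[on], "pos": bf.pos[on], "stat": bf.bf_db[on, j]}
            )
            tracks["baypass"][cov_name] = regions_mod.build_regions(
                bp_sig, tested, gap=cfg.region_gap, flank=cfg.region_flank,
                provenance="baypass", variable=cov_name,
            )
            res = gwa_results.get(cov_name)
            if res is None:
                tracks["gwa"][cov_name] = []
                continue
            sig = np.isfinite(res.p) & (res.p < gwa_thr)
            with np.errstate(divide="ignore"):
                stat = -np.log10(np.clip(res.p, 1e-300, None))
            gw_sig = pd.DataFrame(
                {"chrom": res.chrom[sig], "pos": res.pos[sig], "stat": stat[sig]}
            )
            tracks["gwa"][cov_name] = regions_mod.build_regions(
                gw_sig, tested, gap=cfg.region_gap, flank=cfg.region_flank,
                provenance="gwa", variable=cov_name,
            )
            overlaps = regions_mod.intersect_regions(
                tracks["baypass"][cov_name], tracks["gwa"][cov_name]
            )
            gea_regs.extend(
                regions_mod.consensus_gea_regions(overlaps, tracks["xtx"])
            )
        distinct = regions_mod.distinct_regions(gea_regs)
        hdr_flags, hdr_frac = regions_mod.hyperdivergent_overlap(distinct, hdr_bed)
    else:
        logger.warning("too few populations or markers for GEA; scans skipped")

    return AnalysisResult(
        filter_log=flog,
        isotypes=iso,
        isotype_matrix=iso_mat,
        population_labels=labels,
        pi_windows=pi_windows,
        tajima_windows=tajima,
        pca=pca_res,
        groups=groups,
        pc_env=pc_env,
        omega=omega,
        xtx=xtx,
        bf=bf,
        gwa=gwa_results,
        meff=meff,
        gwa_threshold=gwa_thr,
        tracks=tracks,
        gea_regions=gea_regs,
        distinct=distinct,
        hdr_flags=hdr_flags,
        hdr_fraction=hdr_frac,
    )


def evaluate_planted_recovery(result: AnalysisResult, truth: TruthTables) -> dict:
    """Score consensus regions against the simulator's planted loci.

    A planted locus is recovered when its position falls inside a distinct
    consensus region; a region containing no planted locus counts as
    neutral (a false discovery at the region level).
    """
    planted = truth.adaptive_loci
    n_hit = 0
    for _, row in planted.iterrows():
        if any(
            r.chrom == row["chrom"] and r.start <= row["pos"] <= r.end
            for r in result.distinct
        ):
            n_hit += 1
    n_neutral = sum(
        not any(
            r.chrom == row["chrom"] and r.start <= row["pos"] <= r.end
            for _, row in planted.iterrows()
        )
        for r in result.distinct
    )
    return {
        "n_planted": len(planted),
        "n_recovered": n_hit,
        "recovery": n_hit / len(planted) if len(planted) else float("nan"),
        "n_neutral_regions": n_neutral,
        "n_distinct_regions": len(result.distinct),
    }


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig | dict) -> dict:
    """Execute the full pipeline from a config; returns the run manifest."""
    cfg = validate_config(config)
    os.makedirs(cfg.outdir, exist_ok=True)
    truth: Optional[TruthTables] = None
    if cfg.mode == "simulate":
        sim_cfg = cfg.simulation
        sim_cfg.seed = cfg.seed
        matrix, site_table, truth = simulate_dataset(sim_cfg)
        sim_paths = write_dataset(matrix, site_table, truth, cfg.outdir)
        hdr_bed = truth.hyperdivergent_truth
    else:
        matrix = load_vcf(cfg.vcf)
        site_table = pd.read_csv(cfg.site_table)
        sim_paths = {}
        if cfg.hyperdivergent_bed:
            hdr_bed = pd.read_csv(
                cfg.hyperdivergent_bed, sep="\t", header=None,
                names=["chrom", "start", "end"], usecols=[0, 1, 2],
            )
        else:
            hdr_bed = pd.DataFrame(columns=["chrom", "start", "end"])

    result = analyze(matrix, site_table, hdr_bed, cfg)

    out = {}
    result.pi_windows.to_csv(os.path.join(cfg.outdir, "pi_windows.tsv"),
                             sep="\t", index=False)
    out["pi_windows.tsv"] = os.path.join(cfg.outdir, "pi_windows.tsv")
    result.tajima_windows.to_csv(os.path.join(cfg.outdir, "tajima_windows.tsv"),
                                 sep="\t", index=False)
    out["tajima_windows.tsv"] = os.path.join(cfg.outdir, "tajima_windows.tsv")
    result.isotypes.assignment.to_csv(os.path.join(cfg.outdir, "isotypes.csv"))
    out["isotypes.csv"] = os.path.join(cfg.outdir, "isotypes.csv")
    result.population_labels.to_csv(os.path.join(cfg.outdir, "populations.csv"))
    out["populations.csv"] = os.path.join(cfg.outdir, "populations.csv")
    result.groups.to_csv(os.path.join(cfg.outdir, "genetic_groups.csv"))
    out["genetic_groups.csv"] = os.path.join(cfg.outdir, "genetic_groups.csv")
    result.pc_env.to_csv(os.path.join(cfg.outdir, "pc_env_correlation.tsv"),
                         sep="\t", index=False)
    out["pc_env_correlation.tsv"] = os.path.join(cfg.outdir, "pc_env_correlation.tsv")

    if result.xtx is not None:
        scan = pd.DataFrame({"chrom": result.xtx.chrom, "pos": result.xtx.pos,
                             "xtx": result.xtx.xtx})
        for j, cov_name in enumerate(result.bf.covariates):
            scan[f"bf_db_{cov_name}"] = result.bf.bf_db[:, j]
            res = result.gwa.get(cov_name)
            if res is not None:
                scan[f"p_{cov_name}"] = res.p
        scan.to_csv(os.path.join(cfg.outdir, "scan.tsv"), sep="\t", index=False)
        out["scan.tsv"] = os.path.join(cfg.outdir, "scan.tsv")

    all_regions = list(result.tracks["xtx"])
    for d in (result.tracks["baypass"], result.tracks["gwa"]):
        for regs in d.values():
            all_regions.extend(regs)
    all_regions.extend(result.gea_regions)
    all_regions.extend(result.distinct)
    regions_mod.regions_to_frame(all_regions).to_csv(
        os.path.join(cfg.outdir, "regions.tsv"), sep="\t", index=False
    )
    out["regions.tsv"] = os.path.join(cfg.outdir, "regions.tsv")

    manifest = {
        "config": cfg.to_dict(),
        "outputs": {
            name: _sha256(path) for name, path in {**sim_paths, **out}.items()
        },
        "summary": {
            "n_isotypes": int(result.isotypes.n_isotypes),
            "n_populations": int(result.population_labels.nunique()),
            "n_significant_pcs": int(result.pca.n_significant),
            "n_gea_regions": len(result.gea_regions),
            "n_distinct_regions": len(result.distinct),
            "hdr_overlap_fraction": result.hdr_fraction,
            "meff": None if np.isnan(result.meff) else result.meff,
        },
    }
    with open(os.path.join(cfg.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
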