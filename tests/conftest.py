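import numpy as np
import pytest

from islegea import PipelineConfig, SimulationConfig
from islegea.simulate import simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A compact simulated dataset reused across module tests."""
    cfg = SimulationConfig(n_snvs=3000, seed=42)
    matrix, site_table, truth = simulate_dataset(cfg)
    return cfg, matrix, site_table, truth


@pytest.fixture(scope="session")
def small_analysis(small_dataset):
    from islegea import analyze

    cfg, matrix, site_table, truth = small_dataset
    pcfg = PipelineConfig(seed=42, simulation=cfg)
    return pcfg, analyze(matrix, site_table, truth.hyperdivergent_truth, pcfg), truth


def make_matrix(dosage, chrom=None, pos=None, samples=None, **kw):
    """Hand-rolled GenotypeMatrix from a (sites x samples) dosage array."""
    from islegea.genotypes import GenotypeMatrix

    dosage = np.asarray(dosage, dtype=np.int8)
    n, s = dosage.shape
    return GenotypeMatrix(
        samples=samples or [f"s{i}" for i in range(s)],
        chrom=np.array(chrom if chrom is not None else ["chr1"] * n, dtype=object),
        pos=np.array(pos if pos is not None else np.arange(1, n + 1), dtype=np.int64),
        ref=np.array(["A"] * n, dtype=object),
        alt=np.array(["T"] * n, dtype=object),
        dosage=dosage,
        **kw,
    )
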