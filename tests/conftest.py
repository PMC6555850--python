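import numpy as np
import pytest
from hypothesis import settings

from regscore.genomics import Peak, PeakSet

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")
from regscore.synthetic import SimulationConfig, simulate


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Desk-scale generator config: shrunken genome and distal window,
    everything else at the module defaults."""
    return SimulationConfig(
        n_genes=30,
        n_enriched_genes=20,
        n_tfs=5,
        chrom_length=300_000,
        distal_max_bp=40_000,
        min_gene_spacing=7_000,
        seed=11,
    )


@pytest.fixture(scope="session")
def sim_result(small_config):
    return simulate(small_config)


@pytest.fixture(scope="session")
def sim_dir(small_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("simdata")
    simulate(small_config, out)
    return out


def random_peakset(rng: np.random.Generator, n: int, span: int = 100_000,
                   chroms=("chr1",), label: str = "") -> PeakSet:
    """Random (merged) peak set for oracle comparisons."""
    peaks = []
    for _ in range(n):
        start = int(rng.integers(0, span))
        width = int(rng.integers(10, 500))
        peaks.append(
            Peak(
                chrom=str(rng.choice(list(chroms))),
                start=start,
                end=start + width,
                signal_rpkm=float(rng.lognormal(1, 0.5)),
                q_value=float(rng.uniform(0, 0.049)),
            )
        )
    return PeakSet(peaks, label=label)
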