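import warnings

import numpy as np
import pytest

from linkerscape.config import PipelineConfig, SynthConfig
from linkerscape.genotypes import GenotypeTable

warnings.filterwarnings("ignore", message="zone extends beyond the window")


def make_table(rows, n_loci=None, windows=None, years=None):
    """Build a GenotypeTable from [(id, pop, [(a, b), ...]), ...]."""
    ids = [r[0] for r in rows]
    pops = [r[1] for r in rows]
    genos = np.array([r[2] for r in rows], dtype=np.int64)
    if windows is None:
        windows = ["W0"] * len(rows)
    return GenotypeTable(
        np.array(ids), np.array(pops), np.array(windows), genos,
        years=None if years is None else np.array(years),
    )


@pytest.fixture(scope="session")
def tiny_synth():
    """Small study configuration: quick to generate, still 2 windows."""
    return SynthConfig(
        n_windows=2, window_size_m=2000.0, cell_size_m=20.0,
        n_patches_per_window=4, patch_radius_m=90.0,
        patch_min_separation_m=550.0, n_nuclei=60,
        plants_per_patch=12, workers_per_patch=(10, 14),
        nest_density=14.0, rng_seed=424242,
    )


@pytest.fixture(scope="session")
def tiny_pipe():
    return PipelineConfig(
        node_radii=(125.0, 500.0), link_ratios=(1 / 7, 1 / 2),
        sibship_restarts=2, seed=9,
    )


@pytest.fixture(scope="session")
def tiny_study(tiny_synth):
    from linkerscape.synthetic import generate_study

    return generate_study(tiny_synth)
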