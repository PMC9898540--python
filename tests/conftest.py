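import numpy as np
import pandas as pd
import pytest

from clonetrace import SimulationConfig, generate_dataset
from clonetrace.containers import PROFILE_LEVELS, ClonalAbundanceMatrix
from clonetrace.samples import CELL_TYPES, DEFAULT_TIMEPOINTS


def make_matrix(data, groups=None, timepoints=DEFAULT_TIMEPOINTS):
    """Build a ClonalAbundanceMatrix from {(barcode, mouse): {(ct, tp): val}}.

    Unlisted cells are zero; the full cell-type x timepoint grid is emitted.
    """
    cols = pd.MultiIndex.from_product([CELL_TYPES, timepoints], names=PROFILE_LEVELS)
    index = pd.MultiIndex.from_tuples(list(data), names=("barcode", "mouse"))
    wide = pd.DataFrame(0.0, index=index, columns=cols)
    for clone, cells in data.items():
        for cell, value in cells.items():
            wide.loc[clone, cell] = value
    mice = {m for _, m in data}
    groups = groups or {m: "HSC" for m in mice}
    return ClonalAbundanceMatrix(wide, groups)


def random_abundance_matrix(rng, n_clones, n_mice=1, timepoints=DEFAULT_TIMEPOINTS):
    """Random matrix whose values straddle the classification thresholds.

    Cells are drawn from zero, near-floor (around 0.01), near the
    high-abundance cut (0.05), mid-range, and spike-range (>0.5) regimes so
    oracle comparisons exercise every boundary.
    """
    cols = pd.MultiIndex.from_product([CELL_TYPES, timepoints], names=PROFILE_LEVELS)
    shape = (n_clones * n_mice, len(cols))
    regime = rng.integers(0, 5, size=shape)
    values = np.select(
        [regime == 0, regime == 1, regime == 2, regime == 3],
        [
            0.0,
            rng.uniform(0.0, 0.02, size=shape),
            rng.uniform(0.04, 0.06, size=shape),
            rng.uniform(0.3, 0.8, size=shape),
        ],
        default=rng.lognormal(np.log(0.05), 1.0, size=shape),
    )
    index = pd.MultiIndex.from_tuples(
        [(f"bc{i:04d}", f"m{i // n_clones}") for i in range(n_clones * n_mice)],
        names=("barcode", "mouse"),
    )
    groups = {f"m{j}": "HSC" if j % 2 == 0 else "HSC+MPP" for j in range(n_mice)}
    return ClonalAbundanceMatrix(pd.DataFrame(values, index=index, columns=cols), groups)


@pytest.fixture(scope="session")
def default_dataset():
    """One simulated experiment at the recovery noise level, shared by tests."""
    config = SimulationConfig(sigma=0.3)
    return config, *generate_dataset(config, seed=11)


@pytest.fixture(scope="session")
def small_dataset():
    """A small, fast experiment for end-to-end and CLI tests."""
    config = SimulationConfig(
        n_mice={"HSC": 2, "HSC+MPP": 2}, clones_per_mouse=60, sigma=0.3, seed=7
    )
    return config, *generate_dataset(config, seed=7)
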