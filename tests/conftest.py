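import numpy as np
import pandas as pd
import pytest

from hetarray.io_formats import SPOT_COLUMNS
from hetarray.synthetic_data import SimulationParams, make_design, simulate_signal_matrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_spots(rows):
    """rows: list of (array, probe, fg1, bg1, fg2, bg2, flagged)."""
    return pd.DataFrame(rows, columns=SPOT_COLUMNS).astype(
        {"fg_ch1": float, "bg_ch1": float, "fg_ch2": float, "bg_ch2": float, "flagged": bool}
    )


@pytest.fixture
def tiny_design():
    return make_design(SimulationParams(n_genes=50, n_replicates=1, seed=0))


@pytest.fixture
def small_experiment():
    """Deterministic small simulated signal matrix + design + truth."""
    params = SimulationParams(
        n_genes=200, seed=7, effects={"species": (0.1, 2.0)}, noise_sd=0.2
    )
    return simulate_signal_matrix(params)


def write_tsv(path, text):
    path.write_text(text)
    return str(path)
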