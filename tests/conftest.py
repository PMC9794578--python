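import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # helpers / oracle modules

from averp import synth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def quiet_config():
    """Small noise-free cohort: 1 subject per group, no jitter, no blinks."""
    return synth.SimConfig(
        n_older=1, n_younger=1, seed=7,
        noise=synth.NoiseSpec(white_sd_uv=0.0, pink_sd_uv=0.0,
                              blink_rate_per_min=0.0,
                              subject_amp_sd=0.0, subject_effect_sd=0.0),
    )


@pytest.fixture
def small_design():
    return synth.DesignSpec(targets_per_modality=3, standards_per_modality=12,
                            blocks=("high",))


def make_long_table(Y, rng=None):
    """Long-format DataFrame from an (a, n, k1, ..., km) data array."""
    import itertools

    import pandas as pd

    a, n = Y.shape[:2]
    wfs = [f"W{i+1}" for i in range(Y.ndim - 2)]
    rows = []
    for g in range(a):
        for s in range(n):
            sid = f"g{g}s{s}"
            for combo in itertools.product(*[range(k) for k in Y.shape[2:]]):
                rows.append({"subject": sid, "A": f"a{g}",
                             **{wfs[i]: f"l{c}" for i, c in enumerate(combo)},
                             "y": Y[(g, s) + combo]})
    return pd.DataFrame(rows), wfs
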