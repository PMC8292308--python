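import numpy as np
import pandas as pd
import pytest

from thermoflex import SimConfig
from thermoflex.synthetic import TraceParams


@pytest.fixture
def clean_trace_cfg():
    """Drift- and noise-free trace configuration (planted M_sum = 3.0)."""
    return SimConfig(seed=0, trace=TraceParams(drift_pct_per_hr=0.0, noise_sd_pct=0.0))


@pytest.fixture
def small_fst():
    pops = ["aikeni", "dorsalis", "palliatus", "shufeldti", "thurberi"]
    rng = np.random.default_rng(42)
    th = rng.uniform(0.019, 0.051, size=(5, 5))
    th = (th + th.T) / 2
    np.fill_diagonal(th, 0.0)
    return pd.DataFrame(th, index=pops, columns=pops)
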