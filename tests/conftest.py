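import numpy as np
import pandas as pd
import pytest

from fusionsig import SimulationParams, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort with clear signal, shared across read-only tests."""
    params = SimulationParams(
        n_genes=300,
        n_samples=120,
        n_signal_genes=40,
        effect_size=1.5,
        hazard_coef=1.0,
        seed=11,
    )
    return simulate_cohort(params)


@pytest.fixture
def toy_expr():
    """A 4-gene x 3-sample matrix with hand-readable values."""
    return pd.DataFrame(
        {
            "s1": [3.0, 1.0, 2.0, 0.0],
            "s2": [1.0, 1.0, 4.0, 2.0],
            "s3": [0.5, 0.5, 0.5, 0.5],
        },
        index=["gA", "gB", "gC", "gD"],
    )


def brute_force_running_sum(order_mags: np.ndarray) -> float:
    """Independent oracle: evaluate D(k) at every cut with explicit running sums.

    Pure-Python left-to-right accumulation, mirroring the statistic's
    definition as a running sum rather than any vectorized shortcut.
    """
    v = [float(x) for x in order_mags]
    total_fg = 0.0
    total_bg = 0.0
    for x in v:
        total_fg += x
        total_bg += 1.0 - x
    best = 0.0
    best_abs = -1.0
    fg = 0.0
    bg = 0.0
    for x in v:
        fg += x
        bg += 1.0 - x
        d = fg / total_fg - bg / total_bg
        if abs(d) > best_abs:
            best_abs = abs(d)
            best = d
    return best
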