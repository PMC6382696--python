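import numpy as np
import pytest

from ionscreen.assay_core import KineticTrace


def make_trace(baseline=100.0, post=None, n_baseline=7, dt=1.0):
    """FLIPR-like trace: ``n_baseline`` reads at ``baseline`` followed by the
    ``post`` values; trigger sits between the two segments."""
    post = np.asarray([baseline] * 40 if post is None else post, dtype=float)
    n = n_baseline + post.size
    times = np.arange(n) * dt
    values = np.concatenate([np.full(n_baseline, float(baseline)), post])
    return KineticTrace(
        times=times, values=values,
        trigger_time=(n_baseline - 0.5) * dt,
        baseline_window=(0.0, (n_baseline - 1) * dt),
    )


@pytest.fixture
def flat_trace():
    return make_trace(100.0)


@pytest.fixture
def quench_trace():
    # decays from baseline 100 to a minimum of 40 after the trigger
    post = 40.0 + 60.0 * np.exp(-np.arange(40) / 5.0)
    return make_trace(100.0, post)
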