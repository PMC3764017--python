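import numpy as np
import pytest

from nmjquant import SimParams, Trace
from nmjquant._kernel import sampled_kernel


@pytest.fixture
def quiet_params():
    """Noise-free, event-free baseline parameters for constructed traces."""
    return SimParams(duration=5.0, noise_sd=0.0, mepp_rate=0.0, gmepp_rate=0.0, seed=0)


def make_trace(
    events,
    duration=5.0,
    fs=10_000.0,
    rmp=-70.0,
    noise_sd=0.0,
    tau_rise=0.4,
    tau_decay=3.5,
    seed=0,
):
    """Build a trace with kernels injected at known (sample-aligned) onsets.

    ``events`` is a list of (onset_time_s, amplitude_mV).  Returns the trace
    and the grid-aligned onset times.
    """
    n = int(round(duration * fs))
    rng = np.random.default_rng(seed)
    v = rmp + (noise_sd * rng.standard_normal(n) if noise_sd else np.zeros(n))
    kern = sampled_kernel(fs, tau_rise, tau_decay, tail_frac=0.001)
    onsets = []
    for t, amp in events:
        i = int(round(t * fs))
        m = min(kern.size, n - 1 - i)
        v[i + 1 : i + 1 + m] += amp * kern[:m]
        onsets.append(i / fs)
    return Trace(sampling_rate=fs, voltage=v, rmp_estimate=rmp), onsets
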