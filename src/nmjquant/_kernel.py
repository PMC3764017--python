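"""Postsynaptic event kernel.

The canonical waveform of a miniature or evoked endplate potential is
modelled as a product of an exponential rise and an exponential decay,

    k(t) = (1 - exp(-t / tau_rise)) * exp(-t / tau_decay),   t >= 0

peak-normalized so that an event of amplitude ``a`` contributes
``a * k(t) / max(k)`` to the trace.  Two parameters reproduce the ~1 ms
rise / ~3-4 ms decay kinetics measured at the mouse diaphragm endplate.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "event_waveform",
    "kernel_peak_time",
    "kernel_support_ms",
    "sampled_kernel",
]


def kernel_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Time (ms) at which the raw kernel peaks: tau_r * ln(1 + tau_d/tau_r)."""
    return tau_rise * np.log1p(tau_decay / tau_rise)


def _raw_kernel(t_ms: np.ndarray, tau_rise: float, tau_decay: float) -> np.ndarray:
    t = np.asarray(t_ms, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    out[pos] = -np.expm1(-t[pos] / tau_rise) * np.exp(-t[pos] / tau_decay)
    return out


def event_waveform(
    t_ms: np.ndarray, amp: float, tau_rise: float, tau_decay: float
) -> np.ndarray:
    """Evaluate the peak-normalized event kernel scaled to ``amp`` (mV).

    Parameters
    ----------
    t_ms
        Time grid in milliseconds relative to event onset; the waveform is
        zero for ``t <= 0``.
    amp
        Peak amplitude in mV; must be positive.
    tau_rise, tau_decay
        Rise and decay time constants in ms, with ``tau_rise < tau_decay``.
    """
    if tau_rise <= 0 or tau_decay <= 0:
        raise ValueError("time constants must be positive")
    if tau_rise >= tau_decay:
        raise ValueError("tau_rise must be smaller than tau_decay")
    if amp <= 0:
        raise ValueError("amplitude must be positive")
    t_peak = kernel_peak_time(tau_rise, tau_decay)
    peak = -np.expm1(-t_peak / tau_rise) * np.exp(-t_peak / tau_decay)
    return amp * _raw_kernel(t_ms, tau_rise, tau_decay) / peak


def kernel_support_ms(tau_rise: float, tau_decay: float, tail_frac: float = 0.005) -> float:
    """Length (ms) after which the kernel stays below ``tail_frac`` of its peak."""
    return kernel_peak_time(tau_rise, tau_decay) - tau_decay * np.log(tail_frac)


def sampled_kernel(
    sampling_rate: float, tau_rise: float, tau_decay: float, tail_frac: float = 0.005
) -> np.ndarray:
    """Unit-amplitude kernel sampled at ``sampling_rate`` (Hz), finite support."""
    dt_ms = 1000.0 / sampling_rate
    n = max(int(np.ceil(kernel_support_ms(tau_rise, tau_decay, tail_frac) / dt_ms)), 4)
    t = np.arange(1, n + 1) * dt_ms
    return event_waveform(t, 1.0, tau_rise, tau_decay)
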