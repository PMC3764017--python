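"""Per-fiber quantal characterization.

Amplitudes recorded at different resting membrane potentials (RMP) are
normalized to a common −75 mV reference,

    V_nor = V_obs * (-75) / RMP,

fibers are accepted only when their RMP lies in the [−80, −60] mV window,
and the quantal content m of evoked release is estimated per fiber as the
ratio of the normalized mean EPP amplitude to the normalized mean MEPP
amplitude (ratio-of-means estimator; no nonlinear-summation correction is
applied).  Averaging follows the acquisition protocol: the first 60
consecutive sweeps for EPPs and the first 100 consecutive MEPPs for
spontaneous activity, with explicit short-record flags when fewer are
available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detect import DetectedEvent, EPPMeasure

__all__ = [
    "FiberRecord",
    "REFERENCE_RMP",
    "RMP_WINDOW",
    "check_rmp",
    "gmepp_mepp_ratio",
    "mean_epp",
    "mean_mepp",
    "normalize_amplitude",
    "quantal_content",
    "records_to_frame",
    "summarize_fiber",
]

REFERENCE_RMP = -75.0  # mV, normalization reference
RMP_WINDOW = (-80.0, -60.0)  # inclusive acceptance window
EPP_SWEEPS = 60  # consecutive sweeps averaged per fiber
MEPP_EVENTS = 100  # consecutive MEPPs averaged per fiber


def normalize_amplitude(v_obs: float, rmp: float) -> float:
    """Normalize an amplitude (mV) recorded at ``rmp`` to the −75 mV reference."""
    if rmp >= 0:
        raise ValueError("rmp must be negative")
    return v_obs * REFERENCE_RMP / rmp


def check_rmp(rmp: float) -> bool:
    """True when the resting membrane potential lies in [−80, −60] mV (inclusive)."""
    if not np.isfinite(rmp):
        raise ValueError("rmp must be finite")
    lo, hi = RMP_WINDOW
    return lo <= rmp <= hi


def _mean_sem(values: np.ndarray) -> tuple[float, float]:
    m = float(np.mean(values))
    if values.size < 2:
        return m, float("nan")
    return m, float(np.std(values, ddof=1) / math.sqrt(values.size))


def mean_epp(
    measures: list[EPPMeasure] | np.ndarray,
    rmp: float | np.ndarray | None = None,
    n_sweeps: int = EPP_SWEEPS,
) -> dict[str, float | bool]:
    """Average EPP amplitude over the first ``n_sweeps`` consecutive sweeps.

    Accepts either EPPMeasure objects (whose per-sweep RMP is used for
    normalization) or a plain amplitude array with ``rmp`` given per sweep
    or as one fiber-level value.  Returns raw mean, normalized mean, the
    SEM of normalized amplitudes and a short-record flag when fewer than
    ``n_sweeps`` sweeps were available.
    """
    if len(measures) == 0:
        raise ValueError("no sweeps to average")
    if isinstance(measures[0], EPPMeasure):
        amps = np.array([m.epp_amplitude for m in measures], dtype=float)
        rmps = np.array([m.rmp_at_sweep for m in measures], dtype=float)
    else:
        amps = np.asarray(measures, dtype=float)
        if rmp is None:
            raise ValueError("rmp required with a plain amplitude array")
        rmps = np.broadcast_to(np.asarray(rmp, dtype=float), amps.shape)
    short = amps.size < n_sweeps
    amps, rmps = amps[:n_sweeps], rmps[:n_sweeps]
    nor = np.array([normalize_amplitude(a, r) for a, r in zip(amps, rmps)])
    mean_nor, sem_nor = _mean_sem(nor)
    return {
        "mean_raw": float(np.mean(amps)),
        "mean_nor": mean_nor,
        "sem_nor": sem_nor,
        "n": int(amps.size),
        "short_record": bool(short),
    }


def mean_mepp(
    events: list[DetectedEvent], rmp: float, n_events: int = MEPP_EVENTS
) -> dict[str, float | bool]:
    """Average amplitude and kinetics of the first ``n_events`` consecutive MEPPs.

    Giant MEPPs must be excluded by the caller; their presence violates the
    class precondition and raises.  Failed kinetic measurements (NaN) are
    skipped in the rise/decay averages.
    """
    if any(e.event_class != "MEPP" for e in events):
        raise ValueError("mean_mepp expects MEPP-class events only")
    if len(events) == 0:
        raise ValueError("fiber has no MEPPs")
    short = len(events) < n_events
    sel = events[:n_events]
    amps = np.array([e.amplitude for e in sel])
    rises = np.array([e.rise_time for e in sel])
    decays = np.array([e.decay_time for e in sel])
    amp_mean, amp_sem = _mean_sem(amps)
    nor = np.array([normalize_amplitude(a, rmp) for a in amps])
    nor_mean, nor_sem = _mean_sem(nor)
    rise_mean, rise_sem = _mean_sem(rises[~np.isnan(rises)]) if np.any(~np.isnan(rises)) else (float("nan"),) * 2
    decay_mean, decay_sem = _mean_sem(decays[~np.isnan(decays)]) if np.any(~np.isnan(decays)) else (float("nan"),) * 2
    return {
        "mean_amp": amp_mean,
        "sem_amp": amp_sem,
        "mean_nor": nor_mean,
        "sem_nor": nor_sem,
        "mean_rise": rise_mean,
        "sem_rise": rise_sem,
        "mean_decay": decay_mean,
        "sem_decay": decay_sem,
        "n": len(sel),
        "short_record": bool(short),
    }


def quantal_content(mean_epp_nor: float, mean_mepp_nor: float) -> float:
    """Quantal content m as normalized mean EPP over normalized mean MEPP."""
    if not (mean_mepp_nor > 0):
        raise ValueError("mean MEPP amplitude must be positive")
    if not (mean_epp_nor > 0):
        raise ValueError("mean EPP amplitude must be positive")
    return mean_epp_nor / mean_mepp_nor


def gmepp_mepp_ratio(gmepp_freq: float, mepp_freq: float) -> float:
    """Per-fiber GMEPP/MEPP frequency ratio; defined only for exhibiting fibers."""
    if gmepp_freq <= 0:
        raise ValueError("ratio undefined for fibers without GMEPPs")
    if mepp_freq <= 0:
        raise ValueError("mepp_freq must be positive")
    return gmepp_freq / mepp_freq


@dataclass
class FiberRecord:
    """Per-fiber summary row; NaN marks quantities that could not be computed."""

    fiber_id: str
    rmp: float
    accepted: bool
    mean_epp: float = float("nan")
    mean_epp_nor: float = float("nan")
    mean_mepp: float = float("nan")
    mean_mepp_nor: float = float("nan")
    quantal_content: float = float("nan")
    mepp_rise: float = float("nan")
    mepp_decay: float = float("nan")
    mepp_freq: float = float("nan")
    gmepp_freq: float = float("nan")
    has_gmepps: bool = False
    gmepp_mepp_ratio: float = float("nan")
    group_label: str | None = None
    flags: tuple[str, ...] = ()


def summarize_fiber(
    fiber_id: str,
    rmp: float,
    events: list[DetectedEvent] | None,
    epp_measures: list[EPPMeasure] | None,
    duration: float,
    group_label: str | None = None,
) -> FiberRecord:
    """Assemble the per-fiber summary from detected events and measured sweeps.

    A fiber with an RMP outside the acceptance window is returned with
    ``accepted=False`` and no downstream quantities.  Missing spontaneous or
    evoked data yield a partial record with the corresponding fields NaN and
    an explicit flag.
    """
    if not check_rmp(rmp):
        return FiberRecord(fiber_id, rmp, accepted=False, group_label=group_label,
                           flags=("rmp-rejected",))
    rec = FiberRecord(fiber_id, rmp, accepted=True, group_label=group_label)
    flags: list[str] = []

    if events is None:
        flags.append("no-spontaneous-data")
        mepps: list[DetectedEvent] = []
    else:
        mepps = [e for e in events if e.event_class == "MEPP"]
        gmepps = [e for e in events if e.event_class == "GMEPP"]
        rec.mepp_freq = len(mepps) / duration
        rec.gmepp_freq = len(gmepps) / duration
        rec.has_gmepps = len(gmepps) > 0
        if rec.has_gmepps:
            rec.gmepp_mepp_ratio = gmepp_mepp_ratio(rec.gmepp_freq, rec.mepp_freq)
        if mepps:
            mm = mean_mepp(mepps, rmp)
            rec.mean_mepp = mm["mean_amp"]
            rec.mean_mepp_nor = mm["mean_nor"]
            rec.mepp_rise = mm["mean_rise"]
            rec.mepp_decay = mm["mean_decay"]
            if mm["short_record"]:
                flags.append("short-mepp-record")
        else:
            flags.append("no-mepps")

    if epp_measures:
        me = mean_epp(epp_measures)
        rec.mean_epp = me["mean_raw"]
        rec.mean_epp_nor = me["mean_nor"]
        if me["short_record"]:
            flags.append("short-epp-record")
        if mepps and rec.mean_mepp_nor > 0 and rec.mean_epp_nor > 0:
            rec.quantal_content = quantal_content(rec.mean_epp_nor, rec.mean_mepp_nor)
    else:
        flags.append("no-evoked-data")

    rec.flags = tuple(flags)
    return rec


def records_to_frame(records: list[FiberRecord]) -> pd.DataFrame:
    """Fiber table: one row per FiberRecord (the unit of exchange downstream)."""
    rows = []
    for r in records:
        d = r.__dict__.copy()
        d["flags"] = ";".join(r.flags)
        rows.append(d)
    return pd.DataFrame(rows)
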