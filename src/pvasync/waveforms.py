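"""Ventilator waveform I/O, volume integration and breath segmentation.

Internal unit convention (fixed throughout the package): volume in L, flow
in L/s, pressure in cmH2O, time in s, stiffness/elastance in cmH2O/L,
resistance in cmH2O.s/L.  Flow given in L/min is converted on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .errors import DataError, FormatError, InfeasibleError

__all__ = [
    "WaveformRecord",
    "BreathCycle",
    "PVLoop",
    "read_waveform_csv",
    "write_waveform_csv",
    "integrate_flow_to_volume",
    "detect_breath_onsets",
    "refine_turning_index",
    "split_breaths",
    "build_pv_loop",
]

#: flow threshold (L/s) that a sustained rise must exceed to mark an
#: inspiration onset
ONSET_FLOW_THRESHOLD = 0.05
#: number of consecutive supra-threshold samples required
ONSET_SUSTAIN = 3
#: number of preceding quiet (non-positive) samples required
ONSET_QUIET = 5
#: tolerance for "non-positive" flow, absorbs sensor noise (L/s)
ONSET_QUIET_TOL = 0.02
#: a candidate onset is rejected while the running cycle volume still
#: exceeds this fraction of the cycle's running maximum (suppresses
#: patient-effort flow bumps and stacked second breaths)
ONSET_VOLUME_FRACTION = 0.3
#: minimum running-max volume (L) for the volume guard to be meaningful
ONSET_MIN_GUARD_VOLUME = 0.05


@dataclass
class WaveformRecord:
    """A continuous ventilator recording.

    Attributes
    ----------
    time : array of sample times (s), strictly increasing
    pressure : airway pressure (cmH2O)
    flow : airway flow (L/s)
    sample_rate : nominal sampling rate (Hz)
    meta : free-form metadata; recognised keys are ``peep`` (cmH2O),
        ``mode`` ("VC" or "PC") and ``patient_id``
    """

    time: np.ndarray
    pressure: np.ndarray
    flow: np.ndarray
    sample_rate: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        self.flow = np.asarray(self.flow, dtype=float)
        n = len(self.time)
        if len(self.pressure) != n or len(self.flow) != n:
            raise DataError("time, pressure and flow must have equal length")
        if n >= 2 and not np.all(np.diff(self.time) > 0):
            raise DataError("time must be strictly increasing")
        if not np.all(np.isfinite(self.pressure)):
            raise DataError("pressure contains non-finite values")
        if not self.sample_rate > 0:
            raise DataError("sample_rate must be positive")

    def __len__(self):
        return len(self.time)


@dataclass
class BreathCycle:
    """One breath: per-sample arrays with the volume re-zeroed at onset."""

    time: np.ndarray
    pressure: np.ndarray
    flow: np.ndarray
    volume: np.ndarray
    peep: float
    turning_index: int
    v_max_observed: float
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.time)

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.time)))

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])


@dataclass
class PVLoop:
    """Path-ordered pressure-volume loop of one breath.

    Points are kept in sampling order (inspiration then expiration); the
    path is *not* sorted by volume, so non-monotonic morphologies such as
    expiratory flow reversals and stacked breaths remain representable.
    """

    volume: np.ndarray
    pressure: np.ndarray
    insp_slice: slice
    exp_slice: slice

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.volume, self.pressure])


def _resolve_columns(df: pd.DataFrame, config: dict | None):
    cols = {"time": "time", "pressure": "pressure", "flow": "flow"}
    if config and "columns" in config:
        cols.update(config["columns"])
    for key, name in cols.items():
        if name not in df.columns:
            raise FormatError(f"required column '{name}' (for {key}) not found")
    return cols


def read_waveform_csv(path, config: dict | None = None) -> WaveformRecord:
    """Read a waveform CSV into a :class:`WaveformRecord`.

    ``config`` may carry ``columns`` (mapping of time/pressure/flow to CSV
    header names), ``units`` (``{"flow": "L/min"}`` triggers conversion to
    L/s) and ``meta`` (merged into the record's metadata, e.g. peep/mode).
    The sample rate is inferred from the median time step when absent.
    """
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise FormatError(f"cannot parse waveform CSV {path}: {exc}") from exc
    except OSError as exc:
        raise FormatError(f"cannot read waveform CSV {path}: {exc}") from exc
    if df.empty:
        raise FormatError(f"waveform CSV {path} contains no rows")
    cols = _resolve_columns(df, config)
    time = df[cols["time"]].to_numpy(dtype=float)
    pressure = df[cols["pressure"]].to_numpy(dtype=float)
    flow = df[cols["flow"]].to_numpy(dtype=float)
    units = (config or {}).get("units", {})
    if units.get("flow", "L/s") in ("L/min", "l/min", "lpm"):
        flow = flow / 60.0
    if len(time) >= 2:
        dts = np.diff(time)
        if not np.all(dts > 0):
            raise DataError("time column is not strictly increasing")
        sample_rate = float((config or {}).get("sample_rate") or 1.0 / np.median(dts))
    else:
        sample_rate = float((config or {}).get("sample_rate") or 1.0)
    meta = dict((config or {}).get("meta", {}))
    return WaveformRecord(time, pressure, flow, sample_rate, meta)


def write_waveform_csv(record: WaveformRecord, path) -> None:
    """Write a record to CSV with full float precision (round-trip exact)."""
    df = pd.DataFrame(
        {"time": record.time, "pressure": record.pressure, "flow": record.flow}
    )
    df.to_csv(path, index=False, float_format="%.17g")


def detect_breath_onsets(record: WaveformRecord) -> np.ndarray:
    """Indices of inspiration onsets.

    An onset is a rise of the (3-sample smoothed) flow above
    ``ONSET_FLOW_THRESHOLD`` sustained for ``ONSET_SUSTAIN`` samples, after
    ``ONSET_QUIET`` non-positive samples.  A candidate is additionally
    rejected while the integrated volume since the previous onset still
    exceeds ``ONSET_VOLUME_FRACTION`` of the running cycle maximum: patient
    inspiratory efforts during expiration (premature cycling, the stacked
    second breath of double triggering) produce positive flow at high lung
    volume and must not split the breath.
    """
    n = len(record)
    if n < ONSET_SUSTAIN + 1:
        return np.array([], dtype=int)
    kernel = np.ones(3) / 3.0
    smooth = np.convolve(record.flow, kernel, mode="same")
    above = smooth > ONSET_FLOW_THRESHOLD
    sustained = above.copy()
    for k in range(1, ONSET_SUSTAIN):
        sustained[: n - k] &= above[k:]
        sustained[n - k :] = False
    rising = sustained & ~np.roll(above, 1)
    rising[0] = sustained[0]
    candidates = np.flatnonzero(rising)

    v_raw = cumulative_trapezoid(record.flow, record.time, initial=0.0)
    onsets: list[int] = []
    for i in candidates:
        lo = max(0, i - ONSET_QUIET)
        if i > 0 and np.any(smooth[lo:i] > ONSET_QUIET_TOL):
            continue
        if onsets:
            o = onsets[-1]
            run_max = np.max(v_raw[o : i + 1]) - v_raw[o]
            rel = v_raw[i] - v_raw[o]
            if run_max > ONSET_MIN_GUARD_VOLUME and rel > ONSET_VOLUME_FRACTION * run_max:
                continue
        onsets.append(int(i))
    return np.asarray(onsets, dtype=int)


def integrate_flow_to_volume(record: WaveformRecord) -> np.ndarray:
    """Cumulative trapezoidal volume (L), re-zeroed at every breath onset.

    Re-zeroing per breath removes integration drift so each PV loop starts
    at (0, PEEP).  If no breaths are detectable the raw integral is
    returned with a warning (an all-zero flow yields all-zero volume,
    which is valid).
    """
    v = cumulative_trapezoid(record.flow, record.time, initial=0.0)
    onsets = detect_breath_onsets(record)
    if len(onsets) == 0:
        if np.ptp(v) > 1e-9:
            warnings.warn("no breath onsets detected; volume not re-zeroed")
        return v
    out = v.copy()
    bounds = list(onsets) + [len(v)]
    out[: onsets[0]] -= v[0]
    for a, b in zip(bounds[:-1], bounds[1:]):
        out[a:b] = v[a:b] - v[a]
    return out


def refine_turning_index(volume: np.ndarray, flow: np.ndarray) -> int:
    """Turning index (volume maximum) of one breath.

    The raw argmax of the integrated volume can wander a few samples on
    the flat top under flow noise; the onset of sustained expiratory flow
    (two consecutive samples below -0.1 L/s) marks the turn crisply.  The
    flow-based index is used when it agrees with the argmax to within a
    few samples, so stacked breaths (whose first expiratory flow precedes
    the global volume maximum) keep their argmax turning point.
    """
    i0 = int(np.argmax(volume))
    n = len(volume)
    lo = max(1, i0 - 8)
    for i in range(lo, min(n - 1, i0 + 9)):
        if flow[i] < -0.1 and flow[min(i + 1, n - 1)] < -0.1:
            return i - 1
    return i0


def split_breaths(record: WaveformRecord) -> list[BreathCycle]:
    """Split a record into :class:`BreathCycle` objects at inspiration onsets.

    Samples before the first onset are discarded (with a warning); the
    last cycle runs to the end of the record.  Each cycle's volume is
    re-zeroed at its onset and the turning index marks the global volume
    maximum (earliest sample on ties).
    """
    onsets = detect_breath_onsets(record)
    if len(onsets) == 0:
        warnings.warn("no inspiration onsets found; returning no breaths")
        return []
    if onsets[0] > 0:
        warnings.warn(
            f"{onsets[0]} samples before the first onset are not assigned to a breath"
        )
    v_raw = cumulative_trapezoid(record.flow, record.time, initial=0.0)
    cycles = []
    bounds = list(onsets) + [len(record)]
    for idx, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
        vol = v_raw[a:b] - v_raw[a]
        pressure = record.pressure[a:b]
        peep = record.meta.get("peep")
        if peep is None:
            # elastic pressure at near-zero volume approximates PEEP
            peep = float(np.median(np.concatenate([pressure[:2], pressure[-3:]])))
        turning = refine_turning_index(vol, record.flow[a:b])
        cycles.append(
            BreathCycle(
                time=record.time[a:b].copy(),
                pressure=pressure.copy(),
                flow=record.flow[a:b].copy(),
                volume=vol,
                peep=float(peep),
                turning_index=turning,
                v_max_observed=float(vol[turning]),
                meta={**record.meta, "breath_index": idx},
            )
        )
    return cycles


def build_pv_loop(cycle: BreathCycle, pressure: np.ndarray | None = None) -> PVLoop:
    """Construct the path-ordered PV loop of a breath.

    ``pressure`` may override the cycle's measured pressure (used by the
    pipeline to segment the resistance-corrected elastic pressure).  A
    turning index on the cycle boundary means the breath never completed
    both phases, and no loop (hence no reconstruction) is possible.
    """
    ti = cycle.turning_index
    if ti <= 0 or ti >= cycle.n - 1:
        raise InfeasibleError(
            "turning point lies on the cycle boundary; breath has no complete "
            "inspiration/expiration split",
            breath_id=cycle.meta.get("breath_index"),
        )
    p = cycle.pressure if pressure is None else np.asarray(pressure, dtype=float)
    if len(p) != cycle.n:
        raise DataError("pressure override must match the cycle length")
    return PVLoop(
        volume=cycle.volume,
        pressure=p,
        insp_slice=slice(0, ti + 1),
        exp_slice=slice(ti, cycle.n),
    )
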