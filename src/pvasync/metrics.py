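"""Asynchrony magnitude and reconstruction-quality metrics.

The enclosed area of a PV loop is the work done by the ventilator in the
airway over one breath (energy dissipation).  Patient effort works against
it, so the area deficit of the measured loop relative to the reconstructed
unaffected loop quantifies asynchrony magnitude:

    E_asyn = 100 * (A_ventilated - A_asyn) / A_ventilated   [%]

Reconstruction accuracy is the normalised RMS pressure error

    RMS = 100 * sqrt(mean((P - P_hat)^2)) / mean(P)         [%].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, MetricError

__all__ = [
    "AsynchronyMetrics",
    "CohortSummary",
    "loop_area",
    "compute_easyn",
    "compute_rms",
    "moving_average_easyn",
    "summarize_cohort",
]

#: E_asyn bin edges (%): {0}, (0,10], (10,50], (50,100]
EASYN_BIN_EDGES = (0.0, 10.0, 50.0, 100.0)


@dataclass
class AsynchronyMetrics:
    """Per-breath areas, E_asyn and (optional) reconstruction RMS."""

    a_ventilated: float
    a_asyn: float
    e_asyn: float
    rms_error: float | None = None
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "a_ventilated": self.a_ventilated,
            "a_asyn": self.a_asyn,
            "e_asyn": self.e_asyn,
            "rms_error": self.rms_error,
            "flags": list(self.flags),
        }


@dataclass
class CohortSummary:
    """E_asyn distribution bins and the RMS-error empirical CDF support."""

    n_scored: int
    e_asyn_bins: dict
    rms_cdf: np.ndarray
    n_infeasible: int = 0

    def to_dict(self) -> dict:
        return {
            "n_scored": self.n_scored,
            "e_asyn_bins": dict(self.e_asyn_bins),
            "rms_cdf": list(map(float, self.rms_cdf)),
            "n_infeasible": self.n_infeasible,
        }


def loop_area(volume, pressure=None, rule: str = "net") -> float:
    """Enclosed area of a closed PV path (cmH2O.L).

    Accepts either an (n, 2) array of (V, P) points, a PVLoop, or separate
    volume/pressure arrays.  A closure segment is implicit between the last
    and first point.  ``rule="net"`` (default) is the |net signed shoelace
    area|: sub-loops of a self-intersecting path (stacked breaths)
    traversed in opposite senses cancel.  ``rule="split"`` sums the
    unsigned areas of all sub-loops instead (sensitivity alternative;
    needs shapely).
    """
    if rule not in ("net", "split"):
        raise ValueError("rule must be 'net' or 'split'")
    if pressure is None:
        if hasattr(volume, "volume"):  # PVLoop
            v = np.asarray(volume.volume, dtype=float)
            p = np.asarray(volume.pressure, dtype=float)
        else:
            pts = np.asarray(volume, dtype=float)
            v, p = pts[:, 0], pts[:, 1]
    else:
        v = np.asarray(volume, dtype=float)
        p = np.asarray(pressure, dtype=float)
    if len(v) < 3:
        raise DataError("a loop needs at least 3 points")
    if rule == "split":
        try:
            from shapely.geometry import LineString
            from shapely.ops import polygonize, unary_union
        except ImportError as exc:  # pragma: no cover
            raise ImportError("rule='split' requires shapely") from exc
        pts = np.column_stack([v, p])
        ring = LineString(np.vstack([pts, pts[:1]]))
        return float(sum(poly.area for poly in polygonize(unary_union(ring))))
    cross = v * np.roll(p, -1) - np.roll(v, -1) * p
    return float(abs(0.5 * np.sum(cross)))


def compute_easyn(a_ventilated: float, a_asyn: float) -> tuple[float, list]:
    """Asynchrony magnitude (%) with clamping flags.

    Negative values (measured loop larger than the reconstruction) are
    clamped to 0 and flagged; an unaffected breath scores exactly 0.
    """
    if not a_ventilated > 0:
        raise MetricError("E_asyn undefined: ventilated loop area is not positive")
    e = 100.0 * (a_ventilated - a_asyn) / a_ventilated
    flags = []
    if e < 0:
        flags.append("clamped_negative")
        e = 0.0
    return float(e), flags


def compute_rms(p_observed, p_reconstructed) -> float:
    """Normalised RMS pressure error (%), Eq.-style two-series comparison."""
    p = np.asarray(p_observed, dtype=float)
    q = np.asarray(p_reconstructed, dtype=float)
    if p.shape != q.shape:
        raise DataError(
            f"series lengths differ ({p.shape} vs {q.shape}); resample first"
        )
    if p.size < 1:
        raise DataError("empty pressure series")
    denom = float(np.mean(p))
    if abs(denom) < 1e-12:
        raise MetricError("RMS undefined: observed pressure has zero mean")
    return float(100.0 * np.sqrt(np.mean((p - q) ** 2)) / denom)


def moving_average_easyn(series, window: int) -> tuple[np.ndarray, int]:
    """Trailing moving average of a per-breath E_asyn series.

    The head of the series averages over however many breaths are
    available.  Non-finite entries (infeasible breaths) are skipped and
    counted; a window position with no finite entries yields NaN.
    Returns (smoothed, n_skipped).
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        return x.copy(), 0
    if not 1 <= window <= x.size:
        raise ValueError("window must be in [1, len(series)]")
    ok = np.isfinite(x)
    out = np.empty_like(x)
    for i in range(x.size):
        lo = max(0, i - window + 1)
        w = x[lo : i + 1][ok[lo : i + 1]]
        out[i] = np.mean(w) if w.size else np.nan
    return out, int(np.sum(~ok))


def summarize_cohort(metrics) -> CohortSummary:
    """Bin per-breath E_asyn values and collect the RMS CDF support.

    Bins: {0}, (0,10], (10,50], (50,100] percent.  Breaths flagged
    infeasible (e_asyn None/NaN) are counted separately.
    """
    e_vals, rms_vals, n_inf = [], [], 0
    for m in metrics:
        e = getattr(m, "e_asyn", m if isinstance(m, (int, float)) else None)
        if e is None or not np.isfinite(e):
            n_inf += 1
            continue
        e_vals.append(float(e))
        r = getattr(m, "rms_error", None)
        if r is not None and np.isfinite(r):
            rms_vals.append(float(r))
    if not e_vals:
        raise MetricError("no scored breaths to summarise")
    e = np.asarray(e_vals)
    bins = {
        "0": int(np.sum(e <= 0.0)),
        "(0,10]": int(np.sum((e > 0.0) & (e <= 10.0))),
        "(10,50]": int(np.sum((e > 10.0) & (e <= 50.0))),
        "(50,100]": int(np.sum((e > 50.0) & (e <= 100.0))),
    }
    return CohortSummary(
        n_scored=len(e_vals),
        e_asyn_bins=bins,
        rms_cdf=np.sort(np.asarray(rms_vals)),
        n_infeasible=n_inf,
    )
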