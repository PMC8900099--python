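"""Hysteresis loop analysis (HLA).

Each half of a PV loop is approximated by piecewise-linear segments fitted
*along the sampled path* (segments are contiguous index ranges, so
non-monotonic-volume morphologies remain representable).  Breakpoint search
is an exact dynamic program over sample indices; the segment count is
selected by a Bayesian information criterion with a residual-variance floor
at the pressure-sensor noise scale; a final continuous refinement releases
the junction coordinates to sub-sample precision.

The slopes of the fitted segments are the local stiffnesses k (cmH2O/L)
and the junction volumes are the breakpoints (Vm1, Vm2) of the hysteresis
loop; the volume at the loop's turning point is Vmax.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import UnsegmentableError
from .waveforms import PVLoop

__all__ = [
    "Segment",
    "HalfSegmentation",
    "HLASegmentation",
    "fit_segments",
    "fit_three_segments_windowed",
    "select_segment_count",
    "segment_half",
    "segment_loop",
    "extract_breakpoints",
]

#: default minimum number of samples per segment.  Kept small deliberately:
#: the steep early-expiration limb (k3) lasts only a few samples at 50 Hz
#: under realistic expiratory time constants.
MIN_SPAN = 3
#: default residual floor (cmH2O): model selection does not chase structure
#: below the pressure-sensor resolution scale.
SIGMA_FLOOR = 0.15
#: half-cycles whose pressure dynamic range is below this (cmH2O) are
#: declared unsegmentable.
MIN_DYNAMIC_RANGE = 1.0
MAX_SEGMENTS = 6


@dataclass
class Segment:
    """One linear piece of a half-cycle, in path order.

    ``slope_k`` is dP/dV along the path (cmH2O/L), ``intercept`` the
    pressure of the extended line at V = 0, ``v_start``/``v_end`` the path
    endpoint volumes and ``index_range`` the (inclusive) sample range.
    """

    slope_k: float
    intercept: float
    v_start: float
    v_end: float
    index_range: tuple[int, int]
    rms_resid: float

    def pressure_at(self, v: float) -> float:
        return self.intercept + self.slope_k * v

    def to_dict(self) -> dict:
        return {
            "slope_k": self.slope_k,
            "intercept": self.intercept,
            "v_start": self.v_start,
            "v_end": self.v_end,
            "index_range": list(self.index_range),
            "rms_resid": self.rms_resid,
        }


@dataclass
class HalfSegmentation:
    """Selected piecewise-linear model of one half-cycle."""

    segments: list
    n_segments: int
    rss: float
    bic: float

    @property
    def junction_volumes(self) -> list:
        return [s.v_end for s in self.segments[:-1]]


@dataclass
class HLASegmentation:
    """Joint segmentation of a PV loop with extracted breakpoints.

    ``vm1``/``vm2`` are only set when the corresponding half has exactly
    two segments (the unambiguous ventilated pattern); for asynchronous
    patterns the breakpoints are recovered by the classification step.
    Two morphology measures travel with the segmentation as evidence for
    classification: ``insp_volume_reversal``, the largest volume drawdown
    within the inspiratory phase (L, volume-stacking evidence), and
    ``exp_volume_rebound``, the largest volume rise after a running
    minimum within the expiratory phase (L, evidence of a patient-driven
    positive-flow episode during deflation).
    """

    insp_segments: list
    exp_segments: list
    vm1: float | None
    vm2: float | None
    vmax: float
    fit_score: float
    insp_volume_reversal: float = 0.0
    exp_volume_rebound: float = 0.0
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "insp_segments": [s.to_dict() for s in self.insp_segments],
            "exp_segments": [s.to_dict() for s in self.exp_segments],
            "vm1": self.vm1,
            "vm2": self.vm2,
            "vmax": self.vmax,
            "fit_score": self.fit_score,
            "insp_volume_reversal": self.insp_volume_reversal,
            "exp_volume_rebound": self.exp_volume_rebound,
        }


def _piece_costs(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """SSE of a least-squares line (P on V) for every index range [i, j].

    Returned as an (n, n) matrix with +inf below the diagonal.  Computed
    from cumulative sums, O(n^2) total.
    """
    n = len(x)
    cx = np.concatenate([[0.0], np.cumsum(x)])
    cy = np.concatenate([[0.0], np.cumsum(y)])
    cxx = np.concatenate([[0.0], np.cumsum(x * x)])
    cxy = np.concatenate([[0.0], np.cumsum(x * y)])
    cyy = np.concatenate([[0.0], np.cumsum(y * y)])
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    m = (j - i + 1).astype(float)
    valid = m >= 1
    m = np.where(valid, m, 1.0)
    sx = cx[j + 1] - cx[i]
    sy = cy[j + 1] - cy[i]
    sxx = cxx[j + 1] - cxx[i] - sx * sx / m
    sxy = cxy[j + 1] - cxy[i] - sx * sy / m
    syy = cyy[j + 1] - cyy[i] - sy * sy / m
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        sse = syy - np.where(sxx > 1e-14, sxy * sxy / np.maximum(sxx, 1e-300), 0.0)
    sse = np.clip(sse, 0.0, None)
    return np.where(valid, sse, np.inf)


def _line_params(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope and intercept of y on x (slope 0 when x is flat)."""
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    if sxx < 1e-14:
        return 0.0, float(ym)
    slope = float(np.sum((x - xm) * (y - ym)) / sxx)
    return slope, float(ym - slope * xm)


def _dp_segment(cost: np.ndarray, max_k: int, min_span: int):
    """Exact DP: best piece boundaries for every piece count 1..max_k.

    Returns (rss_by_k, boundaries_by_k) where boundaries are lists of
    (start, end) inclusive index ranges tiling [0, n-1].
    """
    n = cost.shape[0]
    INF = np.inf
    E = np.full((max_k + 1, n), INF)
    back = np.full((max_k + 1, n), -1, dtype=int)
    E[1, min_span - 1 :] = cost[0, min_span - 1 :]
    for k in range(2, max_k + 1):
        jmin = k * min_span - 1
        for j in range(jmin, n):
            i_lo = (k - 1) * min_span
            i_hi = j - min_span + 1  # piece start candidates, inclusive
            if i_hi < i_lo:
                continue
            prev = E[k - 1, i_lo - 1 : i_hi]
            cand = prev + cost[i_lo : i_hi + 1, j]
            a = int(np.argmin(cand))
            if np.isfinite(cand[a]):
                E[k, j] = cand[a]
                back[k, j] = i_lo + a
    rss = {}
    bounds = {}
    for k in range(1, max_k + 1):
        if not np.isfinite(E[k, n - 1]):
            continue
        rss[k] = float(E[k, n - 1])
        pieces = []
        j = n - 1
        kk = k
        while kk > 1:
            i = back[kk, j]
            pieces.append((i, j))
            j = i - 1
            kk -= 1
        pieces.append((0, j))
        bounds[k] = pieces[::-1]
    return rss, bounds


def _segments_from_bounds(x, y, bounds) -> list:
    segs = []
    for s, e in bounds:
        xs, ys = x[s : e + 1], y[s : e + 1]
        slope, intercept = _line_params(xs, ys)
        resid = ys - (intercept + slope * xs)
        segs.append(
            Segment(
                slope_k=slope,
                intercept=intercept,
                v_start=float(xs[0]),
                v_end=float(xs[-1]),
                index_range=(int(s), int(e)),
                rms_resid=float(np.sqrt(np.mean(resid**2))),
            )
        )
    return segs


def fit_segments(
    volume: np.ndarray,
    pressure: np.ndarray,
    n_segments: int,
    min_span: int = MIN_SPAN,
) -> list:
    """Fit ``n_segments`` path-ordered linear pieces to one half-cycle.

    Breakpoints are sample indices chosen by exact dynamic programming to
    minimise the total squared pressure residual of independent per-piece
    line fits.  Raises :class:`UnsegmentableError` when the half-cycle is
    too short.
    """
    x = np.asarray(volume, dtype=float)
    y = np.asarray(pressure, dtype=float)
    if not 1 <= n_segments <= MAX_SEGMENTS:
        raise ValueError(f"n_segments must be in 1..{MAX_SEGMENTS}")
    if len(x) < n_segments * min_span:
        raise UnsegmentableError(
            f"{len(x)} samples cannot support {n_segments} segments "
            f"of span >= {min_span}"
        )
    cost = _piece_costs(x, y)
    rss, bounds = _dp_segment(cost, n_segments, min_span)
    if n_segments not in bounds:
        raise UnsegmentableError(f"no feasible {n_segments}-segment tiling")
    return _segments_from_bounds(x, y, bounds[n_segments])


def select_segment_count(
    volume: np.ndarray,
    pressure: np.ndarray,
    max_segments: int = MAX_SEGMENTS,
    min_span: int = MIN_SPAN,
    sigma_floor: float = SIGMA_FLOOR,
) -> HalfSegmentation:
    """Choose the segment count of a half-cycle by BIC.

    BIC = n ln((RSS + n sigma_floor^2)/n) + p ln(n) with p = 3k - 1 free
    parameters (slope, intercept and breakpoint per piece).  The variance
    floor prevents zero-noise data from being over-segmented below the
    sensor resolution; ties break toward fewer segments.
    """
    x = np.asarray(volume, dtype=float)
    y = np.asarray(pressure, dtype=float)
    n = len(x)
    if n < min_span or np.ptp(y) < MIN_DYNAMIC_RANGE:
        raise UnsegmentableError(
            "half-cycle has too few samples or too little pressure range"
        )
    cost = _piece_costs(x, y)
    kmax = min(max_segments, n // min_span)
    rss, bounds = _dp_segment(cost, kmax, min_span)
    best_k, best_bic = None, np.inf
    for k in sorted(rss):
        p = 3 * k - 1
        bic = n * np.log((rss[k] + n * sigma_floor**2) / n) + p * np.log(n)
        if bic < best_bic - 1e-12:
            best_k, best_bic = k, bic
    segs = _segments_from_bounds(x, y, bounds[best_k])
    return HalfSegmentation(
        segments=segs, n_segments=best_k, rss=rss[best_k], bic=float(best_bic)
    )


def _refine_half(x: np.ndarray, y: np.ndarray, half: HalfSegmentation) -> HalfSegmentation:
    """Continuous piecewise-linear refinement with free junction coordinates.

    The DP places breakpoints at sample indices; the true junction usually
    lies between two samples.  This refit models the half-cycle as a
    connected polyline through nodes (v_j, p_j) — junction volumes move
    freely between their boundary samples — and solves the small nonlinear
    least-squares problem.  On noise-free piecewise-linear data it recovers
    slopes and junctions exactly; with noise it conditions the short steep
    segments (k3) on the junction shared with their long neighbours.
    """
    K = half.n_segments
    if K == 1:
        return half
    bounds = [s.index_range for s in half.segments]
    ends = [e for (_, e) in bounds[:-1]]
    vA = np.array([x[e] for e in ends])
    vB = np.array([x[e + 1] for e in ends])

    def nodes_from(params):
        t = params[: K - 1]
        p = params[K - 1 :]
        v = np.empty(K + 1)
        v[0], v[-1] = x[0], x[-1]
        v[1:-1] = vA * (1 - t) + vB * t
        return v, p

    def residuals(params):
        v, p = nodes_from(params)
        out = np.empty_like(y)
        for j, (s, e) in enumerate(bounds):
            dv = v[j + 1] - v[j]
            seg_x = x[s : e + 1]
            if abs(dv) < 1e-12:
                pred = 0.5 * (p[j] + p[j + 1])
            else:
                pred = p[j] + (p[j + 1] - p[j]) * (seg_x - v[j]) / dv
            out[s : e + 1] = pred - y[s : e + 1]
        return out

    t0 = np.full(K - 1, 0.5)
    p0 = np.empty(K + 1)
    p0[0] = half.segments[0].pressure_at(x[0])
    p0[-1] = half.segments[-1].pressure_at(x[-1])
    for j in range(K - 1):
        vj = 0.5 * (vA[j] + vB[j])
        p0[j + 1] = 0.5 * (
            half.segments[j].pressure_at(vj) + half.segments[j + 1].pressure_at(vj)
        )
    x0 = np.concatenate([t0, p0])
    lb = np.concatenate([np.zeros(K - 1), np.full(K + 1, -np.inf)])
    ub = np.concatenate([np.ones(K - 1), np.full(K + 1, np.inf)])
    try:
        sol = least_squares(residuals, x0, bounds=(lb, ub), xtol=1e-14, ftol=1e-14)
    except Exception:
        return half
    if not np.all(np.isfinite(sol.x)):
        return half
    v, p = nodes_from(sol.x)
    segs = []
    for j, (s, e) in enumerate(bounds):
        dv = v[j + 1] - v[j]
        slope = (p[j + 1] - p[j]) / dv if abs(dv) > 1e-12 else 0.0
        intercept = p[j] - slope * v[j]
        resid = y[s : e + 1] - (intercept + slope * x[s : e + 1])
        segs.append(
            Segment(
                slope_k=float(slope),
                intercept=float(intercept),
                v_start=float(v[j]),
                v_end=float(v[j + 1]),
                index_range=(int(s), int(e)),
                rms_resid=float(np.sqrt(np.mean(resid**2))),
            )
        )
    rss = float(np.sum(sol.fun**2))
    if rss > half.rss + 1e-9:  # refinement must not degrade the fit
        return half
    return HalfSegmentation(segments=segs, n_segments=K, rss=rss, bic=half.bic)


def fit_three_segments_windowed(
    volume: np.ndarray,
    pressure: np.ndarray,
    window: tuple[int, int],
    min_span: int = MIN_SPAN,
    max_tail: int = 25,
    refine: bool = True,
) -> HalfSegmentation:
    """Three path-ordered pieces whose middle piece brackets ``window``.

    Used for the premature-cycling expiration: the patient-effort episode
    (located by its positive-flow volume rebound, ``window`` = first/last
    affected sample) must fall inside the middle piece, and the path
    rejoins the relaxation limb within ``max_tail`` samples of the episode
    end.  An unconstrained fit can otherwise spend its third piece on the
    low-information end-expiratory tail, where volume barely moves.
    """
    x = np.asarray(volume, dtype=float)
    y = np.asarray(pressure, dtype=float)
    n = len(x)
    ja, jb = window
    if n < 3 * min_span:
        raise UnsegmentableError("half-cycle too short for 3 segments")
    cost = _piece_costs(x, y)
    b1_hi = max(min_span - 1, min(ja - 1, n - 2 * min_span - 1))
    b2_lo = max(jb, b1_hi + min_span)
    b2_hi = min(jb + max_tail, n - 1 - min_span)
    best = (np.inf, None)
    for b1 in range(min_span - 1, b1_hi + 1):
        for b2 in range(max(b2_lo, b1 + min_span), b2_hi + 1):
            c = cost[0, b1] + cost[b1 + 1, b2] + cost[b2 + 1, n - 1]
            if c < best[0]:
                best = (c, (b1, b2))
    if best[1] is None:
        raise UnsegmentableError("no feasible windowed 3-segment tiling")
    b1, b2 = best[1]
    bounds = [(0, b1), (b1 + 1, b2), (b2 + 1, n - 1)]
    half = HalfSegmentation(
        segments=_segments_from_bounds(x, y, bounds), n_segments=3,
        rss=float(best[0]), bic=np.nan,
    )
    if refine:
        half = _refine_half(x, y, half)
    return half


def segment_half(
    volume: np.ndarray,
    pressure: np.ndarray,
    n_segments: int | None = None,
    max_segments: int = MAX_SEGMENTS,
    min_span: int = MIN_SPAN,
    sigma_floor: float = SIGMA_FLOOR,
    refine: bool = True,
) -> HalfSegmentation:
    """Segment one half-cycle; with ``n_segments`` the count is imposed
    instead of BIC-selected (used when the asynchrony type dictates the
    pattern, e.g. a premature-cycling expiration refit with 3 pieces)."""
    x = np.asarray(volume, dtype=float)
    y = np.asarray(pressure, dtype=float)
    if n_segments is None:
        half = select_segment_count(x, y, max_segments, min_span, sigma_floor)
    else:
        segs = fit_segments(x, y, n_segments, min_span)
        rss = float(sum(s.rms_resid**2 * (s.index_range[1] - s.index_range[0] + 1)
                        for s in segs))
        half = HalfSegmentation(segments=segs, n_segments=n_segments,
                                rss=rss, bic=np.nan)
    if refine:
        half = _refine_half(x, y, half)
    return half


def segment_loop(
    loop: PVLoop,
    max_segments: int = MAX_SEGMENTS,
    min_span: int = MIN_SPAN,
    sigma_floor: float = SIGMA_FLOOR,
    refine: bool = True,
) -> HLASegmentation:
    """Run HLA on both halves of a PV loop and extract breakpoints.

    ``vm1`` (``vm2``) is the junction volume of a 2-segment inspiration
    (expiration); with any other count the breakpoints belong to an
    asynchronous pattern and are resolved by the classification step.
    """
    vi = loop.volume[loop.insp_slice]
    pi = loop.pressure[loop.insp_slice]
    ve = loop.volume[loop.exp_slice]
    pe = loop.pressure[loop.exp_slice]
    insp = select_segment_count(vi, pi, max_segments, min_span, sigma_floor)
    exp = select_segment_count(ve, pe, max_segments, min_span, sigma_floor)
    if refine:
        insp = _refine_half(vi, pi, insp)
        exp = _refine_half(ve, pe, exp)
    vmax = float(np.max(loop.volume))
    vm1 = insp.junction_volumes[0] if insp.n_segments == 2 else None
    vm2 = exp.junction_volumes[0] if exp.n_segments == 2 else None
    running_max = np.maximum.accumulate(vi)
    reversal = float(np.max(running_max - vi)) if len(vi) else 0.0
    running_min = np.minimum.accumulate(ve)
    rebound = float(np.max(ve - running_min)) if len(ve) else 0.0
    return HLASegmentation(
        insp_segments=insp.segments,
        exp_segments=exp.segments,
        vm1=vm1,
        vm2=vm2,
        vmax=vmax,
        fit_score=insp.bic + exp.bic,
        insp_volume_reversal=reversal,
        exp_volume_rebound=rebound,
    )


def extract_breakpoints(seg: HLASegmentation):
    """Return (vm1, vm2, vmax); absent junctions are None, never invented."""
    return seg.vm1, seg.vm2, seg.vmax
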