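"""Asynchrony classification and ventilated-parameter mapping.

Step 1 of the reconstruction method types each breath from its HLA
segment pattern: a 2+2-segment loop is an unaffected ventilated breath;
a 4-segment inspiration whose stiffness turns negative and back positive
is reverse triggering; two inspiratory and three expiratory segments is
premature cycling; extra inspiratory-phase segments together with volume
stacking (the volume partially falls and rises again beyond the first
maximum) is double triggering.

Step 2 maps the asynchronous stiffnesses k_a1.. back to the four
ventilated stiffnesses k1..k4 and breakpoints Vm1, Vm2, Vmax, using the
sub-segments of the loop the effort left untouched and, where a breakpoint
is hidden by the effort, the intersection of the extended neighbouring
segment lines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from scipy.optimize import least_squares

from .errors import InfeasibleError
from .hla import HLASegmentation, Segment

__all__ = [
    "LABELS",
    "AsynchronyCall",
    "VentilatedParameters",
    "classify_asynchrony",
    "map_parameters",
    "refine_ventilated_parameters",
    "line_intersection",
]

LABELS = (
    "none",
    "reverse_triggering",
    "premature_cycling",
    "double_triggering",
    "unclassifiable",
)

#: slopes with |k| below this (cmH2O/L) are sign-ambiguous under noise
SLOPE_SIGN_TOL = 1.0
#: volume reversal within the inspiratory phase larger than this fraction
#: of Vmax counts as volume stacking
STACKING_FRACTION = 0.05
#: expiratory volume rebound (L) above this marks a patient-driven
#: positive-flow episode during deflation (premature-cycling evidence)
EXP_REBOUND_THRESHOLD = 0.02


@dataclass
class AsynchronyCall:
    """Classification of one breath with its audit evidence."""

    label: str
    evidence: dict = field(default_factory=dict)
    ka: list = field(default_factory=list)
    vmax2: float | None = None

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "evidence": self.evidence,
            "ka": list(self.ka),
            "vmax2": self.vmax2,
        }


@dataclass
class VentilatedParameters:
    """Stiffnesses and breakpoints of the unaffected ventilated loop."""

    k1: float
    k2: float
    k3: float
    k4: float
    vm1: float
    vm2: float
    vmax: float
    peep: float

    def validate(self, breath_id=None) -> "VentilatedParameters":
        checks = {
            "k1 > 0": self.k1 > 0,
            "k2 > 0": self.k2 > 0,
            "k3 > 0": self.k3 > 0,
            "k4 > 0": self.k4 > 0,
            "0 < vm1 < vmax": 0 < self.vm1 < self.vmax,
            "0 < vm2 < vmax": 0 < self.vm2 < self.vmax,
        }
        bad = [name for name, ok in checks.items() if not ok]
        if bad:
            raise InfeasibleError(
                f"mapped ventilated parameters violate {bad}", breath_id=breath_id
            )
        return self

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("k1", "k2", "k3", "k4", "vm1", "vm2", "vmax", "peep")}


def _sign_pattern(slopes) -> list:
    """Collapsed slope-sign sequence with a tolerance band for ~flat pieces."""
    signs = []
    for k in slopes:
        s = 0 if abs(k) < SLOPE_SIGN_TOL else (1 if k > 0 else -1)
        if not signs or signs[-1] != s:
            signs.append(s)
    return signs


def _has_dip(pattern) -> bool:
    """True when the sign sequence contains a +, -, + subsequence."""
    nz = [s for s in pattern if s != 0]
    for i in range(len(nz) - 2):
        if nz[i] > 0 and nz[i + 1] < 0 and nz[i + 2] > 0:
            return True
    return False


def classify_asynchrony(seg: HLASegmentation) -> AsynchronyCall:
    """Step 1: type the breath from its segment pattern.

    The count rules are augmented with the morphological signature that
    defines each type: reverse triggering never moves volume off the
    ventilator trajectory (no stacking); double triggering is, by
    definition, a second breath in the first phase of the loop — an
    inspiratory-phase volume reversal followed by a higher maximum; and
    premature cycling produces a positive-flow episode (volume rebound)
    during deflation.  This keeps the types separable even when a smooth
    effort shape is tessellated into one segment more or fewer than the
    nominal count.  ``unclassifiable`` is a value, not an error.
    """
    ni = len(seg.insp_segments)
    ne = len(seg.exp_segments)
    insp_slopes = [s.slope_k for s in seg.insp_segments]
    exp_slopes = [s.slope_k for s in seg.exp_segments]
    pattern = _sign_pattern(insp_slopes)
    stacked = seg.insp_volume_reversal > STACKING_FRACTION * seg.vmax
    rebound = seg.exp_volume_rebound > EXP_REBOUND_THRESHOLD
    evidence = {
        "n_insp_segments": ni,
        "n_exp_segments": ne,
        "insp_slopes": insp_slopes,
        "exp_slopes": exp_slopes,
        "insp_sign_pattern": pattern,
        "volume_stacking": bool(stacked),
        "insp_volume_reversal": seg.insp_volume_reversal,
        "exp_volume_rebound": seg.exp_volume_rebound,
    }
    ka = insp_slopes + exp_slopes
    if stacked:
        if ni >= 4:
            return AsynchronyCall("double_triggering", evidence, ka, vmax2=seg.vmax)
        return AsynchronyCall("unclassifiable", evidence, ka)
    if rebound and ni <= 2:
        return AsynchronyCall("premature_cycling", evidence, ka)
    if ni == 2 and ne == 3:
        return AsynchronyCall("premature_cycling", evidence, ka)
    if ni >= 3 and _has_dip(pattern):
        return AsynchronyCall("reverse_triggering", evidence, ka)
    if ni <= 2 and ne <= 2 and not rebound:
        return AsynchronyCall("none", evidence, ka)
    return AsynchronyCall("unclassifiable", evidence, ka)


def line_intersection(seg_a: Segment, seg_b: Segment) -> tuple[float, float]:
    """(V, P) where the extended lines of two segments cross.

    Raises :class:`InfeasibleError` for (near-)parallel lines — the
    breakpoint hidden behind the effort cannot be recovered then.
    """
    dk = seg_a.slope_k - seg_b.slope_k
    scale = max(1.0, abs(seg_a.slope_k), abs(seg_b.slope_k))
    if abs(dk) < 1e-9 * scale:
        raise InfeasibleError("segments are parallel; intersection undefined")
    v = (seg_b.intercept - seg_a.intercept) / dk
    return float(v), float(seg_a.pressure_at(v))


def _junction(segs, i) -> float:
    """Junction volume between path-adjacent segments i and i+1."""
    return 0.5 * (segs[i].v_end + segs[i + 1].v_start)


def map_parameters(
    call: AsynchronyCall,
    seg: HLASegmentation,
    vm2_shift: bool = True,
    breath_id=None,
) -> VentilatedParameters:
    """Step 2: recover the ventilated stiffnesses and breakpoints.

    none
        identity mapping from the 2+2 segments.
    reverse triggering
        (k1..k4) = (k_a1, k_a2, k_a5, k_a6); Vmax from the intersection of
        the extended k_a2 and k_a5 lines (the loop's top is distorted by
        the in-inspiration effort); Vm1 and Vm2 from the clean junctions.
    premature cycling
        (k1..k4) = (k_a1, k_a2, k_a3, k_a5); Vm2 from the intersection of
        the extended k_a3 and k_a5 lines (the effort bridges the
        expiratory breakpoint); Vmax read off the loop.
    double triggering
        (k1, k2) from the first inspiration, (k3, k4) from the stacked
        final expiration; Vmax is the first (pre-stacking) volume maximum;
        Vm2 is the stacked expiration's junction translated back by the
        stacking volume Vmax2 - Vmax (``vm2_shift=False`` disables the
        translation for sensitivity analyses).  When the stacked
        expiration yields a single segment, the partial-expiration
        junction inside the inspiratory phase is used directly.

    Raises :class:`InfeasibleError` when a required segment or junction is
    missing (e.g. Vm1 hidden by an effort that began before the breath).
    """
    insp, exp = seg.insp_segments, seg.exp_segments
    if len(insp) < 1:
        raise InfeasibleError("no inspiratory segments", breath_id=breath_id)
    peep = insp[0].intercept

    if call.label == "none":
        if len(insp) < 2 or len(exp) < 2:
            raise InfeasibleError(
                "a breakpoint (Vm1 or Vm2) is hidden in a single-segment "
                "half-cycle", breath_id=breath_id,
            )
        vp = VentilatedParameters(
            k1=insp[0].slope_k, k2=insp[1].slope_k,
            k3=exp[0].slope_k, k4=exp[1].slope_k,
            vm1=_junction(insp, 0), vm2=_junction(exp, 0),
            vmax=seg.vmax, peep=peep,
        )
        return vp.validate(breath_id)

    if call.label == "reverse_triggering":
        if len(insp) < 2:
            raise InfeasibleError(
                "Vm1 / k1-k2 not identifiable (inspiration onset obscured)",
                breath_id=breath_id,
            )
        if len(exp) < 2:
            raise InfeasibleError(
                "expiration did not yield two segments", breath_id=breath_id
            )
        vmax, _ = line_intersection(insp[1], exp[0])
        vp = VentilatedParameters(
            k1=insp[0].slope_k, k2=insp[1].slope_k,
            k3=exp[0].slope_k, k4=exp[-1].slope_k,
            vm1=_junction(insp, 0), vm2=_junction(exp, 0),
            vmax=vmax, peep=peep,
        )
        return vp.validate(breath_id)

    if call.label == "premature_cycling":
        if len(insp) < 2 or len(exp) < 3:
            raise InfeasibleError(
                "premature cycling requires 2 inspiratory and 3 expiratory segments",
                breath_id=breath_id,
            )
        vm2, _ = line_intersection(exp[0], exp[-1])
        vp = VentilatedParameters(
            k1=insp[0].slope_k, k2=insp[1].slope_k,
            k3=exp[0].slope_k, k4=exp[-1].slope_k,
            vm1=_junction(insp, 0), vm2=vm2,
            vmax=seg.vmax, peep=peep,
        )
        return vp.validate(breath_id)

    if call.label == "double_triggering":
        if len(insp) < 4:
            raise InfeasibleError(
                "stacked breath did not yield enough inspiratory-phase segments",
                breath_id=breath_id,
            )
        vmax = _junction(insp, 1)  # first volume maximum, before stacking
        vmax2 = seg.vmax
        delta = vmax2 - vmax
        if len(exp) >= 2:
            v_int, _ = line_intersection(exp[0], exp[-1])
            vm2 = v_int - (delta if vm2_shift else 0.0)
            k3, k4 = exp[0].slope_k, exp[-1].slope_k
        else:
            # stacked expiration merged into one segment: fall back to the
            # partial expiration inside the inspiratory phase (unshifted)
            v_int, _ = line_intersection(insp[2], insp[3])
            vm2 = v_int
            k3, k4 = insp[2].slope_k, insp[3].slope_k
        vp = VentilatedParameters(
            k1=insp[0].slope_k, k2=insp[1].slope_k, k3=k3, k4=k4,
            vm1=_junction(insp, 0), vm2=vm2, vmax=vmax, peep=peep,
        )
        return vp.validate(breath_id)

    raise InfeasibleError(
        f"breath is {call.label}; no parameter mapping defined",
        breath_id=breath_id,
    )


def _unaltered_masks(loop, seg: HLASegmentation, label: str):
    """Index arrays (within each half) of the samples the effort left on
    the ventilated law."""
    n_i = loop.insp_slice.stop - loop.insp_slice.start
    n_e = loop.exp_slice.stop - loop.exp_slice.start
    insp_idx = np.arange(n_i)
    exp_idx = np.arange(n_e)
    if label == "reverse_triggering" and len(seg.insp_segments) >= 2:
        s0, _ = seg.insp_segments[0].index_range
        _, e1 = seg.insp_segments[1].index_range
        insp_idx = np.arange(s0, e1 + 1)
    if label == "premature_cycling" and len(seg.exp_segments) >= 3:
        a = seg.exp_segments[0].index_range
        b = seg.exp_segments[-1].index_range
        exp_idx = np.concatenate(
            [np.arange(a[0], a[1] + 1), np.arange(b[0], b[1] + 1)]
        )
    return insp_idx, exp_idx


def refine_ventilated_parameters(
    loop,
    seg: HLASegmentation,
    call: AsynchronyCall,
    init: VentilatedParameters | None = None,
    breath_id=None,
    trust_observed_vmax: bool = False,
) -> VentilatedParameters:
    """Bounded least-squares refit of the ventilated law (Step 2 refinement).

    The segment-wise mapping estimates the steep early-expiration stiffness
    k3 from only a handful of samples, which makes it (and the Vm2
    intersection) fragile under sensor noise.  This refit re-estimates the
    full piecewise law over all samples the effort left unaltered, using a
    parameterisation that is physically valid by construction: the
    inspiratory limb is (PEEP, Vm1, deltaP1 = k1*Vm1 > 0, k2 > 0) and the
    expiratory limb is the junction point (Vm2, P_j) constrained strictly
    between PEEP and the loop-top pressure, from which k3 and k4 follow.
    With a noise-free, exactly piecewise-linear loop the refit returns the
    mapped parameters unchanged.  Not used for stacked (double-triggering)
    breaths, whose expiration lives in the translated stacked frame.
    """
    vi = np.asarray(loop.volume[loop.insp_slice], dtype=float)
    pi = np.asarray(loop.pressure[loop.insp_slice], dtype=float)
    ve = np.asarray(loop.volume[loop.exp_slice], dtype=float)
    pe = np.asarray(loop.pressure[loop.exp_slice], dtype=float)
    insp_idx, exp_idx = _unaltered_masks(loop, seg, call.label)
    xi, yi = vi[insp_idx], pi[insp_idx]
    xe, ye = ve[exp_idx], pe[exp_idx]

    # premature cycling: the effort chord's endpoints lie on the two
    # expiratory law lines, so the (many) chord samples constrain the laws
    # at the junction volumes va/vb through continuity — essential, since
    # only a handful of pre-effort k3 samples exist.  Vm2 must lie between
    # the chord endpoints.
    chord = None
    if call.label == "premature_cycling" and len(seg.exp_segments) >= 3:
        mid = seg.exp_segments[1]
        s, e = mid.index_range

        def junction(seg_a, seg_b, v_in, v_out):
            # extended-line intersection when it lands near the boundary
            # sample gap (exact on clean data); otherwise the boundary
            # sample itself (within one sample of the true junction)
            try:
                v, _ = line_intersection(seg_a, seg_b)
            except InfeasibleError:
                return float(v_in)
            gap = 2.0 * abs(v_out - v_in) + 1e-9
            return float(v) if abs(v - v_in) <= gap else float(v_in)

        va = junction(seg.exp_segments[0], mid, ve[s], ve[s - 1]) if s >= 1 \
            else float(ve[s])
        vb = junction(mid, seg.exp_segments[-1], ve[e],
                      ve[min(e + 1, len(ve) - 1)])
        if 0 < vb < vb + 0.02 < va <= float(np.max(ve)) + 0.02:
            chord = (va, vb, ve[s : e + 1], pe[s : e + 1])

    vmax_obs = float(np.max(loop.volume))
    vmax = vmax_obs
    # under volume control the effort cannot move the delivered volume, so
    # the observed maximum IS the tidal volume; otherwise prefer the
    # mapped estimate (e.g. an extended-line intersection) when plausible
    if (not trust_observed_vmax and init is not None
            and 0.7 * vmax_obs < init.vmax < 1.3 * vmax_obs):
        vmax = init.vmax

    # joint fit: (peep, vm1_frac, dp1, k2, vm2_frac, pj_frac); both limbs
    # share PEEP so the long low-volume expiratory tail pins it
    peep0 = init.peep if init is not None else float(np.median(pi[:3]))
    f2_lo, f2_hi = 0.05, 0.97
    if chord is not None:
        f2_lo = max(f2_lo, (chord[1] + 0.005) / vmax)
        f2_hi = min(f2_hi, (chord[0] - 0.005) / vmax)
        if f2_lo >= f2_hi:
            f2_lo, f2_hi, chord = 0.05, 0.97, None
    lb = [peep0 - 5.0, 0.03, 0.05, 0.1, f2_lo, 0.02]
    ub = [peep0 + 5.0, 0.90, 100.0, 1000.0, f2_hi, 0.98]

    def resid(p):
        peep, f1, dp1, k2, f2, fj = p
        vm1 = f1 * vmax
        p_top = peep + dp1 + k2 * (vmax - vm1)
        vm2 = f2 * vmax
        p_j = peep + fj * max(p_top - peep, 0.1)
        k3 = (p_top - p_j) / (vmax - vm2)
        k4 = (p_j - peep) / vm2
        insp = peep + (dp1 / vm1) * np.minimum(xi, vm1) \
            + k2 * np.clip(xi - vm1, 0.0, None) - yi
        exp = np.where(xe >= vm2, p_top - k3 * (vmax - xe),
                       peep + k4 * xe) - ye
        parts = [insp, exp]
        if chord is not None:
            va, vb, xc, yc = chord
            pa = p_top - k3 * (vmax - va)
            pb = peep + k4 * vb
            parts.append(pa + (pb - pa) * (xc - va) / (vb - va) - yc)
        return np.concatenate(parts)

    def unpack(p):
        peep, f1, dp1, k2, f2, fj = p
        vm1 = f1 * vmax
        k1 = dp1 / vm1
        p_top = peep + dp1 + k2 * (vmax - vm1)
        vm2 = f2 * vmax
        p_j = peep + fj * max(p_top - peep, 0.1)
        return VentilatedParameters(
            k1=float(k1), k2=float(k2),
            k3=float((p_top - p_j) / (vmax - vm2)),
            k4=float((p_j - peep) / vm2),
            vm1=float(vm1), vm2=float(vm2), vmax=float(vmax),
            peep=float(peep),
        )

    def pack(vp: VentilatedParameters):
        p_top = vp.peep + vp.k1 * vp.vm1 + vp.k2 * (vmax - vp.vm1)
        pj = p_top - vp.k3 * (vmax - vp.vm2)
        return np.clip(
            [vp.peep, vp.vm1 / vmax, vp.k1 * vp.vm1, vp.k2,
             vp.vm2 / vmax, (pj - vp.peep) / max(p_top - vp.peep, 0.1)],
            lb, ub,
        )

    if init is not None:
        x0 = pack(init)
    else:
        dp_span = max(float(np.ptp(yi)), 1.0)
        x0 = np.clip([peep0, 0.2, 0.4 * dp_span, 0.6 * dp_span / vmax,
                      0.75, 0.5], lb, ub)
    sol = least_squares(resid, x0, bounds=(lb, ub), xtol=1e-14, ftol=1e-14)
    if call.label == "reverse_triggering":
        # one-sided robust passes: the effort only lowers inspiratory
        # pressure, so strongly positive model-minus-data residuals mark
        # dip samples that leaked into the "unaltered" mask.  The dip onset
        # is graded, so iterate the exclusion.
        for _ in range(2):
            r_i = sol.fun[: len(xi)]
            scale = 1.4826 * float(np.median(np.abs(r_i - np.median(r_i)))) + 1e-6
            keep = r_i < max(2.5 * scale, 0.45)
            if not np.sum(~keep) or np.sum(keep) < 6:
                break
            xi, yi = xi[keep], yi[keep]
            sol = least_squares(resid, sol.x, bounds=(lb, ub),
                                xtol=1e-14, ftol=1e-14)
    vp = unpack(sol.x)
    # keep the segment-wise mapping when it explains the unaltered samples
    # better (guards against local minima of the joint fit)
    if init is not None:
        try:
            init.validate(breath_id)
            if float(np.sum(resid(pack(init)) ** 2)) < float(np.sum(sol.fun**2)):
                vp = unpack(pack(init))
        except InfeasibleError:
            pass
    return vp.validate(breath_id)


def refine_double_parameters(
    loop,
    seg: HLASegmentation,
    call: AsynchronyCall,
    init: VentilatedParameters | None = None,
    vm2_shift: bool = True,
    breath_id=None,
) -> VentilatedParameters:
    """Bounded joint refit of a stacked (double-triggered) breath.

    Three stretches of the loop are generated by the ventilated law set and
    can be fitted jointly: the first inspiration (inspiratory law up to the
    first volume maximum, which is Vmax), the partial expiration between
    the first maximum and the onset of the patient pull (expiratory law,
    unshifted), and the stacked final expiration (expiratory law anchored
    at the compliance-envelope pressure of the stacked top Vmax2, junction
    translated by the stacking volume Vmax2 - Vmax).  A single
    six-parameter bounded least-squares problem — (PEEP, Vm1 fraction,
    k1*Vm1, k2, Vm2 fraction, junction-pressure fraction) — ties all three
    together, so the short steep limbs are conditioned on the long ones
    and PEEP is pinned by the expiratory tail.  The patient pull and the
    ventilator push samples are excluded.  Exact on noise-free data.
    """
    vi = np.asarray(loop.volume[loop.insp_slice], dtype=float)
    pi = np.asarray(loop.pressure[loop.insp_slice], dtype=float)
    ve = np.asarray(loop.volume[loop.exp_slice], dtype=float)
    pe = np.asarray(loop.pressure[loop.exp_slice], dtype=float)

    # first volume maximum: end of the unaltered first inspiration
    run_max = np.maximum.accumulate(vi)
    draw = np.flatnonzero(run_max - vi > 0.05 * np.max(vi))
    if len(draw) == 0:
        raise InfeasibleError("no volume stacking found", breath_id=breath_id)
    turn1 = int(np.argmax(vi[: draw[0]]))
    if turn1 < 5:
        raise InfeasibleError(
            "first inspiration too short to identify", breath_id=breath_id
        )
    vmax = float(vi[turn1])
    vmax2 = float(np.max(loop.volume))
    delta = vmax2 - vmax
    if delta <= 0:
        raise InfeasibleError("stacked volume does not exceed Vmax",
                              breath_id=breath_id)
    shift = delta if vm2_shift else 0.0
    # partial expiration: from the first maximum down to the volume
    # minimum that precedes the patient pull
    pull_start = turn1 + 1 + int(np.argmin(vi[turn1 + 1 :]))
    xi, yi = vi[: turn1 + 1], pi[: turn1 + 1]
    xp, yp = vi[turn1 + 1 : pull_start + 1], pi[turn1 + 1 : pull_start + 1]
    xe, ye = ve, pe

    peep0 = init.peep if init is not None else float(np.median(yi[:3]))
    lb = [peep0 - 5.0, 0.03, 0.05, 0.1, max(0.05, 1e-3 / vmax), 0.02]
    ub = [peep0 + 5.0, 0.90, 100.0, 1000.0, 0.97, 0.98]

    def terms(p):
        peep, f1, dp1, k2, f2, fj = p
        vm1 = f1 * vmax
        p_top = peep + dp1 + k2 * (vmax - vm1)
        vm2 = f2 * vmax
        p_j = peep + fj * max(p_top - peep, 0.1)
        k3 = (p_top - p_j) / (vmax - vm2)
        k4 = (p_j - peep) / vm2
        return peep, vm1, dp1, k2, p_top, vm2, p_j, k3, k4

    def resid(p):
        peep, vm1, dp1, k2, p_top, vm2, p_j, k3, k4 = terms(p)
        insp = peep + (dp1 / vm1) * np.minimum(xi, vm1) \
            + k2 * np.clip(xi - vm1, 0.0, None) - yi
        part = np.where(xp >= vm2, p_top - k3 * (vmax - xp),
                        peep + k4 * xp) - yp
        p_top2 = peep + dp1 + k2 * (vmax2 - vm1)
        vj = vm2 + shift
        p_js = p_top2 - k3 * (vmax2 - vj)
        stack = np.where(xe >= vj, p_top2 - k3 * (vmax2 - xe),
                         p_js - k4 * (vj - xe)) - ye
        return np.concatenate([insp, part, stack])

    def pack(vp):
        p_top = vp.peep + vp.k1 * vp.vm1 + vp.k2 * (vmax - vp.vm1)
        pj = p_top - vp.k3 * (vmax - vp.vm2)
        return np.clip(
            [vp.peep, vp.vm1 / vmax, vp.k1 * vp.vm1, vp.k2,
             vp.vm2 / vmax, (pj - vp.peep) / max(p_top - vp.peep, 0.1)],
            lb, ub,
        )

    if init is not None:
        x0 = pack(init)
    else:
        dp_span = max(float(np.ptp(yi)), 1.0)
        x0 = np.clip([peep0, 0.2, 0.4 * dp_span, 0.6 * dp_span / vmax,
                      0.8, 0.5], lb, ub)
    sol = least_squares(resid, x0, bounds=(lb, ub), xtol=1e-14, ftol=1e-14)

    def unpack(p):
        peep, vm1, dp1, k2, p_top, vm2, p_j, k3, k4 = terms(p)
        return VentilatedParameters(
            k1=float(dp1 / vm1), k2=float(k2), k3=float(k3), k4=float(k4),
            vm1=float(vm1), vm2=float(vm2), vmax=vmax, peep=float(peep),
        )

    vp = unpack(sol.x)
    if init is not None:
        try:
            init.validate(breath_id)
            if float(np.sum(resid(pack(init)) ** 2)) < float(np.sum(sol.fun**2)):
                vp = unpack(pack(init))
        except InfeasibleError:
            pass
    return vp.validate(breath_id)
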