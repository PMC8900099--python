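"""Hysteresis loop model (HLM): parameters, pressure laws and reconstruction.

The lung mechanics model drives airway pressure from volume through a
hysteretic elastic law plus a resistive term,

    P = PEEP + R*dV/dt + P_el(V, phase),

with a quasi-static piecewise elastic law realising the hysteresis:
during inspiration the stiffness is k1 = Ke + Kh1 below the lower
inflection volume Vm1 (alveolar recruitment) and k2 = Ke above it; during
expiration the loop descends from the turning point (Vmax) with stiffness
k3 down to the upper deflection volume Vm2 and then with k4 back to
(0, PEEP).  The model carries ten parameters: R, Ke, Kh1, Kh2, Vm1, Vm2,
Vmax, PEEP, the steady-state driving amplitude f_V and an inertance
coefficient (default 0 — inertial pressure is negligible at ventilation
frequencies).

Elastances map to the loop stiffnesses as Ke = k2, Kh1 = k1 - k2,
Kh2 = k3 - k4.  The final expiratory limb always lands exactly on
(0, PEEP); its slope equals k4 whenever the parameter set is
closure-consistent, which the model enforces by deriving k4 from
(Ke, Kh1, Kh2, Vm1, Vm2, Vmax) — see :func:`closure_vm2`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .classify import VentilatedParameters
from .errors import InfeasibleError
from .waveforms import BreathCycle, PVLoop

__all__ = [
    "HLMParameters",
    "ReconstructedBreath",
    "derive_hlm_parameters",
    "reconstruct_breath",
    "closure_vm2",
    "inspiratory_pressure",
    "expiratory_pressure",
    "inspiration_flow",
    "expiration_flow",
    "canonical_breath",
    "expiration_tau",
]

#: lower bound (s) on the passive expiratory time constant.  R/(Ke+Kh2) at
#: typical adult parameters is ~0.24 s, which would imply peak passive
#: expiratory flows above 2 L/s; the floor keeps them near 1 L/s.
TAU_EXP_FLOOR = 0.5
#: inspiratory time constant of the pressure-controlled volume rise, as a
#: fraction of the inspiratory time
PC_TAU_FRACTION = 1.0 / 3.0


def closure_vm2(k1, k2, k3, k4, vm1, vmax) -> float:
    """Vm2 that closes the loop at (0, PEEP) for the given stiffnesses.

    Equates the elastic pressure gained over inspiration with that released
    over expiration: k1*vm1 + k2*(vmax-vm1) = k3*(vmax-vm2) + k4*vm2.
    """
    if abs(k4 - k3) < 1e-12:
        return 0.5 * vmax  # degenerate: expiration is a single line anyway
    top = k1 * vm1 + k2 * (vmax - vm1)
    return (top - k3 * vmax) / (k4 - k3)


@dataclass
class HLMParameters:
    """The ten HLM parameters.

    ``r`` cmH2O.s/L; ``ke``, ``kh1``, ``kh2`` cmH2O/L; ``vm1``, ``vm2``,
    ``vmax`` L; ``peep`` cmH2O; ``fv_amplitude`` cmH2O (steady-state
    driving input above PEEP); ``inertance_coeff`` cmH2O.s^2/L.
    """

    r: float
    ke: float
    kh1: float
    kh2: float
    vm1: float
    vm2: float
    vmax: float
    peep: float
    fv_amplitude: float
    inertance_coeff: float = 0.0
    flags: list = field(default_factory=list)

    @property
    def k1(self) -> float:
        return self.ke + self.kh1

    @property
    def k2(self) -> float:
        return self.ke

    @property
    def k4(self) -> float:
        """Expiratory tail stiffness, from loop closure at (0, PEEP)."""
        top = self.k1 * self.vm1 + self.k2 * (self.vmax - self.vm1)
        return (top - self.kh2 * (self.vmax - self.vm2)) / self.vmax

    @property
    def k3(self) -> float:
        return self.kh2 + self.k4

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "r", "ke", "kh1", "kh2", "vm1", "vm2", "vmax", "peep",
            "fv_amplitude", "inertance_coeff")}
        d["flags"] = list(self.flags)
        return d


@dataclass
class ReconstructedBreath:
    """Forward-simulated unaffected breath on the measured time base."""

    pv_loop: PVLoop
    pressure_waveform: np.ndarray
    params: HLMParameters
    volume_trajectory_source: str  # "measured", "canonical" or "hybrid"


def derive_hlm_parameters(vp: VentilatedParameters, r_est: float = 10.0) -> HLMParameters:
    """Map identified loop stiffnesses to HLM elastances (Ke, Kh1, Kh2).

    Ke = k2, Kh1 = k1 - k2, Kh2 = k3 - k4.  Negative hysteresis elastances
    are permitted but flagged as atypical.  The steady-state driving
    amplitude is the elastic pressure span of the loop.
    """
    if r_est < 0:
        raise ValueError("airway resistance must be non-negative")
    ke = vp.k2
    kh1 = vp.k1 - vp.k2
    kh2 = vp.k3 - vp.k4
    flags = []
    if kh1 < 0 or kh2 < 0:
        flags.append("negative_hysteresis_elastance")
    fv = vp.k1 * vp.vm1 + vp.k2 * (vp.vmax - vp.vm1)
    return HLMParameters(
        r=float(r_est), ke=ke, kh1=kh1, kh2=kh2,
        vm1=vp.vm1, vm2=vp.vm2, vmax=vp.vmax, peep=vp.peep,
        fv_amplitude=fv, flags=flags,
    )


def inspiratory_pressure(params: HLMParameters, volume) -> np.ndarray:
    """Quasi-static elastic pressure on the inspiratory limb."""
    v = np.asarray(volume, dtype=float)
    p = params.peep + params.k1 * np.minimum(v, params.vm1) \
        + params.k2 * np.clip(v - params.vm1, 0.0, None)
    return p


def expiratory_pressure(params: HLMParameters, volume) -> np.ndarray:
    """Quasi-static elastic pressure on the expiratory limb.

    Anchored at the turning point (Vmax, P_insp(Vmax)); descends with k3
    to Vm2 and then follows the line through (0, PEEP), whose slope is k4
    for closure-consistent parameters.
    """
    v = np.asarray(volume, dtype=float)
    p_top = float(inspiratory_pressure(params, params.vmax))
    if abs(params.kh2) < 1e-12:
        slope = (p_top - params.peep) / params.vmax
        return params.peep + slope * v
    p_j = p_top - params.k3 * (params.vmax - params.vm2)
    tail_slope = (p_j - params.peep) / params.vm2
    upper = p_top - params.k3 * (params.vmax - v)
    lower = params.peep + tail_slope * v
    return np.where(v >= params.vm2, upper, lower)


def expiration_tau(params: HLMParameters) -> float:
    """Passive expiratory time constant R/(Ke+Kh2), floor-bounded."""
    denom = max(params.ke + params.kh2, 1e-9)
    return max(params.r / denom, TAU_EXP_FLOOR)


# ---------------------------------------------------------------------------
# canonical volume trajectories (shared by the simulator and reconstruction)
# ---------------------------------------------------------------------------

def inspiration_flow(mode: str, n_insp: int, dt: float, vt: float) -> np.ndarray:
    """Inspiratory flow samples 0..n_insp such that the trapezoidal volume
    reaches exactly ``vt`` at sample ``n_insp``.

    VC: constant flow (zero at the very first sample, so the loop starts
    from rest).  PC: first-order decaying flow with time constant
    ``PC_TAU_FRACTION`` of the inspiratory time.
    """
    if n_insp < 2:
        raise ValueError("inspiration must span at least 2 samples")
    if mode.upper() == "VC":
        f = np.ones(n_insp + 1)
        f[0] = 0.0
    elif mode.upper() == "PC":
        tau = max(n_insp * dt * PC_TAU_FRACTION, dt)
        t = np.arange(n_insp + 1) * dt
        f = np.exp(-t / tau)
    else:
        raise ValueError(f"unknown ventilation mode {mode!r}")
    integral = np.trapezoid(f, dx=dt)
    return f * (vt / integral)


def expiration_flow(
    n_exp: int, dt: float, v_peak: float, tau: float, q_turn: float
) -> np.ndarray:
    """Expiratory flow samples (length ``n_exp``) following the turning point.

    Exponential-decay shape scaled so the trapezoidal integral — including
    the bridging step from the last inspiratory sample ``q_turn`` — returns
    the volume exactly to zero.
    """
    if n_exp < 1:
        raise ValueError("expiration must span at least 1 sample")
    t = (np.arange(n_exp) + 1) * dt
    g = -np.exp(-t / tau)
    base = np.concatenate([[0.0], g])
    denom = np.trapezoid(base, dx=dt)
    scale = (-v_peak - 0.5 * dt * q_turn) / denom
    return g * scale


def canonical_breath(
    mode: str, n_samples: int, dt: float, n_insp: int, vt: float, tau_exp: float
) -> tuple[np.ndarray, np.ndarray]:
    """(volume, flow) of a canonical ventilated breath.

    The volume is the exact cumulative-trapezoid integral of the returned
    flow, peaking at precisely ``vt`` at sample ``n_insp`` and returning to
    exactly zero at the last sample.
    """
    if not 2 <= n_insp <= n_samples - 2:
        raise ValueError("inspiratory sample count out of range")
    flow = np.empty(n_samples)
    fi = inspiration_flow(mode, n_insp, dt, vt)
    flow[: n_insp + 1] = fi
    flow[n_insp + 1 :] = expiration_flow(
        n_samples - n_insp - 1, dt, vt, tau_exp, fi[-1]
    )
    volume = cumulative_trapezoid(flow, dx=dt, initial=0.0)
    return volume, flow


def _first_volume_maximum(volume: np.ndarray, vmax_hint: float) -> int:
    """Index of the first volume maximum preceding a significant drawdown.

    For stacked (double-triggered) breaths this is the end of the first
    ventilator inspiration; otherwise it is the global turning point.
    """
    run_max = np.maximum.accumulate(volume)
    draw = run_max - volume
    big = np.flatnonzero(draw > 0.05 * max(vmax_hint, np.max(volume)))
    if len(big) == 0:
        return int(np.argmax(volume))
    return int(np.argmax(volume[: big[0]]))


def reconstruct_breath(
    params: HLMParameters,
    cycle: BreathCycle,
    mode: str = "VC",
    label: str = "none",
    volume_source: str | None = None,
) -> ReconstructedBreath:
    """Step 3: forward-simulate the unaffected ventilated breath.

    The volume trajectory is taken from the measured cycle when the effort
    left it unaltered (no asynchrony, reverse triggering under volume
    control), replaced after the turning point by the canonical passive
    expiration when the effort perturbed expiratory volume (premature
    cycling), and replaced entirely by the canonical mode trajectory capped
    at the identified Vmax when volume was stacked (double triggering).
    Pressure is the quasi-static hysteretic law plus the resistive term.
    """
    if not (0 < params.vm1 < params.vmax and 0 < params.vm2 < params.vmax):
        raise InfeasibleError(
            "breakpoints must satisfy 0 < vm1, vm2 < vmax",
            breath_id=cycle.meta.get("breath_index"),
        )
    if volume_source is None:
        volume_source = {
            "none": "measured",
            "reverse_triggering": "measured",
            "premature_cycling": "hybrid",
            "double_triggering": "canonical",
        }.get(label, "measured")

    n, dt = cycle.n, cycle.dt
    if volume_source == "measured":
        volume = cycle.volume.copy()
        flow = cycle.flow.copy()
        turn = cycle.turning_index
    elif volume_source == "canonical":
        n_insp = _first_volume_maximum(cycle.volume, params.vmax)
        n_insp = int(np.clip(n_insp, 2, n - 2))
        volume, flow = canonical_breath(
            mode, n, dt, n_insp, params.vmax, expiration_tau(params)
        )
        turn = n_insp
    elif volume_source == "hybrid":
        turn = cycle.turning_index
        volume = cycle.volume.copy()
        flow = cycle.flow.copy()
        v_peak = float(volume[turn])
        flow[turn + 1 :] = expiration_flow(
            n - turn - 1, dt, v_peak, expiration_tau(params), flow[turn]
        )
        volume[turn:] = v_peak + cumulative_trapezoid(
            flow[turn:], dx=dt, initial=0.0
        )
    else:
        raise ValueError(f"unknown volume_source {volume_source!r}")

    pressure = np.empty(n)
    pressure[: turn + 1] = inspiratory_pressure(params, volume[: turn + 1])
    pressure[turn + 1 :] = expiratory_pressure(params, volume[turn + 1 :])
    pressure += params.r * flow
    if params.inertance_coeff:
        pressure += params.inertance_coeff * np.gradient(flow, dt)

    loop = PVLoop(
        volume=volume,
        pressure=pressure,
        insp_slice=slice(0, turn + 1),
        exp_slice=slice(turn, n),
    )
    return ReconstructedBreath(
        pv_loop=loop,
        pressure_waveform=pressure,
        params=params,
        volume_trajectory_source=volume_source,
    )
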