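"""Virtual test-lung simulator with known ground truth.

Generates ventilated breaths that obey the hysteresis-loop lung model
exactly (volume-controlled: constant inspiratory flow; pressure-controlled:
first-order volume rise; passive exponential expiration; airway pressure =
PEEP + R*flow + quasi-static hysteretic elastic law), then superimposes
spontaneous-breathing effort reproducing the three laboratory asynchrony
scenarios:

reverse triggering (VC)
    a raised-cosine negative pressure deflection during inspiration —
    ventilator-driven volume is unaltered, the pressure waveform takes the
    characteristic "M" shape.
premature cycling (PC)
    an inspiratory effort early in expiration: a transient positive-flow
    volume bump while the PV path bridges the expiratory corner along a
    straight chord between the k3 and k4 limbs (pressure trajectory
    relatively unmodified).
double triggering (PC)
    an expiratory effort whose pressure deflection exceeds the ventilator
    trigger threshold: a second inspiration is delivered from the current
    lung volume, stacking volume beyond the set tidal volume before a full
    stacked expiration.

Every derived quantity has a known ground truth: the paired with/without
effort loops of the same breath give the true E_asyn, the configured
stiffnesses and breakpoints are the identification targets, and the
scenario label is the classification target.  Noise (Gaussian, seeded) is
added only after ground truth is recorded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .classify import VentilatedParameters
from .errors import ConfigError
from .hlm import (
    HLMParameters,
    canonical_breath,
    closure_vm2,
    derive_hlm_parameters,
    expiration_flow,
    expiratory_pressure,
    inspiratory_pressure,
)
from .metrics import compute_easyn, loop_area
from .waveforms import BreathCycle, WaveformRecord

__all__ = [
    "EffortConfig",
    "ScenarioConfig",
    "BreathTruth",
    "LabelledBreathSet",
    "generate_ventilated_breath",
    "superimpose_effort",
    "generate_scenario_set",
    "scenario_suite",
]

SCENARIOS = ("none", "reverse_triggering", "premature_cycling", "double_triggering")
#: laboratory mode per scenario: reverse triggering was run in volume
#: control, premature cycling and double triggering in pressure control
DEFAULT_MODE = {
    "none": "VC",
    "reverse_triggering": "VC",
    "premature_cycling": "PC",
    "double_triggering": "PC",
}
#: effort volume displaced per cmH2O of muscle pressure (L/cmH2O): sets the
#: size of the expiratory volume bump produced by an inspiratory effort
EFFORT_VOLUME_COMPLIANCE = 0.09
#: duration (s) of the positive-flow volume bump inside the premature
#: cycling effort window — brief enough to overcome the passive
#: expiratory flow and actually reverse flow at the airway
PREMATURE_BUMP_DURATION = 0.3


@dataclass
class EffortConfig:
    """Spontaneous-breathing effort superimposed on a ventilated breath.

    ``amplitude`` is the peak muscle pressure (cmH2O); ``onset`` is a
    fraction of the phase the scenario acts on (inspiration for reverse
    triggering, expiration otherwise); ``duration`` in seconds (None for
    reverse triggering means "until the turning point").
    """

    amplitude: float
    onset: float
    duration: float | None
    shape: str = "raised_cosine"


DEFAULT_EFFORT = {
    "none": EffortConfig(0.0, 0.0, None),
    "reverse_triggering": EffortConfig(3.0, 0.55, None),
    "premature_cycling": EffortConfig(1.8, 0.0225, 0.7),
    "double_triggering": EffortConfig(4.0, 0.15, 0.5),
}


@dataclass
class ScenarioConfig:
    """Full description of one simulated scenario.

    Mechanical defaults are plausible adult ICU values: tidal volume 0.5 L,
    PEEP 5 cmH2O, stiffnesses (k1..k4) = (25, 10, 40, 8) cmH2O/L with the
    lower inflection at 0.1 L, airway resistance 10 cmH2O.s/L, respiratory
    rate 15/min with an 1:2 I:E ratio, sampled at 50 Hz.  Vm2 follows from
    loop closure.  ``seed`` fixes all randomness (effort-amplitude jitter
    and sensor noise).
    """

    scenario: str = "none"
    mode: str | None = None
    vt: float = 0.5
    peep: float = 5.0
    k1: float = 25.0
    k2: float = 10.0
    k3: float = 40.0
    k4: float = 8.0
    vm1: float = 0.1
    r: float = 10.0
    rr: float = 15.0
    ti_fraction: float = 1.0 / 3.0
    effort: EffortConfig | None = None
    trigger_threshold: float = 2.0
    noise_sd_pressure: float = 0.2
    noise_sd_flow: float = 0.01
    n_breaths: int = 10
    seed: int = 0
    sample_rate: float = 50.0
    amplitude_jitter: float = 0.4
    #: double triggering geometry: stacked second-breath volume as a
    #: fraction of VT; fraction of it inhaled during the patient pull; and
    #: the duration (s) of the ventilator re-pressurisation push
    second_breath_fraction: float = 0.85
    pull_volume_fraction: float = 0.4
    push_duration: float = 0.3

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ConfigError(f"unknown scenario {self.scenario!r}")
        if self.mode is None:
            self.mode = DEFAULT_MODE[self.scenario]
        if self.effort is None:
            self.effort = replace(DEFAULT_EFFORT[self.scenario])
        if self.effort.amplitude < 0:
            raise ConfigError("effort amplitude must be non-negative")
        if not 0 <= self.effort.onset < 1:
            raise ConfigError("effort onset must be a fraction in [0, 1)")
        if self.n_breaths < 1:
            raise ConfigError("n_breaths must be >= 1")
        if not 0 < self.vm1 < self.vt:
            raise ConfigError("vm1 must lie strictly inside (0, vt)")
        vm2 = self.vm2
        if not 0 < vm2 < self.vt:
            raise ConfigError(
                f"closure-derived vm2 = {vm2:.4f} L lies outside (0, vt); "
                "stiffness set is infeasible"
            )

    @property
    def vm2(self) -> float:
        return closure_vm2(self.k1, self.k2, self.k3, self.k4, self.vm1, self.vt)

    @property
    def period(self) -> float:
        return 60.0 / self.rr

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    @property
    def n_samples(self) -> int:
        return int(round(self.period * self.sample_rate))

    @property
    def n_insp(self) -> int:
        return int(round(self.period * self.ti_fraction * self.sample_rate))

    def true_parameters(self) -> VentilatedParameters:
        return VentilatedParameters(
            k1=self.k1, k2=self.k2, k3=self.k3, k4=self.k4,
            vm1=self.vm1, vm2=self.vm2, vmax=self.vt, peep=self.peep,
        )

    def hlm_parameters(self) -> HLMParameters:
        return derive_hlm_parameters(self.true_parameters(), self.r)


@dataclass
class BreathTruth:
    """Ground truth for one breath of a labelled set."""

    index: int
    label: str
    effort_amplitude: float
    a_ventilated: float
    a_asyn: float
    e_asyn_true: float
    ventilated_pressure: np.ndarray
    ventilated_volume: np.ndarray
    ventilated_flow: np.ndarray

    def to_dict(self) -> dict:
        return {
            "index": self.index,
            "label": self.label,
            "effort_amplitude": self.effort_amplitude,
            "a_ventilated": self.a_ventilated,
            "a_asyn": self.a_asyn,
            "e_asyn_true": self.e_asyn_true,
            "ventilated_pressure": self.ventilated_pressure.tolist(),
            "ventilated_volume": self.ventilated_volume.tolist(),
            "ventilated_flow": self.ventilated_flow.tolist(),
        }


@dataclass
class LabelledBreathSet:
    """A noisy recording plus per-breath ground truth."""

    record: WaveformRecord
    truths: list
    config: ScenarioConfig

    def to_truth_dict(self) -> dict:
        return {
            "scenario": self.config.scenario,
            "mode": self.config.mode,
            "seed": self.config.seed,
            "n_breaths": self.config.n_breaths,
            "peep": self.config.peep,
            "n_samples_per_breath": self.config.n_samples,
            "breaths": [t.to_dict() for t in self.truths],
        }


def _law_pressure(cfg: ScenarioConfig, volume: np.ndarray, turn: int) -> np.ndarray:
    """Elastic pressure along a volume path split at the turning index."""
    params = cfg.hlm_parameters()
    p = np.empty(len(volume))
    p[: turn + 1] = inspiratory_pressure(params, volume[: turn + 1])
    p[turn + 1 :] = expiratory_pressure(params, volume[turn + 1 :])
    return p


def generate_ventilated_breath(cfg: ScenarioConfig) -> BreathCycle:
    """One noiseless, fully ventilated (passive) breath.

    The canonical mode trajectory peaks at exactly the set tidal volume;
    pressure follows the hysteretic law plus the resistive term.
    """
    from .hlm import expiration_tau

    params = cfg.hlm_parameters()
    volume, flow = canonical_breath(
        cfg.mode, cfg.n_samples, cfg.dt, cfg.n_insp, cfg.vt, expiration_tau(params)
    )
    turn = cfg.n_insp
    pressure = _law_pressure(cfg, volume, turn) + cfg.r * flow
    time = np.arange(cfg.n_samples) * cfg.dt
    return BreathCycle(
        time=time, pressure=pressure, flow=flow, volume=volume,
        peep=cfg.peep, turning_index=turn, v_max_observed=float(volume[turn]),
        meta={"mode": cfg.mode, "peep": cfg.peep, "scenario": "none"},
    )


def _raised_cosine(n: int) -> np.ndarray:
    """Unit-peak raised-cosine window over n samples (0 at both ends)."""
    u = np.linspace(0.0, 1.0, n)
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * u))


def _scaled_segment_flow(shape: np.ndarray, dt: float, f_prev: float, delta_v: float) -> np.ndarray:
    """Scale a flow shape so the trapezoidal volume gained over the segment
    (including the bridging step from the preceding sample's flow
    ``f_prev``) equals exactly ``delta_v``."""
    base = np.trapezoid(np.concatenate([[0.0], shape]), dx=dt)
    bridge = 0.5 * dt * f_prev
    return shape * ((delta_v - bridge) / base)


def _reverse_trigger(breath: BreathCycle, cfg: ScenarioConfig, amp: float) -> BreathCycle:
    turn = breath.turning_index
    i_on = int(round(cfg.effort.onset * turn))
    if cfg.effort.duration is not None:
        i_off = min(turn, i_on + int(round(cfg.effort.duration / cfg.dt)))
    else:
        i_off = turn
    if i_off - i_on < 4:
        raise ConfigError("reverse-trigger effort window is too short")
    dip = amp * _raised_cosine(i_off - i_on + 1)
    pressure = breath.pressure.copy()
    pressure[i_on : i_off + 1] -= dip
    return replace(
        breath,
        pressure=pressure,
        meta={**breath.meta, "scenario": "reverse_triggering"},
    )


def _premature_cycling(breath: BreathCycle, cfg: ScenarioConfig, amp: float) -> BreathCycle:
    turn = breath.turning_index
    n = breath.n
    n_exp = n - 1 - turn
    i1 = turn + max(3, int(round(cfg.effort.onset * n_exp)))
    d = cfg.effort.duration if cfg.effort.duration is not None else 0.7
    i2 = min(n - 4, i1 + int(round(d / cfg.dt)))
    if i2 - i1 < 6:
        raise ConfigError("premature-cycling effort window is too short")
    flow = breath.flow.copy()
    beta = EFFORT_VOLUME_COMPLIANCE * amp
    # brief raised-cosine volume bump centred in the effort window: its
    # rate must exceed the passive expiratory flow to reverse flow at the
    # airway ("positive flow during deflation"); its derivative integrates
    # to ~zero so the volume rejoins the passive trajectory
    d_bump = min(PREMATURE_BUMP_DURATION, 0.5 * d)
    m_b = max(6, int(round(d_bump / cfg.dt)))
    j1 = (i1 + i2 - m_b) // 2
    u = np.linspace(0.0, 1.0, m_b + 2)[1:-1]
    flow[j1 + 1 : j1 + m_b + 1] += beta * (np.pi / d_bump) * np.sin(2.0 * np.pi * u)
    volume = cumulative_trapezoid(flow, dx=cfg.dt, initial=0.0)
    params = cfg.hlm_parameters()
    pressure = _law_pressure(cfg, volume, turn) + cfg.r * flow
    # chord between the points where the path leaves the k3 limb and
    # rejoins the k4 limb (both endpoints on the true expiratory law)
    va, vb = volume[i1], volume[i2]
    if not (vb < cfg.vm2 < va):
        raise ConfigError(
            "premature-cycling effort window must straddle vm2 "
            f"(got V: {va:.3f} -> {vb:.3f}, vm2 = {cfg.vm2:.3f})"
        )
    if np.max(volume[i1:i2]) >= cfg.vt:
        raise ConfigError(
            "premature-cycling volume bump exceeds the tidal volume; "
            "reduce the effort amplitude"
        )
    pa = float(expiratory_pressure(params, va))
    pb = float(expiratory_pressure(params, vb))
    chord = pb + (pa - pb) * (volume[i1 : i2 + 1] - vb) / (va - vb)
    pressure[i1 : i2 + 1] = chord + cfg.r * flow[i1 : i2 + 1]
    if np.max(flow[i1:i2]) <= 0:
        warnings.warn("premature-cycling effort too weak for a positive-flow bump")
    return replace(
        breath,
        pressure=pressure,
        flow=flow,
        volume=volume,
        turning_index=int(np.argmax(volume)),
        v_max_observed=float(np.max(volume)),
        meta={**breath.meta, "scenario": "premature_cycling"},
    )


def _double_trigger(breath: BreathCycle, cfg: ScenarioConfig, amp: float) -> BreathCycle:
    if amp <= cfg.trigger_threshold:
        raise ConfigError(
            f"double-triggering effort ({amp:.2f} cmH2O) must exceed the "
            f"trigger threshold ({cfg.trigger_threshold:.2f} cmH2O); a "
            "sub-threshold effort is premature cycling"
        )
    params = cfg.hlm_parameters()
    n, dt, turn = breath.n, cfg.dt, breath.turning_index
    n_exp = n - 1 - turn
    i_tr = turn + max(3, int(round(cfg.effort.onset * n_exp)))
    d = cfg.effort.duration if cfg.effort.duration is not None else 0.5
    m1 = max(4, int(round(d / dt)))
    m2 = max(4, int(round(cfg.push_duration / dt)))
    i_c1 = i_tr + m1
    i_c2 = i_c1 + m2
    if i_c2 > n - 8:
        raise ConfigError("double-triggering effort does not fit in the cycle")
    flow = breath.flow.copy()
    vt2 = cfg.second_breath_fraction * cfg.vt
    v_tr = breath.volume[i_tr]
    vmax2 = v_tr + vt2
    if vmax2 <= cfg.vt:
        raise ConfigError("stacked volume does not exceed the set tidal volume")
    dv1 = cfg.pull_volume_fraction * vt2
    # patient pull: flow pulse bridging from the passive expiratory flow
    shape1 = _raised_cosine(m1 + 2)[1:-1]
    flow[i_tr + 1 : i_c1 + 1] = _scaled_segment_flow(shape1, dt, flow[i_tr], dv1)
    # ventilator push
    shape2 = _raised_cosine(m2 + 2)[1:-1]
    flow[i_c1 + 1 : i_c2 + 1] = _scaled_segment_flow(shape2, dt, flow[i_c1], vt2 - dv1)
    # stacked passive expiration back to zero volume
    from .hlm import expiration_tau

    flow[i_c2 + 1 :] = expiration_flow(
        n - i_c2 - 1, dt, vmax2, expiration_tau(params), flow[i_c2]
    )
    volume = cumulative_trapezoid(flow, dx=dt, initial=0.0)
    v_tr_act = volume[i_tr]
    v_c1 = volume[i_c1]
    v_top = volume[i_c2]

    pressure = np.empty(n)
    # first inspiration and partial expiration follow the unaltered laws
    pressure[: turn + 1] = inspiratory_pressure(params, volume[: turn + 1])
    pressure[turn + 1 : i_tr + 1] = expiratory_pressure(params, volume[turn + 1 : i_tr + 1])
    # patient pull: pressure falls linearly in V to PEEP - amplitude
    p_tr = float(expiratory_pressure(params, v_tr_act))
    p_low = cfg.peep - amp
    seg = volume[i_tr : i_c1 + 1]
    pressure[i_tr : i_c1 + 1] = p_tr + (p_low - p_tr) * (seg - v_tr_act) / (v_c1 - v_tr_act)
    # ventilator push: pressure recovers to the compliance envelope at vmax2
    p_top2 = float(inspiratory_pressure(params, v_top))
    seg = volume[i_c1 : i_c2 + 1]
    pressure[i_c1 : i_c2 + 1] = p_low + (p_top2 - p_low) * (seg - v_c1) / (v_top - v_c1)
    # stacked expiration: k3/k4 law anchored at the stacked top, junction
    # translated by the stacking volume
    delta = v_top - cfg.vt
    vj = cfg.vm2 + delta
    p_j = p_top2 - cfg.k3 * (v_top - vj)
    seg = volume[i_c2 + 1 :]
    pressure[i_c2 + 1 :] = np.where(
        seg >= vj, p_top2 - cfg.k3 * (v_top - seg), p_j - cfg.k4 * (vj - seg)
    )
    pressure += cfg.r * flow
    return replace(
        breath,
        pressure=pressure,
        flow=flow,
        volume=volume,
        turning_index=int(np.argmax(volume)),
        v_max_observed=float(np.max(volume)),
        meta={**breath.meta, "scenario": "double_triggering"},
    )


def superimpose_effort(
    breath: BreathCycle, cfg: ScenarioConfig, amplitude: float | None = None
) -> BreathCycle:
    """Superimpose the scenario's spontaneous-breathing effort on a
    ventilated breath.  ``amplitude`` overrides the configured effort
    amplitude (used for per-breath jitter).  Zero amplitude returns the
    breath unchanged.
    """
    if cfg.scenario == "none":
        raise ConfigError("scenario 'none' has no effort to superimpose")
    amp = cfg.effort.amplitude if amplitude is None else float(amplitude)
    if amp == 0.0 and cfg.scenario != "double_triggering":
        return replace(breath, meta=dict(breath.meta))
    if cfg.scenario == "reverse_triggering":
        return _reverse_trigger(breath, cfg, amp)
    if cfg.scenario == "premature_cycling":
        return _premature_cycling(breath, cfg, amp)
    return _double_trigger(breath, cfg, amp)


def _breath_amplitudes(cfg: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-breath effort amplitudes with seeded +-jitter."""
    base = cfg.effort.amplitude
    amps = base * (1.0 + cfg.amplitude_jitter * rng.uniform(-1, 1, cfg.n_breaths))
    if cfg.scenario == "double_triggering":
        amps = np.maximum(amps, cfg.trigger_threshold + 0.5)
    return amps


def generate_scenario_set(cfg: ScenarioConfig) -> LabelledBreathSet:
    """Paired (ventilated, asynchronous) breaths as one noisy recording.

    For each of ``cfg.n_breaths`` pairs, the fully ventilated breath comes
    first and its effort-altered counterpart second; scenario "none" emits
    ventilated breaths only.  The true E_asyn of every asynchronous breath
    is computed from the paired noiseless loops before noise is added.
    """
    rng = np.random.default_rng(cfg.seed)
    amps = _breath_amplitudes(cfg, rng)
    vent = generate_ventilated_breath(cfg)
    a_vent = loop_area(vent.volume, vent.pressure)

    breaths, truths = [], []
    for b in range(cfg.n_breaths):
        breaths.append(vent)
        truths.append(
            BreathTruth(
                index=len(breaths) - 1, label="none", effort_amplitude=0.0,
                a_ventilated=a_vent, a_asyn=a_vent, e_asyn_true=0.0,
                ventilated_pressure=vent.pressure, ventilated_volume=vent.volume,
                ventilated_flow=vent.flow,
            )
        )
        if cfg.scenario == "none":
            continue
        asyn = superimpose_effort(vent, cfg, amplitude=amps[b])
        a_asyn = loop_area(asyn.volume, asyn.pressure)
        e_true, _ = compute_easyn(a_vent, a_asyn)
        breaths.append(asyn)
        truths.append(
            BreathTruth(
                index=len(breaths) - 1, label=cfg.scenario,
                effort_amplitude=float(amps[b]),
                a_ventilated=a_vent, a_asyn=a_asyn, e_asyn_true=e_true,
                ventilated_pressure=vent.pressure, ventilated_volume=vent.volume,
                ventilated_flow=vent.flow,
            )
        )

    n_b = cfg.n_samples
    pressure = np.concatenate([b.pressure for b in breaths])
    flow = np.concatenate([b.flow for b in breaths])
    time = np.concatenate(
        [b.time + i * cfg.period for i, b in enumerate(breaths)]
    )
    pressure = pressure + rng.normal(0.0, cfg.noise_sd_pressure, len(pressure))
    flow = flow + rng.normal(0.0, cfg.noise_sd_flow, len(flow))
    record = WaveformRecord(
        time=time, pressure=pressure, flow=flow, sample_rate=cfg.sample_rate,
        meta={"peep": cfg.peep, "mode": cfg.mode, "scenario": cfg.scenario,
              "n_samples_per_breath": n_b},
    )
    return LabelledBreathSet(record=record, truths=truths, config=cfg)


def scenario_suite(
    seed: int,
    n_breaths: int = 10,
    scenarios=("reverse_triggering", "premature_cycling", "double_triggering"),
    **overrides,
) -> dict:
    """One labelled set per scenario, with per-scenario derived seeds."""
    out = {}
    for i, sc in enumerate(scenarios):
        cfg = ScenarioConfig(
            scenario=sc, n_breaths=n_breaths, seed=(seed + 1009 * (i + 1)) % (2**31),
            **overrides,
        )
        out[sc] = generate_scenario_set(cfg)
    return out
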