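# Methods

## Model

One breath is modelled as a hysteresis loop in the volume–pressure plane.
Airway pressure is driven by volume through a quasi-static piecewise
elastic law plus a resistive term,

    P(t) = PEEP + R·V̇(t) + P_el(V(t), phase),

with, during inspiration, stiffness k1 below the lower inflection volume
Vm1 (alveolar recruitment) and k2 above it; during expiration the loop
descends from the turning point (Vmax, P_el(Vmax)) with stiffness k3 down
to the upper deflection volume Vm2 and then along the line through
(0, PEEP), whose slope is k4.  The hysteresis elastances are Ke = k2,
Kh1 = k1 − k2 and Kh2 = k3 − k4; together with R, Vm1, Vm2, Vmax, PEEP and
the steady-state driving amplitude f_V this is a ten-parameter model.  The
inertial term is carried as a configurable coefficient defaulting to zero —
at ventilation frequencies the V̈ contribution is negligible.  The
hysteretic inspiration/expiration state variables are realised implicitly
by the phase-dependent piecewise law rather than as separate ODE states:
this realisation reproduces the segment geometry of measured loops exactly
and keeps every identification step a direct (convex or small bounded
least-squares) calculation.

**Loop closure.**  A top-anchored expiration with independent k3, k4 and
Vm2 generally does not land back on (0, PEEP).  The package resolves this
by construction: the final expiratory limb always ends exactly at
(0, PEEP), its slope equals k4 whenever the parameter set satisfies the
closure identity k1·Vm1 + k2·(Vmax−Vm1) = k3·(Vmax−Vm2) + k4·Vm2, and the
simulator derives Vm2 from that identity (0.4219 L at the default
stiffnesses).  Consequently the HLM parameter set stores Kh2 and recovers
k4 through closure.

## Pipeline

1. **Waveforms.**  Volume is the cumulative trapezoidal integral of flow,
   re-zeroed at every breath onset (each loop starts at (0, PEEP)).  An
   onset is a sustained rise of flow above 0.05 L/s after a quiet
   (non-positive-flow) interval, *and* the integrated cycle volume must
   have fallen below 30% of the running cycle maximum — without the volume
   guard, the positive-flow episodes of premature cycling and the stacked
   second breath of double triggering would falsely split a breath.  The
   turning index is the volume maximum, refined by the onset of sustained
   expiratory flow (< −0.1 L/s), which is crisp where the integrated
   volume has a noise-flattened top.
2. **Resistive correction.**  All segmentation operates on the elastic
   pressure P − R̂·V̇ (V̇ = measured flow).  This makes the elastic loop
   continuous at the turning point, so extended-segment intersections are
   exact.  R̂ starts at the configured value (default 10 cmH2O·s/L) and is
   re-estimated by least squares of the pressure residual against flow
   over the unaltered inspiratory sub-segments; the analysis re-runs once
   when the estimate moves.
3. **HLA.**  Piecewise-linear segments along the sampled path; breakpoint
   search is an exact dynamic program over sample indices minimising the
   pressure SSE of per-piece line fits, with a minimum span of 3 samples.
   The segment count (1–6) minimises
   BIC = n·ln((RSS + n·σ₀²)/n) + (3k−1)·ln n, with a residual floor
   σ₀ = 0.15 cmH2O so that selection does not chase structure below the
   sensor resolution (a zero-noise raised-cosine effort would otherwise be
   over-segmented past its nominal count); ties break toward fewer
   segments.  A continuous refinement then releases junction coordinates
   to sub-sample precision (small bounded least squares; exact on
   noise-free piecewise-linear data).  Half-cycles with less than 1 cmH2O
   of pressure range are declared unsegmentable.
4. **Classification.**  The segment-count rule table (2+2 = none; 4-segment
   inspiration with a +,−,+ stiffness pattern = reverse triggering;
   2 inspiratory and 3 expiratory segments = premature cycling; 5–6
   inspiratory-phase segments = double triggering) is augmented by the
   morphological signatures that define the types: an inspiratory-phase
   volume reversal exceeding 5% of Vmax (volume stacking) is required for —
   and identifies — double triggering, and an expiratory volume rebound
   above 0.02 L (the patient's positive-flow episode) identifies premature
   cycling even when the expiratory chord is nearly collinear with the k4
   limb and the count collapses to two.  Slopes within ±1 cmH2O/L of zero
   are sign-ambiguous.  `unclassifiable` is a reported value, not an
   error; such breaths are excluded from reconstruction and counted.
5. **Parameter mapping.**  none: identity.  Reverse triggering:
   (k1..k4) = (k_a1, k_a2, k_a5, k_a6), Vmax from the intersection of the
   extended k_a2/k_a5 lines, Vm1 and Vm2 from the clean junctions.
   Premature cycling: (k_a1, k_a2, k_a3, k_a5) with Vm2 from the
   k_a3/k_a5 intersection; its 3-piece expiration is fitted with the
   middle piece constrained to bracket the rebound episode and to rejoin
   the relaxation limb within 0.5 s (an unconstrained fit can spend the
   third piece on the low-information end-expiratory tail).  Double
   triggering: (k1, k2) from the first inspiration, (k3, k4) from the
   stacked final expiration, Vmax = the first (pre-stacking) volume
   maximum, Vm2 = the stacked expiration's junction translated back by the
   stacking volume Vmax2 − Vmax (a config flag disables the translation
   for sensitivity analyses).
6. **Bounded refit.**  The segment-wise estimates of the short, steep
   early-expiration limb (k3 spans only a handful of samples at 50 Hz
   under realistic expiratory time constants) are fragile under noise.  A
   joint bounded least-squares refit of the full law over the samples the
   effort left unaltered re-estimates (PEEP, Vm1, k1·Vm1, k2, Vm2, P_j)
   with a parameterisation that is physically valid by construction (the
   expiratory junction pressure is constrained strictly between PEEP and
   the loop top).  Both limbs share PEEP, so the long low-volume
   expiratory tail pins it — fitting the limbs separately lets a small
   inspiratory PEEP bias leverage into a large k4 error.  Per type:
   reverse triggering adds a one-sided robust pass (the effort only lowers
   inspiratory pressure, so strongly positive model-minus-data residuals
   mark dip samples that leaked into the clean mask) and, under volume
   control, takes Vmax from the observed volume maximum — the effort
   cannot move ventilator-delivered volume; premature cycling includes the
   effort-chord samples in the fit, modelling them as the straight line
   whose endpoints lie on the two expiratory law lines at the identified
   junctions (continuity transfers the information of ~30 chord samples
   onto k3 and Vm2, which the few pre-effort samples alone cannot pin) and
   bounds Vm2 between the chord endpoints; double triggering fits first
   inspiration, partial expiration and stacked expiration jointly, the
   stacked limb anchored at the compliance-envelope pressure of the
   observed stacked top with its junction translated by the stacking
   volume.  The segment-wise mapping is kept whenever it explains the
   unaltered samples better than the refit (a guard against local
   minima).  On noise-free data all refits reproduce the mapped
   parameters.
7. **Reconstruction and metrics.**  The unaffected breath is forward
   simulated on the measured volume trajectory when the effort left it
   unaltered (none, reverse triggering under volume control), on the
   measured inspiration plus the canonical passive expiration when
   expiratory volume was perturbed (premature cycling), and on the full
   canonical mode trajectory capped at the identified Vmax when volume was
   stacked (double triggering).  Loop areas are |net signed shoelace| of
   the closed path (self-intersecting stacked loops therefore use the net
   signed area; a summed-|subloop| alternative was considered and
   rejected as non-deterministic in the presence of noise-induced micro
   crossings).  Negative E_asyn is clamped to zero and flagged.  Trailing
   moving averages (default window 10 breaths, recommended 10–20) skip
   infeasible breaths and report the skip count.

## Virtual test lung

The simulator generates ventilated breaths from canonical trajectories —
volume control: constant inspiratory flow; pressure control: first-order
volume rise with τ = Ti/3; passive expiration: exponential decay,
normalised to end at exactly zero volume — with pressure from the model
law.  The expiratory time constant is max(R/(Ke+Kh2), 0.5 s): the
physical value (0.24 s at default parameters) would imply peak passive
expiratory flows above 2 L/s, and the 0.5 s floor keeps them near the
realistic 1 L/s.  The same trajectory builders serve the simulator and the
reconstructor.  Flow profiles are scaled so the trapezoidal volume hits
the set tidal volume and returns to zero exactly, making the simulator and
the pipeline's integration bit-consistent.

Default mechanics are plausible adult ICU values: VT 0.5 L, PEEP 5 cmH2O,
(k1, k2, k3, k4) = (25, 10, 40, 8) cmH2O/L, Vm1 0.1 L, R 10 cmH2O·s/L,
15 breaths/min with a 1:2 I:E ratio, 50 Hz sampling, Gaussian sensor noise
of 0.2 cmH2O (pressure) and 0.01 L/s (flow) added only after ground truth
is recorded.  Effort amplitudes jitter ±40% per breath, seeded.

Effort morphologies (each scenario in its laboratory mode):

- **Reverse triggering (VC).**  Raised-cosine negative pressure deflection
  (default 3 cmH2O) from 55% of inspiration to the turning point; volume
  is unaltered.  Yields the "M"-shaped pressure waveform and a 4-segment
  + − + inspiration.
- **Premature cycling (PC).**  Early-expiratory inspiratory effort: the PV
  path leaves the k3 limb at effort onset and rejoins the k4 limb 0.7 s
  later along a straight chord whose endpoints straddle Vm2 (pressure
  trajectory relatively unmodified), while a brief (0.3 s) raised-cosine
  volume bump — 0.09 L per cmH2O of muscle pressure, default amplitude
  1.8 cmH2O, below the trigger threshold — reverses the airway flow.  The
  bump must be brief: a bump spread over the whole window cannot outpace
  the passive expiratory flow and no flow reversal would occur.
- **Double triggering (PC).**  Expiratory effort whose pressure deflection
  (default 4 cmH2O) exceeds the 2 cmH2O trigger threshold 0.4 s into
  expiration: pressure is pulled linearly (in V) down to PEEP − amplitude
  while volume rises, the ventilator then re-inflates to the compliance
  envelope at the stacked volume (second-breath volume 0.85·VT), and the
  stacked expiration follows the k3/k4 law anchored at the stacked top
  with its junction shifted by the stacking volume.  A sub-threshold
  amplitude is rejected (it would silently be premature cycling).

Ground-truth E_asyn comes from the paired noiseless with/without-effort
loops of the same breath.

**What the simulator does and does not emulate.**  It reproduces the loop
morphologies, segment patterns and timing of the three asynchrony types
with exactly piecewise-linear elastic geometry, additive Gaussian sensor
noise and a stationary patient.  Real recordings add breath-to-breath
mechanical variability, baseline drift, cardiogenic oscillations, other
asynchrony types (ineffective triggering, flow starvation) and ventilator
valve dynamics, none of which are modelled; passing tests therefore
demonstrate correctness of the method's algebra and its robustness to
sensor noise, not clinical performance.  One consequence of including the
resistive term at the default R: the large flow excursions of expiratory
efforts *increase* the measured loop's net area, so under these study
conditions the true (and estimated) E_asyn of premature-cycling and
double-triggering breaths clamps to zero; in a regime where elastic
(hysteretic) work dominated resistive work, stacked breaths would instead
score large positive magnitudes.  The consistency between estimated and
true E_asyn, which is what the validation measures, is unaffected.

## Numerical choices and limitations

- Per-piece fits minimise the pressure residual (P on V): volume noise,
  being integrated flow noise, is orders of magnitude smaller than
  pressure noise, and a total-least-squares formulation would be
  scale-arbitrary across cmH2O and L.
- Breakpoints reported as volumes come from the refined junctions
  (sub-sample); when a junction is degenerate (|ΔV| ~ 0) the slope is
  reported as 0 and such pieces are never used in mapping.
- Intersection of near-parallel extended segments (relative slope
  difference < 1e-9) raises an infeasibility error rather than inventing a
  breakpoint; a breath whose Vm1 is hidden by an effort that began before
  the ventilator cycle is likewise reported infeasible — its Step-1
  classification stands, it is excluded from reconstruction, and the
  cohort report counts it.
- The moving-average window warns outside 10–20 breaths; 10–20 breaths
  (~1 min at typical rates) is the period over which ventilator settings
  respond to persistent asynchrony.
- Problem sizes: the validation suite uses 10 paired breaths per scenario
  (200 samples per breath at 50 Hz) and statistical properties use 100
  seeded noise draws or 25 pairs per scenario; segmentation is O(n²) per
  half-cycle, a few milliseconds per breath.
- Classification accuracy degrades gracefully with noise (100% at the
  default 0.2 cmH2O; ~95% at 0.5 cmH2O, failures reported as
  unclassifiable rather than mistyped).
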