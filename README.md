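# pvasync

Patient–ventilator asynchrony detection, reconstruction and quantification
from pressure–volume (PV) loops.

Spontaneous breathing effort during mechanical ventilation distorts the
measured airway waveforms, so lung mechanics identified from those
waveforms — and any model-based decision built on them — become unreliable.
`pvasync` is for respiratory-mechanics researchers and engineers building
ventilation monitoring tools: it takes ordinary ventilator waveforms (time,
airway pressure, flow), finds the breaths where the patient fought or
assisted the machine, reconstructs what each breath *would* have looked
like without the effort, and quantifies how much work the effort displaced.

## Method

Each breath's PV loop is treated as a hysteresis loop.  **Hysteresis loop
analysis (HLA)** fits path-ordered piecewise-linear segments to each half
of the loop; an unaffected ventilated breath has two segments per half,
with stiffnesses k1, k2 (inspiration, split at the lower inflection volume
Vm1) and k3, k4 (expiration, split at Vm2).  Extra segments identify and
type the asynchrony:

| pattern | type |
|---|---|
| 4-segment inspiration, slopes + − + | reverse triggering |
| 3-segment expiration with a positive-flow episode | premature cycling |
| 5–6 inspiratory-phase segments with volume stacking | double triggering |

The segments the effort left untouched are mapped back to the ventilated
parameters (k1–k4, Vm1, Vm2, Vmax), hidden breakpoints being recovered from
intersections of the extended segment lines.  A **hysteresis loop model
(HLM)** with elastances Ke = k2, Kh1 = k1 − k2, Kh2 = k3 − k4 and airway
resistance R then forward-simulates the unaffected breath,

    P = PEEP + R·dV/dt + P_el(V, phase),

and the asynchrony magnitude is the energy-dissipation metric

    E_asyn = 100 · (A_ventilated − A_asyn) / A_ventilated  [%],

the relative deficit of the measured loop's enclosed area (ventilator work
of breathing) against the reconstructed unaffected loop.  Reconstruction
quality against a known reference is scored by the normalised RMS pressure
error, 100·√(mean (P − P̂)²) / mean(P).

A built-in **virtual test lung** generates ventilated breaths obeying the
same model in volume- or pressure-controlled mode and superimposes the
three effort morphologies with known ground truth, so every step of the
pipeline is validated end to end.

## Worked example

```python
from pvasync import ScenarioConfig, generate_scenario_set, validate_set

lbs = generate_scenario_set(
    ScenarioConfig(scenario="reverse_triggering", n_breaths=10, seed=42))
report = validate_set(lbs)
for row in report["breaths"][:3]:
    print(f"breath {row['index']:2d}: {row['label']:19s} "
          f"E_asyn {row['e_asyn']:5.2f} % (true {row['e_asyn_true']:5.2f} %), "
          f"reconstruction RMS {row['rms_error']:4.2f} %")
rms = report["rms"]
print(f"scenario RMS: mean {rms['mean']:.2f} %, max {rms['max']:.2f} %")
```

prints

```
breath  1: reverse_triggering  E_asyn  7.42 % (true  7.96 %), reconstruction RMS 1.54 %
breath  3: reverse_triggering  E_asyn  6.24 % (true  6.21 %), reconstruction RMS 1.58 %
breath  5: reverse_triggering  E_asyn  8.66 % (true  8.40 %), reconstruction RMS 1.75 %
scenario RMS: mean 1.58 %, max 1.75 %
```

Every breath was correctly typed as reverse triggering; the estimated
asynchrony magnitude tracks the true paired-loop value to within about one
percentage point, and the reconstructed pressure waveform matches the true
ventilated breath to ~2% despite the sensor noise.  The `examples/`
directory holds one short script per capability (simulation,
classification, reconstruction/scoring, cohort monitoring), and the same
functionality is available from the shell:

```sh
pvasync simulate --scenario double_triggering --n 10 --seed 42 \
    --out sim.csv --truth truth.json
pvasync analyze  --input sim.csv --out report.json
pvasync validate --input sim.csv --truth truth.json --out validation.json
```

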