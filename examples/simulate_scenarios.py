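"""Generate virtual test-lung recordings for the three asynchrony scenarios.

Each scenario produces paired breaths — a fully ventilated (passive) breath
followed by the same breath with superimposed patient effort — so the true
asynchrony magnitude E_asyn of every breath is known from the paired loop
areas.  Printed per breath: the effort amplitude (peak muscle pressure,
cmH2O), the two loop areas (cmH2O.L) and the true E_asyn (%).
"""

from pvasync import ScenarioConfig, generate_scenario_set

for scenario in ("reverse_triggering", "premature_cycling",
                 "double_triggering"):
    cfg = ScenarioConfig(scenario=scenario, n_breaths=3, seed=42)
    lbs = generate_scenario_set(cfg)
    print(f"\n{scenario} ({cfg.mode} mode, {len(lbs.record)} samples):")
    for t in lbs.truths:
        if t.label == "none":
            continue
        print(f"  breath {t.index}: effort {t.effort_amplitude:4.2f} cmH2O, "
              f"A_vent {t.a_ventilated:5.3f}, A_asyn {t.a_asyn:6.3f} cmH2O.L"
              f" -> true E_asyn {t.e_asyn_true:5.2f} %")
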