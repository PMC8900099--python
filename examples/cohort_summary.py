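"""Breath-to-breath monitoring summary over a mixed recording.

Analyses a double-triggering recording breath by breath and prints the
E_asyn distribution bins ({0}, (0,10], (10,50], (50,100] percent), the raw
per-breath E_asyn series and its trailing 10-breath moving average — the
smoothed series is what a bedside monitor would track, since ventilator
settings respond to persistent asynchrony rather than single breaths.
"""

from pvasync import AnalysisConfig, ScenarioConfig, analyze_record, \
    generate_scenario_set

lbs = generate_scenario_set(
    ScenarioConfig(scenario="double_triggering", n_breaths=10, seed=7))
results, summary = analyze_record(lbs.record, AnalysisConfig(window=10))

print("labels:", [r.label for r in results])
print("E_asyn bins:", summary["cohort"]["e_asyn_bins"])
series = ["-" if v is None else f"{v:.1f}" for v in summary["e_asyn_series"]]
smooth = ["-" if v is None else f"{v:.1f}"
          for v in summary["e_asyn_moving_average"]]
print("E_asyn per breath (%):", " ".join(series))
print(f"10-breath moving average (%):", " ".join(smooth))
print(f"infeasible breaths: {summary['n_infeasible']}")
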