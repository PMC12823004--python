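"""Threshold diagnosis and the outlier/noise robustness protocol.

The diagnosis compares per-parameter values against configurable health
thresholds (harmful direction per parameter).  The robustness suite
retrains the pipeline on corrupted copies of the data and reports
relative RMSE degradation ratios.
"""
from aquadiag import PipelineConfig, ScheduleConfig, SyntheticConfig, diagnose
from aquadiag.cpso import SwarmConfig
from aquadiag.pipeline import DEFAULT_THRESHOLDS, robustness_suite

report = diagnose({"pH": 7.18, "DO": 5.45, "permanganate": 2.99,
                   "TP": 0.22, "NH3N": 1.48, "COD": 11.8},
                  DEFAULT_THRESHOLDS)
print("diagnosis of a typical prediction vector:")
for name, entry in report.parameters.items():
    flag = "WARN" if entry["warning"] else "ok"
    print(f"  {name:<13s} {entry['value']:>6.2f}  vs {entry['bound']}  [{flag}]")
print(f"overall: {report.overall_status} — {report.risks}")

print("\nrobustness ratios (small run: 200-row data, 2 seeds):")
res = robustness_suite(
    SyntheticConfig(n_samples=200),
    PipelineConfig(isma_pop_size=8, isma_schedule=ScheduleConfig(T=6),
                   swarm_config=SwarmConfig(swarm_size=4, T=3)),
    seeds=(0, 1))
print(f"  outlier sensitivity  {res['outlier_sensitivity']:+.3f} "
      "(relative RMSE increase after outlier injection)")
print(f"  noise resistance     {res['noise_resistance']:.3f} "
      "(1 = noise injection did not hurt at all)")
print(f"  overfitting tendency {res['overfitting_tendency']:.3f} "
      "(train/test RMSE gap fraction)")
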