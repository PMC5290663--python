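"""Run a small multi-round benchmark: simulate, normalize, evaluate.

Five simulation rounds are enough to see the headline pattern; the full
benchmark in scripts/acceptance.py uses 100. The RSD-recovery slope is a
no-intercept regression of post-normalization RSD on true RSD within bins
of per-metabolite missingness: slope 1 = variability perfectly recovered,
slope < 1 = understated.
"""

import logging

from mixnorm import RunConfig, SimConfig, run_benchmark

logging.basicConfig(level=logging.WARNING)

cfg = RunConfig(
    sim=SimConfig(seed_constants=42, seed_rounds=43),
    n_rounds=5,
    methods=("none", "mixnorm", "mean_center"),
    run_associations=True,
    association_methods=("mixnorm",),
    association_analyses=("linear",),
    min_detection_fraction=0.0,
)
report = run_benchmark(cfg)

print("mean per-metabolite RSD% (pooled over rounds):")
print(report.rsd_summary["mean"].unstack().round(2).to_string())
print()
print("RSD-recovery slope by missingness bin (analytical samples):")
print(report.slope_table[["0", "10-15%", "20-25%", "40-45%"]].round(2).to_string())
print()
tp = report.power_table.query("kind == 'true_positive' and beta_threshold == 0.05")
print(f"true-positive probability at |beta| >= 0.05, p < 0.05: "
      f"{tp['probability'].item():.3f}")
print()
print("Read: mixnorm pushes QC RSD back to the ~3% truth and keeps the")
print("recovery slope near 1 deeper into the missingness bins than mean")
print("centering, whose slope sags toward 0.8 by the 20-25% bin.")
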