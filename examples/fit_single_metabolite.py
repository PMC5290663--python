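"""Fit the two-part mixture model to one metabolite's QC series.

Builds a small QC data set (4 batches x 3 QC injections) in which batch B3
runs cold: its values drop by ~2 log2 units, pushing part of the batch
below the detection floor of 14. The mixture likelihood uses each
non-detect — either true absence or a value below the threshold — instead
of discarding it.
"""

import numpy as np

from mixnorm import FitOptions, MixtureDesign, fit_mixture

rng = np.random.default_rng(0)

batches = np.repeat(["B1", "B2", "B3", "B4"], 3)
true_shift = {"B1": 0.0, "B2": 0.4, "B3": -2.1, "B4": 0.2}
y = np.array([16.0 + true_shift[b] for b in batches]) + 0.2 * rng.standard_normal(12)
threshold = np.full(12, 14.0)
detected = y >= threshold

design_cols = [np.ones(12)] + [(batches == b).astype(float) for b in ("B2", "B3", "B4")]
z = np.column_stack(design_cols)
names = ["intercept", "batch:B2", "batch:B3", "batch:B4"]
design = MixtureDesign(z, z, names, list(names))

fit = fit_mixture(y, detected, design, threshold,
                  FitOptions(compute_standard_errors=True))

print(f"detected {fit.n_detected}/12 injections; converged={fit.converged}")
print(f"sigma (residual SD, log2 units): {fit.params.sigma:.3f}")
for name, est in zip(names, fit.params.alpha):
    print(f"  mean-model {name:10s} = {est:+.3f}")
print()
print("The batch:B3 coefficient recovers the ~-2.1 cold-batch shift even")
print("though a B3 injection went undetected: the censored value still")
print("constrains the batch mean through the truncated-normal term.")
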