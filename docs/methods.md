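# Methods

## Model and estimation

`mixnorm` fits, per metabolite, a two-part likelihood over the QC samples.
Writing pᵢ = expit(xᵢ′β) for the probability that the metabolite is present
in sample *i*, μᵢ = zᵢ′α for its mean log2 abundance when present, σ for a
common residual SD, Tᵢ for the sample's batch detection threshold and δᵢ
for the detection indicator, the contribution of sample *i* is

    [(1 − pᵢ) + pᵢ Φ((Tᵢ − μᵢ)/σ)]^(1−δᵢ) · [pᵢ N(yᵢ; μᵢ, σ²)]^δᵢ .

The detected component uses the standard normal density with normalizing
constant 1/(σ√(2π)); any other normalization would not integrate to one and
would corrupt the variance interpretation. The (1 − pᵢ) term allows true
absence (e.g. degradation over a batch); no penalty or prior is placed on
β — estimation is plain maximum likelihood, as in the downstream-analysis
use of the same model family.

Estimation details:

* **Parameterization.** The optimizer works on (β, α, log σ), keeping σ
  positive without constraints.
* **Optimizer.** BFGS (`scipy.optimize.minimize`) with analytic gradients;
  gradient ∞-norm tolerance 1e−6, at most 500 iterations. If the line
  search stalls, one restart from the stalled point (which resets the
  Hessian approximation) and then one seeded random-jitter restart
  (SD 0.1) are tried; the best result is kept and flagged.
* **Initialization.** α from least squares on the detected values; β = 0
  except the intercept at logit of the observed detection fraction
  (clipped to [0.01, 0.99]); log σ from the complete-case residual SD
  (floored at 1e−3).
* **Numerics.** The censored-component log term is computed as
  logaddexp(log(1 − p), log p + logΦ) with Φ via `scipy.special.ndtr`
  / `log_ndtr`; p is clamped to [1e−12, 1 − 1e−12] inside logs; log σ is
  clipped to ±30 inside the objective (unreachable at any optimum).
* **Degenerate cases.** All samples detected → the presence model is
  unidentified (the likelihood is maximised as p → 1), so the logistic
  component is bypassed and the fit is closed-form Gaussian least squares
  on z. Nothing detected → the metabolite is not fittable and is skipped
  with a reason.
* **Standard errors** (for Wald tests) come from the inverse observed
  information, with the Hessian formed by central differences of the
  analytic gradient.

## Detection thresholds

T is per metabolite and per batch: the minimum detected value of that
metabolite among all samples (QC and analytical) run in the batch —
detectability is a property of the instrument run, not of sample class.
The alternative reading, one threshold per batch across all metabolites,
was rejected because the likelihood is specified per metabolite; this
choice is the natural within-model one and is the one the threshold
estimator implements. When a metabolite has no detection at all in a
batch, T falls back to the metabolite's global minimum detected value so
that Φ((T − μ)/σ) remains computable.

## Identifiability of batch corrections

For a batch in which a metabolite has *no detected QC observation*, the
mean-model batch coefficient is not identifiable: the likelihood supremum
for that batch's censored rows sits on the boundary p → 0 (or equivalently
μ → −∞), and an unconstrained quasi-Newton run drifts the coefficient to
arbitrarily large negative values, which would then be subtracted from any
detected analytical values of that batch and explode their spread. Such
batch indicators therefore enter the logistic component only (where they
are informative — they predict non-detection); the location correction for
the batch is reported as unidentified (NaN in the coefficient table) and
applied as zero. Batches with at least one detected QC observation keep
their mean-model indicator: there the censored rows genuinely sharpen the
estimate, which is the point of the mixture.

## Applying the correction

For each normalizable metabolite, the fitted batch coefficient and
run-order term for a sample's covariates are subtracted from every
*detected* cell; undetected cells never change (no imputation). The
unweighted mean of the identified batch coefficients is then added back
uniformly, so normalized values sit at the cross-batch average location
and the output does not depend on which batch served as referent
(`anchor="referent"` preserves the raw referent location instead). The
grand mean of a metabolite's detected values is preserved to ≈0.05 when
the metabolite is detected everywhere; under heavy truncation the detected
cells cover batches unevenly, so their mean can move more — this is a
property of summarising a censored sample, not of the anchor.

QC pool-type offsets (when more than one QC class exists) are always
estimated — batch and run-order effects are estimated jointly from all
QCs — but are applied to analytical samples only on request, via an
explicit mapping from analytical sample class to QC pool type. QC samples
keep their pool offsets: those reflect pool composition, not instrument
state. The run-order term defaults to log(run order); linear and quadratic
forms are selectable. An optional pre-fit filter can drop QC observations
beyond k·SD (default k = 3, off by default).

## Comparators

Mean centering subtracts (batch mean − grand mean) of detected values per
metabolite; median scaling divides detected values by (batch median /
overall median); quantile normalization maps each sample's detected values
onto the mean empirical quantile curve across samples, interpolating when
detected counts differ, with ties receiving the mean of their target
quantiles. All operate on detected values only. External methods can be
registered as plug-ins (an executable exchanging the package's TSV
dialect), so published alternatives can enter an evaluation without being
reimplemented here.

## The simulator

The generator emulates a batched GC/MS experiment and keeps full ground
truth. Defaults: 150 metabolites; 20 batches of 24 analytical + 3 QC
samples (480 + 60); per-metabolite mean abundance α_m ~ N(18, 2²) on the
log2 peak-area scale; analytical phenotype v_i ~ N(0, 1) with association
strength β_m ~ N(0, 1); noise ε ~ N(0, (0.03·α_m)²), i.e. a 3% coefficient
of variation; per-round batch effects b_mk ~ N(0, 2²) added identically to
QC and analytical samples of a batch; 20 detection thresholds evenly
spaced over [12.5, 15] and randomly permuted onto batches each round, with
every value below its batch's threshold marked undetected. QC values are
α_m + ε (a pool of equal aliquots sits at the mean phenotype); analytical
values add β_m·v_i.

α_m, β_m and v_i are drawn once from a constants seed and held fixed
across rounds; each round's noise, batch effects and threshold permutation
come from a stream deterministic in (rounds seed, round index), so rounds
are independently reproducible bit-for-bit. QCs are placed at the
beginning, middle and end of each 27-injection batch; since no run-order
effect is simulated, placement is informational only.

What the simulator does *not* emulate — retention-time drift, correlated
metabolites, peak-shape artifacts, heteroscedastic within-batch drift —
bounds what passing tests show: they demonstrate correct recovery of
additive per-batch structure under batch-specific left truncation, not
robustness to every failure mode of real chromatography.

## Evaluation metrics

* **RSD** = 100 · sample SD / mean over a sample set's detected values
  (n − 1 divisor); undefined below two values. Metabolites more than 80%
  undetected in a round are omitted from that round's summaries, and
  summaries pool all (metabolite, round) values rather than averaging
  per-round means (the two differ negligibly at these sizes).
* **RSD-recovery slope**: per 5%-wide missingness bin (exact 0 its own
  bin, left-open/right-closed above), the no-intercept regression slope
  Σ(true·est)/Σ(true²) of post-normalization RSD on true (pre-batch-effect)
  RSD, pooled across rounds.
* **Association scans**: analytical samples only; linear = OLS of detected
  values on phenotype (+ adjustments) with a two-sided t-test; mixture =
  the same covariates in both components with batch thresholds, Wald test
  on the linear-component phenotype coefficient. Fewer than 10 usable
  samples → skipped with a reason. True-positive probability at grid value
  t = fraction of tests with |β_m| ≥ t rejected at p < 0.05 (no
  multiplicity correction); false positives are counted among |β_m| < 0.05,
  the smallest grid value, since "β approaching zero" needs an explicit
  cut — both are configurable.
* **Correlation metrics**: pairwise Spearman between QC samples of a pool
  (metabolites ≥ 20% detected, pairwise-complete, average ranks for ties)
  and per-analyte Spearman against targeted assays by analytical sample
  class.

## Problem sizes

The default test suite runs the full-design benchmark for 40 rounds and
the acceptance script for 100 (the original study used 1000); with the
constants held fixed across rounds, the pooled means stabilise well below
these counts, and the tolerances asserted in the tests comfortably cover
the remaining Monte-Carlo error.

## Known limitations

* Coefficients for batches with no detected QC observation are
  unidentified and left uncorrected (see above); heavily truncated
  metabolites can retain batch structure in the few detected values of
  such batches.
* The logistic component separates whenever a batch's QCs are all
  detected or all undetected; the probability clamp makes the fit finite
  and stable, but logistic coefficients for separated batches are
  boundary artifacts and should not be interpreted.
* Wald standard errors assume the observed information is positive
  definite at the optimum; for nearly-unidentified fits the test reports
  the singularity rather than a number.
* The per-metabolite model assumes a common σ across batches,
  as the likelihood specifies; strongly batch-dependent variance would be
  attributed to the mean structure.
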