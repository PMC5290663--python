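# mixnorm

Mixture-model normalization of batch and run-order effects in non-targeted
GC/MS metabolomics data.

## The problem

Large non-targeted gas-chromatography/mass-spectrometry studies run samples
in batches over weeks or months. Instrument state drifts between batches
and within a batch by injection order, adding technical structure to the
log2 peak areas that can dwarf the biology. Worse, each batch has its own
detection floor: a low-abundance metabolite may be reported in one batch
and silently missing in the next, so the missingness itself is batch
structure, not noise. Standard fixes either ignore the non-detects or
impute them, both of which distort per-metabolite variability.

When pooled quality-control (QC) aliquots from a common serum pool are
injected into every batch, all between-QC variation for a metabolite is
technical. `mixnorm` uses those QCs to estimate per-metabolite batch and
run-order effects under a likelihood that models non-detection explicitly,
then subtracts the fitted location shifts from every sample. It is aimed at
analysts preparing batched GC/MS (or similar peak-area) data for downstream
association analysis.

## The model

For sample *i* of a given metabolite, with detection indicator δᵢ, observed
log2 abundance yᵢ, and batch detection threshold Tᵢ (the minimum detected
value of that metabolite in the batch), the likelihood contribution is

```
[(1 − pᵢ) + pᵢ Φ((Tᵢ − μᵢ)/σ)]^(1−δᵢ) · [pᵢ · N(yᵢ; μᵢ, σ²)]^δᵢ
```

where

* logit(pᵢ) = xᵢ′β — a logistic model for metabolite *presence*
  (an undetected metabolite is either truly absent, with probability
  1 − pᵢ, or present below the floor, with probability pᵢ Φ(·));
* μᵢ = zᵢ′α — a linear model for the mean abundance when present;
* σ² — a common residual variance across the fitting samples.

Covariates in x and z are technical: batch indicators (referent = the
batch whose QC median abundance is the per-metabolite median), optionally
QC pool type and a log run-order term. Parameters are estimated per
metabolite by BFGS maximum likelihood over all QCs, and the fitted batch
and run-order shifts are subtracted from QC and analytical samples alike.
Undetected cells are never imputed and never change.

The package also ships the standard comparators (per-batch mean centering,
per-batch median scaling, quantile normalization), a fully seeded simulator
of a batched GC/MS experiment with ground truth, and the evaluation metrics
used to judge normalization quality: per-metabolite RSD (100·SD/mean),
no-intercept RSD-recovery slopes by missingness bin, phenotype-association
power, pairwise QC Spearman correlation and agreement with targeted assays.

## A worked example

`examples/normalize_simulated_experiment.py` simulates one round of a
batched experiment (150 metabolites; 20 batches of 24 analytical + 3 QC
samples; additive batch effects ~ N(0, 2²); batch detection thresholds
12.5–15) and compares methods by mean per-metabolite QC RSD:

```
true mean QC RSD (pre batch effects): 2.98%
mean QC RSD after none        :  10.03%
mean QC RSD after mixnorm     :   2.43%
mean QC RSD after mean_center :   3.11%
mean QC RSD after median_scale:   3.16%
mean QC RSD after quantile    :  10.17%
```

Batch effects inflate purely-technical QC variation from ~3% to ~10%;
mixnorm restores it to 2.4% (slightly below truth, because each batch shift
is estimated from the same three QCs it corrects), the per-batch
comparators get close, and quantile normalization — which cannot express
per-metabolite batch effects — leaves it untouched. The other scripts in
`examples/` show a single-metabolite fit with censored injections, a
multi-round benchmark with association power, and a two-QC-pool design with
run-order drift.

A thin CLI wraps the same library calls:

```sh
mixnorm simulate --out-prefix sim
mixnorm normalize --method mixnorm --matrix sim_matrix.tsv \
    --annotation sim_annotation.tsv --out normalized.tsv --fit-report fits.tsv
mixnorm evaluate-qc --matrix normalized.tsv --annotation sim_annotation.tsv \
    --qc-class qc_pool --out qc_metrics.tsv
```

Input is tab-delimited: a metabolite × sample matrix of log2 peak areas
with `NA` for undetected cells, and an annotation with `sample_id`,
`batch`, `run_order`, `sample_class` columns (extra columns are treated as
phenotypes).

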