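"""Evaluation metrics for normalization quality.

Four families of metrics:

* **RSD** — the relative standard deviation (100 * SD / mean) of a
  metabolite across a sample set; between-QC RSD is purely technical noise,
  so a normalizer is judged by how far it pushes QC RSD back toward the
  pre-batch-effect truth without erasing analytical-sample variability.
* **RSD recovery slopes** — no-intercept regression of post-normalization
  RSD on true RSD, stratified by how often the metabolite went undetected;
  a slope of 1 means the normalizer preserves true variability, below 1
  means it understates it.
* **Phenotype association scans** — per-metabolite tests of normalized
  analytical values against a phenotype, by ordinary least squares on
  detected values or by the downstream mixture model, summarised as true
  and false positive probabilities over simulation rounds.
* **Correlation metrics** — pairwise Spearman correlation between QC
  samples, and Spearman agreement with targeted assays of the same
  compounds when such data are supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .data import AbundanceMatrix, SampleAnnotation, ThresholdSet, compute_batch_thresholds
from .mixture import FitOptions, MixtureDesign, NotFittableError, fit_mixture, wald_test

#: |beta| grid at which true-positive probabilities are reported
DEFAULT_BETA_GRID = (0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 1.0)
#: metabolites with |true beta| below this count as null for false positives
NULL_BETA_CUT = 0.05
SIGNIFICANCE_LEVEL = 0.05

_BIN_WIDTH = 0.05
_BIN_MAX = 0.80


def rsd(values: np.ndarray) -> float:
    """Relative standard deviation in percent: 100 * sample SD / mean.

    Computed over the finite entries of ``values`` (undetected cells enter
    as NaN and are ignored). Returns NaN when fewer than two values remain
    or the mean is zero.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 2:
        return float("nan")
    mean = v.mean()
    if mean == 0:
        return float("nan")
    return float(100.0 * v.std(ddof=1) / mean)


def rsd_table(matrix: AbundanceMatrix, sample_ids: Sequence[str]) -> pd.Series:
    """Per-metabolite RSD% over the detected values of the given samples."""
    sub = matrix.select_samples(list(sample_ids))
    vals = np.where(sub.detected, sub.values, np.nan)
    return pd.Series(
        [rsd(row) for row in vals],
        index=pd.Index(matrix.metabolite_ids, name="metabolite_id"),
        name="rsd",
    )


def missingness_bin(fraction: float) -> str:
    """5%-wide missingness bin label; exact zero is its own bin.

    Bins are left-open/right-closed: "0", "0-5%", "5-10%", ..., "75-80%",
    and ">80%" for metabolites omitted from analysis.
    """
    if not np.isfinite(fraction) or fraction < 0 or fraction > 1:
        raise ValueError(f"fraction must lie in [0, 1], got {fraction}")
    if fraction == 0:
        return "0"
    if fraction > _BIN_MAX:
        return ">80%"
    k = int(np.ceil(fraction / _BIN_WIDTH))
    lo, hi = round((k - 1) * 5), round(k * 5)
    return f"{lo}-{hi}%"


def missingness_bin_labels() -> list[str]:
    """All analysis bins in order (excludes the omitted >80% bin)."""
    labels = ["0"]
    for k in range(int(_BIN_MAX / _BIN_WIDTH)):
        labels.append(f"{round(k * 5)}-{round((k + 1) * 5)}%")
    return labels


def rsd_recovery_slope(
    true_rsd: np.ndarray,
    est_rsd: np.ndarray,
    missing_fraction: np.ndarray,
) -> pd.Series:
    """No-intercept regression slope of estimated on true RSD, per bin.

    Within each missingness bin the slope is sum(true * est) / sum(true^2)
    over all contributing (metabolite, round) pairs; slope 1 indicates the
    normalizer recovers true variability exactly. Pairs with a missing
    estimated RSD and metabolites with > 80% undetected values are omitted;
    an empty bin yields NaN.
    """
    t = np.asarray(true_rsd, dtype=float)
    e = np.asarray(est_rsd, dtype=float)
    f = np.asarray(missing_fraction, dtype=float)
    if not (len(t) == len(e) == len(f)):
        raise ValueError("inputs must be of equal length")
    keep = np.isfinite(t) & np.isfinite(e) & (f <= _BIN_MAX)
    bins = np.array([missingness_bin(x) for x in f[keep]])
    t, e = t[keep], e[keep]
    out = {}
    for label in missingness_bin_labels():
        sel = bins == label
        denom = float(np.sum(t[sel] ** 2))
        out[label] = float(np.sum(t[sel] * e[sel]) / denom) if denom > 0 else float("nan")
    return pd.Series(out, name="slope")


def association_scan(
    matrix: AbundanceMatrix,
    annotation: SampleAnnotation,
    phenotype: str,
    adjustment: Sequence[str] = (),
    analysis: str = "linear",
    thresholds: Optional[ThresholdSet] = None,
    min_samples: int = 10,
    fit_options: Optional[FitOptions] = None,
) -> pd.DataFrame:
    """Per-metabolite association tests against a phenotype column.

    Uses analytical samples only. ``analysis="linear"`` regresses detected
    values on the phenotype (plus adjustments) and reports the two-sided
    t-test; ``analysis="mixture"`` fits the mixture model with the same
    covariates in both components, using batch detection thresholds, and
    reports the Wald test on the linear-component phenotype coefficient.
    Metabolites with fewer than ``min_samples`` usable samples are skipped
    with a reason.
    """
    if analysis not in ("linear", "mixture"):
        raise ValueError("analysis must be 'linear' or 'mixture'")
    an_ids = annotation.analytical_sample_ids()
    if not an_ids:
        raise ValueError("no analytical samples in annotation")
    cols = [phenotype, *adjustment]
    for c in cols:
        if c not in annotation.table.columns:
            raise KeyError(f"phenotype column {c!r} not in annotation")
    covar = annotation.table.loc[an_ids, cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(covar)):
        raise ValueError("phenotype/adjustment values must be present for all samples")
    sub = matrix.select_samples(an_ids)
    design_full = np.column_stack([np.ones(len(an_ids)), covar])
    names = ["intercept", *cols]

    if analysis == "mixture" and thresholds is None:
        detected_any = matrix.detected.any(axis=1)
        if not detected_any.all():
            raise NotFittableError(
                "matrix contains metabolites never detected; filter before scanning"
            )
        thresholds = compute_batch_thresholds(matrix, annotation)
    batches = annotation.batch_of(an_ids)
    fit_options = fit_options or FitOptions(compute_standard_errors=True)

    rows = []
    for i, met in enumerate(matrix.metabolite_ids):
        det = sub.detected[i]
        y = sub.values[i]
        n_used = int(det.sum()) if analysis == "linear" else len(an_ids)
        if int(det.sum()) < min_samples:
            rows.append((met, np.nan, np.nan, np.nan, np.nan, int(det.sum()),
                         "skipped: fewer than min_samples detected"))
            continue
        try:
            if analysis == "linear" or det.all():
                res = sm.OLS(y[det], design_full[det]).fit()
                j = names.index(phenotype)
                rows.append((met, res.params[j], res.bse[j], res.tvalues[j],
                             res.pvalues[j], int(det.sum()), "ok"))
            else:
                design = MixtureDesign(design_full, design_full, names, list(names))
                t_i = thresholds.per_sample(met, batches)
                fit = fit_mixture(y, det, design, t_i, fit_options, metabolite_id=met)
                if not fit.converged:
                    rows.append((met, np.nan, np.nan, np.nan, np.nan, n_used,
                                 "skipped: mixture fit did not converge"))
                    continue
                w = wald_test(fit, phenotype, "linear")
                rows.append((met, w.estimate, w.std_error, w.z_value, w.p_value,
                             n_used, "ok"))
        except (NotFittableError, ValueError, np.linalg.LinAlgError) as exc:
            rows.append((met, np.nan, np.nan, np.nan, np.nan, n_used,
                         f"skipped: {exc}"))
    return pd.DataFrame(
        rows,
        columns=["metabolite_id", "estimate", "std_error", "statistic",
                 "p_value", "n_used", "status"],
    ).set_index("metabolite_id")


def power_summary(
    p_values: pd.Series,
    true_beta: pd.Series,
    beta_grid: Sequence[float] = DEFAULT_BETA_GRID,
    null_cut: float = NULL_BETA_CUT,
    alpha: float = SIGNIFICANCE_LEVEL,
) -> pd.DataFrame:
    """True/false positive probabilities over pooled association tests.

    ``p_values`` is indexed by metabolite id (repeated across rounds is
    fine); ``true_beta`` maps metabolite id to its simulated association
    strength. The true-positive probability at grid value t is the fraction
    of tests with |beta| >= t rejected at ``alpha``; the false-positive
    probability is the rejection rate among tests with |beta| < ``null_cut``.
    Missing p-values (skipped metabolites) count as non-rejections.
    """
    beta = true_beta.reindex(p_values.index).to_numpy(dtype=float)
    if np.isnan(beta).any():
        raise KeyError("true_beta is missing some scanned metabolites")
    p = p_values.to_numpy(dtype=float)
    reject = np.where(np.isfinite(p), p < alpha, False)
    rows = []
    for t in beta_grid:
        sel = np.abs(beta) >= t
        prob = float(reject[sel].mean()) if sel.any() else float("nan")
        rows.append(("true_positive", t, prob, int(sel.sum())))
    null = np.abs(beta) < null_cut
    fp = float(reject[null].mean()) if null.any() else float("nan")
    rows.append(("false_positive", null_cut, fp, int(null.sum())))
    return pd.DataFrame(
        rows, columns=["kind", "beta_threshold", "probability", "n_tests"]
    )


@dataclass
class EvaluationReport:
    """Aggregated benchmark output.

    ``rsd_summary``: per (method, sample class) mean/min/max of pooled
    per-metabolite RSD%. ``slope_table``: per method, the no-intercept
    RSD-recovery slope in each missingness bin. ``power_table``: per
    (method, analysis), true/false positive probabilities over the |beta|
    grid. ``per_metabolite_rsd``: the long table the summaries pool, with
    explicit NaN for metabolites whose RSD was not computable.
    """

    rsd_summary: pd.DataFrame
    slope_table: pd.DataFrame
    power_table: Optional[pd.DataFrame]
    per_metabolite_rsd: pd.DataFrame = None
    correlation_summary: Optional[pd.DataFrame] = None

    def write(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.rsd_summary.to_csv(out / "rsd_summary.tsv", sep="\t")
        self.slope_table.to_csv(out / "slope_table.tsv", sep="\t")
        if self.power_table is not None:
            self.power_table.to_csv(out / "power_table.tsv", sep="\t", index=False)
        if self.per_metabolite_rsd is not None:
            self.per_metabolite_rsd.to_csv(
                out / "per_metabolite_rsd.tsv", sep="\t", index=False
            )
        if self.correlation_summary is not None:
            self.correlation_summary.to_csv(
                out / "correlation_summary.tsv", sep="\t", index=False
            )


@dataclass
class CorrelationSummary:
    mean: float
    min: float
    max: float
    n_pairs: int
    per_pair: pd.DataFrame = field(repr=False, default=None)


def pairwise_qc_spearman(
    matrix: AbundanceMatrix,
    annotation: SampleAnnotation,
    qc_class: str,
    min_detection: float = 0.2,
) -> CorrelationSummary:
    """Pairwise Spearman correlations between QC samples of one pool type.

    Metabolites are restricted to those detected in at least
    ``min_detection`` of all samples; each unordered QC pair is correlated
    over its pairwise-complete metabolites (average ranks for ties).
    """
    qc_ids = [
        s for s, c in zip(annotation.sample_ids, annotation.class_of(annotation.sample_ids))
        if c == qc_class
    ]
    if len(qc_ids) < 2:
        raise ValueError(f"fewer than two QC samples of class {qc_class!r}")
    keep = matrix.detection_fraction() >= min_detection
    sub = matrix.select_samples(qc_ids)
    vals = np.where(sub.detected, sub.values, np.nan)[keep]
    rows = []
    for a in range(len(qc_ids)):
        for b in range(a + 1, len(qc_ids)):
            pair = vals[:, [a, b]]
            complete = np.isfinite(pair).all(axis=1)
            if complete.sum() < 2:
                rho = float("nan")
            else:
                rho = float(stats.spearmanr(pair[complete, 0], pair[complete, 1]).statistic)
            rows.append((qc_ids[a], qc_ids[b], rho, int(complete.sum())))
    per_pair = pd.DataFrame(rows, columns=["sample_a", "sample_b", "spearman", "n_metabolites"])
    rho = per_pair["spearman"].dropna()
    return CorrelationSummary(
        mean=float(rho.mean()), min=float(rho.min()), max=float(rho.max()),
        n_pairs=len(per_pair), per_pair=per_pair,
    )


def targeted_correlation(
    nontargeted: AbundanceMatrix,
    targeted: pd.DataFrame,
    mapping: dict[str, str],
    annotation: SampleAnnotation,
) -> pd.DataFrame:
    """Spearman agreement of non-targeted metabolites with targeted assays.

    ``targeted`` is indexed by sample id with one column per analyte;
    ``mapping`` links non-targeted metabolite ids to targeted analyte
    columns. Correlations are computed per analyte within each analytical
    sample class over pairwise-complete observations; rows with
    ``analyte == "<summary>"`` carry the per-class mean/min/max.
    """
    if not mapping:
        raise ValueError("empty metabolite-to-analyte mapping")
    shared = [s for s in nontargeted.sample_ids if s in targeted.index]
    if not shared:
        raise ValueError("no shared sample ids between non-targeted and targeted data")
    classes = annotation.class_of(shared)
    rows = []
    for cls in dict.fromkeys(classes):
        ids = [s for s, c in zip(shared, classes) if c == cls]
        sub = nontargeted.select_samples(ids)
        for met, analyte in mapping.items():
            if met not in nontargeted.metabolite_ids or analyte not in targeted.columns:
                raise KeyError(f"mapping entry ({met!r}, {analyte!r}) not found in data")
            i = sub.metabolite_index(met)
            x = np.where(sub.detected[i], sub.values[i], np.nan)
            y = targeted.loc[ids, analyte].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            rho = float(stats.spearmanr(x[ok], y[ok]).statistic) if ok.sum() >= 2 else float("nan")
            rows.append((cls, analyte, met, rho, int(ok.sum())))
    out = pd.DataFrame(
        rows, columns=["sample_class", "analyte", "metabolite_id", "spearman", "n_samples"]
    )
    summaries = []
    for cls, grp in out.groupby("sample_class", sort=False):
        rho = grp["spearman"].dropna()
        summaries.append((cls, "<summary>", "", float(rho.mean()), len(rho)))
        summaries.append((cls, "<summary_min>", "", float(rho.min()), len(rho)))
        summaries.append((cls, "<summary_max>", "", float(rho.max()), len(rho)))
    return pd.concat(
        [out, pd.DataFrame(summaries, columns=out.columns)], ignore_index=True
    )
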