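"""Location-shift normalization of batch and run-order effects.

The central method fits the mixture model of :mod:`mixnorm.mixture` to the
QC samples of every metabolite — batch indicators (and optionally QC pool
type and a run-order term) enter both the presence and mean components —
and then subtracts the fitted technical terms from *all* samples, QC and
analytical alike. Undetected cells are never imputed and never change.

Three standard comparators operating on detected values only are provided:
per-batch mean centering, per-batch median scaling, and quantile
normalization across samples. External normalizers can be registered as
plug-ins so third-party methods can enter an evaluation without being
reimplemented here.
"""

from __future__ import annotations

import logging
import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .data import (
    AbundanceMatrix,
    SampleAnnotation,
    ThresholdSet,
    ValidationError,
    compute_batch_thresholds,
    read_dataset,
    write_dataset,
)
from .mixture import FitOptions, MixtureDesign, MixtureFit, NotFittableError, fit_mixture

logger = logging.getLogger("mixnorm")

#: run-order covariate tokens and the transform each applies to run order
RUN_ORDER_FORMS = {
    "log_run_order": np.log,
    "run_order": lambda r: r,
    "run_order_sq": lambda r: r**2,
}
_COVARIATE_TOKENS = ("batch", "qc_type", *RUN_ORDER_FORMS)


@dataclass
class MixnormSpec:
    """Covariate and filtering choices for a mixnorm fit.

    ``x_covariates`` feed the logistic presence component, ``z_covariates``
    the linear mean component; ``x`` may be a subset of ``z`` when sparse
    non-detects make the full logistic model fragile. Batch indicators use
    the batch whose QC median abundance is the median across batches as the
    referent (per metabolite). Metabolites detected in fewer than
    ``min_detection_fraction`` of all samples are excluded from fitting.
    ``qc_outlier_sd`` optionally drops QC observations farther than that
    many SDs from the metabolite's QC mean before fitting (off by default).
    """

    x_covariates: tuple[str, ...] = ("batch",)
    z_covariates: tuple[str, ...] = ("batch",)
    min_detection_fraction: float = 0.2
    qc_outlier_sd: Optional[float] = None
    fit_options: FitOptions = field(default_factory=FitOptions)

    def __post_init__(self) -> None:
        for tokens in (self.x_covariates, self.z_covariates):
            unknown = [t for t in tokens if t not in _COVARIATE_TOKENS]
            if unknown:
                raise ValueError(
                    f"unknown covariate token(s) {unknown}; valid: {_COVARIATE_TOKENS}"
                )


@dataclass
class NormalizationModel:
    """Fitted per-metabolite location-shift corrections.

    ``batch_coefficients`` has one row per normalizable metabolite and one
    column per batch, with the referent batch at exactly zero. Excluded
    metabolites (below the detection filter, nothing detected in QCs, or a
    non-converged fit) are listed in ``excluded`` with a reason and pass
    through :func:`apply_mixnorm` unchanged.
    """

    spec: MixnormSpec
    batches: list[str]
    qc_classes: list[str]
    referent_qc_class: Optional[str]
    batch_coefficients: pd.DataFrame
    run_order_coefficients: pd.DataFrame
    qc_type_coefficients: pd.DataFrame
    sigma: pd.Series
    referent_batch: pd.Series
    thresholds: ThresholdSet
    fits: dict[str, MixtureFit] = field(repr=False, default_factory=dict)
    excluded: dict[str, str] = field(default_factory=dict)

    @property
    def normalizable(self) -> list[str]:
        return list(self.batch_coefficients.index)

    def fit_report(self) -> pd.DataFrame:
        """One row per input metabolite: convergence, sigma, status."""
        rows = []
        for met in self.normalizable:
            fit = self.fits[met]
            rows.append(
                (met, "normalized", fit.converged, fit.n_detected,
                 fit.n_undetected, float(self.sigma[met]),
                 self.referent_batch[met], fit.neg_log_lik)
            )
        for met, reason in self.excluded.items():
            rows.append((met, reason, False, np.nan, np.nan, np.nan, "", np.nan))
        return pd.DataFrame(
            rows,
            columns=["metabolite_id", "status", "converged", "n_detected",
                     "n_undetected", "sigma", "referent_batch", "neg_log_lik"],
        ).set_index("metabolite_id")


def _referent_batch(qc_values: np.ndarray, qc_detected: np.ndarray,
                    qc_batches: np.ndarray, batches: list[str]) -> str:
    """Batch whose detected-QC median is the median across batch medians;
    ties break toward the lower batch label."""
    medians = {}
    for b in batches:
        sel = (qc_batches == b) & qc_detected
        if sel.any():
            medians[b] = float(np.median(qc_values[sel]))
    target = float(np.median(list(medians.values())))
    return min(medians, key=lambda b: (abs(medians[b] - target), b))


def _build_design(
    annotation_rows: pd.DataFrame,
    tokens: Sequence[str],
    batches: list[str],
    referent_batch: str,
    qc_classes: list[str],
    referent_qc_class: Optional[str],
    batch_subset: Optional[set[str]] = None,
) -> tuple[np.ndarray, list[str]]:
    cols: list[np.ndarray] = [np.ones(len(annotation_rows))]
    names = ["intercept"]
    if "batch" in tokens:
        b = annotation_rows["batch"].to_numpy()
        for batch in batches:
            if batch == referent_batch:
                continue
            if batch_subset is not None and batch not in batch_subset:
                continue
            cols.append((b == batch).astype(float))
            names.append(f"batch:{batch}")
    if "qc_type" in tokens and len(qc_classes) > 1:
        c = annotation_rows["sample_class"].to_numpy()
        for cls in qc_classes:
            if cls == referent_qc_class:
                continue
            cols.append((c == cls).astype(float))
            names.append(f"qc_type:{cls}")
    for token, form in RUN_ORDER_FORMS.items():
        if token in tokens:
            cols.append(form(annotation_rows["run_order"].to_numpy(dtype=float)))
            names.append(token)
    return np.column_stack(cols), names


def fit_mixnorm(
    matrix: AbundanceMatrix,
    annotation: SampleAnnotation,
    spec: Optional[MixnormSpec] = None,
) -> NormalizationModel:
    """Estimate batch and run-order effects from QC samples, per metabolite.

    Every batch must contain at least one QC sample; batch and run-order
    effects are estimated jointly across all QC pool types. Detection
    thresholds are the per-metabolite batch minima over all samples.
    """
    spec = spec or MixnormSpec()
    qc_ids = annotation.qc_sample_ids()
    if not qc_ids:
        raise ValidationError("no QC samples in annotation")
    batches = annotation.batches
    qc_batch_set = set(annotation.batch_of(qc_ids))
    missing = [b for b in batches if b not in qc_batch_set]
    if missing:
        raise ValidationError(f"batch(es) without QC samples: {missing}")
    qc_classes = annotation.qc_classes
    referent_qc_class = qc_classes[0] if len(qc_classes) > 1 else (
        qc_classes[0] if qc_classes else None
    )

    frac = matrix.detection_fraction()
    excluded: dict[str, str] = {}
    fit_ids = []
    for met, f in zip(matrix.metabolite_ids, frac):
        if f == 0:
            excluded[met] = "excluded: no detections anywhere"
        elif f < spec.min_detection_fraction:
            excluded[met] = (
                f"excluded: detected in {f:.1%} of samples, below the "
                f"{spec.min_detection_fraction:.0%} filter"
            )
        else:
            fit_ids.append(met)
    if excluded:
        logger.info("mixnorm: %d metabolite(s) below detection filter", len(excluded))
    work = matrix.select_metabolites(fit_ids) if fit_ids else None
    if work is None:
        raise ValidationError("no metabolite passes the detection filter")
    thresholds = compute_batch_thresholds(work, annotation)

    qc_rows = annotation.table.loc[qc_ids]
    qc_batches = annotation.batch_of(qc_ids)
    qc_cols = matrix.sample_indexer(qc_ids)

    fits: dict[str, MixtureFit] = {}
    referents: dict[str, str] = {}
    batch_rows, ro_rows, qt_rows, sigma_rows = {}, {}, {}, {}
    ro_tokens = [t for t in RUN_ORDER_FORMS if t in spec.z_covariates]

    for i, met in enumerate(work.metabolite_ids):
        row = matrix.metabolite_index(met)
        y = matrix.values[row, qc_cols]
        det = matrix.detected[row, qc_cols]
        if det.sum() == 0:
            excluded[met] = "excluded: no detected QC values"
            continue
        keep = np.ones(len(qc_ids), dtype=bool)
        if spec.qc_outlier_sd is not None and det.sum() >= 3:
            mu, sd = y[det].mean(), y[det].std(ddof=1)
            if sd > 0:
                keep = ~(det & (np.abs(y - mu) > spec.qc_outlier_sd * sd))
                if (~keep).any():
                    logger.info(
                        "mixnorm: %s: dropped %d outlying QC observation(s)",
                        met, int((~keep).sum()),
                    )
        ref = _referent_batch(y[keep], det[keep], qc_batches[keep], batches)
        rows_ann = qc_rows.loc[keep]
        # The mean-model coefficient of a batch with no detected QC
        # observation is not identifiable (the likelihood is maximised on
        # the boundary where that batch's presence probability vanishes),
        # so its indicator enters the logistic component only; its location
        # correction is reported as unidentified (NaN) and applied as zero.
        identified = {
            b for b in batches if ((qc_batches[keep] == b) & det[keep]).any()
        }
        try:
            x, x_names = _build_design(
                rows_ann, spec.x_covariates, batches, ref, qc_classes, referent_qc_class
            )
            z, z_names = _build_design(
                rows_ann, spec.z_covariates, batches, ref, qc_classes,
                referent_qc_class, batch_subset=identified,
            )
            design = MixtureDesign(x, z, x_names, z_names)
            t_i = thresholds.per_sample(met, qc_batches[keep])
            fit = fit_mixture(
                y[keep], det[keep], design, t_i, spec.fit_options, metabolite_id=met
            )
        except (NotFittableError, ValueError) as exc:
            excluded[met] = f"excluded: {exc}"
            continue
        if not fit.converged:
            excluded[met] = "excluded: mixture fit did not converge"
            continue
        fits[met] = fit
        referents[met] = ref
        coef = dict(zip(z_names, fit.params.alpha))
        if "batch" in spec.z_covariates:
            batch_rows[met] = [
                0.0 if b == ref else coef.get(f"batch:{b}", np.nan) for b in batches
            ]
        else:
            batch_rows[met] = [0.0] * len(batches)
        ro_rows[met] = [coef.get(t, 0.0) for t in ro_tokens]
        qt_rows[met] = [
            0.0 if c == referent_qc_class else coef.get(f"qc_type:{c}", 0.0)
            for c in qc_classes
        ]
        sigma_rows[met] = fit.params.sigma

    if not fits:
        raise ValidationError("mixnorm fit failed for every metabolite")
    idx = pd.Index(list(fits), name="metabolite_id")
    return NormalizationModel(
        spec=spec,
        batches=batches,
        qc_classes=qc_classes,
        referent_qc_class=referent_qc_class,
        batch_coefficients=pd.DataFrame(
            [batch_rows[m] for m in idx], index=idx, columns=batches
        ),
        run_order_coefficients=pd.DataFrame(
            [ro_rows[m] for m in idx], index=idx, columns=ro_tokens
        ),
        qc_type_coefficients=pd.DataFrame(
            [qt_rows[m] for m in idx], index=idx, columns=qc_classes
        ),
        sigma=pd.Series({m: sigma_rows[m] for m in idx}, name="sigma"),
        referent_batch=pd.Series(referents, name="referent_batch"),
        thresholds=thresholds,
        fits=fits,
        excluded=excluded,
    )


def apply_mixnorm(
    model: NormalizationModel,
    matrix: AbundanceMatrix,
    annotation: SampleAnnotation,
    apply_qc_type_shift: bool = False,
    analytical_class_map: Optional[dict[str, str]] = None,
    anchor: str = "grand_mean",
) -> AbundanceMatrix:
    """Subtract fitted batch/run-order shifts from every detected cell.

    With ``anchor="grand_mean"`` (default) the unweighted mean of the batch
    coefficients is added back after subtraction, so normalized values sit
    at the cross-batch average and the output is invariant to the referent
    choice; ``anchor="referent"`` leaves values at the referent batch's
    location. QC pool-type shifts are applied to analytical samples only
    when ``apply_qc_type_shift`` is set, using ``analytical_class_map`` to
    map analytical sample classes to QC pool types. Undetected cells are
    untouched; metabolites the model excluded pass through unchanged.
    """
    if anchor not in ("grand_mean", "referent"):
        raise ValueError("anchor must be 'grand_mean' or 'referent'")
    sample_batches = annotation.batch_of(matrix.sample_ids)
    unknown = sorted(set(sample_batches) - set(model.batches))
    if unknown:
        raise ValidationError(f"sample batch(es) absent from model: {unknown}")
    run_order = annotation.run_order_of(matrix.sample_ids).astype(float)
    classes = annotation.class_of(matrix.sample_ids)

    out = matrix.copy()
    batch_pos = {b: k for k, b in enumerate(model.batches)}
    col_batch = np.array([batch_pos[b] for b in sample_batches])
    ro_design = np.column_stack(
        [RUN_ORDER_FORMS[t](run_order) for t in model.run_order_coefficients.columns]
    ) if len(model.run_order_coefficients.columns) else None

    for met in model.normalizable:
        row = matrix.metabolite_index(met)
        bc = model.batch_coefficients.loc[met].to_numpy()
        # NaN marks a batch whose location shift was unidentified (no
        # detected QC observation): those samples receive zero correction.
        shift = np.nan_to_num(bc)[col_batch]
        if ro_design is not None:
            shift = shift + ro_design @ model.run_order_coefficients.loc[met].to_numpy()
        if apply_qc_type_shift and len(model.qc_classes) > 1:
            qt = model.qc_type_coefficients.loc[met]
            for j, cls in enumerate(classes):
                mapped = (analytical_class_map or {}).get(cls)
                if mapped is not None:
                    shift[j] += float(qt[mapped])
        if anchor == "grand_mean":
            # uniform add-back of the mean identified batch coefficient:
            # a constant per metabolite, so spread is unaffected and the
            # output does not depend on which batch was the referent
            shift = shift - np.nanmean(bc)
        out.values[row] = np.where(
            out.detected[row], out.values[row] - shift, out.values[row]
        )
    return out


def mean_center(matrix: AbundanceMatrix, annotation: SampleAnnotation) -> AbundanceMatrix:
    """Per metabolite, subtract (batch mean - grand mean) of detected values
    from every detected cell of the batch; batches where the metabolite has
    no detection are left uncorrected."""
    out = matrix.copy()
    sample_batches = annotation.batch_of(matrix.sample_ids)
    vals = np.where(matrix.detected, matrix.values, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        grand = np.nanmean(vals, axis=1)
    for batch in annotation.batches:
        cols = sample_batches == batch
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            bmean = np.nanmean(vals[:, cols], axis=1)
        absent = np.isnan(bmean)
        if absent.any():
            logger.debug(
                "mean_center: %d metabolite(s) undetected in batch %s",
                int(absent.sum()), batch,
            )
        shift = np.where(absent, 0.0, bmean - grand)
        block = out.values[:, cols]
        out.values[:, cols] = np.where(
            out.detected[:, cols], block - shift[:, None], block
        )
    return out


def median_scale(matrix: AbundanceMatrix, annotation: SampleAnnotation) -> AbundanceMatrix:
    """Per metabolite, divide detected cells by (batch median / overall
    median) of detected values; requires a positive overall median on the
    working (log2) scale."""
    out = matrix.copy()
    sample_batches = annotation.batch_of(matrix.sample_ids)
    vals = np.where(matrix.detected, matrix.values, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        overall = np.nanmedian(vals, axis=1)
    bad = np.isfinite(overall) & (overall <= 0)
    if bad.any():
        names = [m for m, b in zip(matrix.metabolite_ids, bad) if b]
        raise ValidationError(
            f"non-positive overall median for metabolite(s) {names}; median "
            "scaling is defined for positive log2 peak areas"
        )
    for batch in annotation.batches:
        cols = sample_batches == batch
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            bmed = np.nanmedian(vals[:, cols], axis=1)
        with np.errstate(invalid="ignore"):
            ratio = np.where(
                np.isnan(bmed) | np.isnan(overall), 1.0, bmed / overall
            )
        block = out.values[:, cols]
        out.values[:, cols] = np.where(
            out.detected[:, cols], block / ratio[:, None], block
        )
    return out


def quantile_norm(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Quantile normalization on detected values, per sample column.

    Each sample's detected values are mapped onto the mean empirical
    quantile curve across samples, with linear interpolation where detected
    counts differ; ties receive the mean of their target quantiles. Samples
    with fewer than two detected values pass through unchanged.
    """
    out = matrix.copy()
    n_det = matrix.detected.sum(axis=0)
    usable = n_det >= 2
    if (~usable).any():
        logger.info(
            "quantile_norm: %d sample(s) with <2 detected values passed through",
            int((~usable).sum()),
        )
    if not usable.any():
        return out
    grid_n = int(n_det[usable].max())
    grid = np.linspace(0.0, 1.0, grid_n)
    curves = []
    for j in np.nonzero(usable)[0]:
        v = np.sort(matrix.values[matrix.detected[:, j], j])
        q = np.linspace(0.0, 1.0, len(v))
        curves.append(np.interp(grid, q, v))
    reference = np.mean(curves, axis=0)
    from scipy.stats import rankdata

    for j in np.nonzero(usable)[0]:
        det = matrix.detected[:, j]
        v = matrix.values[det, j]
        q = (rankdata(v, method="average") - 1.0) / (len(v) - 1.0)
        out.values[det, j] = np.interp(q, grid, reference)
    return out


# ---------------------------------------------------------------------------
# method registry / plug-in hook

Normalizer = Callable[[AbundanceMatrix, SampleAnnotation], AbundanceMatrix]

_REGISTRY: dict[str, Normalizer] = {}


def register_normalizer(name: str, func: Normalizer) -> None:
    """Register a plug-in normalizer under ``name`` for use in evaluations."""
    _REGISTRY[name.lower()] = func


def external_normalizer(executable: Sequence[str]) -> Normalizer:
    """Wrap an external executable as a normalizer plug-in.

    The executable is invoked as ``<executable...> <matrix.tsv>
    <annotation.tsv> <out.tsv>`` using this package's TSV dialect, so
    third-party methods can enter an evaluation without reimplementation.
    """

    def run(matrix: AbundanceMatrix, annotation: SampleAnnotation) -> AbundanceMatrix:
        with tempfile.TemporaryDirectory() as tmp:
            m_path = Path(tmp) / "matrix.tsv"
            a_path = Path(tmp) / "annotation.tsv"
            o_path = Path(tmp) / "normalized.tsv"
            write_dataset(matrix, annotation, m_path, a_path)
            subprocess.run(
                [*executable, str(m_path), str(a_path), str(o_path)], check=True
            )
            normalized, _ = read_dataset(o_path, a_path)
            return normalized

    return run


def normalize_by_name(
    method: str,
    matrix: AbundanceMatrix,
    annotation: SampleAnnotation,
    spec: Optional[MixnormSpec] = None,
    apply_qc_type_shift: bool = False,
) -> AbundanceMatrix:
    """Dispatch a normalization method by name.

    Built-ins: ``none``, ``mixnorm``, ``mean_center``, ``median_scale``,
    ``quantile``; any name registered via :func:`register_normalizer` is
    also accepted.
    """
    key = method.lower()
    if key == "none":
        return matrix.copy()
    if key == "mixnorm":
        model = fit_mixnorm(matrix, annotation, spec)
        return apply_mixnorm(model, matrix, annotation, apply_qc_type_shift)
    if key == "mean_center":
        return mean_center(matrix, annotation)
    if key == "median_scale":
        return median_scale(matrix, annotation)
    if key == "quantile":
        return quantile_norm(matrix)
    if key in _REGISTRY:
        return _REGISTRY[key](matrix, annotation)
    raise ValueError(f"unknown normalization method {method!r}")
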