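"""Core data containers and TSV I/O for metabolite abundance experiments.

The working scale throughout is log2-transformed MS peak area. A dataset is
a pair of tab-delimited files:

* the abundance matrix, one row per metabolite, one column per sample, with
  undetected cells written as ``NA`` (empty cells are also accepted on read);
* the sample annotation, one row per sample, with required columns
  ``sample_id``, ``batch``, ``run_order`` and ``sample_class``; any further
  columns are treated as real-valued phenotype covariates.

Undetected cells are carried as an explicit boolean mask rather than being
imputed: every downstream computation either ignores them or models them as
left-truncated at a batch-specific detection threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: sample_class value denoting samples of analytical interest; anything else
#: is treated as a named QC pool type.
ANALYTICAL = "analytical"

_MISSING_TOKENS = ("", "NA")


class ValidationError(ValueError):
    """Raised when an input file or object violates the data contract."""


@dataclass
class AbundanceMatrix:
    """Log2 peak areas (metabolites x samples) with an explicit detection mask.

    Where ``detected`` is False the corresponding entry of ``values`` is
    undefined and ignored by all computation (it is stored as NaN).
    """

    values: np.ndarray
    detected: np.ndarray
    metabolite_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.detected = np.asarray(self.detected, dtype=bool)
        if self.values.shape != self.detected.shape:
            raise ValidationError(
                f"values shape {self.values.shape} != detected shape "
                f"{self.detected.shape}"
            )
        if self.values.shape != (len(self.metabolite_ids), len(self.sample_ids)):
            raise ValidationError(
                "matrix shape does not match id lists: "
                f"{self.values.shape} vs ({len(self.metabolite_ids)}, "
                f"{len(self.sample_ids)})"
            )
        for name, ids in (
            ("metabolite_ids", self.metabolite_ids),
            ("sample_ids", self.sample_ids),
        ):
            dup = _duplicates(ids)
            if dup:
                raise ValidationError(f"duplicate {name}: {sorted(dup)}")
        if not np.all(np.isfinite(self.values[self.detected])):
            bad = np.argwhere(~np.isfinite(self.values) & self.detected)
            i, j = bad[0]
            raise ValidationError(
                "non-finite detected value at metabolite "
                f"{self.metabolite_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )
        # canonical storage: undefined cells are NaN
        self.values = np.where(self.detected, self.values, np.nan)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def metabolite_index(self, metabolite_id: str) -> int:
        return self.metabolite_ids.index(metabolite_id)

    def sample_indexer(self, sample_ids) -> np.ndarray:
        pos = {s: k for k, s in enumerate(self.sample_ids)}
        try:
            return np.array([pos[s] for s in sample_ids], dtype=int)
        except KeyError as exc:
            raise ValidationError(f"unknown sample id {exc.args[0]!r}") from exc

    def select_samples(self, sample_ids) -> "AbundanceMatrix":
        idx = self.sample_indexer(sample_ids)
        return AbundanceMatrix(
            self.values[:, idx],
            self.detected[:, idx],
            list(self.metabolite_ids),
            list(sample_ids),
        )

    def select_metabolites(self, metabolite_ids) -> "AbundanceMatrix":
        pos = {m: k for k, m in enumerate(self.metabolite_ids)}
        try:
            idx = np.array([pos[m] for m in metabolite_ids], dtype=int)
        except KeyError as exc:
            raise ValidationError(f"unknown metabolite id {exc.args[0]!r}") from exc
        return AbundanceMatrix(
            self.values[idx],
            self.detected[idx],
            list(metabolite_ids),
            list(self.sample_ids),
        )

    def detection_fraction(self) -> np.ndarray:
        """Per-metabolite fraction of samples in which it was detected."""
        return self.detected.mean(axis=1)

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(
            self.values.copy(),
            self.detected.copy(),
            list(self.metabolite_ids),
            list(self.sample_ids),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.where(self.detected, self.values, np.nan),
            index=pd.Index(self.metabolite_ids, name="metabolite_id"),
            columns=self.sample_ids,
        )


@dataclass
class SampleAnnotation:
    """Per-sample technical metadata: batch, run order, class, phenotypes."""

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("sample_id", "batch", "run_order", "sample_class")

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise ValidationError(f"annotation missing required columns: {missing}")
        dup = _duplicates(t["sample_id"].tolist())
        if dup:
            raise ValidationError(f"duplicate sample_id in annotation: {sorted(dup)}")
        t = t.copy()
        t["batch"] = t["batch"].astype(str)
        t["sample_class"] = t["sample_class"].astype(str)
        try:
            t["run_order"] = t["run_order"].astype(int)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"run_order must be integer: {exc}") from exc
        if (t["run_order"] < 1).any():
            raise ValidationError("run_order must be a positive integer")
        for batch, grp in t.groupby("batch"):
            if grp["run_order"].duplicated().any():
                raise ValidationError(
                    f"duplicate run_order within batch {batch!r}"
                )
        self.table = t.set_index("sample_id", drop=False)

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def batches(self) -> list[str]:
        """Batch labels in order of first appearance."""
        return list(dict.fromkeys(self.table["batch"]))

    @property
    def phenotype_columns(self) -> list[str]:
        return [c for c in self.table.columns if c not in self.REQUIRED]

    def batch_of(self, sample_ids) -> np.ndarray:
        return self.table.loc[list(sample_ids), "batch"].to_numpy()

    def run_order_of(self, sample_ids) -> np.ndarray:
        return self.table.loc[list(sample_ids), "run_order"].to_numpy()

    def class_of(self, sample_ids) -> np.ndarray:
        return self.table.loc[list(sample_ids), "sample_class"].to_numpy()

    def is_qc(self) -> pd.Series:
        return self.table["sample_class"] != ANALYTICAL

    @property
    def qc_classes(self) -> list[str]:
        qc = self.table.loc[self.is_qc(), "sample_class"]
        return list(dict.fromkeys(qc))

    def qc_sample_ids(self) -> list[str]:
        return self.table.loc[self.is_qc(), "sample_id"].tolist()

    def analytical_sample_ids(self) -> list[str]:
        return self.table.loc[~self.is_qc(), "sample_id"].tolist()

    def subset(self, sample_ids) -> "SampleAnnotation":
        return SampleAnnotation(
            self.table.loc[list(sample_ids)].reset_index(drop=True)
        )


@dataclass
class ThresholdSet:
    """Per-metabolite, per-batch detection thresholds (log2 intensity).

    ``table`` has one row per metabolite and one column per batch; entry
    (m, k) is the detectability floor T used for samples of batch k when
    modelling metabolite m.
    """

    table: pd.DataFrame

    def threshold(self, metabolite_id: str, batch: str) -> float:
        return float(self.table.at[metabolite_id, str(batch)])

    def per_sample(self, metabolite_id: str, batches) -> np.ndarray:
        """Threshold vector aligned with a sequence of sample batch labels."""
        row = self.table.loc[metabolite_id]
        return row.loc[[str(b) for b in batches]].to_numpy(dtype=float)


def _duplicates(items) -> set:
    seen: set = set()
    dup: set = set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


def read_dataset(matrix_path, annotation_path) -> tuple[AbundanceMatrix, SampleAnnotation]:
    """Read and cross-validate an abundance matrix and its sample annotation.

    Undetected cells are encoded as an empty field or the literal ``NA``.
    Raises :class:`ValidationError` naming the offending row/column on a
    malformed header, duplicate ids, a non-numeric detected cell, or a
    matrix sample missing from the annotation.
    """
    # header=None so duplicate sample columns are caught rather than mangled
    raw = pd.read_csv(
        matrix_path,
        sep="\t",
        dtype=str,
        keep_default_na=False,
        header=None,
    )
    header = [str(c) for c in raw.iloc[0]]
    if len(header) < 2 or header[0] != "metabolite_id":
        raise ValidationError(
            f"{matrix_path}: header must start with 'metabolite_id' followed "
            "by sample ids"
        )
    raw = raw.iloc[1:]
    metabolite_ids = raw.iloc[:, 0].astype(str).tolist()
    sample_ids = header[1:]
    dup = _duplicates(sample_ids)
    if dup:
        raise ValidationError(f"{matrix_path}: duplicate sample columns {sorted(dup)}")
    dup = _duplicates(metabolite_ids)
    if dup:
        raise ValidationError(f"{matrix_path}: duplicate metabolite rows {sorted(dup)}")

    cells = raw.iloc[:, 1:].to_numpy(dtype=object)
    detected = ~np.isin(cells, _MISSING_TOKENS)
    values = np.full(cells.shape, np.nan)
    for i, j in zip(*np.nonzero(detected)):
        try:
            values[i, j] = float(cells[i, j])
        except ValueError:
            raise ValidationError(
                f"{matrix_path}: non-numeric cell {cells[i, j]!r} at "
                f"metabolite {metabolite_ids[i]!r}, sample {sample_ids[j]!r}"
            ) from None

    matrix = AbundanceMatrix(values, detected, metabolite_ids, sample_ids)

    ann_table = pd.read_csv(annotation_path, sep="\t", dtype={"sample_id": str})
    annotation = SampleAnnotation(ann_table)

    ann_ids = set(annotation.sample_ids)
    missing = [s for s in sample_ids if s not in ann_ids]
    if missing:
        raise ValidationError(
            f"annotation {annotation_path} lacks matrix sample(s): {missing}"
        )
    # align annotation to matrix column order, dropping annotation-only rows
    annotation = annotation.subset(sample_ids)
    return matrix, annotation


def write_dataset(
    matrix: AbundanceMatrix,
    annotation: SampleAnnotation,
    matrix_path,
    annotation_path,
) -> None:
    """Write the TSV pair; undetected cells are written as ``NA``."""
    frame = matrix.to_frame()
    frame.to_csv(matrix_path, sep="\t", na_rep="NA", float_format="%.12g")
    annotation.table.reset_index(drop=True).to_csv(
        annotation_path, sep="\t", index=False
    )


def compute_batch_thresholds(
    matrix: AbundanceMatrix, annotation: SampleAnnotation
) -> ThresholdSet:
    """Per-metabolite, per-batch detection thresholds.

    T(metabolite, batch) is the minimum detected value of that metabolite
    among all samples (QC and analytical) run in the batch — detectability
    is a property of the instrument run, not of sample class. When a
    metabolite has no detection in a batch, T falls back to the metabolite's
    global minimum detected value so the truncation probability stays
    computable. A metabolite detected nowhere has no threshold: callers must
    filter such metabolites out first.
    """
    batches = annotation.batches
    sample_batches = annotation.batch_of(matrix.sample_ids)
    n_det = matrix.detected.sum(axis=1)
    if (n_det == 0).any():
        bad = [m for m, n in zip(matrix.metabolite_ids, n_det) if n == 0]
        raise ValidationError(
            f"metabolite(s) with zero detections anywhere: {bad}; "
            "filter them out before computing thresholds"
        )
    global_min = np.nanmin(np.where(matrix.detected, matrix.values, np.nan), axis=1)
    out = np.empty((matrix.n_metabolites, len(batches)))
    for k, batch in enumerate(batches):
        cols = sample_batches == batch
        vals = np.where(matrix.detected[:, cols], matrix.values[:, cols], np.inf)
        batch_min = vals.min(axis=1) if cols.any() else np.full(
            matrix.n_metabolites, np.inf
        )
        out[:, k] = np.where(np.isinf(batch_min), global_min, batch_min)
    table = pd.DataFrame(
        out,
        index=pd.Index(matrix.metabolite_ids, name="metabolite_id"),
        columns=[str(b) for b in batches],
    )
    return ThresholdSet(table)
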