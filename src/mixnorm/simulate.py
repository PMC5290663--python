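"""Synthetic GC/MS experiments with known batch effects and truncation.

The generator emulates a pooled-QC batch design: ``n_batches`` instrument
batches, each containing ``analytical_per_batch`` analytical samples and
``qc_per_batch`` QC aliquots drawn from a common pool. For metabolite m and
sample i (log2 peak-area scale):

* each metabolite gets a mean abundance alpha_m ~ N(alpha_mean, alpha_sd^2);
* each analytical sample carries a phenotype v_i ~ N(0, pheno_sd^2), with
  per-metabolite association strength beta_m ~ N(0, beta_sd^2);
* measurement noise is proportional to abundance,
  eps ~ N(0, (noise_cv * alpha_m)^2);
* QC values are alpha_m + eps (the pool sits at the mean phenotype);
  analytical values are alpha_m + beta_m * v_i + eps;
* per-round batch effects b_mk ~ N(0, batch_effect_sd^2) are added to every
  sample of batch k, identically for QC and analytical samples;
* each round, detection thresholds spaced evenly over
  [threshold_low, threshold_high] are randomly permuted onto batches, and
  every value below its batch's threshold is marked undetected.

alpha_m, beta_m and v_i are drawn once (from ``seed_constants``) and held
fixed across simulation rounds; noise, batch effects and the threshold
permutation are redrawn each round from a stream deterministic in
(``seed_rounds``, round index), so any round is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ANALYTICAL, AbundanceMatrix, SampleAnnotation
from .evaluate import missingness_bin, rsd

QC_CLASS = "qc_pool"


@dataclass
class SimConfig:
    """Study-design constants for the simulated experiment."""

    n_metabolites: int = 150
    n_batches: int = 20
    analytical_per_batch: int = 24
    qc_per_batch: int = 3
    alpha_mean: float = 18.0
    alpha_sd: float = 2.0
    pheno_sd: float = 1.0
    beta_sd: float = 1.0
    noise_cv: float = 0.03
    batch_effect_sd: float = 2.0
    threshold_low: float = 12.5
    threshold_high: float = 15.0
    n_rounds: int = 1000
    seed_constants: int = 20170202
    seed_rounds: int = 316

    def __post_init__(self) -> None:
        for name in ("n_metabolites", "n_batches", "analytical_per_batch",
                     "qc_per_batch", "n_rounds"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.noise_cv < 1.0:
            raise ValueError("noise_cv must lie in [0, 1)")
        if self.threshold_low > self.threshold_high:
            raise ValueError("threshold_low must be <= threshold_high")

    @property
    def n_analytical(self) -> int:
        return self.n_batches * self.analytical_per_batch

    @property
    def n_qc(self) -> int:
        return self.n_batches * self.qc_per_batch

    def threshold_grid(self) -> np.ndarray:
        """The incremental detection thresholds permuted onto batches."""
        if self.threshold_low == self.threshold_high:
            return np.full(self.n_batches, self.threshold_low)
        return np.linspace(self.threshold_low, self.threshold_high, self.n_batches)


@dataclass
class SimulationTruth:
    """Everything the generator knows that an analyst would not."""

    metabolite_ids: list[str]
    alpha_m: np.ndarray
    beta_m: np.ndarray
    v: pd.Series  # phenotype, indexed by analytical sample id
    batch_effects: pd.DataFrame  # metabolites x batches (b_mk)
    batch_thresholds: pd.Series  # batch label -> applied threshold
    pre_batch_values: pd.DataFrame  # metabolites x all samples, no batch effect
    true_rsd_qc: pd.Series  # per-metabolite RSD% of pre-batch QC values
    true_rsd_analytical: pd.Series
    round_index: int = 1


def _constants(cfg: SimConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    rng = np.random.default_rng(cfg.seed_constants)
    alpha_m = cfg.alpha_mean + cfg.alpha_sd * rng.standard_normal(cfg.n_metabolites)
    v = cfg.pheno_sd * rng.standard_normal(cfg.n_analytical)
    beta_m = cfg.beta_sd * rng.standard_normal(cfg.n_metabolites)
    return alpha_m, v, beta_m


def _sample_layout(cfg: SimConfig) -> pd.DataFrame:
    """Batch-major sample table; QC aliquots at the beginning, middle and
    end of each batch (the simulation carries no run-order effect, so QC
    placement is informational only)."""
    rows = []
    per_batch = cfg.analytical_per_batch + cfg.qc_per_batch
    if cfg.qc_per_batch >= 2:
        qc_pos = set(
            int(round(p))
            for p in np.linspace(1, per_batch, cfg.qc_per_batch)
        )
    else:
        qc_pos = {1}
    pos = 1
    while len(qc_pos) < cfg.qc_per_batch:  # rounding collisions on tiny batches
        if pos not in qc_pos:
            qc_pos.add(pos)
        pos += 1
    for k in range(1, cfg.n_batches + 1):
        batch = f"B{k:02d}"
        n_a = n_q = 0
        for pos in range(1, per_batch + 1):
            if pos in qc_pos and n_q < cfg.qc_per_batch:
                n_q += 1
                rows.append((f"{batch}_QC{n_q}", batch, pos, QC_CLASS))
            else:
                n_a += 1
                rows.append((f"{batch}_A{n_a:02d}", batch, pos, ANALYTICAL))
    return pd.DataFrame(rows, columns=["sample_id", "batch", "run_order", "sample_class"])


def simulate_experiment(
    cfg: SimConfig, round_index: int = 1
) -> tuple[AbundanceMatrix, SampleAnnotation, SimulationTruth]:
    """Generate one simulation round.

    Returns the observed (batch-affected, truncated) abundance matrix, the
    sample annotation, and a :class:`SimulationTruth` retaining the
    constants, the round's batch effects and thresholds, the
    pre-batch-effect values and the true per-metabolite RSDs.
    """
    if not 1 <= round_index <= cfg.n_rounds:
        raise ValueError(f"round_index must lie in [1, {cfg.n_rounds}]")
    alpha_m, v, beta_m = _constants(cfg)
    layout = _sample_layout(cfg)

    is_qc = (layout["sample_class"] == QC_CLASS).to_numpy()
    sample_ids = layout["sample_id"].tolist()
    qc_ids = layout.loc[is_qc, "sample_id"].tolist()
    an_ids = layout.loc[~is_qc, "sample_id"].tolist()
    batches = list(dict.fromkeys(layout["batch"]))
    batch_idx = layout["batch"].map({b: i for i, b in enumerate(batches)}).to_numpy()

    rng = np.random.default_rng([cfg.seed_rounds, round_index])
    noise_sd = cfg.noise_cv * alpha_m  # per-metabolite, proportional to mean
    n_samples = len(sample_ids)
    eps = noise_sd[:, None] * rng.standard_normal((cfg.n_metabolites, n_samples))
    b_mk = cfg.batch_effect_sd * rng.standard_normal((cfg.n_metabolites, cfg.n_batches))
    thresholds = rng.permutation(cfg.threshold_grid())

    # pre-batch-effect values: QC = alpha + eps; analytical adds beta * v
    pre = np.repeat(alpha_m[:, None], n_samples, axis=1) + eps
    v_series = pd.Series(v, index=an_ids, name="phenotype")
    an_cols = np.nonzero(~is_qc)[0]
    pre[:, an_cols] += beta_m[:, None] * v[None, :]

    values = pre + b_mk[:, batch_idx]
    detected = values >= thresholds[batch_idx][None, :]

    metabolite_ids = [f"M{m + 1:03d}" for m in range(cfg.n_metabolites)]
    matrix = AbundanceMatrix(values, detected, metabolite_ids, sample_ids)
    annotation = SampleAnnotation(layout)

    met_index = pd.Index(metabolite_ids, name="metabolite_id")
    pre_frame = pd.DataFrame(pre, index=met_index, columns=sample_ids)
    truth = SimulationTruth(
        metabolite_ids=metabolite_ids,
        alpha_m=alpha_m,
        beta_m=beta_m,
        v=v_series,
        batch_effects=pd.DataFrame(b_mk, index=met_index, columns=batches),
        batch_thresholds=pd.Series(thresholds, index=batches),
        pre_batch_values=pre_frame,
        true_rsd_qc=pre_frame[qc_ids].apply(lambda r: rsd(r.to_numpy()), axis=1),
        true_rsd_analytical=pre_frame[an_ids].apply(lambda r: rsd(r.to_numpy()), axis=1),
        round_index=round_index,
    )
    return matrix, annotation, truth


def truncation_profile(matrix: AbundanceMatrix) -> pd.DataFrame:
    """Per-metabolite undetected fraction, its 5%-wide missingness bin, and
    whether the metabolite is excluded from analysis (> 80% undetected)."""
    frac = 1.0 - matrix.detection_fraction()
    return pd.DataFrame(
        {
            "undetected_fraction": frac,
            "bin": [missingness_bin(f) for f in frac],
            "excluded": frac > 0.80,
        },
        index=pd.Index(matrix.metabolite_ids, name="metabolite_id"),
    )
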