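"""End-to-end simulation benchmark: simulate, normalize, evaluate.

Runs the simulated experiment for a number of rounds, applies each
requested normalization method, and pools the evaluation metrics: RSD
summaries per sample class, RSD-recovery slopes by missingness bin, and —
when association scanning is enabled — true/false positive probabilities
for recovering the simulated phenotype associations.

Everything is driven by a :class:`RunConfig` that serialises to a flat
``key = value`` text file, so a run is reproducible from the config alone;
all randomness flows from the two simulation seeds.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .data import SampleAnnotation
from .evaluate import (
    DEFAULT_BETA_GRID,
    EvaluationReport,
    association_scan,
    power_summary,
    rsd_recovery_slope,
    rsd_table,
)
from .normalize import MixnormSpec, normalize_by_name
from .simulate import QC_CLASS, SimConfig, simulate_experiment

logger = logging.getLogger("mixnorm")

DEFAULT_METHODS = ("none", "mixnorm", "mean_center", "median_scale", "quantile")
_MISSING_OMIT = 0.80  # metabolites above this undetected fraction are omitted


@dataclass
class RunConfig:
    """Full specification of one benchmark run."""

    sim: SimConfig = field(default_factory=SimConfig)
    methods: tuple[str, ...] = DEFAULT_METHODS
    n_rounds: int = 100
    x_covariates: tuple[str, ...] = ("batch",)
    z_covariates: tuple[str, ...] = ("batch",)
    min_detection_fraction: float = 0.0
    run_associations: bool = False
    association_methods: tuple[str, ...] = ("mixnorm",)
    association_analyses: tuple[str, ...] = ("linear", "mixture")
    beta_grid: tuple[float, ...] = DEFAULT_BETA_GRID
    out_dir: Optional[str] = None
    verbosity: str = "info"

    def mixnorm_spec(self) -> MixnormSpec:
        return MixnormSpec(
            x_covariates=self.x_covariates,
            z_covariates=self.z_covariates,
            min_detection_fraction=self.min_detection_fraction,
        )


def _coerce(value: str, typ):
    if typ is bool:
        return value.lower() in ("1", "true", "yes", "on")
    if typ is int:
        return int(value)
    if typ is float:
        return float(value)
    if typ is str or typ == Optional[str]:
        return value
    # tuples: comma separated; element type guessed from content
    items = [v.strip() for v in value.split(",") if v.strip()]
    try:
        return tuple(float(v) if "." in v or "e" in v.lower() else int(v) for v in items)
    except ValueError:
        return tuple(items)


def load_config(path) -> RunConfig:
    """Parse the flat ``section.key = value`` config dialect."""
    cfg = RunConfig()
    sim_fields = {f.name: f.type for f in dataclasses.fields(SimConfig)}
    run_fields = {f.name: f for f in dataclasses.fields(RunConfig)}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        if key.startswith("sim."):
            name = key[4:]
            if name not in sim_fields:
                raise ValueError(f"{path}:{lineno}: unknown simulation key {name!r}")
            current = getattr(cfg.sim, name)
            setattr(cfg.sim, name, _coerce(value, type(current)))
        elif key in run_fields and key != "sim":
            current = getattr(cfg, key)
            typ = type(current) if current is not None else str
            setattr(cfg, key, _coerce(value, typ))
        else:
            raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
    cfg.sim.__post_init__()
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    lines = []
    for f in dataclasses.fields(SimConfig):
        lines.append(f"sim.{f.name} = {getattr(cfg.sim, f.name)}")
    for f in dataclasses.fields(RunConfig):
        if f.name == "sim":
            continue
        v = getattr(cfg, f.name)
        if isinstance(v, tuple):
            v = ",".join(str(x) for x in v)
        lines.append(f"{f.name} = {v if v is not None else ''}")
    Path(path).write_text("\n".join(lines) + "\n")


def _annotation_with_phenotype(annotation: SampleAnnotation, v: pd.Series) -> SampleAnnotation:
    table = annotation.table.reset_index(drop=True).copy()
    table["phenotype"] = table["sample_id"].map(v)
    return SampleAnnotation(table)


def run_benchmark(cfg: RunConfig) -> EvaluationReport:
    """Run the full simulate / normalize / evaluate loop.

    Per-metabolite RSDs are pooled over all (metabolite, round) pairs;
    metabolites more than 80% undetected in a round are omitted from that
    round's summaries, and failures are recorded per (round, method,
    metabolite) rather than aborting the run.
    """
    rsd_rows: list[pd.DataFrame] = []
    scan_p: dict[tuple[str, str], list[pd.Series]] = {}
    truth0 = None
    spec = cfg.mixnorm_spec()

    for rnd in range(1, cfg.n_rounds + 1):
        matrix, annotation, truth = simulate_experiment(cfg.sim, rnd)
        if truth0 is None:
            truth0 = truth
        qc_ids = [s for s, c in zip(matrix.sample_ids,
                                    annotation.class_of(matrix.sample_ids))
                  if c == QC_CLASS]
        an_ids = annotation.analytical_sample_ids()
        undet_frac = 1.0 - matrix.detection_fraction()
        omit = undet_frac > _MISSING_OMIT

        base = pd.DataFrame(
            {
                "round": rnd,
                "metabolite_id": matrix.metabolite_ids,
                "undetected_fraction": undet_frac,
                "true_rsd_qc": truth.true_rsd_qc.to_numpy(),
                "true_rsd_analytical": truth.true_rsd_analytical.to_numpy(),
            }
        )
        truth_row = base.copy()
        truth_row["method"] = "truth"
        truth_row["rsd_qc"] = truth.true_rsd_qc.to_numpy()
        truth_row["rsd_analytical"] = truth.true_rsd_analytical.to_numpy()
        rsd_rows.append(truth_row)

        for method in cfg.methods:
            try:
                normalized = normalize_by_name(method, matrix, annotation, spec)
            except Exception as exc:  # recorded, benchmark continues
                logger.warning("round %d: method %s failed: %s", rnd, method, exc)
                failed = base.copy()
                failed["method"] = method
                failed["rsd_qc"] = np.nan
                failed["rsd_analytical"] = np.nan
                rsd_rows.append(failed)
                continue
            row = base.copy()
            row["method"] = method
            row["rsd_qc"] = np.where(
                omit, np.nan, rsd_table(normalized, qc_ids).to_numpy()
            )
            row["rsd_analytical"] = np.where(
                omit, np.nan, rsd_table(normalized, an_ids).to_numpy()
            )
            rsd_rows.append(row)

            if cfg.run_associations and method in cfg.association_methods:
                ann_ph = _annotation_with_phenotype(annotation, truth.v)
                scan_mets = [
                    m for m, o in zip(normalized.metabolite_ids, omit) if not o
                ]
                scan_matrix = normalized.select_metabolites(scan_mets)
                for analysis in cfg.association_analyses:
                    try:
                        scan = association_scan(
                            scan_matrix, ann_ph, "phenotype", analysis=analysis
                        )
                        scan_p.setdefault((method, analysis), []).append(
                            scan["p_value"]
                        )
                    except Exception as exc:
                        logger.warning(
                            "round %d: %s %s scan failed: %s",
                            rnd, method, analysis, exc,
                        )
        if rnd % 10 == 0 or rnd == cfg.n_rounds:
            logger.info("benchmark: completed round %d / %d", rnd, cfg.n_rounds)

    long = pd.concat(rsd_rows, ignore_index=True)

    summaries = []
    for method in ("truth", *cfg.methods):
        sub = long[long["method"] == method]
        for cls, col in (("qc", "rsd_qc"), ("analytical", "rsd_analytical")):
            vals = sub[col].dropna()
            summaries.append(
                (method, cls, vals.mean() if len(vals) else np.nan,
                 vals.min() if len(vals) else np.nan,
                 vals.max() if len(vals) else np.nan, len(vals))
            )
    rsd_summary = pd.DataFrame(
        summaries, columns=["method", "sample_class", "mean", "min", "max", "n"]
    ).set_index(["method", "sample_class"])

    slopes = {}
    for method in cfg.methods:
        sub = long[long["method"] == method]
        slopes[method] = rsd_recovery_slope(
            sub["true_rsd_analytical"].to_numpy(),
            sub["rsd_analytical"].to_numpy(),
            sub["undetected_fraction"].to_numpy(),
        )
    slope_table = pd.DataFrame(slopes).T.rename_axis("method")

    power_table = None
    if scan_p:
        true_beta = pd.Series(
            truth0.beta_m, index=pd.Index(truth0.metabolite_ids, name="metabolite_id")
        )
        blocks = []
        for (method, analysis), series_list in scan_p.items():
            pooled = pd.concat(series_list)
            tab = power_summary(pooled, true_beta, cfg.beta_grid)
            tab.insert(0, "analysis", analysis)
            tab.insert(0, "method", method)
            blocks.append(tab)
        power_table = pd.concat(blocks, ignore_index=True)

    report = EvaluationReport(
        rsd_summary=rsd_summary,
        slope_table=slope_table,
        power_table=power_table,
        per_metabolite_rsd=long[
            ["round", "method", "metabolite_id", "undetected_fraction",
             "true_rsd_qc", "true_rsd_analytical", "rsd_qc", "rsd_analytical"]
        ],
    )
    if cfg.out_dir:
        report.write(cfg.out_dir)
        save_config(cfg, Path(cfg.out_dir) / "run_config.txt")
    return report
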