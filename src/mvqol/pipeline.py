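"""End-to-end pipeline: simulate/load -> score -> filter -> factor -> fit -> report.

The pipeline is configured by a single YAML/JSON file (or an equivalent
dict) and writes a bundle of CSV artifacts plus a JSON run manifest
recording the seed, package versions, a parameter hash and per-stage
status, so any run is reproducible from its manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .comparison import compare_models, contrast_table, effect_table, fit_statistics
from .constants import DOMAINS, SUBJECT_COL, TIME_COL
from .dataset import CohortDataset, CovariateSchema
from .exceptions import ValidationError
from .factors import fit_clinical_components
from .mvml import (
    ModelSpec,
    fit_independent,
    fit_mvml,
    random_effect_correlations,
    transformed_residuals,
)
from .scoring import filter_complete_visits, filter_min_visits, score_dataset
from .synthetic import SimulationConfig, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    Exactly one of ``input_path`` / ``simulation`` must be given.
    """

    output_dir: str = "mvqol_out"
    seed: int = 0
    input_path: str | None = None
    simulation: dict[str, Any] | None = None
    model: dict[str, Any] = field(default_factory=dict)
    factor: dict[str, Any] = field(default_factory=dict)
    contrasts: list[dict[str, Any]] = field(default_factory=list)
    variants: str = "both"  # "related" | "independent" | "both"
    min_visits: int = 2

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        cfg = cls(**raw)
        if (cfg.input_path is None) == (cfg.simulation is None):
            raise ValidationError(
                "config must provide exactly one of input_path / simulation"
            )
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        text = Path(path).read_text()
        raw = yaml.safe_load(text)
        return cls.from_dict(raw)

    def param_hash(self) -> str:
        blob = json.dumps(
            {k: v for k, v in self.__dict__.items()}, sort_keys=True, default=str
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def simulation_config_from_dict(raw: dict[str, Any], seed: int) -> SimulationConfig:
    """Build a SimulationConfig from plain YAML-able values."""
    kwargs = dict(raw)
    kwargs.setdefault("seed", seed)
    for key in ("omega_G", "omega_R", "visit_schedule"):
        if key in kwargs:
            kwargs[key] = np.asarray(kwargs[key], dtype=float)
    return SimulationConfig(**kwargs)


def model_spec_from_dict(raw: dict[str, Any]) -> ModelSpec:
    kwargs = dict(raw)
    if "outcomes" in kwargs:
        kwargs["outcomes"] = tuple(kwargs["outcomes"])
    return ModelSpec(**kwargs)


# --------------------------------------------------------------------------
# CSV input/output
# --------------------------------------------------------------------------


def load_cohort_csv(path: str | Path, schema: CovariateSchema | None = None) -> CohortDataset:
    """Load a long-format cohort CSV.

    Requires ``subject_id`` and ``visit_time_months`` columns and either
    domain-score columns (ph/psy/ind/soc) or item columns
    (``dom{k}_item{i}``).  Categorical schema levels default to the
    observed values sorted, first level as reference.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    for col in (SUBJECT_COL, TIME_COL):
        if col not in df.columns:
            raise ValidationError(f"input CSV lacks required column {col!r}")
    if not pd.api.types.is_numeric_dtype(df[TIME_COL]):
        raise ValidationError(f"column {TIME_COL!r} must be numeric")
    has_scores = all(k in df.columns for k in DOMAINS)
    has_items = any(c.startswith("dom1_item") for c in df.columns)
    if not (has_scores or has_items):
        raise ValidationError(
            "input CSV needs either score columns "
            + "/".join(DOMAINS)
            + " or item columns dom{k}_item{i}"
        )
    if schema is None:
        spec = {}
        reserved = set(DOMAINS) | {SUBJECT_COL, TIME_COL}
        for col in df.columns:
            if col in reserved or col.startswith("dom"):
                continue
            if pd.api.types.is_numeric_dtype(df[col]):
                spec[col] = {"type": "continuous"}
            else:
                spec[col] = {
                    "type": "categorical",
                    "levels": sorted(df[col].dropna().unique().tolist()),
                }
        schema = CovariateSchema(spec)
    return CohortDataset(df, schema)


def write_cohort_csv(dataset: CohortDataset, path: str | Path) -> None:
    dataset.data.to_csv(path, index=False)


# --------------------------------------------------------------------------
# orchestration
# --------------------------------------------------------------------------


@dataclass
class ReportBundle:
    """Everything one pipeline run produced."""

    manifest: dict[str, Any]
    outputs: dict[str, Path]
    converged: bool


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run every stage; partial outputs survive a failing stage.

    Artifacts written to ``config.output_dir``: the scored/filtered
    cohort, factor loadings and scree tables, fit statistics, the
    random-effect correlation matrix, the effect table, the contrast
    table, residual Q-Q data, and ``manifest.json``.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "seed": config.seed,
        "mvqol_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "python_version": sys.version.split()[0],
        "param_hash": config.param_hash(),
        "stages": {},
    }
    outputs: dict[str, Path] = {}
    converged = False

    def _write(name: str, frame: pd.DataFrame, **kw) -> None:
        path = outdir / f"{name}.csv"
        frame.to_csv(path, **kw)
        outputs[name] = path

    def _finish(failed_stage: str | None = None) -> ReportBundle:
        manifest["failed_stage"] = failed_stage
        path = outdir / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2, default=str))
        outputs["manifest"] = path
        return ReportBundle(manifest=manifest, outputs=outputs, converged=converged)

    stage = "load"
    try:
        if config.simulation is not None:
            stage = "simulate"
            sim = simulation_config_from_dict(config.simulation, config.seed)
            cohort = generate_cohort(sim)
        else:
            cohort = load_cohort_csv(config.input_path)
        manifest["stages"][stage] = "ok"

        stage = "score"
        cohort = score_dataset(cohort)
        manifest["stages"][stage] = "ok"

        stage = "filter"
        cohort, n_dropped, pct = filter_complete_visits(cohort)
        cohort, n_subj_dropped = filter_min_visits(cohort, config.min_visits)
        manifest["stages"][stage] = "ok"
        manifest["filter"] = {
            "visits_dropped": n_dropped,
            "pct_dropped": pct,
            "subjects_dropped": n_subj_dropped,
            "visits_kept": cohort.n_visits,
            "subjects_kept": cohort.n_subjects,
        }
        _write("cohort_scored", cohort.data, index=False)

        stage = "factor"
        factor_cfg = dict(config.factor)
        if factor_cfg.get("enabled", True):
            models, scores = fit_clinical_components(
                cohort.data,
                groups=factor_cfg.get("groups"),
                extraction=factor_cfg.get("extraction", "ml"),
            )
            cohort.data[scores.columns] = scores.to_numpy()
            loadings = pd.concat(
                {g: m.loadings for g, m in models.items()}, names=["group", "variable"]
            )
            labels = pd.concat(
                {g: m.strength_labels for g, m in models.items()},
                names=["group", "variable"],
            )
            _write("factor_loadings", loadings)
            _write("factor_loading_strengths", labels)
            eig = pd.concat(
                {
                    g: pd.Series(m.eigenvalues, name="eigenvalue")
                    for g, m in models.items()
                },
                names=["group", "component"],
            )
            _write("factor_eigenvalues", eig.to_frame())
        manifest["stages"][stage] = "ok"

        stage = "fit"
        spec = model_spec_from_dict(config.model)
        fits = {}
        if config.variants in ("independent", "both"):
            fits["independent"] = fit_independent(cohort, spec)
        if config.variants in ("related", "both"):
            fits["related"] = fit_mvml(cohort, spec)
        primary = fits.get("related", next(iter(fits.values())))
        converged = all(f.converged for f in fits.values())
        manifest["stages"][stage] = "ok"
        manifest["converged"] = {k: f.converged for k, f in fits.items()}

        stage = "report"
        _write("effects", effect_table(primary), index=False)
        if len(fits) == 2:
            cmp_res = compare_models(fits["related"], fits["independent"])
            _write("fit_statistics", cmp_res.table)
            manifest["preferred_model"] = cmp_res.preferred
            manifest["lr_statistic"] = cmp_res.lr_statistic
            manifest["lr_df"] = cmp_res.lr_df
        else:
            _write("fit_statistics", fit_statistics(primary).as_series().to_frame("value"))
        corr = random_effect_correlations(primary)
        _write("re_correlations", corr.matrix)
        _, qq = transformed_residuals(primary)
        _write("qq_residuals", qq, index=False)
        if config.contrasts:
            _write("contrasts", contrast_table(primary, config.contrasts), index=False)
        manifest["stages"][stage] = "ok"
    except Exception as err:  # noqa: BLE001 - manifest records the failing stage
        logger.exception("pipeline stage %s failed", stage)
        manifest["stages"][stage] = f"failed: {err}"
        return _finish(failed_stage=stage)
    return _finish()
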