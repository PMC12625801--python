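"""End-to-end body-mass estimation runs: config, validation, reports.

A run fits the requested allometric models to the extant reference table
under the tree's λ-scaled covariance, selects the best model by AIC,
predicts every fossil specimen with prediction limits, aggregates to
species-level weighted means, and (optionally) compares the new species
means against prior estimate sets.  Four delimited-text reports plus a JSON
manifest are written; re-running with the same config and seed reproduces
the reports byte for byte (the timestamp lives only in the manifest).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aggregate import paired_log_t_test, species_weighted_mean
from .io import (
    apply_synonyms,
    read_specimen_table,
    read_synonym_map,
    read_trait_table,
    read_tree,
    write_model_report,
    write_predictions,
    write_species_summaries,
)
from .pgls import FORMULAS, fit_model, compare_models
from .predict import FossilPlacement, predict_specimens, records_to_frame
from .tree import normalize_label, vcv_from_tree

__all__ = ["RunConfig", "ValidationReport", "validate_inputs", "run_estimation"]


@dataclass
class RunConfig:
    """Paths and settings for one estimation run."""

    tree: str
    extant_table: str
    fossil_table: str
    output_dir: str
    synonyms: str | None = None
    priors: str | None = None
    models: tuple[str, ...] = ("BM~FCSA", "BM~FL", "BM~FCSA+FL")
    selection: str = "aic"
    mode: str = "independent"
    level: float = 0.95
    seed: int = 0
    rounding: int = 2

    def __post_init__(self) -> None:
        if not 0.0 < self.level < 1.0:
            raise ValueError("level must lie in (0, 1)")
        if self.selection != "aic":
            raise ValueError(f"unknown selection rule {self.selection!r}")
        if self.mode not in ("independent", "blup"):
            raise ValueError(f"unknown prediction mode {self.mode!r}")
        for m in self.models:
            key = m.replace(" ", "").upper()
            if key not in FORMULAS:
                raise ValueError(f"unknown model {m!r}; expected {sorted(FORMULAS)}")
        self.models = tuple(m.replace(" ", "").upper() for m in self.models)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValueError("run config must be a mapping")
        if "models" in raw and isinstance(raw["models"], list):
            raw["models"] = tuple(raw["models"])
        return cls(**raw)


@dataclass
class ValidationReport:
    """Report-only input checks: issues grouped by reason, with counts."""

    issues: list[dict[str, Any]] = field(default_factory=list)

    def add(self, reason: str, message: str, rows: list[str] | None = None) -> None:
        self.issues.append(
            {"reason": reason, "message": message, "rows": rows or []}
        )

    @property
    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for issue in self.issues:
            out[issue["reason"]] = out.get(issue["reason"], 0) + max(
                1, len(issue["rows"])
            )
        return out

    def ok(self) -> bool:
        return not self.issues


def validate_inputs(config: RunConfig) -> ValidationReport:
    """Check tree/table concordance, positivity, and duplicates."""
    report = ValidationReport()
    for label, path in (("tree", config.tree),
                        ("extant_table", config.extant_table),
                        ("fossil_table", config.fossil_table)):
        if not Path(path).exists():
            report.add("missing_file", f"{label} not found: {path}")
    if report.issues:
        return report
    synonyms = read_synonym_map(config.synonyms) if config.synonyms else {}
    try:
        tree = read_tree(config.tree)
    except ValueError as exc:
        report.add("tree_error", str(exc))
        return report
    tips = set(apply_synonyms(tree.tip_labels, synonyms))

    extant = pd.read_csv(config.extant_table)
    for col in ("bm_kg", "fcsa_mm2"):
        if col in extant.columns:
            bad = extant.loc[~(pd.to_numeric(extant[col], errors="coerce") > 0)]
            if len(bad):
                report.add(
                    "nonpositive_value",
                    f"non-positive {col} in extant table",
                    bad["species"].astype(str).tolist(),
                )
    if "species" in extant.columns:
        species = apply_synonyms(extant["species"].astype(str), synonyms)
        dup = sorted({s for s in species if species.count(s) > 1})
        if dup:
            report.add("duplicate_species", "duplicate extant species", dup)
        absent = sorted(set(species) - tips)
        if absent:
            report.add("species_not_in_tree",
                       "extant species missing from tree", absent)

    fossil = pd.read_csv(config.fossil_table)
    if "fcsa_mm2" in fossil.columns:
        bad = fossil.loc[~(pd.to_numeric(fossil["fcsa_mm2"], errors="coerce") > 0)]
        if len(bad):
            report.add(
                "nonpositive_value",
                "non-positive fcsa_mm2 in fossil table",
                bad["specimen_id"].astype(str).tolist(),
            )
    if "specimen_id" in fossil.columns:
        ids = fossil["specimen_id"].astype(str)
        dup = sorted(ids[ids.duplicated()].unique())
        if dup:
            report.add("duplicate_specimen", "duplicate fossil specimen ids", dup)
    if config.mode == "blup" and "species" in fossil.columns:
        fsp = set(apply_synonyms(fossil["species"].astype(str), synonyms))
        absent = sorted(fsp - tips)
        if absent:
            report.add("fossil_not_in_tree",
                       "fossil species absent from tree (blup mode)", absent)
    return report


class StageError(RuntimeError):
    """An estimation stage failed; carries the stage name in the message."""


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def run_estimation(config: RunConfig) -> dict[str, Any]:
    """Execute a full run and write the report bundle to ``output_dir``.

    Returns the in-memory bundle: fits, ranking, prediction/summary/
    comparison frames, the validation report, and the manifest dict.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    with _stage("load"):
        synonyms = read_synonym_map(config.synonyms) if config.synonyms else {}
        tree = read_tree(config.tree)
        if synonyms:
            tree = tree.rename_tips(synonyms)
        extant = read_trait_table(
            config.extant_table,
            require_fl=any("FL" in m for m in config.models),
        )
        extant["species"] = apply_synonyms(extant["species"], synonyms)
        fossil = read_specimen_table(config.fossil_table)
        fossil["species"] = apply_synonyms(fossil["species"], synonyms)

    validation = validate_inputs(config)

    with _stage("fit"):
        fits = [fit_model(extant, tree, m) for m in config.models]
        ranking = compare_models(fits)
        best = fits[ranking.best]
        model_report = write_model_report(fits, outdir / "models.csv")

    with _stage("predict"):
        placements = None
        if config.mode == "blup":
            placements = _placements_from_tree(tree, best, fossil)
        records = predict_specimens(
            best, fossil, level=config.level, mode=config.mode,
            placements=placements,
        )
        predictions = records_to_frame(records)
        write_predictions(predictions, outdir / "predictions.csv",
                          decimals=config.rounding)

    with _stage("aggregate"):
        summaries = species_weighted_mean(predictions)
        write_species_summaries(summaries, outdir / "species_summaries.csv",
                                decimals=config.rounding)

    comparisons = None
    if config.priors:
        with _stage("compare"):
            comparisons = _compare_with_priors(
                summaries, config.priors, synonyms, outdir, config.rounding
            )

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "models": list(config.models),
        "selected": best.formula,
        "lambda_hat": {f.formula: f.lambda_hat for f in fits},
        "coefficients": {f.formula: f.params.to_dict() for f in fits},
        "aic": {f.formula: f.aic for f in fits},
        "n_extant": best.n,
        "n_specimens": int(len(predictions)),
        "n_species": int(len(summaries)),
        "prediction_mode": config.mode,
        "level": config.level,
        "validation_counts": validation.counts,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "fits": fits,
        "ranking": ranking,
        "model_report": model_report,
        "predictions": predictions,
        "summaries": summaries,
        "comparisons": comparisons,
        "validation": validation,
        "manifest": manifest,
    }


def _placements_from_tree(tree, fit, fossil: pd.DataFrame):
    """Derive BLUP placements for fossil species that are tips of the tree."""
    fossil_species = sorted(set(fossil["species"].map(normalize_label)))
    tips = set(tree.tip_labels)
    absent = sorted(set(fossil_species) - tips)
    if absent:
        raise ValueError(
            f"blup mode needs fossil species as tree tips; missing: {absent}"
        )
    taxa = list(fit.taxa) + fossil_species
    C = vcv_from_tree(tree, taxa=taxa).C
    ne = len(fit.taxa)
    return {
        sp: FossilPlacement(cov_to_extant=C[ne + i, :ne].copy(),
                            depth=float(C[ne + i, ne + i]))
        for i, sp in enumerate(fossil_species)
    }


def _compare_with_priors(summaries, priors_path, synonyms, outdir, rounding):
    priors = pd.read_csv(priors_path)
    priors["species"] = apply_synonyms(priors["species"].astype(str), synonyms)
    current = dict(
        zip(apply_synonyms(summaries["species"], synonyms), summaries["mean_bm_kg"])
    )
    results = {}
    rows = []
    for col in priors.columns:
        if col == "species":
            continue
        prior_map = dict(zip(priors["species"], priors[col]))
        res = paired_log_t_test(current, prior_map)
        results[col] = res
        rows.append(
            {
                "comparison": col,
                "n_pairs": res.n_pairs,
                "t": round(res.t, rounding),
                "df": res.df,
                "p": res.p,
                "mean_log_ratio": round(res.mean_log_ratio, 4),
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "comparisons.csv", index=False)
    return results
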