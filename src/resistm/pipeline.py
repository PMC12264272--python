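"""End-to-end pipeline: simulate or load a cohort, score signatures,
stratify survival, compare subtypes, test enrichment, assemble the
heatmap table, and write a reproducible run report."""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import SyntheticCohortConfig, simulate_cohort, truth_summary
from .enrichment import build_heatmap_table, compare_scores_by_subtype, enrichment_test
from .io import read_clinical, read_expression, read_gmt, write_clinical, write_expression
from .scoring import assign_risk, assign_status, score_mean, score_reflected_median
from .signatures import builtin_registry
from .survival import stratified_km_report

__all__ = ["PipelineConfig", "run_pipeline", "report_to_dict"]

log = logging.getLogger("resistm")

# scoring method per signature: combined RESIST-M uses the reflected
# median; single arms and comparators use mean expression
DEFAULT_METHODS = {
    "RESIST-M": "reflected_median",
    "RESIST-M1": "mean",
    "RESIST-M2": "mean",
    "Yin": "mean",
    "Lin": "mean",
    "RCC7": "mean",
    "RPS": "mean",
}


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one input mode: ``"synthetic"`` simulates a cohort from
    ``cohort``; ``"files"`` loads ``expression_path`` / ``clinical_path``.
    """

    mode: str = "synthetic"
    expression_path: str | None = None
    clinical_path: str | None = None
    gmt_path: str | None = None
    signatures: tuple = tuple(DEFAULT_METHODS)
    endpoint: str = "OS"
    conf_level: float = 0.95
    seed: int = 1
    outdir: str | None = None
    missing_gene_policy: str = "warn"
    cohort: SyntheticCohortConfig = field(default_factory=SyntheticCohortConfig)

    def validate(self, registry) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValueError("mode must be 'synthetic' or 'files'")
        if self.mode == "files":
            for p in (self.expression_path, self.clinical_path):
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"input file not found: {p}")
        absent = [s for s in self.signatures if s not in registry]
        if absent:
            raise KeyError(f"signature(s) not in registry: {absent}")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) if path.suffix in (".yml", ".yaml") else json.load(fh)
        cohort = SyntheticCohortConfig(**raw.pop("cohort", {}))
        cfg = cls(cohort=cohort, **raw)
        cfg.signatures = tuple(cfg.signatures)
        return cfg


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, pd.Series):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else repr(v)
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def report_to_dict(report: dict) -> dict:
    """Convert a run report (nested dataclasses / pandas objects) to a
    JSON-serializable dict at full double precision."""
    return _jsonable(report)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and return the run report.

    Stages: simulate-or-load -> score every selected signature (reflected
    median for the combined RESIST-M, mean for arms and comparators) ->
    median-split -> per-signature KM/log-rank/Cox -> CMS subtype
    comparisons -> CMS4/iCMS3-fibrotic enrichment of the RESIST-M risk
    group -> z-scored heatmap table.  With ``outdir`` set, writes
    ``report.json`` plus TSV artifacts.
    """
    registry = dict(builtin_registry())
    if config.gmt_path:
        registry.update(read_gmt(config.gmt_path))
    config.validate(registry)

    caught: list[str] = []
    with warnings.catch_warnings(record=True) as wlog:
        warnings.simplefilter("always")

        if config.mode == "synthetic":
            cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
            cohort = simulate_cohort(cohort_cfg)
            expr, clinical = cohort.expression, cohort.clinical
            truth = truth_summary(cohort)
        else:
            expr = read_expression(config.expression_path)
            clinical = read_clinical(config.clinical_path)
            cohort, truth = None, None
        log.info("cohort: %d genes x %d samples", *expr.shape)

        score_summaries = {}
        survival_reports = {}
        for name in config.signatures:
            sig = registry[name]
            method = DEFAULT_METHODS.get(name, "mean")
            rep = stratified_km_report(expr, clinical, sig, method=method,
                                       conf_level=config.conf_level)
            scores = rep.pop("scores")
            rep.pop("risk")
            survival_reports[name] = rep
            score_summaries[name] = {
                "method": method,
                "polarity": scores.polarity,
                "mean": float(scores.scores.mean()),
                "median": float(scores.scores.median()),
                "sd": float(scores.scores.std(ddof=1)),
            }
            log.info("%s: log-rank p=%.3g HR=%.3g", name,
                     rep["logrank"].p_value, rep["cox"].hr)

        resist = score_reflected_median(expr, registry["RESIST-M"],
                                        missing_policy=config.missing_gene_policy)
        risk = assign_risk(resist)
        comparisons = compare_scores_by_subtype(resist, clinical, grouping="cms")
        enr = enrichment_test(risk, clinical)
        heatmap = build_heatmap_table(expr, registry, clinical, scores=resist)

        caught = [str(w.message) for w in wlog]

    report = {
        "provenance": {
            "package_version": __version__,
            "seed": config.seed,
            "endpoint": config.endpoint,
            "config": _jsonable(dataclasses.asdict(config)),
        },
        "truth": truth,
        "scores": score_summaries,
        "survival": survival_reports,
        "subtype_comparisons": comparisons,
        "enrichment": enr,
        "warnings": caught,
    }

    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        if config.mode == "synthetic":
            write_expression(expr, out / "expression.tsv")
            write_clinical(clinical, out / "clinical.tsv")
            cohort.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        comparisons.to_csv(out / "subtype_comparisons.tsv", sep="\t", index=False)
        heatmap.to_long().to_csv(out / "heatmap_long.tsv", sep="\t", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(report_to_dict(report), fh, indent=2)
    report["heatmap"] = heatmap
    return report
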