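#!/usr/bin/env python
"""Survival separation of the median-split groups, per signature.

For each signature, splits the cohort at the median score, estimates
per-group Kaplan-Meier curves, and quantifies separation with the
log-rank test and a Cox hazard ratio (risk-high vs risk-low).
"""

import argparse
import json
from pathlib import Path

from resistm import builtin_registry, read_clinical, read_expression, \
    stratified_km_report
from resistm.pipeline import DEFAULT_METHODS, report_to_dict

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    argparse.ArgumentParser().parse_args()
    expr = read_expression(ROOT / "scratch" / "cohort" / "expression.tsv")
    clinical = read_clinical(ROOT / "scratch" / "cohort" / "clinical.tsv")
    registry = builtin_registry()
    reports = {}
    print(f"{'signature':<10} {'HR':>6} {'95% CI':>16} {'log-rank p':>12}")
    for name, method in DEFAULT_METHODS.items():
        rep = stratified_km_report(expr, clinical, registry[name], method=method)
        rep.pop("scores")
        rep.pop("risk")
        cox, lr = rep["cox"], rep["logrank"]
        print(f"{name:<10} {cox.hr:>6.2f} "
              f"[{cox.ci_lower:>6.2f}, {cox.ci_upper:>6.2f}] {lr.p_value:>12.3g}")
        reports[name] = report_to_dict(rep)
    resdir = ROOT / "results" / "analysis"
    resdir.mkdir(parents=True, exist_ok=True)
    with open(resdir / "survival_reports.json", "w") as fh:
        json.dump(reports, fh, indent=2)
    print(f"wrote stratified survival reports -> {resdir / 'survival_reports.json'}")


if __name__ == "__main__":
    main()
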