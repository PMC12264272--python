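#!/usr/bin/env python
"""Subtype comparisons, heatmap table, and CMS4-fibrotic enrichment.

Compares the combined RESIST-M score between CMS4 and the other CMS
classes (Wilcoxon rank-sum), assembles the z-scored multi-signature
heatmap table ordered by clinical annotation, and tests enrichment of
the RESIST-M risk-high group in the CMS4/fibrotic subset (Fisher exact).
"""

import argparse
import json
from pathlib import Path

from resistm import assign_risk, build_heatmap_table, builtin_registry, \
    compare_scores_by_subtype, enrichment_test, read_clinical, read_expression, \
    score_reflected_median
from resistm.pipeline import report_to_dict

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    argparse.ArgumentParser().parse_args()
    expr = read_expression(ROOT / "scratch" / "cohort" / "expression.tsv")
    clinical = read_clinical(ROOT / "scratch" / "cohort" / "clinical.tsv")
    registry = builtin_registry()

    scores = score_reflected_median(expr, registry["RESIST-M"])
    comparisons = compare_scores_by_subtype(scores, clinical)
    risk = assign_risk(scores)
    enr = enrichment_test(risk, clinical)
    heatmap = build_heatmap_table(expr, registry, clinical, scores=scores)

    resdir = ROOT / "results" / "analysis"
    resdir.mkdir(parents=True, exist_ok=True)
    comparisons.to_csv(resdir / "subtype_comparisons.tsv", sep="\t", index=False)
    with open(resdir / "enrichment.json", "w") as fh:
        json.dump(report_to_dict(enr), fh, indent=2)
    scratch = ROOT / "scratch"
    scratch.mkdir(exist_ok=True)
    heatmap.to_long().to_csv(scratch / "heatmap_long.tsv", sep="\t", index=False)

    print(comparisons[["group_a", "group_b", "n_a", "n_b", "p_value",
                       "direction"]].to_string(index=False))
    (a, b), (c, d) = enr.table
    print(f"risk-high x CMS4-fibrotic table: [[{a}, {b}], [{c}, {d}]]; "
          f"OR = {enr.odds_ratio:.3g}, Fisher p = {enr.p_value:.3g}")


if __name__ == "__main__":
    main()
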