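"""Subtype comparisons, signature heatmap assembly, and enrichment of the
risk-high group in a target molecular subtype.

Score distributions are compared between consensus molecular subtypes
(CMS) with the two-sided Wilcoxon rank-sum test (exact by enumeration on
small tie-free samples, normal approximation with tie and continuity
correction otherwise).  The clinically motivated claim that
signature-positive patients concentrate in the stroma-rich, poor-
prognosis CMS4/iCMS3-fibrotic class is formalized as a Fisher exact test
on the 2x2 table (risk status x target subtype); the table-based test is
this package's quantitative stand-in for what is usually shown only as a
heatmap annotation, and is labeled as such.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .scoring import ScoreVector, zscore_rows, score_reflected_median
from .signatures import GeneSignature

__all__ = [
    "wilcoxon_rank_sum",
    "compare_scores_by_subtype",
    "HeatmapTable",
    "build_heatmap_table",
    "EnrichmentResult",
    "enrichment_test",
]

CMS_ORDER = ("CMS1", "CMS2", "CMS3", "CMS4", "unlabeled")
ICMS_ORDER = ("iCMS2", "iCMS3", "unlabeled")
FIBROSIS_ORDER = ("non-fibrotic", "fibrotic", "unlabeled")
HEATMAP_BLOCK_ORDER = ("RESIST-M", "Lin", "Yin", "RCC7", "RPS")


def wilcoxon_rank_sum(x, y) -> tuple[float, float, str]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Exact p by enumeration when both samples have <= 12 observations and
    no ties across the pooled data; otherwise the normal approximation
    with midrank tie correction and continuity correction.  Returns
    (U statistic of x, two-sided p, method used).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ties = np.unique(pooled).size < pooled.size
    if x.size <= 12 and y.size <= 12 and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue), method


def compare_scores_by_subtype(
    scores: ScoreVector,
    clinical: pd.DataFrame,
    grouping: str = "cms",
    reference_group: str = "CMS4",
) -> pd.DataFrame:
    """Compare a score between the reference subtype and every other.

    Emits one row per comparison (reference vs each other subtype, plus
    reference vs rest) with the rank-sum U, two-sided p, BH-adjusted p,
    shift direction (sign of the median difference, reference minus
    other) and per-group n.  Unlabeled samples are dropped with a
    warning; raw p-values are primary, adjusted ones always reported.
    """
    clin = clinical.set_index("sample_id") if "sample_id" in clinical.columns else clinical
    s = scores.scores
    common = s.index.intersection(clin.index)
    labels = clin.loc[common, grouping]
    keep = labels != "unlabeled"
    if (~keep).any():
        warnings.warn(
            f"dropping {int((~keep).sum())} sample(s) without a {grouping} label",
            UserWarning,
            stacklevel=2,
        )
    labels = labels[keep]
    vals = s.loc[labels.index]
    sizes = labels.value_counts()
    if (sizes >= 2).sum() < 2:
        raise ValueError("need at least two groups with >= 2 samples")
    if reference_group not in sizes.index:
        raise ValueError(f"reference group {reference_group!r} absent")
    ref = vals[labels == reference_group].to_numpy()
    rows = []
    others = [g for g in sizes.index if g != reference_group]
    for other in sorted(others):
        oth = vals[labels == other].to_numpy()
        u, p, method = wilcoxon_rank_sum(ref, oth)
        rows.append((scores.signature_name, grouping, reference_group, other,
                     len(ref), len(oth), u, p,
                     "higher" if np.median(ref) >= np.median(oth) else "lower", method))
    rest = vals[labels != reference_group].to_numpy()
    u, p, method = wilcoxon_rank_sum(ref, rest)
    rows.append((scores.signature_name, grouping, reference_group, "rest",
                 len(ref), len(rest), u, p,
                 "higher" if np.median(ref) >= np.median(rest) else "lower", method))
    out = pd.DataFrame(
        rows,
        columns=["signature", "grouping", "group_a", "group_b", "n_a", "n_b",
                 "statistic", "p_value", "direction", "method"],
    )
    out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


@dataclass(frozen=True)
class HeatmapTable:
    """Z-scored signature-gene matrix ordered for display.

    Rows are genes grouped in fixed signature blocks; columns are
    samples sorted by (CMS, iCMS, fibrosis, combined RESIST-M score);
    ``annotations`` carries the per-sample tracks in column order.
    """

    matrix: pd.DataFrame        # z-scored genes x ordered samples
    blocks: pd.Series           # gene -> signature block name
    annotations: pd.DataFrame   # ordered samples x (cms, icms, msi, fibrosis, status)

    def to_long(self) -> pd.DataFrame:
        """Long-format table: one row per (gene, sample) with z-score and
        sample annotations."""
        long = (
            self.matrix.reset_index()
            .melt(id_vars="gene", var_name="sample_id", value_name="zscore")
        )
        long["signature_block"] = long["gene"].map(self.blocks)
        ann = self.annotations.reset_index().rename(columns={"index": "sample_id"})
        return long.merge(ann, on="sample_id")[
            ["gene", "signature_block", "sample_id", "zscore"]
            + list(self.annotations.columns)
        ]


def build_heatmap_table(
    expr: pd.DataFrame,
    registry: dict[str, GeneSignature],
    clinical: pd.DataFrame,
    scores: ScoreVector | None = None,
    block_order: tuple[str, ...] = HEATMAP_BLOCK_ORDER,
) -> HeatmapTable:
    """Assemble the z-scored multi-signature heatmap table.

    Signature genes (in fixed block order) are row z-scored; columns are
    sorted by CMS, iCMS, fibrosis and then the combined RESIST-M
    reflected-median score (computed if not supplied).
    """
    clin = clinical.set_index("sample_id") if "sample_id" in clinical.columns else clinical
    samples = [s for s in expr.columns if s in clin.index]
    if not samples:
        raise ValueError("no overlapping sample ids between expression and clinical")
    sub = expr[samples]
    rows: list[str] = []
    blocks: dict[str, str] = {}
    for block in block_order:
        sig = registry[block]
        for g in sig.genes:
            if g in sub.index and g not in blocks:
                rows.append(g)
                blocks[g] = block
    if not rows:
        raise KeyError("no signature genes present in the expression matrix")
    z = zscore_rows(sub.loc[rows])
    if scores is None:
        scores = score_reflected_median(sub, registry["RESIST-M"])
    from .scoring import assign_risk  # local import avoids cycle at module load

    risk = assign_risk(scores)
    ann = pd.DataFrame(
        {
            "cms": pd.Categorical(clin.loc[samples, "cms"], categories=CMS_ORDER,
                                  ordered=True),
            "icms": pd.Categorical(clin.loc[samples, "icms"], categories=ICMS_ORDER,
                                   ordered=True),
            "msi": clin.loc[samples, "msi"],
            "fibrosis": pd.Categorical(clin.loc[samples, "fibrosis"],
                                       categories=FIBROSIS_ORDER, ordered=True),
            "score": scores.scores.loc[samples],
            "status": risk.loc[samples],
        },
        index=pd.Index(samples, name="sample_id"),
    )
    order = ann.sort_values(["cms", "icms", "fibrosis", "score"],
                            kind="mergesort").index
    return HeatmapTable(
        matrix=z[order],
        blocks=pd.Series(blocks, name="signature_block"),
        annotations=ann.loc[order],
    )


@dataclass(frozen=True)
class EnrichmentResult:
    """Fisher exact test of risk status against a target subtype.

    ``table`` rows are status (high, low), columns are target membership
    (yes, no).  The odds ratio is the cross-product ratio ad/bc with the
    infinity convention for zero cells.
    """

    table: np.ndarray
    odds_ratio: float
    p_value: float
    n: int


def enrichment_test(
    statuses: pd.Series,
    clinical: pd.DataFrame,
    target: Callable[[pd.DataFrame], pd.Series] | None = None,
) -> EnrichmentResult:
    """Test enrichment of status = 1 samples in a target subtype.

    ``target`` maps the indexed clinical frame to a boolean Series; the
    default marks CMS4-and-fibrotic samples.  Two-sided Fisher exact p
    by hypergeometric enumeration.
    """
    if hasattr(statuses, "statuses"):  # accept a RiskStatus directly
        statuses = statuses.statuses
    clin = clinical.set_index("sample_id") if "sample_id" in clinical.columns else clinical
    common = statuses.index.intersection(clin.index)
    st = statuses.loc[common].astype(int)
    sub = clin.loc[common]
    if target is None:
        in_target = (sub["cms"] == "CMS4") & (sub["fibrosis"] == "fibrotic")
    else:
        in_target = target(sub).astype(bool)
    if int(in_target.sum()) == 0:
        raise ValueError("target subtype class is empty")
    a = int(((st == 1) & in_target).sum())
    b = int(((st == 1) & ~in_target).sum())
    c = int(((st == 0) & in_target).sum())
    d = int(((st == 0) & ~in_target).sum())
    table = np.array([[a, b], [c, d]])
    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
    else:
        odds = (a * d) / (b * c)
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return EnrichmentResult(table=table, odds_ratio=float(odds), p_value=float(p),
                            n=int(table.sum()))
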