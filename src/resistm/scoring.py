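"""Signature scoring: min–max reflection, combined median and mean scores,
median-split risk status, and row z-scoring.

The central transformation is the per-gene min–max *reflection*

    reflected = min + (max - min) * (max - x) / (max - min) = min + max - x,

with min/max taken over the cohort being scored.  Reflecting a risk-up
gene inverts its ranking so it combines coherently with protective-down
genes: after reflection, *low* transformed values consistently mark the
risk phenotype.  The combined signature score of a sample is the median
of its transformed signature-gene values ("reflected median"); comparator
signatures use a plain mean of member-gene expression.

Scores are cohort-relative (min/max and the median-split threshold are
recomputed per cohort) and are not transferable across cohorts.  Any
monotone normalized expression scale is accepted; log2(TPM+1) is
recommended because the median across genes mixes gene magnitudes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signatures import GeneSignature

__all__ = [
    "ScoreVector",
    "RiskStatus",
    "reflect_gene",
    "score_reflected_median",
    "score_mean",
    "assign_status",
    "assign_risk",
    "zscore_rows",
]

POLARITY_REFLECTED = "lower = higher risk"
POLARITY_MEAN = "higher = higher expression"


@dataclass(frozen=True)
class ScoreVector:
    """Continuous per-sample signature score.

    ``polarity`` documents which direction of the score marks risk:
    reflected-median scores are *lower* in the risk phenotype, mean
    scores simply track expression.
    """

    signature_name: str
    method: str  # "reflected_median" | "mean"
    scores: pd.Series  # indexed by sample id, float
    polarity: str

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.scores.to_numpy(dtype=float))):
            raise ValueError("scores contain non-finite values")


@dataclass(frozen=True)
class RiskStatus:
    """Median-split binarization of a :class:`ScoreVector`.

    ``statuses`` is 1 where the score is strictly above the cohort-median
    threshold, 0 otherwise (samples exactly at the median are "low").
    """

    statuses: pd.Series  # indexed by sample id, int in {0, 1}
    threshold: float
    rule: str = "strictly_greater"


def reflect_gene(values, sample_ids=None) -> np.ndarray:
    """Reflect one gene's expression about its cohort min/max.

    Implements ``min + (max - min) * (max - x) / (max - min)``, which
    simplifies to ``min + max - x``: the minimum maps to the maximum and
    vice versa, and the ordering is exactly reversed.  A constant vector
    (max = min, where the printed form is 0/0) is returned unchanged —
    the continuous limit of the formula.

    Parameters
    ----------
    values:
        Per-sample expression of a single gene (1-D, length >= 1).
    sample_ids:
        Optional ids used to name offending samples in error messages.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("reflect_gene requires a non-empty 1-D vector")
    bad = ~np.isfinite(x)
    if bad.any():
        if sample_ids is not None:
            names = [str(s) for s, b in zip(sample_ids, bad) if b]
        else:
            names = [str(i) for i in np.nonzero(bad)[0]]
        raise ValueError(f"non-finite expression for samples: {names}")
    return x.min() + x.max() - x


def _present_genes(expr: pd.DataFrame, wanted, name: str, missing_policy: str):
    present = [g for g in wanted if g in expr.index]
    missing = [g for g in wanted if g not in expr.index]
    if missing:
        if missing_policy == "error":
            raise KeyError(f"signature {name!r}: genes missing from matrix: {missing}")
        warnings.warn(
            f"signature {name!r}: {len(missing)} gene(s) missing from matrix, "
            f"scoring on the intersection: {missing}",
            UserWarning,
            stacklevel=3,
        )
    return present


def score_reflected_median(
    expr: pd.DataFrame,
    sig: GeneSignature,
    missing_policy: str = "warn",
) -> ScoreVector:
    """Combined signature score: per-sample median of transformed genes.

    Rows of ``expr`` (genes x samples) belonging to ``sig.up_genes`` are
    reflected across the cohort with :func:`reflect_gene`; ``down_genes``
    rows are used unchanged; each sample's score is the median over the
    signature genes.  Polarity: lower score = higher risk.

    ``missing_policy``: ``"warn"`` (default) proceeds on the intersection
    with a warning listing absent genes; ``"error"`` raises.
    """
    if missing_policy not in ("warn", "error"):
        raise ValueError("missing_policy must be 'warn' or 'error'")
    up = _present_genes(expr, sig.up_genes, sig.name, missing_policy)
    down = _present_genes(expr, sig.down_genes, sig.name, missing_policy)
    if not up and not down:
        raise KeyError(f"signature {sig.name!r}: no signature genes present in matrix")
    rows = []
    for g in up:
        rows.append(reflect_gene(expr.loc[g].to_numpy(), expr.columns))
    for g in down:
        rows.append(expr.loc[g].to_numpy(dtype=float))
    mat = np.vstack(rows)
    if not np.all(np.isfinite(mat)):
        raise ValueError("expression matrix contains non-finite values")
    scores = pd.Series(np.median(mat, axis=0), index=expr.columns, name=sig.name)
    return ScoreVector(sig.name, "reflected_median", scores, POLARITY_REFLECTED)


def score_mean(expr: pd.DataFrame, genes, name: str = "mean_score") -> ScoreVector:
    """Mean-expression score over ``genes`` (no reflection).

    Used for the single-arm RESIST-M1/M2 scores and the comparator
    signatures.  Raises if none of the listed genes is present; missing
    genes otherwise trigger a warning and the mean runs on the
    intersection.
    """
    present = _present_genes(expr, tuple(genes), name, "warn")
    if not present:
        raise KeyError(f"score_mean: none of the listed genes present for {name!r}")
    sub = expr.loc[present].to_numpy(dtype=float)
    if not np.all(np.isfinite(sub)):
        raise ValueError("expression matrix contains non-finite values")
    scores = pd.Series(sub.mean(axis=0), index=expr.columns, name=name)
    return ScoreVector(name, "mean", scores, POLARITY_MEAN)


def assign_status(scores: ScoreVector) -> RiskStatus:
    """Median-split a score vector into high (1) / low (0) status.

    The threshold is the median of all samples' scores; a sample is
    "high" iff its score is strictly above the threshold, "low"
    otherwise.  All-identical scores yield an all-zero split with a
    degenerate-split warning.
    """
    s = scores.scores
    if len(s) < 2:
        raise ValueError("assign_status requires at least 2 samples")
    threshold = float(np.median(s.to_numpy(dtype=float)))
    statuses = (s > threshold).astype(int)
    if statuses.sum() == 0 and s.nunique() == 1:
        warnings.warn(
            "all scores identical: degenerate median split (all samples 'low')",
            UserWarning,
            stacklevel=2,
        )
    return RiskStatus(statuses=statuses, threshold=threshold)


def assign_risk(scores: ScoreVector) -> pd.Series:
    """Per-sample risk group (1 = higher-risk) from a median split.

    Accounts for score polarity: for reflected-median scores (lower =
    higher risk) the risk group is the at-or-below-median half; for mean
    scores the above-median half.
    """
    status = assign_status(scores)
    if scores.polarity == POLARITY_REFLECTED:
        return (1 - status.statuses).rename(scores.signature_name)
    return status.statuses.rename(scores.signature_name)


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Z-score each row to mean 0, sample SD 1 (n-1 denominator).

    Constant rows map to all zeros with a warning; a single-sample
    matrix is an error (SD undefined).
    """
    if matrix.shape[1] < 2:
        raise ValueError("zscore_rows requires at least 2 samples")
    vals = matrix.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    constant = (sd == 0).ravel()
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant row(s) z-scored to all zeros",
            UserWarning,
            stacklevel=2,
        )
    safe_sd = np.where(sd == 0, 1.0, sd)
    out = (vals - mean) / safe_sd
    out[constant, :] = 0.0
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
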