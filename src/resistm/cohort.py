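"""Synthetic expression–survival cohort generator.

Emulates the structure of the bulk-RNA colorectal-cancer cohorts the
scoring and survival stages expect: a genes x samples log2-expression
matrix with per-gene baselines and Gaussian noise, CMS/iCMS/MSI/fibrosis
subtype labels, a latent risk subpopulation (by default the CMS4 and
fibrotic samples) in which RESIST-M1 genes are shifted up and RESIST-M2
genes down, optional comparator shifts (stromal genes up, cell-cycle
genes down in risk samples), and exponential proportional-hazards
survival with independent exponential censoring.

All randomness flows through one seeded generator in a fixed draw order
(gene means -> labels -> expression noise -> survival -> censoring), so
identical configs with identical seeds yield bit-identical cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np
import pandas as pd

from .signatures import builtin_registry, RESIST_M1_GENES, RESIST_M2_GENES

__all__ = ["SyntheticCohortConfig", "SyntheticCohort", "simulate_cohort", "truth_summary"]

# Gene groups addressable from comparator_shifts; positive shift = up in risk
# samples.  Signs follow the phenotype: stroma up, cell cycle down.
COMPARATOR_GROUPS = {
    "stromal_up": ("INHBA", "BGN", "FAP", "GADD45B"),
    "cell_cycle_down": ("MKI67", "MYC", "MYBL2"),
}

_DEFAULT_PROPORTIONS = {
    "CMS1": 0.15,
    "CMS2": 0.35,
    "CMS3": 0.15,
    "CMS4": 0.25,
    "unlabeled": 0.10,
}

# Deterministic CMS -> (iCMS, MSI) map; fibrosis is drawn only within CMS4.
_CMS_TO_ICMS = {"CMS1": "iCMS3", "CMS2": "iCMS2", "CMS3": "iCMS2", "CMS4": "iCMS3",
                "unlabeled": "unlabeled"}
_CMS_TO_MSI = {"CMS1": "MSI", "CMS2": "MSS", "CMS3": "MSS", "CMS4": "MSS",
               "unlabeled": "unlabeled"}


@dataclass
class SyntheticCohortConfig:
    """Parameters of the synthetic cohort.

    Expression is simulated directly in log2 space so that shifts are
    additive; survival is exponential with hazard multiplied by
    ``planted_hr`` for risk samples, censored by an independent
    exponential clock.
    """

    n_samples: int = 400
    subtype_proportions: dict = field(default_factory=lambda: dict(_DEFAULT_PROPORTIONS))
    fibrotic_fraction_in_cms4: float = 0.8
    n_filler_genes: int = 200
    baseline_mean: float = 6.0   # log2 units
    baseline_sd: float = 1.5     # log2 units
    noise_sd: float = 1.0        # log2 units
    m1_shift: float = 2.0        # added to RESIST-M1 genes in risk samples
    m2_shift: float = 2.0        # subtracted from RESIST-M2 genes in risk samples
    comparator_shifts: dict | None = None  # group name -> log2 shift magnitude
    baseline_hazard: float = 0.02   # events per time unit (months)
    planted_hr: float = 2.5
    censoring_rate: float = 0.015  # censoring events per time unit
    seed: int = 0
    extra_genes: tuple = ()      # additional symbols appended to the universe

    def validate(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        probs = np.array(list(self.subtype_proportions.values()), dtype=float)
        if (probs < 0).any() or (probs > 1).any():
            raise ValueError("subtype proportions must lie in [0, 1]")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(f"subtype proportions sum to {probs.sum()}, not 1")
        if not 0.0 <= self.fibrotic_fraction_in_cms4 <= 1.0:
            raise ValueError("fibrotic_fraction_in_cms4 must lie in [0, 1]")
        for name in ("baseline_sd", "noise_sd", "m1_shift", "m2_shift",
                     "baseline_hazard", "censoring_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.planted_hr <= 0:
            raise ValueError("planted_hr must be positive")
        if self.n_filler_genes < 0:
            raise ValueError("n_filler_genes must be nonnegative")
        if self.comparator_shifts:
            unknown = set(self.comparator_shifts) - set(COMPARATOR_GROUPS)
            if unknown:
                raise ValueError(f"unknown comparator groups: {sorted(unknown)}")


@dataclass
class SyntheticCohort:
    """Expression matrix, clinical table and per-sample latent truth.

    Sample ids are identical and identically ordered across the three
    components; ``truth['risk']`` is 1 for planted RESIST-M-like samples
    (default rule: CMS4 and fibrotic).
    """

    expression: pd.DataFrame  # genes x samples, log2 scale
    clinical: pd.DataFrame    # sample_id, time, event, cms, icms, msi, fibrosis
    truth: pd.DataFrame       # sample_id, risk
    config: SyntheticCohortConfig


def _gene_universe(config: SyntheticCohortConfig) -> list[str]:
    registry = builtin_registry()
    sig_genes: list[str] = []
    for name in ("RESIST-M", "Yin", "Lin", "RCC7", "RPS"):
        for g in registry[name].genes:
            if g not in sig_genes:
                sig_genes.append(g)
    fillers = [f"FILLER{i:04d}" for i in range(1, config.n_filler_genes + 1)]
    universe = sig_genes + fillers + list(config.extra_genes)
    seen: set[str] = set()
    dupes: list[str] = []
    for g in universe:
        if g in seen and g not in dupes:
            dupes.append(g)
        seen.add(g)
    if dupes:
        raise ValueError(f"duplicate gene symbols in universe: {dupes}")
    return universe


def simulate_cohort(
    config: SyntheticCohortConfig,
    risk_predicate: Callable[[pd.DataFrame], "pd.Series"] | None = None,
) -> SyntheticCohort:
    """Simulate one cohort under ``config``.

    ``risk_predicate`` maps the clinical label frame to a boolean Series
    marking the planted risk subpopulation; the default marks samples
    that are both CMS4 and fibrotic.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _gene_universe(config)
    n = config.n_samples
    samples = [f"S{i:04d}" for i in range(1, n + 1)]

    # 1) per-gene baseline means
    mu = rng.normal(config.baseline_mean, config.baseline_sd, size=len(genes))

    # 2) subtype labels
    labels = list(config.subtype_proportions)
    probs = np.array(list(config.subtype_proportions.values()), dtype=float)
    cms = rng.choice(labels, size=n, p=probs / probs.sum())
    fibrotic_draw = rng.random(n) < config.fibrotic_fraction_in_cms4
    fibrosis = np.where(
        cms == "CMS4", np.where(fibrotic_draw, "fibrotic", "non-fibrotic"), "non-fibrotic"
    )
    fibrosis = np.where(cms == "unlabeled", "unlabeled", fibrosis)
    icms = np.array([_CMS_TO_ICMS.get(c, "unlabeled") for c in cms])
    msi = np.array([_CMS_TO_MSI.get(c, "unlabeled") for c in cms])

    labels_df = pd.DataFrame(
        {"sample_id": samples, "cms": cms, "icms": icms, "msi": msi, "fibrosis": fibrosis}
    )
    if risk_predicate is None:
        risk = ((labels_df["cms"] == "CMS4") & (labels_df["fibrosis"] == "fibrotic"))
    else:
        risk = risk_predicate(labels_df).astype(bool)
    risk = risk.to_numpy()
    if risk.sum() == 0:
        warnings.warn("no samples in the planted risk stratum", UserWarning, stacklevel=2)
    if (~risk).sum() == 0:
        warnings.warn("all samples fall in the planted risk stratum", UserWarning,
                      stacklevel=2)

    # 3) expression = baseline + planted effects + noise
    expr = np.tile(mu[:, None], (1, n)) + rng.normal(0.0, config.noise_sd,
                                                     size=(len(genes), n))
    gene_index = {g: i for i, g in enumerate(genes)}
    risk_cols = np.nonzero(risk)[0]
    if risk_cols.size:
        for g in RESIST_M1_GENES:
            expr[gene_index[g], risk_cols] += config.m1_shift
        for g in RESIST_M2_GENES:
            expr[gene_index[g], risk_cols] -= config.m2_shift
        for group, shift in (config.comparator_shifts or {}).items():
            sign = 1.0 if group.endswith("_up") else -1.0
            for g in COMPARATOR_GROUPS[group]:
                expr[gene_index[g], risk_cols] += sign * abs(shift)

    # 4) survival: exponential PH, hazard scaled by planted_hr for risk samples
    hazard = config.baseline_hazard * np.where(risk, config.planted_hr, 1.0)
    with np.errstate(divide="ignore"):
        event_time = rng.exponential(1.0 / np.where(hazard > 0, hazard, np.nan), size=n)
    event_time = np.where(hazard > 0, event_time, np.inf)

    # 5) independent exponential censoring (rate 0 => never censored)
    if config.censoring_rate > 0:
        cens_time = rng.exponential(1.0 / config.censoring_rate, size=n)
    else:
        cens_time = np.full(n, np.inf)

    time = np.minimum(event_time, cens_time)
    event = (event_time <= cens_time).astype(int)

    expression = pd.DataFrame(expr, index=pd.Index(genes, name="gene"), columns=samples)
    clinical = labels_df.assign(time=time, event=event)[
        ["sample_id", "time", "event", "cms", "icms", "msi", "fibrosis"]
    ]
    truth = pd.DataFrame({"sample_id": samples, "risk": risk.astype(int)})
    return SyntheticCohort(expression=expression, clinical=clinical, truth=truth,
                           config=config)


def truth_summary(cohort: SyntheticCohort) -> dict:
    """Summarize a cohort: stratum counts, event/censoring rates, and the
    planted parameters echoed back."""
    clin = cohort.clinical
    counts = clin["cms"].value_counts().to_dict()
    n = len(clin)
    event_rate = float(clin["event"].mean())
    return {
        "n_samples": n,
        "subtype_counts": counts,
        "n_risk": int(cohort.truth["risk"].sum()),
        "event_rate": event_rate,
        "censoring_rate_observed": 1.0 - event_rate,
        "planted": {
            "m1_shift": cohort.config.m1_shift,
            "m2_shift": cohort.config.m2_shift,
            "planted_hr": cohort.config.planted_hr,
            "baseline_hazard": cohort.config.baseline_hazard,
            "censoring_rate": cohort.config.censoring_rate,
            "noise_sd": cohort.config.noise_sd,
            "seed": cohort.config.seed,
        },
    }
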