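# resistm

Gene-signature scoring and survival stratification for bulk-expression
cohorts of colorectal cancer (CRC), built around the nine-gene RESIST-M
oxaliplatin-resistance/metastasis signature.

Adjuvant oxaliplatin is standard of care for resected stage II/III CRC,
but the stroma-rich CMS4 (and iCMS3-fibrotic) subtype benefits least and
relapses most. RESIST-M captures the transcriptional state of
oxaliplatin-resistant, pro-metastatic tumor cells with two arms:

* **RESIST-M1** (risk-up): *SERPINE1*, *SMARCD3*
* **RESIST-M2** (protective-down, cholesterol biosynthesis): *SC5D*,
  *FDPS*, *MVD*, *HMGCS1*, *HMGCR*, *CYP51A1*, *ACAT2*

This package implements the full stratification analysis as a tested
library plus thin analysis drivers: scoring, median-split risk groups,
Kaplan–Meier / log-rank / Cox survival separation, CMS-subtype
comparisons, the multi-signature heatmap table, a Fisher test of
enrichment in CMS4/fibrotic patients, and a synthetic cohort generator
standing in for cohorts such as TCGA-COADREAD. Four published comparator
signatures ship in the registry (Yin, Lin, the 7-gene recurrence-score
subset RCC7, and the DNA-repair score RPS).

## The score

For each risk-up gene, expression is *reflected* about its cohort range,

    reflected(x_s) = min + (max − min) · (max − x_s) / (max − min) = min + max − x_s,

so that its ranking is inverted and it combines coherently with the
protective-down genes. A sample's combined RESIST-M score is the median
of its nine transformed gene values (lower score = higher risk); each
sample is called high or low by comparison with the cohort-median score
(strictly above = "high"). Single arms and comparator signatures use the
mean of member-gene expression. Risk groups are compared with the
log-rank test and a Cox proportional-hazards hazard ratio (HR), with
log-log Greenwood confidence intervals on the KM curves.

## Worked example

```python
from resistm import (PipelineConfig, run_pipeline)

report = run_pipeline(PipelineConfig(seed=1))   # synthetic demo cohort, n=400
cox = report["survival"]["RESIST-M"]["cox"]
lr = report["survival"]["RESIST-M"]["logrank"]
enr = report["enrichment"]
print(f"HR {cox.hr:.2f} [{cox.ci_lower:.2f}, {cox.ci_upper:.2f}], "
      f"log-rank p {lr.p_value:.3g}, enrichment p {enr.p_value:.3g}")
```

prints

```
HR 1.45 [1.12, 1.87], log-rank p 0.00433, enrichment p 1.06e-22
```

i.e. on the default simulated cohort (risk stratum = the ~20% of samples
that are CMS4 and fibrotic, RESIST-M1 up / RESIST-M2 down by 2 log2
units, planted hazard ratio 2.5) the RESIST-M-high half of the cohort
has a 1.45-fold higher death hazard — attenuated from 2.5 because the
forced 50/50 median split dilutes a 20% risk stratum — and is very
strongly enriched for CMS4/fibrotic patients.

The same analysis as a narrative, step by step:

```
python analysis/01_simulate_cohort.py      # cohort -> scratch/cohort/
python analysis/02_score_signatures.py     # per-sample scores + risk calls
python analysis/03_survival_stratification.py
python analysis/04_subtype_enrichment.py
python analysis/05_calibration.py          # replicated calibration studies
```

`03` prints, for the same seed-1 cohort:

```
signature      HR           95% CI   log-rank p
RESIST-M     1.45 [  1.12,   1.87]      0.00433
RESIST-M1    1.28 [  0.99,   1.66]       0.0555
RESIST-M2    0.55 [  0.43,   0.72]     6.04e-06
Yin          0.87 [  0.67,   1.12]        0.275
Lin          1.10 [  0.85,   1.41]        0.483
RCC7         1.03 [  0.80,   1.33]          0.8
RPS          1.10 [  0.85,   1.42]        0.482
```

— the combined signature and its arms separate survival (high RESIST-M2
expression is protective, HR < 1), while the comparator signatures,
which the generator leaves untouched, do not. A `resistm` command-line
interface (`generate`, `score`, `stratify`, `enrich`, `run`) wraps the
same functions for file-based cohorts.

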