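# iescape

Immune-escape (IE) profiling of lymphoma transcriptomes: a reusable
pipeline for the two-axis enrichment analysis that places tumors such as
classical Hodgkin's lymphoma (cHL) and diffuse large B-cell lymphoma
(DLBCL, GCB and non-GCB subtypes) into four immune-escape stages, together
with signature-based leukocyte deconvolution, immunohistochemistry marker
dichotomization, and survival analysis.

## Who this is for

Computational groups working with bulk lymphoma expression cohorts
(normalized log2 microarray or RNA-seq matrices) who want to score
immune-escape biology per sample, relate it to tumor composition, and
test its prognostic value — plus a fully synthetic cohort generator so
the entire pipeline can be exercised and validated without any external
download.

## The method

**Sample enrichment score (SES).** For a gene set *S* with *m* genes in a
matrix of *G* genes, each sample's genes are ranked by descending
expression (ties broken by ascending symbol). A running sum gains
`r_i^α / Σ_{j∈S} r_j^α` at each in-set gene (with `r_i = G − rank + 1`
the descending rank weight and `α` the weight exponent, default 0.25) and
loses `1/(G − m)` at each out-of-set gene; the SES is the sum of the
running-sum values over all *G* ranks. At `α = 0` the score depends on
ranks only and is invariant under any monotone per-sample transform.

**IE staging.** Each sample is scored on two axes — the 33-gene
immune-escape signature IEGS33 (checkpoints, their ligands,
immunosuppressive enzymes and cytokines) and a 44-gene T-cell-activation
signature — and thresholded against the pooled mean SES of 1000 random
gene sets of matched size (platform-specific null calibration):

| stage | IEGS33 | T-activation | interpretation |
|---|---|---|---|
| 1 | low | low | non-immunogenic tumor |
| 2 | low | high | immunogenic, not escaped |
| 3 | high | high | immunogenic, escaped |
| 4 | high | low | fully escaped |

**Deconvolution.** Per-sample proportions of 14 leukocyte and
non-hematopoietic cell types solve `min ‖S f − b‖₂, f ≥ 0` in linear
expression space over the signature genes (per-gene dispersion weighting;
NNLS default, linear ν-SVR optional), renormalized to the simplex.

**Survival.** Kaplan–Meier with Greenwood variance and log-log 95% CIs,
log-rank tests, and univariate Cox regression (Efron ties). Times are in
months; 5-year survival is the curve at t = 60. IHC markers are split
high/low at 10% positive cells (microenvironment/total) or 20% (tumor
cells), strictly greater counting as high.

## Worked example

```python
import numpy as np
from iescape import (CohortSpec, simulate_cohort, score_axes, assign_stage,
                     stage_summary, fit_fractions, km_estimate, logrank_test)

cohort = simulate_cohort(CohortSpec(seed=7))   # 400 samples, 3 groups
axes = score_axes(cohort.expression, cohort.iegs_set, cohort.tact_set,
                  n_draws=1000, seed=7)
staged = assign_stage(axes, groups=cohort.stages["group"])
print(stage_summary(staged).to_string(index=False))
```

```
        group  stage  count  percent
    GCB DLBCL      1     40     40.0
    GCB DLBCL      2     35     35.0
    GCB DLBCL      3     10     10.0
    GCB DLBCL      4     15     15.0
          cHL      1      1      1.0
          cHL      2      1      1.0
          cHL      3     97     97.0
          cHL      4      1      1.0
non-GCB DLBCL      1     50     25.0
non-GCB DLBCL      2     46     23.0
non-GCB DLBCL      3     64     32.0
non-GCB DLBCL      4     40     20.0
```

The staged composition recovers the generator's design exactly: nearly
all cHL at stage 3 (97%) versus roughly a third of non-GCB DLBCL (32%),
the structure this kind of analysis is built to expose. Continuing:

```python
fractions = fit_fractions(cohort.signature, cohort.expression,
                          scale="log2_input")
mae = np.abs(fractions.data.to_numpy()
             - cohort.fractions.data.to_numpy()).mean()
print(f"deconvolution MAE vs generating truth: {mae:.4f}")
for stage in (1, 2, 3, 4):
    sub = cohort.survival[cohort.survival["stage"] == stage]
    km = km_estimate(sub)
    lo, hi = km.ci_at(60.0)
    print(f"stage {stage}: S(60 mo) = {km.survival_at(60):.2f} "
          f"[{lo:.2f}, {hi:.2f}]  (n={len(sub)})")
```

```
deconvolution MAE vs generating truth: 0.0104
stage 1: S(60 mo) = 0.56 [0.43, 0.66]  (n=91)
stage 2: S(60 mo) = 0.73 [0.60, 0.82]  (n=82)
stage 3: S(60 mo) = 0.54 [0.45, 0.63]  (n=171)
stage 4: S(60 mo) = 0.50 [0.34, 0.64]  (n=56)
```

Cell-type fractions are recovered to about one percentage point under
0.5 log2 units of measurement noise, and the stage-wise Kaplan–Meier
curves reflect the generator's survival calibration (best outcome at
stage 2, worst at stage 4) within the confidence intervals one expects
at these group sizes.

A command-line interface mirrors the library
(`iescape simulate | score | stage | deconvolve | survival | compare |
report`); `iescape report --config run.yaml` runs the full pipeline and
writes a provenance manifest that suffices to reproduce the run.

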