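# Methods

This note documents the models, parameter choices, numerical conventions
and limitations behind the `iescape` pipeline, in the order the method
runs.

## Enrichment scoring

The sample enrichment score (SES) is a single-sample GSEA statistic.
Within each sample, genes are ranked by descending expression; ties are
broken by ascending gene symbol so that results are identical across
runs and platforms. Walking down the ranked list, the running sum gains
a normalized rank weight `r^α / Σ_{in-set} r^α` at each in-set gene
(`r = G − position + 1`, so the most expressed gene carries weight `G`)
and loses `1/(G − m)` at each of the `G − m` out-of-set genes. The SES
is the sum of the running-sum values over all `G` positions — the area
under the walk. The implementation uses the equivalent closed form
`Σ_k increment_k · (G − k + 1)`, which reduces scoring to two
matrix products and lets thousands of gene sets (e.g. null draws) be
scored at once; the test suite checks it against a literal running-sum
enumeration.

Parameters: `weight_exponent` (unitless, default 0.25). At 0 every
in-set gene contributes equally and the score is a pure rank statistic,
invariant under any strictly monotone per-sample transform; 0.25 gives
the classic mild up-weighting of highly expressed genes. The scoring
variant of single-sample GSEA in circulation differs between tools, so
the exact form here is a package decision and the exponent is exposed.

Degenerate inputs: a set with no gene in the matrix, or covering every
matrix gene (miss term undefined), is an error. No cross-sample
normalization is applied by default — scores are compared within a
cohort on one platform; an optional min-max rescaling is provided.

## Null calibration and staging thresholds

Random gene sets do not score zero, and their typical SES differs
between platforms, so the high/low decision threshold is estimated on
the cohort being staged: `n_draws` (default 1000) uniform random sets of
the same effective size as the signature are scored, and the pooled mean
over draws and samples is the threshold. Draws are seeded and
reproducible. Published stagings of this kind do not pin down whether
thresholds were random-set means, normal-tissue means, or fixed
constants; the calibration strategy here is configurable (explicit
thresholds can be passed) and the random-null pooled mean is the
package's documented default, not a claim about anyone else's choice.

Staging is strict: a score exactly on the threshold is "low"
(strictly-greater is the package's documented boundary convention). The quadrant map is
(low, low) → 1, (low IEGS, high T-act) → 2, (high, high) → 3,
(high IEGS, low T-act) → 4; the four stages partition any cohort.

A caveat that matters for interpretation: for an *unspiked* cohort the
fixed signature is statistically one draw from the null, so its SES sits
on one side of the pooled null mean for the whole cohort at once. The
per-axis false-positive rate of the threshold is therefore a statement
across cohorts, not across samples within one cohort.

## Differential expression and clustering

Per-gene two-group comparisons within a signature use the Mann–Whitney
U test (default) or Student's t, two-sided, with no multiple-testing
correction by default — matching the per-gene "p < 0.05" convention of
the field — and Benjamini–Hochberg behind a flag. Genes constant in both
groups are reported with statistic 0 and p = 1 rather than an error.
Average-linkage hierarchical clustering of samples on z-scored signature
rows is provided as an ordering utility only; dendrogram layout is not
part of the tested surface.

## Deconvolution

The mixture model is linear in linear-scale expression: `b = S f` with
`f` on the simplex. Log2 input is unlogged (`2^x`) before solving,
controlled by the `scale` flag, because log-space mixing is not linear.
Before solving, each signature gene is weighted by the inverse of the
signature's per-gene standard deviation across cell types. This weighting
is deliberately *not* a full z-score: subtracting the per-gene mean would
make the weighted signature columns sum to zero gene-wise, leaving the
solution identifiable only up to a uniform offset, and would break both
exact recovery of noiseless mixtures and scale equivariance. The
dispersion-only weighting is linear, so a noiseless simplex mixture is
recovered exactly for any signature, and multiplying a bulk profile by a
positive constant provably leaves the normalized fractions unchanged.
Full centering is available via `center=True` for comparison.

Solvers: NNLS (deterministic, default) and linear ν-SVR over
ν ∈ {0.25, 0.5, 0.75}, keeping the ν with the lowest RMSE and clipping
negative coefficients — the support-vector flavour of CIBERSORT-style
deconvolution. Both renormalize to the simplex. No per-sample
permutation p-value is computed (out of scope).

`build_signature` derives a signature from labeled pure profiles: mean
profile per type, signature genes = union of the top-k genes by
*absolute* one-vs-rest mean difference per type (down-regulated markers
are markers too), deterministic given input order. The actual 14-type
signature used on real cohorts is treated as a required user input; the
package ships only synthetic signatures for testing.

A known identifiability caveat: fractions estimated from expression are
expression-mass fractions. If cell types differ in total mRNA content,
cell-count proportions differ from the recovered simplex by per-type
mass factors; the generator sidesteps this by simulating mixtures in
expression space.

## Survival analysis

Kaplan–Meier, log-rank and Cox fits are delegated to lifelines behind
the module surface. Choices: Efron tie handling for Cox (month-resolution
clinical data is heavily tied, where Efron is markedly better than
Breslow), log-log 95% confidence intervals for KM (bounds stay in
[0, 1]), Greenwood variance reported per event time and set to 0 once the
risk set is exhausted. Time is months throughout; "5-year survival" is
the curve at t = 60. PFS and OS share the machinery — the event column
of the clinical table defines the endpoint. Complete separation in Cox
(monotone partial likelihood) is caught, refit with a small ridge
penalty, flagged on the result and warned about rather than returning an
unbounded coefficient.

A closed-form Cox score test at β = 0 is implemented directly
(`cox_score_test`); on tie-free two-group data it equals the log-rank
chi-square, which the tests verify to 1e-6 as a cross-check between the
two computational routes.

Marker dichotomization: 10% positive cells for microenvironment and
whole-section scores, 20% for tumor-cell scores (the conventional
cutoffs for these stains), strict ">", with a cohort-median alternative
behind a flag. Survival splits default to the 10% microenvironment
cutoff.

## Group statistics

Two-group tests (Student t with pooled variance, or Mann–Whitney exact
for two tie-free groups of ≤ 8, normal approximation with tie correction
otherwise) and one-way ANOVA are thin wrappers over scipy. The
normal-versus-non-normal gate that decides between t and U in practice
is an analytic decision and is *not* automated: the caller chooses, and
an optional Shapiro–Wilk advisory is logged. ICC(A,1) — two-way model,
absolute agreement, single rater — is computed from the two-way ANOVA
mean squares, so a constant bias between raters lowers the coefficient;
it is cross-checked against pingouin in the tests. The Hans
cell-of-origin rule is implemented as published (CD10+ → GCB;
CD10−/BCL6− → non-GCB; CD10−/BCL6+ splits on MUM1), with the
conventional 30% positivity threshold as an upstream parameter.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
at desk scale:

* **Genes.** Default 2000 genes (a deliberate scale-down of the
  ~20,000-gene collapsed matrices the method targets; nothing in the
  pipeline depends on the total beyond null-set sizes). The immune-escape
  set has 33 genes and the T-activation set 44, matching the published
  set sizes; named members are real symbols from the starter lists,
  padded with clearly-labelled synthetic symbols (`*_SYN*`).
* **Expression.** Pure profiles have shared Gaussian log2 baseline
  N(6, 1); each of 14 cell types raises its 30 marker genes by 3 log2
  units. Marker rows are then lowered by the expected log2 elevation a
  Dirichlet mixture inherits from the raised type (computed by
  quadrature over the Beta marginal), so every gene's expected bulk
  level equals its baseline and zero-spike cohorts remain exchangeable
  with random gene sets. Bulk samples mix pure profiles on the simplex
  (flat Dirichlet by default) in linear space and are re-logged;
  Gaussian log2 noise (default sd 0.5) is added last.
* **Quadrant placement.** Per sample a designed stage is fixed
  (largest-remainder allocation of each group's stage proportions, so
  designed compositions are exact); the IEGS33 genes move by ±spike/2
  (up in stages 3–4, down in 1–2) and the T-activation genes likewise
  (up in stages 2–3). The symmetric placement makes designed-low samples
  sit below the random-null threshold and designed-high above it, and
  collapses to exchangeability when the spike is 0. Default spikes are
  3 log2 units.
* **Default composition.** cHL 100 samples at 97% stage 3; non-GCB
  DLBCL 200 samples with 32% stage 3 (remainder 25/23/20 across stages
  1/2/4); GCB DLBCL 100 samples weighted toward stages 1–2 — the
  published composition where printed, a realistic choice where not.
* **Survival.** Stage-dependent exponential with monthly hazard
  `λ_s = −ln(S5_s)/60`, calibrated to 5-year survival 44/70/48/38% for
  stages 1–4, with independent uniform censoring on [0, 120] months
  (roughly half the observation window — realistic mixed censoring with
  no extra parameters), switchable off.
* **Markers.** Stage-conditioned Beta draws: checkpoint markers
  (PD-1, PD-L1, LAG-3, TIM-3) in stages 3–4 use Beta(3,7) (ME) and
  Beta(3,6) (tumor) versus Beta(1,19)/Beta(1,24) otherwise; T-cell
  markers (CD3/4/8) are Beta(5,4) in immunogenic stages 2–3 versus
  Beta(2,8). These shapes exist to exercise dichotomization and survival
  splits, not as a biological claim.

One seed drives everything through named `SeedSequence` children
(profiles, fractions, stages, noise, survival, markers); identical seeds
give bitwise-identical cohorts.

**What passing tests do and do not show.** The generator preserves the
rank structure the SES depends on, simplex mixing, and stage-conditioned
survival/marker structure. It does not emulate probe-level noise, batch
effects across assembled series, platform differences, gene–gene
correlation beyond cell-type co-expression, or the extreme rarity of
malignant Hodgkin cells (~1% tumor content) beyond a mixing fraction.
Recovery results here therefore validate the pipeline's correctness and
calibration, not its robustness to every artifact of real microarray
meta-series.

## Problem sizes and reproducibility

Validation runs use cohorts of 400 samples × 2000 genes for staging,
200 mixtures for deconvolution, 500 subjects per stage for survival
calibration, and 1000 random draws for null thresholds — sizes chosen so
the whole validation suite completes in well under a minute while
keeping Monte-Carlo error small against the tolerances tested. The
acceptance script averages survival estimates over seeded replicates at
the same per-cohort sizes to report calibrated values rather than single
noisy draws. Every stochastic step takes an explicit seed; the pipeline
writes a manifest (input hashes, parameters, seed, version) sufficient
to re-run identically.

## Known limitations

* Exact reproduction of published signature scores requires the full
  IEGS33/T-activation GMT and the real 14-type signature matrix as user
  inputs; the package ships starter gene lists and synthetic signatures.
* Gene symbols are matched case-sensitively after trimming; no alias
  resolution.
* No multivariable Cox, proportional-hazards diagnostics, competing
  risks, batch correction, or deconvolution significance testing.
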