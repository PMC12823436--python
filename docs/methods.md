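# Methods

`metbmi-kit` implements a metabolome-informed BMI (metBMI) analysis stack:
per-layer variance explained by nested cross-validated penalized regression,
a balanced-sampling metBMI model with residual phenotyping, outcome risk
models with likelihood-ratio tests, metabolite panel reduction, and a
bidirectional three-grid mediation engine with rule-based linkage
classification. A seeded synthetic cohort generator with recorded ground
truth makes every stage verifiable at desk scale. This note documents the
models, the conventions chosen where the design was genuinely open, and the
known limits of what the synthetic tests demonstrate.

## Synthetic cohort generator

The generator emulates a middle-aged deep-phenotyping cohort: n = 1,408
participants by default, balanced sexes (coded female = 0 / male = 1
throughout), ages uniform on 50–65 years, BMI lognormal
(meanlog ln 26.5, sdlog 0.145) clipped to [18, 46] kg/m². The sdlog was set
so that, with the default planted metabolome R² of 0.40, the metBMI
residual SD lands near 1.9 kg/m² and the ±2.5 kg/m² residual cuts each
capture roughly 10% of the cohort — the tail-occupancy regime the residual
phenotyping is designed around.

**Metabolome.** Metabolites are generated directly on log scale. The
informative block (267 of 300 by default) follows

    m_j = mu_j + s_j (z + lam f) + gamma h_j d + psi eps_j

with `z` standardized BMI, `f` a shared nuisance factor loading identically
(given the sign `s_j = ±1`) on every informative metabolite, `d` a latent
"metabolic deviation" score independent of BMI with an alternating loading
pattern `h_j` (near-orthogonal to the signal), and `eps_j` idiosyncratic
noise. Because the signal and shared-factor loadings are parallel, the
population R² of BMI on the informative block has the closed form
R² = k / (psi² + k(1 + lam²)), and given a requested joint R² and a
per-metabolite correlation target (default ρ = 0.3, mirroring a prefilter
regime where individual metabolites correlate moderately with BMI) the pair
(lam², psi²) is solved exactly. Requests that admit no positive-variance
solution raise naming the offending parameters; an over-tight per-metabolite
target is relaxed with a log note rather than silently violated. The
achieved population R² is written to the truth record; tests verify it
independently by OLS on an oversized (n = 100,000) oracle sample.

**Microbiome.** Species counts are zero-inflated compositional: per-feature
prevalence uniform on (0.10, 0.95), a per-feature Bernoulli presence mask
applied to lognormal relative abundances, then multinomial sampling at a
uniform random depth (50,000–100,000 reads). This reproduces the behavior a
prevalence filter and multiplicative zero replacement are designed for. No
phylogenetic correlation structure is attempted.

**Outcomes and phenotypes.** Binary outcomes follow
logit = intercept + b₁·z_BMI + b₂·d (defaults: intercept −2.5/−1.5, b₁
0.9/1.0 per SD — odds ratios in the 2.5–2.7 range of cardiometabolic
outcomes). Mediation triples are planted by overwriting the mediator column
with a·exposure + noise and the outcome with b·mediator + c′·exposure +
noise; conflicting triples sharing a mediator (or outcome) raise. The truth
file is written into a separate `truth/` directory and no inference stage
reads it.

**What the generator does not emulate:** batch effects, longitudinal
sampling, non-Gaussian phenotype tails beyond the lognormal BMI,
measurement missingness, and phylogenetic or pathway structure. Passing
tests therefore demonstrate algorithmic correctness and statistical
calibration under a clean generative model, not robustness to real-data
artifacts.

## Preprocessing

Compositional chain: prevalence filter (retain features present in
≥ ceil(p·n) samples; the 5% boundary is inclusive), total-sum scaling,
multiplicative zero replacement with δ = half the row's smallest nonzero
proportion (the paper-cited technique leaves δ unstated; half-minimum keeps
replaced values below all observed ones), then CLR. Row-sum invariants are
enforced to 1e-9.

Rarefaction richness subsamples exactly `depth` reads without replacement
(multivariate hypergeometric), averaging richness over 50 repeats;
under-depth samples are reported missing. The production default depth is
configurable (the reference workflow uses 22 million reads); tests use
small depths where exhaustive enumeration is possible.

Near-zero-variance screening uses frequency-ratio ≥ 19 (= 95/5) and
unique-fraction ≤ 10%, the defaults of the screening tool the analysis
convention comes from. The normality-gated log transform uses the
Anderson–Darling test with the estimated-parameters correction
AA = A²(1 + 0.75/n + 2.25/n²) and the standard piecewise-exponential
p-value approximation (scipy exposes only critical values); non-normal
variables get ln(x + offset) with offset 0 when min > 0, else 1 − min.

## Variance explained (nested CV)

Outer 10-fold / inner 10-fold. Outer folds are seeded and stratified on
target deciles (variance reduction for skewed targets; the convention is
pinned by tests). Within each outer-training set, features are standardized
(training moments only), a 100-point log-spaced penalty grid is built from
the data-derived λ_max down to λ_max·10⁻⁵ (the min-ratio reading of the
"length 100, range 10⁻³–10⁻⁵" convention; an absolute range is available
via `lambda_range`), and the inner CV picks the penalty minimizing mean
squared error with ties broken toward the larger penalty. For ridge the
grid anchor is 1000× the lasso λ_max (the glmnet-style data-scaled anchor)
and the path is evaluated by a single SVD per inner fold.

Hold-out R² uses the held-out fold's own mean in the denominator, so a
predictor emitting that mean scores exactly 0 and negative values are
reported as-is. Per-fold coefficient hashes are retained so the no-leakage
property (corrupting a fold's targets after fold assignment leaves that
fold's model unchanged) is directly assertable.

Layer comparison: pairwise two-sided rank-sum tests on per-fold R² vectors
(exact enumeration for small tie-free samples, normal approximation
otherwise), BH-corrected, with a compact letter display from the maximal
cliques of the not-significantly-different graph.

## metBMI model

1. **Prefilter** — metabolites with |Spearman ρ| > 0.1 against measured BMI
   and BH q < 0.05 (both gates on by default; the q-gate can be disabled).
2. **Balanced pool** — equal numbers sampled without replacement from the
   six sex × WHO-BMI-class strata (classes [18.5, 25), [25, 30), ≥ 30),
   limited by the smallest stratum. BMI < 18.5 falls outside all strata and
   routes to the non-test set.
3. **Split** — stratified 75/25; the extended test set is the test set plus
   every non-pool sample.
4. **Fit** — ridge by default (lasso available), penalty chosen by 10-fold
   CV-MSE on the same grid machinery as above; predictions are a
   deterministic linear score using stored standardization constants.
5. **Residual phenotyping** — metBMI is residualized by OLS on age, sex and
   measured BMI over the full cohort (the residual-model sample was a free
   choice; full cohort documented and pinned). Residuals > +2.5 kg/m² are
   HmetBMI, < −2.5 LmetBMI — strict inequalities, so boundary residuals
   keep their WHO class. Thresholds are in metBMI units and configurable.
   Cohorts here contain essentially no underweight participants; BMI below
   18.5 is folded into the normal-weight class.

## Risk models

Binomial GLM via IRLS (statsmodels) on the listwise-complete sample, focal
predictors standardized to SD 1 with the population (ddof = 0) SD so
odds ratios per 1-SD are invariant to affine rescaling and row duplication.
Wald CIs at z = 1.96. Constant covariates are dropped with a warning;
perfect collinearity and separation (|standardized coefficient| > 15) raise
rather than fit silently. The LRT is computed from deviances of nested fits
on the identical sample (enforced by a data fingerprint), with the
chi-square upper tail; null calibration is verified by simulation and the
deviances against a direct likelihood optimization.

## Panel selection

The shadow-feature stage appends a permuted shadow copy of **every**
feature each run (keeping the shadow-max threshold's severity constant as
features resolve), computes importances, and records a hit when a real
feature beats the best shadow. Decisions are two-sided binomial tests on
hit counts vs 0.5, Bonferroni-corrected across candidate features, applied
only after a 12-run burn-in (sequential testing from run 1 spends its alpha
on lucky streaks). The run cap (default 999) is a budget; iteration stops
once all features are resolved. The default importance source is the
permutation importance of an extremely-randomized-trees regressor
(256 trees, sqrt feature subsampling), scored on a held-out 30% of rows —
training-set importance rewards memorization and blunts the real-vs-shadow
contrast. A ridge-coefficient source is pluggable; note that sharp linear
importances will eventually "confirm" the top in-sample-spurious feature of
a fixed null dataset (max |r| ≈ 0.15 at n = 500, p = 50 is genuinely
detectable against a permutation null) — an inherent property of
all-relevant selection, masked in practice by ensemble importance noise.

The stability stage fits an L1 model with CV-chosen penalty on ten seeded
80% resamples and reports per-feature selection frequency. The default
panel rule is the confirmed set ranked by frequency then |ρ|; the `union`
rule adds features selected in every stability resample, mirroring the
multi-source union that produced the published 66-metabolite panel. Panels
are refit with the same ridge pipeline on the original split and reported
next to the full model's hold-out R².

## Mediation engine

For each (exposure x, mediator m, outcome y): OLS fits m = α₀ + a·x and
y = β₀ + c′·x + b·m; ACME = a·b (unstandardized indirect effect),
ADE = c′, total = a·b + c′ — an exact identity for linear models.
Uncertainty: joint case-resampling bootstrap of both fits (default 1,000
draws), percentile 95% CIs, two-sided p = 2·min(P(draw ≤ 0), P(draw ≥ 0))
floored at 2/(n_boot + 1). The bootstrap is vectorized — resample index
matrices feed closed-form moment solutions — so full grids run in seconds.
No covariates enter the fits by default (the model is y = x + m); a
covariate hook exists but is off. When the mediator is an exact linear
function of the exposure the outcome design is singular; the degenerate
case is resolved to full mediation (b from y ~ m, c′ the residual direct
effect, zero under exact collinearity), which also fixes the convention for
noiseless worked examples. Proportion mediated is the per-draw ratio
ACME/total summarized by its median and percentile CI, flagged unstable
when more than 5% of total-effect draws cross zero.

**Grids and linkage rules.** Every candidate triple (from a cross-set
Spearman prefilter: |ρ| ≥ 0.1, BH q < 0.05 within each set-pair, features
kept only with ≥ 1 significant cross-set partner) is evaluated in three
orderings: direct (microbiome → metabolite → phenotype), reverse1
(microbiome → phenotype → metabolite), reverse2 (phenotype → metabolite →
microbiome). ACME p-values are BH-corrected within each grid (grid-specific
FDR quantities), ADE p-values within reverse2 only. Classification applies
mutually exclusive rule conjunctions in order: forward requires
FDR-ACME(direct) < 0.05 with all reverse ACME/ADE p-values > 0.05; the
mirror rule gives microbiome → metabolome via phenotype; phenotype →
microbiome requires both forward ACME p-values > 0.05 and a significant
reverse2 FDR (subclassed mediated / direct / combined by which of
ACME/ADE fires); otherwise none. Per-grid per-triple bootstrap seeds derive
deterministically from the master seed and the triple id.

**Identifiability limit (important).** For linear-Gaussian chains the three
orderings are close to likelihood-equivalent: a genuine forward chain
x → m → y implies nonzero indirect effects in the reverse grids
(e.g. ACME(reverse1) = ab·b·Var(e_m)/Var(y|x)), and the reverse2 grid is
the distributional mirror of the direct chain with its weak link tested by
a marginal rather than partial correlation — i.e. with *more* power. At
n = 800 and moderate effects the reverse p-values are significant
essentially always, so the rule conjunctions cannot orient clean Gaussian
chains; on such data the classifier returns "none" for planted forward
triples (and labels fork structures phenotype → microbiome). Direction
calls on real data therefore reflect finite-sample asymmetries and
non-Gaussian structure, not identification. The false-linkage control under
a global null (≤ 5% of triples classified) does hold and is verified by
simulation. The acceptance suite asserts the forward-recovery property at
its stated conditions and that assertion is expected to fail on
linear-Gaussian data; it is retained as an honest record of the gap.

## Association statistics

Partial Spearman = rank both variables (average ranks), residualize each on
the covariate design by OLS, Pearson-correlate the residuals; p from the t
approximation at df = n − k − 2. With no covariates this equals plain
Spearman exactly. BH is a vectorized step-up with NaN propagation.
Group-difference testing: tie-corrected Kruskal–Wallis omnibus plus
pairwise rank-sum with BH; exact enumeration is used for small tie-free
groups and serves as the oracle in tests.

## Pipeline and reproducibility

One master seed fans out to per-stage (and per-triple) streams via a
CRC-mix of (seed, stage label), so stages are decoupled and reruns are
bit-identical for deterministic outputs. The run manifest records the
config snapshot, input digests, per-stage timings and counts, software
version and the seed ledger. Default desk-scale pipeline: n = 800, 300
metabolites, 150 species, 20 phenotypes, 200 bootstrap draws.

## Problem sizes used in tests and the acceptance script

Cohort-scale checks run at the generator defaults (n = 1,408, 300
metabolites, planted R² 0.4) or the stated study conditions (nested CV at
n = 1,400 / p = 300 / R² 0.6; mediation coverage at n = 500 with 500
bootstrap draws and 200 replicates; null linkage grids of 100 triples).
The shadow-selection run budget is 40 runs at desk scale (decisions
typically resolve by run 20–35 at n = 600; the 999-run default remains the
production budget), and the acceptance script reports null-linkage rates
over 10 seeds and forward recovery over 5 seeds of 10 triples.

## Known limitations

- Direction of mediation is not identified for Gaussian data (above).
- Percentile bootstrap CIs slightly undercover for strongly skewed ACME
  distributions at small n; coverage is verified at n = 500.
- The mediation engine handles continuous variables only (binary outcomes
  and mediators are out of scope).
- Shadow selection tests in-sample relevance; with sharp importance
  sources it will confirm the strongest spurious feature of a fixed null
  draw given enough runs.
- The generator's clean factor structure makes penalized-regression
  recovery easier than on real metabolomes with heteroscedastic,
  platform-dependent noise.
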