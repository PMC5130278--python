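# Methods

## Phenotype and cohort model

The generator emulates a two-generation longitudinal study of weekly alcohol
consumption. Each cohort is described by a `CohortDesign`: a list of
occasions (label, mean age, age SD), a never-drinker fraction, an
incidental-zero fraction, and a per-wave dropout hazard. The built-in
designs place mothers on 10 occasions at mean ages 28.2 → 48.3 (age SD
~4.5 y) and offspring on 5 occasions at 15.1 → 20.5 (age SD 0.3–0.6 y).

Log weekly units follow a random-intercept linear model,

    log u_it = μ + β_age·age_it + Σ_j β_j g_ij + a_i + e_it,
    a_i ~ N(0, τ²),   e_it ~ N(0, σ²),

with units = exp(log u). All logs are natural logs throughout (so a
log-scale effect β converts to a 100·(1 − e^β) percent change in units).
Zero inflation acts at two levels, mirroring the zero patterns of real
consumption questionnaires: a fraction `p_never_drinker` (default 0.10) of
persons report zero at every occasion, and each remaining occasion is
independently zeroed with `p_zero_occasion` (default 0.15). Dropout is
cumulative from the second wave (default hazard 0.05/wave), reproducing the
declining wave sizes typical of postal follow-up.

Defaults `τ² = 0.7`, `σ² = 0.5` give an intra-person correlation of ~0.58
for the non-genetic part — heavy tracking of drinking habit over time —
and, with 5 occasions and vg = 0.2, a person-level (occasion-averaged)
variance of 1.0, which is convenient when comparing against the accuracy
model (below). `β_age = 0.02`/yr and `μ = 0.3` put median weekly units in
the single digits, the scale of the emulated questionnaires.

## Genotypes

Markers are a curated candidate panel (default m = 89; roughly three
quarters GWAS-sourced, the rest functional; MAF ~ U(0.05, 0.5); about two
thirds imputed). Markers are simulated **without LD**: the emulated panel
is a curated candidate set spread over the genome, and the accuracy model
assumes independent markers. Hard-called markers are Binomial(2, maf) under
HWE. Imputed markers are posterior-mean-like continuous dosages in [0, 2]
built as the sum of two Beta allele doses with mean maf and variance scaled
by an imputation accuracy of r² = 0.9 (the emulated panel retains imputed
markers only above r² = 0.8) — so imputed dosages are slightly
variance-shrunk, as real posterior means are.

Sparse effects: exactly round(m·π₀) markers are null; the rest draw
standardized effects N(0, vg/(m(1 − π₀))), so the panel explains vg of the
trait variance in expectation. Dosage-scale effects divide by the marker's
**actual** dosage SD — including the imputation shrinkage — rather than the
idealised √(2·maf·(1−maf)); without this the realized genetic variance of a
two-thirds-imputed panel falls ~8% short of the declared vg, which is
measurable as a downward bias of cross-validated R² against the accuracy
model. Both scales are stored; association is reported per copy of the
minor allele (dosage scale).

A structured two-subpopulation mode for the PC covariates is deliberately
not provided-by-default: PCs are independent standard normals, and the
confounder panel (default 48 columns, half binary/half continuous) is drawn
independently of genotype, making the pleiotropy screen null by
construction; a single confounder can be injected with a chosen correlation
to a named SNP as a positive control.

## Association stage

Analysis is restricted to ever-drinkers (persons whose units are zero at
every observed occasion are dropped person-wise, as derived from the data);
zero-unit occasions among ever-drinkers are dropped record-wise because
log 0 is undefined. Both removals, plus sensitivity exclusions (whole waves;
flagged records such as pregnancy), are reported in a filter audit.

Two routes fit the per-SNP repeated-measures model:

* `fit_repeated` — REML `statsmodels.MixedLM` with a person random
  intercept; fixed effects dosage + age + 10 PCs; Wald test with the normal
  approximation. On REML non-convergence it refits once by ML, then flags
  `converged=False` rather than returning silent NaNs.
* `scan_repeated` — estimates (τ², σ²) once per dataset from the
  covariate-only model by Swamy–Arora moments, whitens each record
  (y*_it = y_it − θ_i ȳ_i with θ_i = 1 − √(σ²/(σ² + k_i τ²))) and solves
  every per-SNP regression in closed form via Frisch–Waugh residualisation
  on the shared covariates. For a person-constant regressor this is the GLS
  estimator and is asymptotically identical to the mixed model while being
  ~10³× faster, which is what makes cross-validation and the simulation
  studies tractable. The two routes are compared directly in the test
  suite; the scan's null z statistics are calibrated (mean 0, SD 1.01 at
  n = 3,200 in our checks).

Cross-sectional analysis is OLS per occasion with the same covariates.
Multiplicity uses Bonferroni; the cross-sectional family counts occasions
across both cohorts (10 + 5 = 15). Reported p-values are rounded to two
significant figures in report files only; machine-readable outputs keep
full precision.

The pleiotropy screen regresses each confounder on each instrument (OLS for
continuous, logistic for binary), with a Bonferroni verdict per pair; the
same operation with `kind="outcome"` and an age adjustment serves
score-vs-risk-factor regressions (e.g. HDL, blood pressures).

## Score construction and cross-validation

A score at threshold t is S_i = Σ_{j: p_j ≤ t} β̂_j g_ij with training-sample
weights; selections are nested in t by construction. Cross-validation
splits **persons** (never records) 80/20, stratified by cohort when both are
analysed together; per repeat the per-SNP models are re-fit on training
persons only and a score per threshold is evaluated on held-out persons;
the default grid is {0.01, 0.05, 0.1, 0.2, 0.4, 0.5} over five repeats, and
ties in mean R² resolve to the smaller (more parsimonious) threshold. Final
weights are re-fit on all persons at the selected threshold and exported in
a PLINK `--score`-compatible layout.

Predictive R² for repeated measures is not uniquely defined; we use the
squared Pearson correlation between the score and **person-mean log units**,
both residualized on person mean age and the PCs — simple, model-free, and
faithful to "predict repeated measures" since the person mean is the
minimum-variance summary under the random-intercept model. A zero-variance
score reports R² = 0 with a warning rather than NaN.

## Accuracy model (variance explained)

For a unit-variance trait, m independent standardized markers, training
size n₁ and per-marker sampling variance s² = 1/n₁, a marker's estimated
effect is X ~ N(0, σ_γ² + s²) (non-null, σ_γ² = vg/(m(1−π₀))) or N(0, s²)
(null), and enters the score when |X| > c = z_{1−p/2}·s. With
E_v[X²; c] = v·2(Φ(−a) + aφ(a)), a = c/√v, the expected score–trait
squared correlation is

    ρ² = Cov² / VarS,
    Cov  = m(1−π₀)·(σ_γ²/(σ_γ²+s²))·E_{σ_γ²+s²}[X²; c],
    VarS = m(1−π₀)·E_{σ_γ²+s²}[X²; c] + m·π₀·E_{s²}[X²; c],

which reduces to the classical vg²/(vg + m/n₁) at p = 1. A brute-force
two-stage simulation with the same assumptions (`simulate_two_stage_r2`)
validates the formula: at m = 89, n₁ = n₂ = 4,000 the analytic value agrees
with 3,000-replicate simulation to within ~0.001 absolute (the residual is
a genuine finite-m/finite-n₂ second-order effect, well inside the
Monte-Carlo tolerance used in testing).

Inversion: observed score results (z statistics, or R̂² converted via
z = √(n₂R²/(1−R²))) are modelled z ~ N(√λ, 1), λ = n₂ρ²/(1−ρ²), and the
likelihood is maximised over vg ∈ [0, 1) with π₀ fixed (default; the
typical workflow reports one score per cohort) or jointly estimated from
≥ 2 thresholds — in which case thresholds are treated as independent
observations, an acknowledged approximation since nested selections are
correlated, and the result is flagged `multi_threshold`. The 95% CI is by
profile likelihood (χ²₁ cut-off 3.841); a boundary solution at vg = 0
yields a one-sided interval. In simulation at vg = 0.05, n₁ = n₂ = 20,000,
single threshold 0.5, the estimator shows < 1% median relative bias and
~95% CI coverage.

When the cross-validated pipeline is compared against this model (the
package's own consistency check), the generator runs with zero inflation
and dropout off and person-level variance normalized to 1 (τ² = 0.7,
σ² = 0.5, 5 occasions, vg = 0.2), because the accuracy model assumes a
complete continuous unit-variance trait; n₁ in the prediction is the
post-split training count. Across replicate cohorts of n = 4,000 the mean
held-out R² at the selected threshold matches the forward prediction with
no detectable bias (−0.002 ± 0.005 over 60 runs during development).

## MR design formulas

The score–outcome Wald test through an instrument explaining r² of exposure
variance has non-centrality λ = n·r²·(ln OR)²·φ(1−φ) for a binary outcome
with case fraction φ, giving

    n = (z_{1−α/2} + z_{pow})² / (r²·(ln OR)²·φ(1−φ)),

and power Φ(√λ − z_{1−α/2}); the continuous-outcome analogue replaces
(ln OR)²·φ(1−φ) with β². Design sizes are reported rounded **up** to a
granularity of 100 (conservative design numbers; configurable). This
formula with that convention reproduces all four published CVD/CHD design
sizes exactly (126,500; 54,200; 89,300; 38,300 at OR 0.75/0.71 ×
r² 0.3%/0.7%), whereas the attenuation-corrected variant used by some online
calculators does not; the ceiling convention is therefore a documented
assumption of this module.

## Numerical and engineering choices

* All randomness flows through `numpy.random.default_rng` with explicit
  seeds; a fixed seed reproduces byte-identical tables, CV results and
  pipeline output directories (no timestamps are written).
* Moment-based variance components are clipped at 0 (τ²) and 10⁻¹² (σ²);
  monomorphic SNPs raise a degenerate-input error instead of emitting NaNs.
* Profile-likelihood roots are bracketed by `brentq` at 10⁻¹⁰ tolerance;
  the vg optimiser is bounded scalar minimisation at 10⁻⁸.
* Genotypes travel as VCF v4.2 (DS dosage field preferred, GT fallback;
  multi-allelic records rejected by name) or wide TSV + panel TSV; missing
  dosages exclude a person from that SNP's analysis (complete-case).
* Test problem sizes: simulation studies in the suite use cohorts of
  500–4,000 persons, 500-replicate brute-force grids and 200-replicate
  recovery/coverage runs — chosen so each check has useful Monte-Carlo
  resolution while the whole suite runs in about a minute.

## What passing tests do and do not show

The generator realises exactly the model the analysis assumes: independent
markers, normal sparse effects, a linear age trend, exchangeable occasions,
missingness (dropout, zeros) independent of genotype. Passing checks
therefore demonstrate internal statistical correctness — calibration,
recovery, agreement with closed forms — not robustness to LD between
candidate SNPs, genotype-correlated attrition or reporting bias,
non-normal effect-size distributions, age-varying genetic effects, or real
population stratification (PCs here are pure noise). Random slopes and
richer within-person covariance are deliberately not simulated: the
analysis stage fits a random-intercept model, and the generator emulates
exactly that structure.
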