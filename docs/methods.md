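# Methods

`famgxe` estimates how the predictive power of polygenic indices (PGIs) for
cognitive and noncognitive skills varies with family socioeconomic status
(SES) across seven educational outcomes, using the three family-based
designs of the gene-environment (G×E) interaction literature: between-family
regression, within-family (sibling/DZ-twin) fixed effects, and the trio
design that conditions on both parents' PGIs. Because the register data such
analyses run on cannot be redistributed, the package pairs the estimation
machinery with a synthetic family-cohort generator whose structural
parameters are known, so every stage is testable by parameter recovery.

## 1. The synthetic cohort

**Genetics.** Each family has a father, a mother, a twin pair (MZ or DZ) and
possibly one or two full siblings, with the arrangement drawn from a
configurable mix. Founder genotypes at `n_loci` biallelic loci are
`Binomial(2, p_l)` with `p_l ~ U(maf_low, maf_high)`; loci are unlinked.
Children inherit one allele per locus from each parent (`Bernoulli(d/2)`
for parental dosage `d`); an MZ pair is one meiosis duplicated. Linkage
disequilibrium is deliberately absent: the designs rest on the transmission
algebra (MZ correlation 1, sibling/parent-child PGI correlation 1/2,
child-midparent 1/√2), not on realistic LD structure, and those
correlations are verified by simulation against their closed forms.

**PGIs.** Two weight vectors (cognitive, noncognitive) are drawn once per
scenario, i.i.d. normal with scale `pgi_weights_scale`. Raw scores are
weighted dosage sums, z-standardised against the genotyped children; the
same affine map is applied to parents so child and parent PGIs share a
scale. Genotype missingness is person-wise at `missing_genotype_rate`
(default 0.25, applied to parents as well — that is what gives the trio
design its stricter sample); masked persons keep NaN observed PGIs while
the latent truth is retained in `pgi_*_true` columns, because biology does
not depend on assay availability.

**Passive rGE and SES.** Each parent's education propensity is
`rge_strength · (PGIcog + PGInoncog)/√2 + N(0,1)`, thresholded so that the
family-level maximum of the two education indicators (the dominance rule)
equals `ses_base_rate` in expectation — with independent parents the
per-parent rate is `1 − √(1 − ses_base_rate)`. The default base rate of
0.41 mirrors the share of higher-educated fathers in genotyped twin-register
analytical samples. Because SES depends on parental genotypes only, the
child-PGI/SES correlation induced by `rge_strength > 0` vanishes
conditional on both parents' PGIs — exactly the identification property the
trio design exploits, and a property test of the generator.

**Outcomes.** Each of the seven outcomes has its own latent index

    Y* = intercept + β_cog·PGIcog + β_noncog·PGInoncog + β_ses·SES
         + γ_cog·PGIcog·SES + γ_noncog·PGInoncog·SES
         + η_cog·(PGIcog^F + PGIcog^M) + η_noncog·(PGInoncog^F + PGInoncog^M)
         + u_family + e,    u ~ N(0, family_sd²), e ~ N(0, noise_sd²).

`γ` is the G×SES interaction of interest (positive under the Scarr-Rowe
hypothesis, negative under compensatory advantage); `η` is a genetic-nurture
channel (parents' PGIs acting through the rearing environment), zero by
default and switched on only to demonstrate the bias the trio design
removes. Mapping to printed scales:

* *Grades (ages 7/10, maths and reading)*: the z-scaled latent is cut at
  fixed points (−2.054, −1.341, −0.253, 1.036), i.e. category shares
  2/7/31/45/15%, giving SD ≈ 0.89 on the 1–5 scale.
* *CITO test score*: `cito_raw = clip(539.81 + 10.45·z, 501, 550)`; the
  pre-censoring mean/SD were solved once from the censored-normal moment
  equations so the clipped score has mean 538.9 and SD 9.0. The analysis
  variable `cito_z` is the *centred, un-rescaled* latent: the default
  calibration keeps it near unit variance, and — unlike a z-score of the
  censored score, which attenuates slopes by ~3% through the ceiling —
  it makes the structural coefficients the exact estimands of the linear
  fits, which the parameter-recovery tests rely on.
* *Track / attainment*: probit-style thresholds on the z-scaled latent at
  configured prevalences (defaults 0.50 and 0.35; the registry prevalences
  are not published, so these are calibration choices).

Default effect sizes (per-outcome, latent scale) are chosen to be of the
order of the associations reported for these outcomes (roughly 0.1–0.25
latent SD per PGI SD, 0.3–0.55 for SES), with all default interactions
negative (the compensatory direction the evidence favours). Ten ancestry-PC stand-ins and a genotyping
platform indicator are independent noise by default; an optional switch
loads PC1 on mean dosage to emulate stratification. Defaults produce
between-family samples of ~3,700 children (scalable by one multiplier).

## 2. Analytical samples

Per (design, outcome), from children with complete PGIs, SES and the
outcome:

* **between** — one co-twin of every complete MZ pair is dropped at random
  (MZ pairs carry no independent genetic variation).
* **within** — a balanced two-per-family sample: (1) a complete DZ pair;
  else (2) a lone twin plus a (random) sibling; else (3) one random member
  of a complete MZ pair plus a sibling. Families fitting no rule are
  dropped and logged; in user data with inconsistent co-twin zygosity a
  warning is emitted and the MZ rule applies.
* **trio** — the between sample restricted to children with both parents'
  PGIs observed, reusing the between draw so trio ⊆ between.

Random picks use one named sub-seed per (design, outcome) — the register
analyses build per-outcome samples, and whether exclusions are redrawn per
outcome is unstated there; per-(design, outcome) seeding is this package's
documented choice. Every decision lands in a per-family selection log.

## 3. Models and estimation

The baseline between-family model regresses the outcome on both PGIs, SES
and the controls (10 PCs + platform indicators); within-family models drop
SES (family-constant, absorbed); trio models add the four parental PGIs.
Interacted models apply the full covariate-interaction ("Keller") set: the
focal PGI and SES are each interacted with the other PGI, with every
control, and (trio) with every parental PGI — 39 slopes for the between
design with two platform levels, 51 for the trio design. Controls are never
interacted with each other, and "platform × PGI" means one term per
indicator level. A robustness recoding replaces each PGI by middle/top
tercile indicators (boundaries computed on the design sample), carrying the
full interaction structure.

Continuous outcomes use OLS, binary outcomes a linear probability model
(predictions are not truncated to [0,1]), with logistic regression as a
robustness variant. All covariances are family-clustered CR1 sandwiches,
`G/(G−1)·(N−1)/(N−K)`, with t-tests on `G−1` degrees of freedom — the
applied convention; the exact small-sample correction is rarely stated in
this literature, so CR1/`G−1` is the package's documented default. The
within design is fitted by family demeaning (equal to dummy-variable least
squares, verified to 1e-8); `K` counts the demeaned slope columns only.
Family-constant regressors are reported inestimable; collinear columns are
dropped greedily in term order and logged. SES-stratified fixed-effects
fits yield high-minus-low slope differences with
`se² = se_high² + se_low²`; because SES partitions whole families, the
difference equals the interaction coefficient of a pooled fully
SES-interacted FE model (tested to 1e-8). Its reference distribution is t
with `min(G_high, G_low) − 1` df — normal quantiles undercover at
desk-scale family counts.

## 4. Multiplicity

Tests are grouped into families of 7 outcomes per (design, PGI). Bonferroni
uses the analytic clustered-t p-values (per-test threshold 0.05/7 ≈ 0.007).
Romano-Wolf is a step-down maxT adjustment with a pairs cluster bootstrap:
families are resampled with replacement *jointly* across the seven
hypotheses (preserving cross-outcome dependence despite differing
subsamples), each drawn family copy becomes a new cluster, and each
hypothesis is refitted to form recentred studentised statistics
`t* = (β* − β̂)/se*`. Within-design hypotheses bootstrap the stratified
slope difference on per-family demeaned data (demeaning commutes with
family resampling). Rather than literally re-running the sample builders
per resample, each hypothesis reuses its per-family selected rows —
selection is deterministic given the per-(design, outcome) seed and family
content, so the result is identical family-by-family. Singular refits are
redrawn with a cap (default 2B) and a logged count. `B` defaults to 1,000;
tests use 250. Adjusted p-values use the step-down max rule with enforced
monotonicity, `(1 + #{max|t*| ≥ |t|})/(B+1)`.

"Romano-Wolf rejects at least as much as Bonferroni" is not a pointwise
theorem; at desk scale a lone Bonferroni rejection can carry a heavy
bootstrap tail. The suite asserts it per-run under strong signal and in
expectation across the global-null simulation, alongside familywise error
control.

## 5. Power

The analytic calculation inverts the 1-df incremental F-test: adding the
interaction to a model with `k_full` slopes, power is
`P(F(1, n−k_full−1; λ) > F_crit)` with `λ = n·ΔR²/(1−R²_full)` and
`R²_full = r2_base + ΔR²`; the minimum detectable ΔR² at power 0.8 is found
by root-finding (tolerance 1e-10, verified against a grid-scan oracle to
1e-6). The numerator df is 1 because the tested addition is the single
focal interaction. `r2_base` (the reduced-model R², unstated in the
emulated analyses) defaults to 0 and is a parameter. Monte-Carlo post-hoc
power simulates full cohorts under the *generating* effect sizes and runs
the complete chain per replicate, reporting the rejection rate with its
binomial MC standard error; observed-effect post-hoc power is deliberately
not offered (it is known to be uninformative), and the output says the
estimate is assumption-based.

## 6. Pipeline

One run builds the 2 PGIs × 7 outcomes × 3 designs = 42 cells. Between/trio
cells report the focal PGI × SES coefficient from the fully interacted
model; within cells report the stratified FE slope difference — the
comparable quantity in a design where the SES main effect is inestimable.
Cell failures are attached to the cell, never dropped. The tally counts
negative/positive interactions and rejections at raw, Romano-Wolf and
Bonferroni levels; `classify_support` turns the pattern into a verdict on
the two hypotheses. Prediction plots show outcome-scale lines over the
focal PGI in [−2, 2] for low/high SES with delta-method bands from the
clustered covariance.

## 7. Problem sizes in the test suite

Property and acceptance tests run at desk scale, chosen as the package's
own trade-off between Monte-Carlo resolution and turnaround: kinship
correlations at 10,000 families; parameter-recovery coverage at 300
families × 200 replicates (binomial 3-SE bands); the rGE bias contrast at
400 families × 50 replicates; interaction recovery at 300 families × 100
replicates; familywise error at 150 families × 200 cohorts × B=250; power
cross-checks at 400 families × 120 replicates with the implied ΔR²
estimated on 3 × 8,000 families. Several simulation scenarios reduce
`n_loci` to 60–100; locus count only affects PGI granularity, not the
transmission algebra.

## 8. What the generator does and does not emulate

It emulates: family structure with MZ/DZ twins and siblings, Mendelian
transmission, passive rGE with a tunable dial, genetic nurture, SES by the
dominance rule, outcome scales and calibration moments, person-wise
genotype missingness, per-outcome analytical samples. It does not emulate:
linkage disequilibrium or realistic GWAS weight error, assortative mating,
population stratification (beyond an optional toy switch), outcome-specific
participation/missingness, cohort effects, or sampling weights. Passing
recovery tests therefore show the estimators are calibrated under the
stated structural model — not that real-data estimates are unbiased under
violations such as assortative mating (which inflates sibling PGI
correlations above 1/2) or uncorrected stratification.

## 9. Known limitations

LPM interaction estimates on binary outcomes are scale-dependent; the logit
robustness variant addresses direction, not effect-size comparability. The
CR1/t(G−1) convention is first-order; wild-cluster bootstrap inference is
not implemented. The Romano-Wolf implementation assumes the cohort's
families are exchangeable under resampling; stratified or weighted sampling
schemes are out of scope.
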