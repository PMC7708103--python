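# Methods

This note documents the models and procedures implemented in `neomort`,
the defaults they ship with, and the design decisions taken where the
problem left genuine choices open.

## Cohort construction

The analysis cohort is built from three tables (maternal, infant,
cause-of-death questionnaire; schema v1.0, CSV with empty fields for
missing values).  Exclusions are applied sequentially: mothers not
resident in a study cluster, mothers who died before delivery, then
pregnancy outcomes other than live birth (miscarriage, medical
termination, stillbirth).  The ledger counts excluded infant rows per
reason so that excluded + retained always equals the input row count —
an invariant asserted on every generated dataset.  Multiples each
contribute one analysis row sharing the maternal covariates.  Missing
covariates are retained in the cohort and dropped per analysis
(complete case per variable), which is why denominators differ across
tables.  Miscarriage versus stillbirth is an input label, not
recomputed from gestational age; the synthetic generator labels losses
below 20 completed weeks miscarriage and at/after 20 weeks stillbirth.

## Cause-of-death hierarchy

One cause per death, assigned deterministically:

1. major congenital anomaly → *congenital anomaly*;
2. else any infection sign or suspicion (tetanus, omphalitis, sepsis,
   pneumonia, or a general suspicion flag; "present" and "suspected"
   are treated identically) → *infection*;
3. else banded on gestational age at delivery, with birth weight as a
   fallback **only when gestational age is missing** (the weight
   thresholds read as a fallback, and a measured GA is the more direct
   datum):
   - term, GA ≥ 37.0 completed weeks (fallback ≥ 2500 g): *asphyxia*
     if breathing difficulty at birth or respiratory distress, else
     *unknown*;
   - moderate preterm, GA ∈ [34, 37) weeks (fallback [2000, 2500) g):
     *asphyxia* if breathing difficulty and/or any maternal pregnancy
     complication, else *complications of prematurity*;
   - GA < 34 weeks (fallback < 2000 g): *complications of prematurity*.

A moderate-preterm death with no positive sign is not covered by the
narrative rules; it is assigned *prematurity* (a preterm death with
nothing else implicated) and flagged with the provenance code
`moderate_preterm_no_signs` so such assignments can be audited.  Every
assignment carries a rule code.  A record with neither GA nor weight
is assigned *unknown* with a warning rather than an error.  "Breathing
difficulty at birth" and "respiratory distress" are kept as two input
fields; either satisfies the asphyxia sign criterion.  "Maternal
pregnancy complication" is a single caller-supplied flag; the
generator documents what it emits it for.  All band boundaries are
module-level constants.

## Descriptive statistics

The neonatal mortality rate is deaths within 28 days per 1,000 live
births, overall and per delivery year.  Cause distributions are
percentages of classified deaths.  Values are carried at full
precision and rounded half-up to one decimal for display (matching how
surveillance tables are printed); rounding uses decimal arithmetic,
not binary floats.  Categorical status tables use within-status
complete-case denominators.

## Crude relative risks

For a 2×2 table (exposed events *a* of *n₁*, unexposed *c* of *n₀*):
RR = (a/n₁)/(c/n₀), with the log-scale Wald interval
exp(log RR ± z·√(1/a − 1/n₁ + 1/c − 1/n₀)) and a two-sided normal
p-value; z is fixed at 1.959964.  Zero event counts leave the ratio or
interval undefined; the estimate is returned flagged rather than
raising.

## Cluster-robust relative risks (GEE)

One exposure at a time, a log-link binary-outcome marginal model is
fitted by GEE with indicator contrasts against the schema's
conventional reference level, clustered on the study-area identifier.
The working variance is binomial (log-binomial model), started at the
Poisson-variance solution; if that fit fails to converge or produces
invalid fitted means, the log-link Poisson-variance fit is returned
instead and tagged (`cluster_gee_poisson_fallback`).  The working
correlation defaults to independence — sandwich covariances keep the
intervals cluster-robust under any true correlation — with
exchangeable available by option.

Because registries typically have only a few dozen clusters, the plain
robust sandwich is biased downward.  Wald inference therefore defaults
to the Mancl–DeRouen bias-reduced sandwich (`cov_type="bias_reduced"`);
in our simulations at 20 clusters this raised 95% CI coverage from
about 0.90 to about 0.91 for a well-identified birth-weight contrast
(the crude closed form sits near 0.92 at the same conditions).  The
plain robust covariance remains available and is what the QIC uses.
The per-variable p-value is a joint Wald test across the exposure's
non-reference terms (not the minimum per-level p).  A single cluster
is refused with an informative error.  Continuous exposures
(gestational age at delivery) are parameterised per one-unit
*decrease*, so RR > 1 means risk rises as the variable falls.

## Predictive model, QIC, marginal R²

The multivariable model is log-link with Poisson working variance
(binary outcome), robust clustered covariance; exponentiated
coefficients are adjusted relative risks.  The shipped final-model
preset is gestational age at delivery (per-week decrease), birth-weight
band, and antenatal-care visit category.  Newborn treatments and
essential-newborn-care indicators are excluded from default candidate
sets: their occurrence is a consequence of the infant's condition, not
a primary risk factor.

QIC follows Pan (2001): −2·QL(μ̂; independence) + 2·tr(Ω̂ᵢ V̂ᵣ), with QL
the working-family quasi-likelihood at scale 1, Ω̂ᵢ = Σ xᵢxᵢᵀ·(dμ/dη)²/v(μᵢ)
the model-based information under independence, and V̂ᵣ the plain robust
covariance.  On independent data with a correctly specified model this
reproduces the classical −2·loglik + 2p within a fraction of a percent
(an asserted test).  Marginal R² is the squared-error form
1 − Σ(y−μ̂)²/Σ(y−ȳ)² on the response scale (Zheng 2000); it is exactly 0
for an intercept-only fit and 1 for a perfect fit.

Forward selection is greedy: starting from the intercept, each step
adds the candidate minimising QIC and stops when no candidate lowers
it; ties break by candidate list order.  Caveats, by design:

- QIC behaves like AIC, so with several null multi-degree-of-freedom
  candidates the selector admits a noise variable in a nontrivial
  fraction of replicates; it reliably finds a strong true predictor
  first but does not reliably stop immediately after it.  The tests
  assert what the criterion actually delivers (true predictor found
  first and retained).
- QIC values are comparable only across models fitted to the same
  rows; candidates should not differ wildly in missingness.
- An indicator level with no observed events has a divergent log-RR
  and a singular independence information matrix; such terms are
  dropped (merged with the reference) with a warning.  A genuinely
  singular information matrix raises an error naming the term.
- Aliased (linearly dependent) columns are dropped with a warning.

## Synthetic registry generator

The generator emulates the statistical structure the analysis assumes,
at configurable scale, fully reproducible from a seed (random streams
are split per concern — structure, covariates, outcomes, signs, care —
so extending one concern does not perturb the others).

Defaults (a "study conditions" configuration):

- 20 clusters × 5 years, deliveries per cluster-year uniform in
  [300, 500].
- Exclusion cascade fractions 8578/47614 (non-resident), 11/47614
  (maternal death), then 4929 / 2542 / 884 of the remaining 39025
  (miscarriage / termination / stillbirth).
- Maternal covariate marginals equal to the surviving-infant column of
  the reference cohort's maternal table; covariates are drawn
  independently of one another (a stated simplification — no
  ANC × education dependence, for example), with a 0.001 per-variable
  missingness rate.
- Gestational age: two-component truncated-normal mixture, preterm
  probability 0.1046, term N(39.4, 1.3) on [37, 43], preterm
  N(34.4, 2.2) on [22, 36.9] — overall mean ≈ 38.8, SD ≈ 2.3 weeks.
- Birth weight given GA: linear mean 2890 + 165·(GA − 39) g, SD 380 g.
  These constants were tuned once so the birth-weight band frequencies
  among live births land near 0.4 / 0.8 / 19.9 / 78.9 percent
  (realised ≈ 0.2 / 1.0 / 19.9 / 78.9).
- Risk of death among live births: log p = log(0.0135) +
  log(25.6)·[<1000 g] + log(19.8)·[1000–1499] + log(3.1)·[1500–2499] +
  log(1.6)·[ANC 0–1] + log(1.4)·[ANC 2] + log(1.2)·[ANC 3] + u_cluster,
  u ~ N(0, 0.25²) on the log scale.  The intercept was set so the
  implied marginal mortality is ≈ 24.5/1000 (the 2 and 3-visit ANC
  effects, not separately published, are plausible monotone values
  between the 0–1-visit effect and the reference).  Configurations
  whose deterministic worst-case pattern implies p ≥ 1 are rejected at
  validation, naming the pattern; the cluster effect is additionally
  clamped so p < 1 at draw time.  A per-week GA effect and a year
  effect are available but default to off (no secular-trend mechanism
  is simulated).
- Latent causes: each death receives one latent cause.  The hierarchy
  cannot recover every cause at every GA (prematurity needs a preterm
  death; unknown needs a term death), so per-GA-stratum cause
  probabilities are obtained by iterative proportional fitting between
  the realised GA strata of the deaths and the target mixture
  (18.4 / 23.7 / 27.9 / 25.1 / 4.9 percent), restricted to recoverable
  causes.  Signs are then emitted from the latent cause with
  probability `sign_fidelity` (default 0.95): anomalies set the anomaly
  flag; infections set one infection sign (sepsis 0.45, pneumonia 0.30,
  omphalitis 0.10, suspicion 0.10, tetanus 0.05); term asphyxia sets
  breathing difficulty (plus respiratory distress half the time);
  moderate-preterm asphyxia sets breathing difficulty or the
  questionnaire's maternal-complication item; prematurity and unknown
  emit no positive signs.  At fidelity 1.0 the classifier recovers the
  latent labels exactly (a tested round trip).  The questionnaire's
  complication item is sign-driven; the maternal table's
  pregnancy-complication flag is an independent covariate (rate 0.15).
- Twins: Bernoulli event per pregnancy (p = 286/30657), sharing
  maternal covariates, cluster and GA.
- Care/treatment flags: drawn conditional on vital status at the
  reference cohort's observed rates (e.g. bag-mask 50.3% among deaths,
  3.4% among survivors).  Note these are *marginal* emulations — the
  generator does not model the care→outcome causal direction, so
  estimated treatment "effects" on synthetic data reproduce the
  reverse-causal associations of observational registries by
  construction.
- Death timing: truncated geometric (p = 0.15) over days 0–27, a
  front-loaded profile typical of neonatal deaths; the COD form is
  missing with probability 8/758.

What passing tests on this generator do **not** show about real data:
covariate dependence structures, verbal-autopsy misclassification
beyond the single fidelity parameter, geographic or temporal structure
beyond exchangeable cluster effects, and any care-effect causality.

## Numerical conventions and degenerate inputs

- 95% critical value fixed at z = 1.959964.
- Band boundaries: term ≥ 37.0 weeks; moderate preterm [34, 37) weeks,
  weight fallback [2000, 2500) g; strict `<` at 34 weeks / 2000 g.
- Half-up decimal rounding for displayed rates and percentages.
- GEE fits: maximum 200 iterations; log-binomial started at the
  Poisson solution; independence working correlation by default.
- Zero denominators (no live births, empty exposure level) are
  reported as missing/skipped with warnings, not errors; referential
  violations (unknown mother, duplicate infant) are hard errors.
- Pipeline outputs are written with canonical cell formatting (flags
  as 1/0, GA to 0.1 week, weight to 1 g), so a fixed seed yields
  byte-identical artifacts across runs.

## Problem sizes used by the test suite

The default-scale configuration (~40,000 pregnancies) is exercised for
marginal-fidelity and parsing checks; statistical property tests run at
desk scale — typically 10–20 clusters and 2,000–7,000 pregnancies per
replicate, with 40–200 replicates per property — sizes chosen so each
property is well identified while the whole suite stays quick.  CI
coverage, selection-recovery and QIC-penalty rates at these sizes are
recorded in the corresponding tests.

## Known limitations

- The GEE estimates on real registry extracts depend on the actual
  cluster assignments; only crude closed-form estimates are exactly
  reproducible from published count tables.
- The log-binomial fit can fail on covariate patterns with fitted risk
  near 1; the Poisson-variance fallback gives consistent point
  estimates but slightly conservative intervals.
- Marginal R² for rare binary outcomes is intrinsically small and
  depends strongly on the discriminating power of the generating
  effects; it is a descriptive summary, not a goodness-of-fit test.
- The selector's stepwise paths are data-dependent; permuting the
  candidate list changes only tie-broken steps.
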