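# Methods

## Model structure

`coloncc` implements a deterministic Markov cohort model of stage II
colon cancer after curative resection. States: *alive without
recurrence* (the entry state), *recurrence* (expanded into tunnel
sub-states indexed by months since recurrence), and three absorbing
death states — 90-day mortality (90DM), death from other causes (DOC)
and death from colon cancer (DCC). The cycle length is one month; the
default horizon is 600 cycles (50 years, effectively lifelong), with an
early stop once total alive mass falls below 1e-9. Death from colon
cancer is only reachable through recurrence: the model assumes no direct
diagnosis-to-DCC path, so under-ascertainment of recurrences in source
data would propagate to under-predicted cancer mortality.

The Markov property is preserved in the presence of time-dependent
post-recurrence mortality by the tunnel construction: mass entering
recurrence in cycle *c* occupies tunnel slot 1 in that cycle and
advances one slot per cycle, so the slot index equals months since
recurrence. The number of slots equals the horizon; in short-horizon
runs mass reaching the last slot is held there with its hazard frozen at
the final value (conservation is maintained and the condition is
logged).

## Transition parameterization

All parameters live in a YAML registry
(`src/coloncc/data/default_registry.yaml`); the packaged defaults are
the published point estimates of the underlying registry analysis.
Units: time in months, hazards per month.

* **DIAG-90DM** — a total 90-day death probability per 5-year age band
  (0.028 at 50–54 up to 0.333 at 90–95), converted to a constant
  monthly probability via `1 − (1−q)³ = p90` and active in cycles 1–3
  only. The complement rule (not `p90/3`) is used so probabilities
  compose multiplicatively.
* **DIAG-DOC** — Gompertz proportional-hazards model,
  `h(t) = b·exp(β_age)·exp(0.010·t)`, with age-band log hazard ratios
  (reference 50–54). The published baseline rate rounds to 0.000 with a
  CI of (0.000; 0.001), so it is re-derived by a one-dimensional least
  squares fit of `b·exp(β_age)` to the published monthly REC-DOC
  probability column (the model's own assumption is that the other-cause
  hazard is the same before and after recurrence). The closed-form
  optimum is `b = Σ q·e^β / Σ e^{2β}` = 2.28839e-4 per month, inside the
  published CI; it is stored explicitly in the registry so results do
  not depend on re-running the calibration. The probability column is
  treated as the hazard evaluated at state entry (t = 0); treating it as
  a typical-time value would change `b` by well under the width of the
  published CI.
* **DIAG-REC** — Gompertz with shape −0.016 (decreasing hazard; the
  distribution is defective, i.e. a fraction of the cohort is cured of
  recurrence risk), baseline rate 0.004, and proportional-hazards
  coefficients: ≥10 evaluated lymph nodes −0.519, pT4 vs pT3 1.081,
  left- vs right-sided 0.505. Two registry versions are packaged:
  `original_2002_2008` and `updated_2015`, which multiplies the pT4
  coefficient by the external-validation factor 1.36 (1.081 → 1.470).
  Strategy evaluation defaults to `updated_2015`.
* **Biomarker status** enters as hazard ratios multiplying the
  covariate-adjusted recurrence hazard: MSI 0.247, MSS double-wild-type
  0.880, MSS BRAF/KRAS-mutant 1.528, applied as printed without
  renormalizing the population-average hazard to one (the implied mild
  population-level shift, average multiplier ≈ 0.93 under the default
  biomarker mix, is accepted as part of the parameterization).
* **Treatment** multiplies the recurrence hazard by the regimen hazard
  ratio in treated arms; the default regimen is FOLFOX-vs-none,
  0.78 × 0.94 = 0.7332 (the product of the two trial-derived ratios; it
  prints as 0.73). The alternative reading in which the Gompertz *shape*
  is multiplied by the hazard ratio is available behind
  `treatment_on_shape=True` but is not the default: scaling the negative
  shape would flatten the hazard's time decay and *raise* late hazard,
  contradicting a protective effect, whereas the proportional-hazards
  reading matches how the ratio was estimated.
* **REC-DEATH** — log-logistic accelerated-failure-time model, shape
  1.17, scale 1390 months times `exp(offset)` per age band; the offsets
  (−3.439 … −6.059) are exactly linear in band index (−0.3275 per band,
  i.e. −0.0655 per year of midpoint age), consistent with an underlying
  continuous-age fit. The resulting median post-recurrence survival
  ranges from ≈ 45 months at 50–54 to ≈ 3 months at 90–95.
* **REC-DOC / REC-DCC** — the monthly other-cause probability per age
  band (0.000 … 0.006) is subtracted from the all-cause monthly
  probability derived from the log-logistic survival ratio; the
  colon-cancer share is the remainder, floored at zero (the floor is
  logged; it does not bind under the packaged parameters).

## Competing-risk correction

The three transitions out of the alive state are mutually exclusive.
Per cycle, cause-specific cumulative-hazard increments `ΔH_k` are
computed (for 90DM, `−log(1−q_monthly)` in cycles 1–3), and the mass
leaving the alive state is `(1 − exp(−ΔH_tot))·S_{t−1}`, shared among
causes in proportion to `ΔH_k/ΔH_tot`. This exact-exponential form
cannot transfer more mass than is available, reduces to `1 − exp(−ΔH)`
for a single cause (which is how the engine reproduces closed-form
single-risk survival to 1e-9), and agrees with the first-order literal
product `h·S` for small monthly hazards; the literal form is available
via `cicr_form="literal"` for sensitivity analysis (it shifts five-year
all-cause mortality by ≈ 0.005 in a high-risk subgroup — regression
tested).

Mass conservation is asserted inside the engine at 1e-9 and verified in
tests at 1e-12 per cycle.

## Cohort composition and strategies

The evaluation cohort spans 216 cells: 9 × 5-year age bands (50–95; the
youngest published band is realized as 50–54 because the model covers
ages from 50), 2 lymph-node categories, 2 pT stages, 2 sidedness levels,
3 biomarker classes. Default weights are the product of independent
marginals: age from a Normal(70.7, 10.9) truncated to [50, 95) and
binned; pT4 214/2221, ≥10 nodes 946/2144, left-sided 987/2238 (registry
cohort counts with unknowns excluded); biomarker (28, 39, 36)/103 from
the external biomarker cohort. Independence of biomarker status from
clinical factors is an explicit assumption. Aggregation over cells (and
over treated/untreated arms within cells) is linear, which the tests
exploit as a mixture invariant.

Patients are not aged across bands during a run: a subgroup keeps its
baseline age-band hazards for the whole horizon (a convention inherited
from the source parameterization; it matters mostly beyond the five-year
reporting window). Patients surviving past the oldest band retain its
coefficients.

**Known limitation — composition sensitivity.** Absolute per-1,000
counts at five years are strongly sensitive to the assumed cohort
composition, much more than the between-strategy differences: the
recurrence hazard varies roughly seven-fold across cells (e^1.47 for
pT4 alone), so shifting a few percent of weight between high- and
low-risk cells moves the cohort totals by several per 1,000. In
particular, raising the ≥10-evaluated-nodes prevalence toward
contemporary levels (node yields rose substantially after the
mid-2000s) lowers both recurrence and DCC counts appreciably while
leaving the relative strategy comparisons nearly unchanged. Comparisons
against an external cohort should therefore re-weight via
`build_cohort_weights` rather than rely on the defaults.

## Fitting workflow

`fit_parametric` maximizes the censored log likelihood
`Σ d_i·log h(t_i) − H(t_i)` for the four candidate families (Gompertz
PH; Weibull, log-normal, log-logistic AFT — all four are implemented
because the development workflow compares them even though the final
model uses only two). Positivity of rate/scale/shape is enforced by
optimizing on the log scale (quasi-Newton with a Nelder–Mead fallback;
non-convergence raises with the final gradient norm). Standard errors
come from the numerically differentiated observed information
(delta-method back-transforms for log-scale parameters). Categorical
covariates are dummy-coded against the first canonical level; rows with
missing covariate values are dropped (complete case). `select_family`
picks the lowest AIC (ties broken by listed order) and returns the AIC
table for the human visual-inspection step. `forward_select` adds, per
step, the candidate with the smallest Wald p (joint chi-square across a
covariate's dummies, which reduces to the two-sided z-test for a single
coefficient), stopping at the two-sided threshold p ≥ 0.157 — the
AIC-equivalent rule, |z| ≈ √2. All parameters are refitted at each
step; the procedure is deterministic given the data. One unit test
cross-checks a Gompertz fit against R's `flexsurv` on the same records.

## Validation statistics

`uno_c` is the inverse-probability-of-censoring-weighted concordance:
pairs (i, j) with `t_i < t_j`, `t_i < τ` and an observed event for i are
weighted `1/G(t_i^-)²`, with G the Kaplan–Meier estimate of the
censoring distribution (via lifelines); risk ties count one half. It is
invariant under strictly monotone transforms of the predictions, and
with no censoring it equals Harrell's C (verified against a brute-force
pair enumeration and against scikit-survival's implementation). The
confidence interval is a leave-one-subject-out jackknife that holds the
censoring estimate fixed — the extra variance from estimating G is
higher-order and ignored.

`gnd_test` groups subjects by predicted-risk quantiles (ties to the
lower group, deterministic), compares the per-group Kaplan–Meier
observed risk at the landmark time (default 36 months) with the mean
predicted risk, standardized by Greenwood's variance, and sums the
squared standardized differences. Event-free or degenerate groups are
merged with their upper neighbour (logged). The statistic is referred
to chi-square with (groups − 1) degrees of freedom, which is calibrated
when the predictions come from a model fitted to the same data (the
internal-validity workflow; verified by simulation: statistic mean ≈ 8.9
and variance ≈ 20 with 10 groups). With fully external predictions the
statistic has approximately one more degree of freedom, and sparse
groups (≲ 10 expected events) inflate it — hence the ≥ 5 expected
events precondition and the warning the function emits.

## Synthetic-data generator

`synthetic_data` emulates the statistical structure the fitting and
validation modules assume — nothing more. Per patient: a subgroup cell
is drawn from the composition; 90-day mortality is a latent exponential
with hazard `−log(1−p90)/3` on (0, 3] months (marginally exactly
Bernoulli(p90), but on the same cause-specific-hazard footing as the
other transitions, so that patient-level competing risks are the exact
micro-level equivalent of the cohort engine's CICR allocation);
other-cause death and recurrence are independent latent inverse-CDF
draws from the Gompertz models (the defective recurrence distribution
returns +∞ beyond the cure mass); post-recurrence survival is
log-logistic, with the death cause classified by the monthly
other-cause share at the discretized death month. Censoring defaults to
administrative cut-off at 60 months plus uniform(0, 120) dropout —
loosely emulating registry follow-up, without claiming to reproduce it.
Output is a long-format record table (one row per patient per
transition, competing events acting as censoring within each
transition) plus a wide per-patient history table whose discretized
outcome months use the same cycle conventions as the engine, making
empirical state occupancies directly comparable to a cohort trace (the
engine-vs-Monte-Carlo acceptance check uses a million patients and a
three-binomial-SE band).

What the generator does **not** emulate: registry under-reporting of
recurrences, missing-data patterns, covariate-dependent censoring,
biomarker–clinical correlation, or treatment-effect heterogeneity.
Passing recovery and equivalence tests therefore show internal
consistency of the machinery, not fidelity to any real registry.

## Numerical conventions

* Time origin t = 0 at state entry; cycles are half-open months
  (t−1, t]; a continuous event time in that interval belongs to cycle t.
* Gompertz cumulative hazard uses the `expm1(x)/x` form, continuous at
  shape 0 (the exponential limit).
* No half-cycle correction: reported outcomes are cumulative event
  counts, not person-time; a half-cycle option is left to a future
  cost-effectiveness layer.
* Report tables round half-up; unrounded values are always retained.
* Registry YAML round-trips floats bit-exactly; unknown or missing keys
  are hard errors, guarding against silent misconfiguration.
* The CLI writes a JSON manifest (command, parameter hash, seeds,
  timestamps, outputs) for every run; the only stochastic component is
  the synthetic-data generator, which is fully determined by its seed.

## Scope

Costs, utilities/QALYs, probabilistic sensitivity analysis and
treatment-effect heterogeneity are out of scope. The cohort engine is
the primary computational path; micro-simulation exists only as a test
oracle. Problem sizes used by the test suite (10⁶ Monte-Carlo patients,
2 × 10⁴-patient recovery fits, 500–1,000 statistical replicates) were
chosen as the smallest sizes at which the statistical tolerances are
sharp.
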