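# Methods

## The model

`lnmrisk` builds a clinical risk score for time-to-lymph-node-metastasis
(LNM) after HCC resection from binary covariates. The statistical core is
a Cox proportional-hazards model of time from surgery to LNM, with all
non-LNM exits treated as right-censoring. The score-building recipe is:

1. **Univariate screening.** Each of the 19 candidate factors (age > 51,
   female sex, HBsAg, HCV antibody, AFP > 20, ALT > 40, γ-GT > 50,
   cirrhosis, Child-Pugh B, differentiation III–IV, size > 5 cm, multiple
   tumors, absent encapsulation, vascular invasion, BCLC B–C, and the four
   binary miRNA calls) is fit alone in a Cox model; factors with two-sided
   Wald p < α (default 0.05) proceed. Contingency-style association
   (Pearson χ² without continuity correction, or two-sided Fisher exact
   when any expected cell is below 5) is available for descriptive tables.
2. **Joint fit and pruning.** Screened factors enter a joint Cox fit
   (partial likelihood, Efron tie approximation via lifelines). Covariates
   whose joint Wald p ≥ α are dropped and the model is refit once, so the
   final score contains only independently predictive factors.
3. **Weights.** Each retained covariate's Wald statistic
   χ²ⱼ = (β̂ⱼ/seⱼ)² is divided by the smallest retained χ² and rounded
   half-away-from-zero to one decimal. The minimum factor therefore weighs
   exactly 1.0 and weights express relative contribution to the joint fit.
   The rounding convention matters at the boundary (11.665/4.496 = 2.594 →
   2.6; 7.485/4.496 = 1.665 → 1.7) and is applied with an explicit
   half-away rule rather than banker's rounding.
4. **Total score and cutoff.** A patient's score is the sum of the
   weights of the factors they carry. Cutoff candidates are the midpoints
   between consecutive distinct attained scores; for each candidate the
   2×2 (score > cutoff × event) Pearson χ² is computed and the maximizer
   chosen, ties broken toward the smaller cutoff. The Cochran–Armitage
   χ² for linear trend across all attained score levels is computed
   alongside as a diagnostic (it equals N·r² for the point-biserial
   correlation r; this identity is exercised in the tests). The trend
   test names the selection *criterion family*; since the search
   procedure itself is under-determined in the source material, the
   deterministic max-χ²-midpoint rule was chosen and both statistics are
   reported.

### Marker scoring

Two pathologists' readings are combined by averaging **final scores**
(not raw components), then thresholding the mean without rounding:
miR-145 positive iff score > 4 (additive 0–5 system), miR-31 positive iff
score > 3 (same system), miR-92a positive iff score > 0.5 (intensity-only
0–3; the half-point threshold only makes sense on averaged values), and
miR-10b high iff ≥ 20 % of cells stain (inclusive on the high side; the
other three markers are negative at their threshold). Any number of
raters ≥ 1 is accepted; readings from multiple tissue cores are averaged
together with rater replicates and the multi-core case is logged, since
no separate core-resolution rule is defined. qRT-PCR relative expression
is 2^−ΔΔCt with ΔCt = Ct(target) − Ct(reference) in sample and calibrator.

### Evaluation conventions

* Risk group is **high iff score > cutoff**; a score exactly at the
  cutoff is low-risk. This convention is fixed and embedded in the model
  artifact.
* Horizon metrics (default 60 months): a patient is a case if the event
  occurred by the horizon, a control if followed event-free through it,
  and **excluded** if censored event-free earlier. No
  inverse-probability-of-censoring weighting is applied; reports carry a
  `censoring_convention` label. When a denominator is empty the metric is
  NaN with a warning, not an exception.
* AUC is the Mann–Whitney probability of correct case/control ranking of
  the **continuous** total score (ties get half credit), computed on the
  horizon-evaluable subset.
* Cumulative incidence is 1 − Kaplan–Meier survival with right-continuous
  step lookup; no competing-risks decomposition (death before LNM is
  censored, which overstates absolute incidence when competing mortality
  is high — a known limitation).
* The high-vs-low contrast is a single-covariate Cox fit of the group
  indicator plus the standard two-group log-rank χ².

### Numerical choices

* Cox fits use lifelines. Its default Newton step can overshoot into a
  divergent region on perfectly well-conditioned inputs (observed with a
  14 %-prevalence covariate at n = 2000); fits are therefore retried with
  damped step sizes (0.5, 0.25, 0.1). A fit that only completes with
  convergence warnings is *flagged*: univariate flags become a
  separation sentinel (infinite hazard ratio, NaN p) that screening skips
  on p, and joint-fit flags surface as warnings.
* Wald quantities are recomputed from (β̂, se): χ² = (β̂/se)², 95 % CI =
  exp(β̂ ± 1.96·se), p from the 1-df χ² survival function. exp() overflow
  maps to infinity rather than raising.
* Collinearity among joint-fit covariates is detected up front (pairwise
  |r| ≈ 1 and design-matrix rank) and reported with the offending factor
  names.
* Only the Efron tie approximation is available; requesting another tie
  method is a validation error rather than a silent fallback.

## The synthetic-cohort generator

Real patient-level data behind the motivating study are not deposited, so
the generator stands in for them with the structure the pipeline assumes:

* **Factors:** a Gaussian copula — draw Z ~ N(0, R), set xⱼ = 1 iff
  Zⱼ ≤ Φ⁻¹(pⱼ) — gives exact marginal prevalences with positive
  association among the five score factors. Default prevalences are the
  192-patient training-cohort marginals (e.g. vascular invasion 27/192,
  miR-31 35/192). Default latent correlation is 0.4 among the five score
  factors and 0 elsewhere: the qualitative correlation is asserted in the
  source material but unquantified, so 0.4 is an explicit assumption
  exposed as a config default, not an estimate.
* **Event times:** exponential with rate h₀·exp(Σβⱼxⱼ), default βⱼ =
  log of the five published multivariate hazard ratios (5.151, 2.899,
  3.630, 3.506, 3.449) and 0 for the 14 remaining factors. The constant
  baseline is the simplest shape consistent with proportional hazards;
  nothing in the pipeline depends on baseline shape.
* **Censoring:** uniform on (36, 126) months, spanning the studies'
  reported follow-up ranges. When h₀ is not given it is solved (Brent's
  method on a closed-form event probability averaged over a fixed-seed
  Monte-Carlo covariate sample, memoized per parameter set) so the
  expected observed-event fraction is 12 %, matching the ~23 events per
  ~200-patient cohort of the motivating design.
* **Cohort pair:** `generate_paperlike_pair` draws independent 192- and
  209-patient cohorts from disjoint child seeds.
* **ISH readings:** for each patient × marker, two raters' readings are
  emitted from fixed representative patterns ((3,2) for miR-145-positive —
  the only additive cell scoring above 4 — (3,1)/(1,1) for miR-31, 2/0 for
  miR-92a, 60 %/5 % for miR-10b). Optional rater noise slips intensity by
  ±1 (±5 percentage points for miR-10b) per reading; a call can then flip
  only when both raters slip toward the boundary, so the flip rate is
  bounded by (noise/2)² per flip-prone call, which the tests verify.

What the generator does **not** emulate: non-proportional hazards,
time-varying covariates, competing mortality, informative censoring,
inter-hospital case-mix differences, and any marker-to-outcome pathway
beyond the log-linear hazard. Passing recovery tests therefore show that
the pipeline correctly inverts its own generative assumptions at scale;
they do not validate those assumptions against real registries.

## The recovery study

`run_recovery_study` repeatedly (default 50 replicates, chosen to bound
the full-suite runtime while keeping Monte-Carlo error on mean weights
below ~0.05) simulates 2000-patient cohorts under the default effects,
re-screens all 19 factors, refits the joint model, and re-derives weights
and cutoff. Two measurement choices:

* the *recovery rate* is the fraction of replicates in which all five
  true factors pass univariate screening (noise factors passing at rate
  ~α do not count against it);
* mean weights are computed from the five true factors' joint-fit χ²
  normalized among themselves. At n = 2000 the true factors carry χ²
  ≈ 30–130 while a false-positive noise covariate enters near the χ²
  significance floor (~4); letting such a covariate set the denominator
  would rescale the entire weight vector by a factor of ~10 in the ~⅓ of
  replicates where one appears, making the factor-for-factor comparison
  against the reference vector meaningless. Normalizing within the five
  target factors measures what the comparison needs: the relative
  contributions of the true model components.

The production path (`build_model`) is stricter than the study: it prunes
joint-fit non-significant covariates and refits, so a deployed score only
contains independently predictive factors.

## Tunable parameters

| Parameter | Default | Units | Notes |
|---|---|---|---|
| `alpha` | 0.05 | — | two-sided screening and pruning threshold |
| `horizon_months` | 60 | months | case/control horizon for confusion metrics |
| `km_lookup_months` | 12, 24, 60 | months | cumulative-incidence report points |
| `tie_method` | efron | — | only Efron implemented |
| `target_event_fraction` | 0.12 | — | simulator calibration target |
| `censoring_window` | (36, 126) | months | uniform follow-up window |
| latent ρ | 0.4 | — | copula correlation among the five score factors |
| `rater_noise` | 0.0 | — | per-reading slip probability in ISH emission |

## Known limitations

* Weights inherit Wald-χ² sampling noise; at ~23 events per cohort the
  derived weight vector (and even the retained factor set) varies
  markedly between replicates, as the README example shows. The score is
  only as stable as its event count.
* The expected-cell < 5 Fisher fallback is a convention; near the
  boundary the two tests can disagree in p-value magnitude.
* The exclude-early-censored horizon metrics are biased when censoring
  before the horizon is outcome-dependent; IPCW alternatives are out of
  scope by design.
* No penalized or stepwise selection, no competing risks, binary
  covariates only.
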