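# lnmrisk

Risk modelling of **lymph-node metastasis (LNM) after resection of
hepatocellular carcinoma (HCC)** from routine clinicopathological factors
and dichotomized miRNA in-situ-hybridization (ISH) calls.

Roughly one in ten HCC patients develops LNM after hepatectomy, and
identifying the high-risk minority early enough for prophylactic regional
radiotherapy requires a pre-metastasis risk score. `lnmrisk` implements the
full construction and evaluation of such a score for biostatisticians and
translational researchers:

1. **Marker scoring** — semi-quantitative ISH readings for miR-145,
   miR-31, miR-92a, and miR-10b are scored per rater (additive
   intensity + percentage systems, an intensity-only four-tier system, or
   percent-of-cells-stained), averaged across raters, and dichotomized at
   each marker's published threshold. qRT-PCR relative expression via the
   2^−ΔΔCt method is included.
2. **Score construction** — each binary factor is screened by a
   univariate Cox proportional-hazards fit of time-to-LNM (two-sided
   α = 0.05); screened factors enter a joint Cox fit (Efron ties); each
   retained covariate's Wald statistic χ²ⱼ = (β̂ⱼ/se ⱼ)² is divided by the
   smallest retained χ² and rounded to one decimal, giving weight

   &nbsp;&nbsp;&nbsp;&nbsp;wⱼ = round(χ²ⱼ / min ₖ χ²ₖ, 1),

   so the least influential factor scores exactly 1.0. A patient's total
   score is Σⱼ wⱼ xⱼ. The high/low-risk cutoff maximizes the 2×2 Pearson
   χ² over midpoints between attained scores (the Cochran–Armitage
   χ² for linear trend is reported alongside).
3. **Evaluation** — risk-group assignment (score > cutoff ⇒ high),
   sensitivity/specificity/PPV/NPV at a follow-up horizon (default 60
   months, excluding patients censored event-free before the horizon),
   Mann–Whitney AUC of the continuous score, Kaplan–Meier cumulative LNM
   incidence, log-rank test, and the high-vs-low Cox hazard ratio.
4. **Synthetic cohorts** — a Gaussian-copula generator draws correlated
   binary factors at specified prevalences and exponential
   proportional-hazards event times with uniform censoring, calibrated to
   a ~12 % event fraction, so the whole pipeline is testable end to end
   without patient-level data (which the motivating study did not release).

## Worked example

The score components of the published five-factor model follow directly
from its printed multivariate Wald χ² values:

```python
from lnmrisk import derive_weights, generate_paperlike_pair, build_model, evaluate_model

chi2 = {"vascular_invasion": 11.665, "bclc_b_c": 5.632,
        "mir145_positive": 6.011, "mir31_positive": 7.485,
        "mir92a_positive": 4.496}
table = derive_weights(chi2)
print("weights:", table.weights)
print("max score:", table.max_score)
```

```
weights: {'vascular_invasion': 2.6, 'bclc_b_c': 1.3, 'mir145_positive': 1.3, 'mir31_positive': 1.7, 'mir92a_positive': 1.0}
max score: 7.9
```

Vascular invasion contributes 2.6 points (11.665/4.496 ≈ 2.59), miR-31
1.7 points, and so on; a patient carrying all five factors scores 7.9
(reported as a 0–8 scale). Rebuilding the model from scratch on a
simulated cohort pair and validating it on the held-out cohort:

```python
train, valid = generate_paperlike_pair(seed=7)   # 192 + 209 patients
model = build_model(train)                        # screen -> fit -> weights -> cutoff
print("fitted weights:", model.score_table.weights)
print("cutoff:", model.cutoff)
report = evaluate_model(valid, model, horizon_months=60.0)
m = report["metrics"]
print(f"sensitivity {m['sensitivity']:.3f}  specificity {m['specificity']:.3f}  AUC {m['auc']:.3f}")
```

```
fitted weights: {'vascular_invasion': 1.0, 'bclc_b_c': 1.3, 'mir145_positive': 1.5, 'mir31_positive': 1.4}
cutoff: 2.85
sensitivity 0.652  specificity 0.955  AUC 0.933
```

At 192 patients (~23 events) screening keeps a data-dependent subset of
the true factors and the weights are noisy — exactly the small-sample
behaviour the recovery study quantifies at n = 2000, where all five
factors are recovered and mean weights land within ±0.5 of the reference
vector.

The same workflow is available from the shell:

```bash
lnmrisk simulate --seed 7 --out-dir data/
lnmrisk build --train data/training.tsv --out-model model.json
lnmrisk evaluate --model model.json --cohort data/validation.tsv --out report.json
lnmrisk apply --model model.json --cohort data/validation.tsv --out scored.tsv
```

`lnmrisk build --chi2-bypass '{"vascular_invasion": 11.665, ...}'` feeds
printed χ² values straight into the weight derivation, making the worked
example executable without any cohort table, and
`lnmrisk score-markers` turns raw two-rater ISH readings into the binary
marker columns the model consumes.

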