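# riskhte

Risk-based analysis of heterogeneous treatment effects (HTE) in randomized
controlled trials with a binary outcome.

The overall effect reported by a trial rarely applies equally to every
patient. Traditional one-variable-at-a-time subgroup analyses (men vs
women, old vs young) are underpowered and compare patients who barely
differ in prognosis. The *risk-modeling* approach does better by
stratifying patients on a multivariable summary — their predicted baseline
probability of the outcome — and asking how treatment benefit varies across
those risk strata. `riskhte` implements that workflow end to end for
trialists and methodologists:

1. a **treatment-blinded** multivariable logistic risk model
   (logit P(Y=1) = β₀ + Σβⱼxⱼ, allocated treatment excluded),
2. a **likelihood-ratio test** of the treatment × linear-predictor
   interaction (`outcome ~ T + LP` vs `outcome ~ T + LP + T:LP`, χ²₁),
3. **quantile binning** of the predicted probabilities into risk groups
   Q1…Qk (quartiles by default),
4. treatment benefit on the **absolute risk difference** scale —
   RD = p̂_treated − p̂_control with Wald 95% CIs — overall, per risk
   stratum, and per traditional subgroup for contrast.

A synthetic-trial generator with controllable effect heterogeneity
(IST-3-like covariates, logistic outcome, interaction of treatment with the
centered linear predictor) makes the whole pipeline testable with no data
download, and powers the shipped calibration/power/coverage simulations.

## Worked example

```python
from riskhte import HTEAnalysis, default_ist3_config, generate_trial

table = generate_trial(default_ist3_config(seed=1))   # 3035 patients
results = HTEAnalysis(table).fit()
print(results.summary())
```

Output (abridged):

```
Risk-based heterogeneous-treatment-effect analysis
====================================================
Complete cases: 3035 of 3035 (0 dropped)

Treatment-blinded logistic risk model
  n = 3035, terms = 22, converged = True
  c statistic = 0.80   Brier score = 0.17
  ...
  age                             0.96      (0.95, 0.97) 3.64e-19
  nihss                           0.85      (0.84, 0.87) 7.26e-94
  ...

LR test for treatment x linear-predictor interaction: chi2(1) = 10.76,
p = 0.0010 (interaction coefficient -0.294 +/- 0.090)

Overall risk difference: -1.8% (95% CI -5.3 to 1.6; P = 0.29)

Quantile risk strata (absolute risk difference, treated - control):
  stratum       n   mean p    RD %              95% CI
  Q1          759    0.069     2.6         (-1.5, 6.6)
  Q2          758    0.252    -2.0         (-7.7, 3.8)
  Q3          759    0.455    -0.8         (-7.9, 6.3)
  Q4          759    0.678    -9.5       (-15.9, -3.0)

Traditional subgroup: sex
  sex=Male                1481    0.359    -1.8         (-6.7, 3.1)
  sex=Female              1554    0.368    -1.8         (-6.6, 3.0)
```

Reading it: the risk model discriminates well (c = 0.80) and orders
patients by baseline probability of a favorable outcome (stratum means
0.07 → 0.68). The overall effect looks null (−1.8%, P = 0.29), but the
interaction test rejects effect homogeneity (p = 0.001), and the stratum
risk differences reveal the gradient the generator encodes: possible
benefit for patients with poor baseline prognosis (Q1), clear harm for
those likely to recover anyway (Q4, −9.5%). Single-variable subgroups
(age, sex) barely register the gradient — their members span nearly the
full risk range, so each subgroup's effect sits close to the overall
−1.8%.

The same analysis runs from the shell:

```bash
riskhte simulate --n 3035 --seed 1 --out trial.csv
riskhte analyze --input trial.csv --schema examples/ist3_schema.yaml --outdir reports/
riskhte oc --n 2000 --replicates 200        # test calibration / power / coverage
```

`reports/` then contains `report.json` (every fitted quantity plus
provenance), `model_fit.json` (the odds-ratio table as data),
`stratum_table.csv`, and `figure_data.json` (per-group probability
densities, overlap coefficients, empirical and model-based stratum RDs —
enough to redraw the standard ridgeline and benefit figures;
`riskhte.plots` renders basic versions).

To analyze a real deposited trial table instead, declare its schema
(`examples/ist3_schema.yaml`) and a column-name mapping from the raw
export (`examples/ist3_mapping.yaml`, user-editable) and pass both to
`riskhte analyze --input ...`.

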