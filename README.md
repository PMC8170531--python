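# mrrest — excess mortality from aggregated prevalence and incidence

Chronic-disease registries, health surveys and insurance claims increasingly
publish *aggregated* age-specific prevalence and incidence, but rarely the
mortality of the diseased themselves. `mrrest` estimates the age-specific
**mortality rate ratio** R(a) = m₁(a)/m₀(a) — the excess mortality of people
with a chronic condition relative to those without — from exactly such
aggregated inputs, and quantifies what imperfect diagnostic accuracy
(sensitivity and specificity of the recorded diagnoses) does to those
estimates.

It is aimed at epidemiologists and biostatisticians working with secondary
data sources such as statutory-health-insurance claims.

## The model

The package is built on the illness-death model for chronic conditions
(states Healthy → Diseased → Dead, no remission). With age-specific incidence
i(a), general mortality m(a) and rate ratio R(a), the age-specific prevalence
p(a) obeys

    dp/da = (1 − p) · { i − m · p(R−1) / [1 + p(R−1)] }        (forward model)

which rearranges into a closed-form estimator for the excess mortality,

    R = 1 + (1/p) · (i − D) / (m − i + D),   D = (dp/da)/(1 − p).

When diagnoses carry sensitivity se and specificity sp, the observed
prevalence mixes true and false positives, `p_obs = se·p + (1−sp)(1−p)`,
which inverts exactly to `p = (p_obs − 1 + sp)/(se + sp − 1)` (and likewise
for incidence, with separate parameters se_p/sp_p and se_i/sp_i interpolated
affine-linearly between a younger and an older anchor age).

Three workflows build on this:

* **Simulation study** (`study`, `tornado`): two built-in settings — a rare
  condition with high excess mortality in young adults (lupus-like, ages
  20–70, prevalence < 1%) and a common condition of older ages
  (type-2-diabetes-like, ages 40–80, prevalence up to ~30%) — quantify the
  upward bias that imperfect accuracy induces in R̂ and rank the eight
  accuracy anchors by importance in a tornado analysis.
* **Correction**: when se/sp are known, observed prevalence and incidence are
  corrected before estimation, removing the bias exactly.
* **Specificity inversion** (`invert-sp`, `fpr-envelope`): for grouped
  claims-style data (prevalence at two calendar years, incidence at
  mid-period, R and m per age group) with the same unknown se and sp for
  prevalence and incidence, the forward model determines sp from the data at
  any assumed se. Sampling se uniformly (default 0.7–0.99, N = 10000)
  propagates the uncertainty into an envelope for the false-positive ratio
  FPR = 1 − sp.

## Worked example

```python
from mrrest import builtin_scenario, base_case_accuracy, run_simulation_study

scenario = builtin_scenario("high_prevalence")
profile = base_case_accuracy("high_prevalence")   # se 95%, sp 99.95%
df = run_simulation_study(scenario, profile)
print(df[df.age.isin([45.0, 55.0, 65.0, 75.0])]
        [["age", "R_true", "R_obs_perfect", "R_obs_imperfect"]])
```

```
 age   R_true  R_obs_perfect  R_obs_imperfect
45.0 3.814282       3.814282        31.312354
55.0 2.864336       2.864336         5.110405
65.0 2.288165       2.288165         2.709315
75.0 1.938699       1.938699         2.053596
```

With perfect diagnostic accuracy the estimator reproduces the true rate
ratio to numerical precision. The base-case imperfection (5% missed cases,
5-per-10,000 false positives) inflates the estimate 8-fold at age 45 but only
by ~6% at 75: false positives overwhelm the small true prevalence and
incidence of the young. The tornado analysis makes the culprit explicit —
the top-ranked inputs are the specificity of the incidence at the younger
and older anchor, and every specificity outranks every sensitivity:

```python
from mrrest import tornado_analysis
for e in tornado_analysis(scenario, profile)[:4]:
    print(f"{e.input_name:12s} {e.outcome_change:.3g}")
```

```
sp_i_young   18.6
sp_i_old     2.41
sp_p_old     0.552
sp_p_young   0.401
```

The same pipeline runs from the shell, e.g.

```
mrrest synth-claims --scenario high_prevalence \
    --midpoints 45,50,55,60,65,70,75 --group-width 5 --seed 1 --out claims.csv
mrrest fpr-envelope --claims claims.csv --se-range 0.7 0.99 --n 10000 \
    --seed 1 --out envelope.csv
```

which writes per-age-group minimum/maximum false-positive ratios and sample
counts. Real grouped datasets use the same CSV format (see
`mrrest.claims.save_claims`): columns `age_mid, p_obs_y1, p_obs_y2, i_obs,
R, m` with `# year1=… # year2=… # group_width=…` header comments.

## Layout

| module | contents |
| --- | --- |
| `mrrest.rates` | rate tables, built-in scenarios, mortality decomposition |
| `mrrest.forward` | prevalence ODE solver (RK4), finite differences |
| `mrrest.misclassification` | accuracy profiles, corrupt/correct maps |
| `mrrest.estimator` | rate-ratio estimator, per-age profiles |
| `mrrest.inversion` | specificity inversion Φ, FPR envelope |
| `mrrest.claims` | grouped claims datasets, synthetic generator, CSV I/O |
| `mrrest.study` | simulation-study workflow, tornado analysis |
| `mrrest.cli` | `mrrest` command-line interface |

See `docs/methods.md` for the modelling assumptions, numerical choices and
known limitations.
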