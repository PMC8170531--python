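# Methods

## Model and scope

`mrrest` treats a chronic condition with the three-state illness-death model
(Healthy, Diseased, Dead; no remission). Transition rates are the incidence
i(a), the mortality of the healthy m₀(a) and of the diseased m₁(a); instead
of (m₀, m₁) the package works with the general mortality
m = p·m₁ + (1−p)·m₀ and the mortality rate ratio R = m₁/m₀, which are the
quantities available from vital statistics and published studies. All rates
are treated as functions of age only (time-homogeneous). Under that
reduction the directional derivative (∂t + ∂a)p of the age-specific
prevalence becomes the ordinary derivative of a single age profile and the
prevalence obeys

    dp/da = (1 − p)·{ i − m·p(R−1)/[1 + p(R−1)] }.

Calendar-time trends, cohort effects and remission are out of scope.

Solving this ODE forward is the simulation engine; solving it for R given
(p, dp/da, i, m) is the estimator; combining it with the misclassification
algebra below yields the specificity inversion.

## Misclassification

Observed prevalence and incidence mix true and false positives:

    x_obs = se·x + (1 − sp)·(1 − x),    x ∈ {p, i},

with separate (se, sp) for prevalence and incidence, each anchored at a
younger and an older age and interpolated affine-linearly. For se + sp > 1
the map inverts exactly; corrected values outside [0, 1] raise a flagged
error rather than being clipped, because infeasibility is itself informative
(it bounds the admissible accuracy). The incidence correction applies the
same proportion algebra to the per-person-year rate as printed; no
person-time adjustment is attempted.

The identifiability condition se + sp > 1 is enforced at profile
construction. Note the structural asymmetry that drives all downstream
results: (1 − sp) enters x_obs *additively* (a false-positive floor), while
(1 − se) only *scales* x — so specificity errors dominate wherever x is
small, i.e. at young ages and for incidence generally.

## Built-in scenarios

Two parametric settings emulate the regimes in which the method is used.
The exact rate inputs behind such studies are typically literature tables;
here they are smooth parametric stand-ins with realistic magnitudes, chosen
once so that the two settings reproduce the qualitative regime reported for
this class of analysis (low vs high prevalence, upward bias decaying with
age, specificity-dominated error budget):

* **low_prevalence** (lupus-like, women, ages 20–70): i ≡ 5·10⁻⁵/py;
  R(a) = 2 + 10·e^{−(a−20)/20} (≈12 at 20, ≈2.8 at 70, in line with
  published standardized mortality ratios for systemic lupus in young
  women); m(a) = e^{−10.39+0.0884a}, a Gompertz fit at German adult-female
  magnitudes (1.8·10⁻⁴/y at 20, 1.5·10⁻²/y at 70). Entry prevalence 10⁻³
  (juvenile onset before the considered range). Solved prevalence stays
  below 1%.
* **high_prevalence** (type-2-diabetes-like, men, ages 40–80):
  i(a) = 0.03/(1 + e^{−(a−65)/9}) (≈1.8/1000 py at 40, plateauing near
  25/1000 py at 80); R(a) = 1.4 + 3.1·e^{−(a−40)/20}; m(a) =
  e^{−10.296+0.0931a} (1.4·10⁻³/y at 40, 5.8·10⁻²/y at 80). Disease-free at
  entry; prevalence reaches ≈31% at 80.

Base-case accuracy: se 99.5%, sp 99.999% (low setting, anchors 20/70);
se 95%, sp 99.95% (high setting, anchors 40/80); equal at both anchors but
treated as eight independent inputs.

These stand-ins are *not* the historical rate tables of any one study;
quantitative agreement with published bias curves is not claimed, only the
regime-level behaviour that the tests assert.

## Numerical choices

* **Solver**: classic fixed-step RK4 on a uniform grid (default step 0.1 y),
  grid built with `linspace` so the endpoint stays inside the rate tables'
  span. Prevalence leaving [0, 1) aborts with the offending age. Rate tables
  interpolate linearly between knots and refuse extrapolation.
* **Stored derivative**: a trajectory carries dp/da evaluated analytically
  from the ODE right-hand side at the solved values (it agrees with central
  differences to O(step²)). This matters: the estimator's numerator i − D
  cancels almost completely where prevalence is small, so finite-difference
  noise of relative size 10⁻⁶ can still produce double-digit-percent errors
  in R̂ near the entry age. Data-driven paths (`numerical_dp`, grouped
  claims) use second-order finite differences or splines, since there is no
  analytic derivative to fall back on.
* **Estimator**: denominators |m − i + D| below 10⁻¹²·max(m, i, |D|, 1)
  yield a `singular` status instead of an exception — near-singular ages are
  a finding of the method, not a numerical accident. Prevalences outside
  (0, 1) after correction yield `infeasible_input`.
* **Simulation study**: the observed series are corrupted analytically and
  their derivative is computed in closed form (the corruption is affine in p
  with affine-linear age coefficients), so bias measurements are free of
  discretisation artifacts. Estimates are tabulated on the interior grid;
  the entry age is excluded because p there is the initial condition.
* **Tornado analysis**: the outcome is the summed absolute relative error of
  the uncorrected estimate over a 2.5-year age-group grid starting one group
  above the entry age. Each of the eight anchors is perturbed by a *common
  decrement* δ = 2·10⁻⁴ (one at a time, others fixed). A common perturbation
  size is what makes the bars comparable as importances: perturbing each
  input "to perfect" instead would scale every bar by that input's own
  baseline imperfection and mask the additive-vs-multiplicative asymmetry
  between specificity and sensitivity. Rankings are stable for δ within at
  least [2·10⁻⁴, 5·10⁻⁴] and for 1–2.5-year outcome grids; much larger δ
  drives the low-prevalence setting through a pole of the estimator
  (m − i + D = 0) and saturates the comparison.
* **Specificity inversion**: Φ is realised as a bracketed root search (Brent,
  xtol 10⁻¹²) on the ODE defect as a function of sp over (1 − se, 1],
  restricted to candidates whose corrected prevalence lies in (0, 1). The
  corrected derivative rescales as dp_obs/(se + sp − 1) because the
  correction is affine with per-group constant coefficients. Several sign
  changes would be resolved in favour of the root closest to sp = 1 (the
  smallest FPR); on synthetic data the root is unique. No sign change with
  the smallest |defect| at sp = 1 → `boundary` (FPR pinned at 0); otherwise
  `no_root`. A 10⁻⁶-lattice exhaustive search serves as the independent test
  oracle.
* **Grouped derivative**: for claims data the cohort (directional)
  derivative is computed per group as the sum of its two components — the
  age part from the derivative of a not-a-knot cubic spline through the
  year-averaged grouped prevalence (finite differences below 4 groups), the
  calendar part from the same-age difference of the two years over the gap.
  This equals the cohort-diagonal difference [p_y2(a+g/2) − p_y1(a−g/2)]/g
  up to that scheme's O(g²) truncation error, which at a 6-year gap already
  exceeds 10⁻⁴ where prevalence is large and would dominate the specificity
  recovery. The mid-period prevalence entering the defect is the same-age
  average of the two years.
* **Envelope seeding**: one root seed spawns an independent substream per
  age group, so each group's Monte-Carlo draws are reproducible regardless
  of the other groups.

## Synthetic claims generator

`synthesize_claims` solves a scenario on a fine grid (step 0.05 y),
aggregates prevalence, incidence, R and m to group means over each group's
age span (default geometry: 9 groups of width 7.5 y centred at 25…85,
prevalence years 6 apart), corrupts p and i with the accuracy profile at the
group midpoints, and optionally applies multiplicative unit-mean lognormal
noise. Because rates are age-only, the two calendar years' prevalence
columns coincide before noise. The ground-truth sidecar (true p, i, R, m,
se, sp per group) suffices to verify every downstream stage without any
external data.

What the generator does *not* emulate: sampling noise with realistic
claims-size variance structure, calendar trends in accuracy or rates,
individual-level coding behaviour, and group-level heaping. Passing tests
therefore demonstrate correctness of the algebra and numerics under the
model's assumptions, not robustness to real-data violations of them.

## Known limitations

* Eq-level identifiability requires se + sp > 1 and, for the inversion, the
  equal-accuracy assumption (same se, sp for prevalence and incidence within
  a group); neither is testable from the aggregated data themselves.
* The inversion treats the supplied R and m as error-free; misclassification
  in R propagates directly into the recovered specificity.
* With a 6-year gap between prevalence years, accuracy is assumed constant
  over the period.
* Confidence intervals for R̂ are not provided — the aggregated inputs come
  without a sampling model.
* The boundary classification (`FPR = 0`) depends on the sign of a defect of
  order of the grouped-data discretisation error; with noisy real data,
  boundary and near-boundary results should be read as "FPR compatible with
  zero" rather than exact zeros.
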