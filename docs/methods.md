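# Methods

## Data model

The unit datum is a fate-tracked colony: detected alive at an annual survey
(year 0) and classified at each later survey as `alive`, `dead` (skeleton in
place, no living tissue) or `lost` (dislodged and gone). Both terminal
categories are mortality for the likelihood; the distinction is carried only
in fate summaries, because the two reflect different mechanisms of death.
Status sequences are monotone — once terminal, always terminal — and a
violation is a validation error, not a censoring mechanism: records with
genuinely unresolvable years are out of scope for this version.

Longevity is the truncated integer number of annual intervals survived.
Survey 0 is the detection year, so the `0` class is colonies that died
before the first resurvey, and colonies alive at the final survey of a
`T`-year window form the right-censored `≥T` class. The default window is
`T = 4` (five surveys).

## Likelihood

Annual survival `s_t` (probability of surviving year `t−1` to `t`) satisfies
`s_0 = 1` by detection conditioning. The two families are `s_t = s_c`
(constant) and `s_t = s/(1+e^{−bt})` (logistic). `s` and `s_c` are
constrained to `(0, 1]` so every `s_t` is a probability; `b` is an
unrestricted real — a negative `b` (survival declining with age) is a
legitimate fit outcome, not a domain error.

The longevity-class probabilities are `P(t) = (1−s_{t+1})·Π_{i=0..t} s_i`
for `t < T` and `P(≥T) = Π_{i=0..T} s_i`; they telescope to 1, so the cohort
is multinomial and the log-likelihood is `Σ_class n_class · ln P_class`.
Products are accumulated in log space. Any observed class with zero
probability yields `−inf` (the optimiser sees a large finite penalty
instead, 1e12, to keep the simplex well-behaved).

## Fitting

Nelder–Mead on an unconstrained parameterisation: logit for `s_c`/`s`,
identity for `b`. Starting values are moment-based — the crude annual
survival implied by person-year exposure (intervals survived / intervals at
risk), clipped to `[0.02, 0.995]`, with `b = 1`. Because the constant model
is the `b → ∞` limit of the logistic family, a second deterministic start at
`b = 8` guarantees the logistic fit can reach the near-constant ridge when
the data carry no age signal; remaining restarts (8 by default) jitter the
base start with unit-normal noise from a seeded generator, so fits are
bit-reproducible given a seed. Convergence tolerances are `fatol = 1e-8` on
the objective and `xatol = 1e-6` on parameters. Estimates of `s` within
`1e-6` of 1 are flagged as boundary estimates (e.g. an all-survivors
cohort), never rejected.

Two-habitat structures (ids 3–6) fit independent parameters to the
unconsolidated and consolidated strata; their log-likelihoods add and
parameter counts sum (2, 3, 3, 4). Structure 4 is constant-unconsolidated +
logistic-consolidated, structure 5 the reverse, following the
(unconsolidated + consolidated) column-order convention of the comparison
table. Groupings need ≥ 10 colonies for one-habitat fits and ≥ 5 colonies
per habitat for two-habitat fits; ineligible cells are recorded as skipped,
and a failed fit is recorded without aborting the grid.

## Model comparison

The constant and logistic one-habitat models are compared by
likelihood-ratio test, `χ² = 2·ΔlnL` against a chi-square with df equal to
the parameter difference. This nesting sits on the boundary of the logistic
family (constant is the large-`b` limit), which tends to make the standard
χ²₁ reference conservative; the standard reference is used deliberately, and
simulation under constant truth shows the realised type-I error near but
slightly below nominal (the calibration test brackets it in [0.02, 0.08] at
α = 0.05). The full six-structure grid, which is not mutually nested, is
ranked by AIC = −2 ln L + 2n; the lowest-AIC structure per grouping is best,
ties break toward fewer parameters then lower id, and structures within
ΔAIC < 2 are marked comparably supported. AIC is displayed at one decimal
but compared at full precision. No multiple-testing correction is applied
across taxa.

## Demographic reporting

* Longevity-class expectations wrap the fitted model's class distribution;
  for two-habitat fits the per-stratum distributions are mixed with stratum
  sample-share weights, matching how pooled empirical bars are composed.
* Survival curves evaluate the fitted `s_t` (annual and cumulative) on an
  integer-year grid to a default horizon of 10 years. Years beyond the
  fitted window re-evaluate the fitted function — they are not held at the
  last within-window value — and carry an `extrapolated` flag, because
  projections past the window ignore episodic disturbance.
* Crude constant annual survival converts a whole-window survival share `p`
  to `p^{1/T}`.
* Time to near-maximal survival is the smallest integer `t` with
  `s_t ≥ f·s` on the *annual* (not cumulative) scale, i.e.
  `ceil(ln(f/(1−f))/b)` clamped to ≥ 1, default `f = 0.99`; it requires
  `b > 0` (with declining survival the question is vacuous, and for constant
  models the caller can note `t = 1` trivially). A tiny epsilon (1e−12)
  inside the ceiling guards float ties so the closed form agrees with a
  linear scan.

## Synthetic cohorts

The generator simulates exactly the process the likelihood assumes:
independent colonies, habitat drawn Bernoulli per taxon, survival simulated
year by year under the taxon/habitat truth model, mortality attributed
`dead` vs `lost` with probability 0.51/0.49 (echoing a pooled mortality
composition of roughly 30% dead vs 29% lost); one seeded generator threads
through all draws, so a (spec, seed) pair is bit-reproducible.

The packaged default spec emulates a 537-colony, 12-taxon, 4-year cohort
with the published extremes (165 most-abundant, 3 least) pinned and the
intermediate abundances filled with a fixed illustrative vector; per-taxon
habitat fractions average ~0.80 consolidated. Three mid-abundance taxa
(Hydnophora, Acropora, Favites analogues) are concentrated on consolidated
substrate (fractions 0.92–0.95) so they miss the 5-per-habitat threshold and
reproduce the excluded cells of a two-habitat comparison grid, while the
taxa that do enter that grid (e.g. Porites, Pavona, Astrea analogues) carry
lower fractions (0.70–0.78). Truth models give most taxa rising (logistic)
survival with asymptotes 0.88–0.95 and rates 0.8–1.3/yr, one high constant
taxon (0.90) and one low constant taxon (0.58) as contrast; the implied
pooled 4-year survival is ≈ 0.41. All of these per-taxon values are
synthetic stand-ins chosen once at design time to make the pooled cohort
favour logistic survival — they are illustrative, not estimates of any
field dataset, and passing tests on them demonstrates correctness of the
machinery, not fidelity to any particular reef.

What the generator does *not* emulate: spatial structure among colonies,
colony growth and size-dependent survival, inter-annual environmental
variation (truth parameters are time-stationary), and observation error in
fate assignment. Tests passing on synthetic cohorts therefore say nothing
about those features of real data.

## Problem sizes and numerical choices

Recovery and calibration suites use cohort sizes chosen as the package's
own test design: single fits at n = 1000 (constant) and n = 5000
(logistic); LRT type-I calibration over 500 cohorts of n = 500; AIC
structure recovery over 200 cohorts of n = 1000 with 3 restarts per fit
(the likelihood is a 5-class multinomial, so restarts are cheap and 3
suffice at these sizes). Chi-square values below −1e−6 raise an
optimiser-failure error rather than being silently clipped; values in
(−1e−6, 0) are treated as 0.

## Known limitations

* No standard errors or confidence intervals for fitted parameters; model
  uncertainty is expressed only through LRT/AIC comparison.
* `lost` is treated strictly as mortality; if some lost colonies were in
  fact alive but undetectable, survival is underestimated.
* The LRT's boundary conservatism is documented, not corrected (no mixture
  reference distribution).
* Settlement-to-detection age is out of scope: reported times start at the
  detection survey, not at settlement.
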