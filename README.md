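# coralrec

Discrete-time survivorship analysis for fate-tracked cohorts of juvenile
reef-building corals.

## The problem

Newly settled corals pass through a prolonged survivorship bottleneck before
their demographic rates resemble those of adults. Annual fate-tracking of a
cohort of juvenile colonies (maximum diameter 1–5 cm at first detection)
yields, for each colony, an integer *longevity* — the number of complete
annual intervals it survived — right-censored at the end of the survey
window. `coralrec` asks whether annual survival is age-independent or
improves with age, whether it differs between consolidated and unconsolidated
reef substrate, and how long a cohort takes to approach its maximal annual
survival rate.

## The model

Annual survival is `s_t`, the probability of surviving from year `t−1` to
year `t`, with `s_0 ≡ 1` (a colony must survive to its detection survey).
Two nested families are contrasted:

* **constant**: `s_t = s_c` for all `t ≥ 1`;
* **logistic**: `s_t = s / (1 + e^(−b·t))`, rising toward the asymptote `s`
  when `b > 0`.

Over a window of `T` years the probability of longevity `t < T` is
`(1 − s_{t+1}) · Π_{i=0..t} s_i`, and colonies alive at the final survey fall
in the censored class `P(≥T) = Π_{i=0..T} s_i`. Colonies are independent, so
the cohort is multinomial over longevity classes and the log-likelihood is
the sum of log class probabilities. Six candidate structures — constant or
logistic, pooled or with independent parameters per habitat — are fitted by
Nelder–Mead maximum likelihood (logit-transformed survival parameters,
multi-start restarts), compared by likelihood-ratio test where nested and by
AIC (`−2 ln L + 2n`) across the grid, with structures within ΔAIC < 2 of the
best treated as comparably supported. Fits require at least 10 colonies per
grouping (one-habitat models) and at least 5 per habitat (two-habitat
models).

A seeded synthetic-cohort generator reproduces the structure the analysis
assumes — by default a 537-colony, 12-taxon cohort (165 down to 3 colonies
per taxon, ~81% on consolidated substrate) tracked over a 4-year window — so
the entire pipeline is testable without field data.

## Worked example

```python
from coralrec import (default_palmyra_spec, generate, derive_longevities,
                      SurvivorshipMLE, lrt, years_to_fraction_of_max)

cohort = generate(default_palmyra_spec())
obs = derive_longevities(cohort)
fit_const = SurvivorshipMLE(obs, structure=1).fit(seed=0)
fit_logis = SurvivorshipMLE(obs, structure=2).fit(seed=0)
print(fit_logis.summary())
test = lrt(fit_const, fit_logis)
print(f"chi2={test.chi2:.1f}, df={test.df}, p={test.p_value:.2g} "
      f"-> prefer model {test.preferred}")
print("years to 99% of max annual survival:",
      years_to_fraction_of_max(fit_logis.stratum_models["all"], 0.99))
```

prints

```
             Juvenile Coral Survivorship MLE
==========================================================
Grouping:       All corals            Model:   2 (Logistic)
N colonies:     537                   Window:  4 years
Log-likelihood: -743.5363             AIC:     1491.0726
Converged:      True                  Restarts:8
----------------------------------------------------------
stratum         family     param     estimate
all             logistic   s           0.8661
all             logistic   b           1.1817
==========================================================
chi2=56.8, df=1, p=4.9e-14 -> prefer model 2
years to 99% of max annual survival: 4
```

The pooled cohort decisively favours age-improving (logistic) survival: the
likelihood-ratio chi-square of 56.8 on 1 df rejects the constant model, the
fitted asymptotic annual survival is 0.87, and annual survival reaches 99% of
that asymptote four years after detection. The same analysis runs per taxon
and with habitat-stratified structures through `fit_all` / `select`, or from
the shell:

```bash
coralrec run --seed 11 --out runs/demo          # simulate -> fit -> select -> report
coralrec simulate --default-palmyra --out cohort.csv
coralrec fit --input cohort.csv --models 1,2 --seed 3 --out fits.csv
coralrec select --fits fits.csv --out comparison.csv
coralrec report --fits fits.csv --out report/
```

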