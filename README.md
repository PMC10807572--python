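# gvhdtte

Dynamic parametric time-to-event modelling of **grades II–IV acute
graft-versus-host disease (aGvHD)** within 100 days of allogeneic
hematopoietic stem-cell transplantation (HSCT), for pharmacometricians and
transplant researchers who want hazard-based, covariate-aware risk
prediction rather than static baseline scores.

## The model

Time to first aGvHD diagnosis follows `S(t) = exp(−∫₀ᵗ h(s) ds)`. The
baseline hazard is non-monotonic and delayed: a unit signal passes through
a chain of `n = 7` transit compartments with rate `k_tr` (mean onset delay
`n/k_tr ≈ 11.3` days) into an effect state `A` eliminated at a
patient-specific rate, giving a Bateman-like rise-and-decline with its
peak around day 16–17:

```
dA/dt = k_tr Tₙ(t) − kel_i(t) · A,     h_i(t) = f · m_static,i · (WBC_i(t)/median(t))^γ · A(t)
kel_i(t) = k_el · (1 + slope·(CsA_i(t) − 250)) · (age_i/54)^(γ_age · related_i)
```

Static risk factors multiply the hazard (female donor → male recipient
×1.45; matched related donor ×0.773; fludarabine+TBI conditioning
×0.768). Time-varying covariates enter continuously: the white-blood-cell
count through a power of its ratio to the daily population median
(γ = 0.125), and the cyclosporine A (CsA) trough concentration through the
elimination rate — higher exposure makes the hazard decline faster.

The package provides maximum-likelihood estimation for this model and the
simpler candidate families (constant, Weibull, Gompertz, Bateman),
likelihood-ratio model comparison and forward covariate selection,
stochastic simulation (incidence bands, adjusted risk ratios, required-CsA
analyses), day-7/14/21 cumulative-hazard risk stratification, five-fold
cross validation, and a synthetic cohort generator that stands in for the
access-restricted clinical data.

## Worked example

```python
import gvhdtte as g

params = g.FinalModelParameters()          # reference estimates
cohort = g.generate_cohort(g.GeneratorConfig(n_patients=300, seed=1))

# hazard trajectory of a reference patient (median WBC, CsA 250 ng/mL)
tr = g.hazard_trajectory(
    g.StaticCovariates("ref", 54.0),
    g.LongitudinalCovariate.constant("ref", 1.0),
    g.LongitudinalCovariate.constant("ref", 250.0),
    g.PopulationReference.constant(1.0),
    params,
)
print(tr.peak_day, 1 - tr.survival[-1])

from gvhdtte.stratification import stratify
res = stratify(cohort.to_grids(), params, cutoff_day=7)

rr = g.risk_ratio(cohort, params,
                  exposure={"female_to_male": True},
                  reference={"female_to_male": False},
                  n_replicates=500, seed=1)

ad = g.csa_adaptation(
    g.StaticCovariates("f2m", 54.0, female_to_male=True), params,
    reference=(g.StaticCovariates("ref", 54.0), 200.0),
)
```

Output (seed 1):

```
events: 147 of 300
peak day 16.3, 100-day incidence 42.2%
day-7 split: high 55.5% vs low 42.9% (n_high=146, n_low=147)
adjusted RR female->male: 1.27 (95% CI 1.19-1.38)
required CsA for f2m patient to match reference at 200 ng/mL: 327 ng/mL
```

Reading this: the reference patient's hazard peaks on day 16.3 and implies
a 42% 100-day incidence; splitting the synthetic cohort at the median
day-7 cumulative hazard separates observed event rates by ~13 percentage
points; toggling the female-donor→male-recipient flag counterfactually
raises the simulated 100-day risk by ~27%; and such a patient would need
roughly 327 ng/mL constant CsA to match the reference patient's risk at
200 ng/mL.

The same pipeline is scriptable from the shell:

```bash
gvhdtte generate --out-dir cohort --seed 1 --n-patients 300
gvhdtte fit      --data cohort/longitudinal.csv --static cohort/static.csv \
                 --reference cohort/reference.csv --family transit --out-dir fit
gvhdtte stratify --data cohort/longitudinal.csv --static cohort/static.csv \
                 --reference cohort/reference.csv --cutoff-day 7
```

Every command writes a `manifest.json` (inputs' checksums, config, seed)
and refuses to overwrite outputs without `--force`.

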