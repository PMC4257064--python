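# forestrisk

Mapping where tropical forest is most likely to be lost next — and how much
carbon that would commit to the atmosphere.

`forestrisk` implements a complete deforestation-risk pipeline of the kind
used to set REDD+ baselines on active frontiers such as Madre de Dios
(Peru): combine several imperfect forest/non-forest classifications into a
conservative consensus change map, estimate annualized deforestation rates,
build a travel-time accessibility surface from roads, rivers and towns, fit
a presence-only maximum-entropy model of clearing risk, convert the soft
risk map into a rate-constrained hard prediction of future loss, validate
it against later observed change, and account the carbon at risk. A
seed-reproducible synthetic-landscape generator stands in for satellite
rasters, so the entire pipeline is testable end to end.

It is written for landscape ecologists and land-change modelers who want a
scriptable, inspectable alternative to the GIS-toolchain version of this
workflow.

## The model

**Rates.** Forest-area change between assessments at `t1` and `t2` is
annualized with the instantaneous rate

```
r = ln(A2 / A1) / (t2 − t1)
```

(negative for loss; reported as |r| in %/yr), with the FAO compound form
`q = (A2/A1)^(1/(t2−t1)) − 1` available for comparison. Forward projection
is the exact inverse, `A(t) = A0 · e^(r·t)`.

**Accessibility.** Each cell gets a traversal cost (min/m) of
`60 / (1000 · v)`, where the speed `v` (km/h) comes from its land cover —
overridden on river and road cells — divided by `(1 + slope/30°)`. Minimal
cumulative travel time from town sources is computed by Dijkstra over
8-connected moves (step cost = step length × mean of the two cells'
costs), and mapped to an index `exp(−t/τ)` in [0, 1].

**Risk.** Deforestation presences (consensus-cleared cells; absences are
unreliable under cloud cover) are modeled against a uniform background
sample with a Gibbs distribution `q(x) ∝ exp(λ·f(x))` over linear,
quadratic, hinge and categorical-indicator features. `λ` maximizes the
L1-penalized presence log-likelihood; the optimum is the maximum-entropy
distribution whose feature expectations match the presence means within the
penalty slack. Per-cell risk is reported on the entropy-calibrated logistic
scale `p = q·e^H / (1 + q·e^H)`.

**Hard map and carbon.** The projected loss area (from the business-as-usual
rate) is matched by thresholding the risk map on a whole-percent ladder
(1.00, 0.99, …), and the selected area × carbon density (default 113
Mg C/ha, CO₂ = 44/12 × C) gives the emissions at stake.

**Validation.** Centroids of later consensus-deforested patches (≥ 10 ha)
are compared with random stable-forest points by predicted risk
(Mann–Whitney U, exact for small samples).

## Worked example

```python
from forestrisk.pipeline import run_pipeline

res = run_pipeline(seed=42)          # 200×200 1-ha synthetic landscape
print(res.results.summary())
print(res.results.percent_contribution(seed=42).round(1))
print(res.validation.summary())
```

prints (abridged):

```
Maximum-entropy deforestation-risk model
presences:            500
background points:    5000
converged:            True (40 iterations)
entropy H:            7.1632
max KKT violation:    -4.25e-05

accessibility       94.3
land_designation     5.7

Risk-map validation against later observed change
deforested-patch centroids: 5  mean risk 55% (SD 29)
no-change points:           316  mean risk 12% (SD 17)
Mann-Whitney U = 121.0, two-sided p = 0.00117
```

The synthetic landscape plants clearing risk dominated by accessibility;
the fitted model recovers accessibility as the overwhelming contributor
(94% here), and a risk map fitted on the first six simulated years sharply
separates where clearing happened in the next three (55% vs 12% mean
predicted risk, p < 0.01). The KKT line is the maximum-entropy optimality
check: every fitted feature expectation matches the presence mean within
its regularization slack.

The same stages are available as a CLI (`forestrisk simulate | consensus |
rate | access | fit | predict | harden | validate | report`); every
stochastic command requires `--seed` and writes a run manifest.

Rate arithmetic on the published Madre de Dios areas:

```sh
$ forestrisk rate --a1 4146955 --a2 4109955 --t1 2006 --t2 2009 --project-years 11
   period     A1_ha     A2_ha  loss_ha  r_puyravaud     r_fao  percent_per_year
2006-2009 4146955.0 4109955.0  37000.0    -0.002987 -0.002983               0.3
projected area after 11 yr: 3977090 ha (loss 132865 ha)
```

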