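# poctherm

Does burial temperature control how much organic carbon survives millions
of years of burial in marine sediments?  `poctherm` implements the full
statistical analysis behind that question for ocean-drilling data: an
Arrhenius forward model of labile particulate-organic-carbon (POC) loss
along each sediment parcel's burial temperature history, a temperature
score that ranks drill sites by the thermal histories their sediments
experienced, sedimentation-rate distribution-matched POC-versus-age
averages with bootstrap uncertainty, and a Monte Carlo randomization test
for the difference between the coldest and warmest site sets.  A synthetic
drill-site generator with the statistical structure of the global
compilation makes every stage testable end to end.

The audience is marine biogeochemists and deep-biosphere geomicrobiologists
working with drill-core POC, in-situ temperature, and age-model data — and
anyone who needs the statistical core (inverse-density distribution
matching, equal-count binned averages, bootstrap bands, randomization
inference) on comparable observational compilations.

## The model in brief

At a site with linear geotherm `T(z) = T_sf + Γ z` and a piecewise-linear
age-depth model `z(a)`, a parcel of present age `a` experienced

    depth(t) = z(a) − z(a − t),   T(t) = T_sf + Γ · depth(t),   t ∈ [0, a].

Its labile carbon fraction decays as `dG/dt = −k(T(t)) G` with the
Arrhenius rate constant `k = A·exp(−Ea/RT)` (defaults `A = 3e18 /Ma`,
`Ea = 110 kJ/mol`), i.e. `G = G0 · exp(−∫ k dt)`.  Evaluating `G(t)` at 100
ages on [0, 10] Ma gives the site's predicted POC curve and its temperature
score

    S = 1 − (1/10 Ma) ∫₀¹⁰ G(t) dt ∈ [0, 1],

low where burial stayed cold, high where sediments heated quickly.  Sites
with the lowest and highest 40% of scores form the low- and
high-temperature sets; each POC point is weighted by the ratio of a target
lognormal to its set's kernel-smoothed density of log sedimentation rate,
so both sets behave as if they shared the same rate distribution; and the
significance of the 5–10 Ma difference is the fraction of 1000 random
re-partitions whose (reweighted) difference is at least as large.

## Worked example

The numbered drivers under `analysis/` run the whole study on a synthetic
230-site ensemble and write their tables under `results/`:

```
$ python analysis/01_simulate_sites.py
wrote .../results/synthetic
  sites: 230
  POC measurements: 7184
  ...
$ python analysis/02_temperature_scores.py
high-POC-deposition filter: kept 203 of 230 sites
age models: 203 valid, 0 rejected
geotherms: 198 of 203 pass QC (median gradient 0.053 degC/m)
scored 198 sites -> 79 low / 39 mid / 80 high
$ python analysis/03_weighted_poc_curves.py
common sedimentation-rate range: 19.0-425 m/Ma
low-temperature set: 2327 points, 94.5% with nonzero weight, 33 bins
  1-2 Ma weighted average POC: 1.30%
  5-10 Ma weighted average POC: 1.19%
high-temperature set: 2666 points, 70.6% with nonzero weight, 38 bins
  1-2 Ma weighted average POC: 1.24%
  5-10 Ma weighted average POC: 0.50%
$ python analysis/04_randomization_test.py
observed |low - high| 5-10 Ma difference: 0.691% POC
randomization p-value over 1000 iterations: 0.007
```

Read: the two site sets deposit similar POC (1–2 Ma averages ≈ 1.3%), but
by 5–10 Ma the warm set has lost most of its labile carbon (0.50% vs
1.19%), and only 7 of 1000 random site re-partitions produce a difference
that large — the injected temperature effect is recovered.  The same
pipeline is scriptable via the `poctherm` CLI (`simulate`, `filter`,
`agemodel`, `geotherm`, `score`, `select`, `average`, `randtest`,
`run-all`) or the library (`poctherm.run_full_analysis`).

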