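# palmfrug

Macroecological analysis of size matching between palm fruits and the
mammalian frugivores that disperse them, at the grain of botanical countries
(TDWG level-3 units). The package builds per-country trait summaries from
species checklists, models assemblage-level maximum fruit size as a function
of maximum frugivore body size and climate, contrasts present-day frugivore
assemblages with the counterfactual "present-natural" assemblages that
include Late Pleistocene/Holocene extinct megafauna, and projects how much
assemblage fruit size would have to change to keep pace with frugivore
extinction over the next 100 years.

It is aimed at macroecologists and conservation scientists who work with
checklist-by-country presence-absence data and species trait tables, and who
want the full statistical machinery behind such an analysis as tested,
reusable code. All inputs are plain CSV; a synthetic-data generator with
known ground truth makes every stage testable end to end without downloads.

## The model

For each botanical country *c* and faunal scenario, the assemblage "maximum"
of a trait is its 95th percentile across member species (a robust maximum).
Writing `F_c` for maximum fruit length (cm) and `M_c` for maximum frugivore
body mass (kg), the core regression is the all-subsets OLS family

    log F_c = b0 + b1 log M_c + b2 PC1_c + b3 PC2_c + b4 PC3_c
              + b5 dT_c + b6 dP_c + e_c

where PC1-PC3 are the first three components of a correlation-matrix PCA of
six bioclimatic variables and dT, dP are the magnitudes of temperature and
precipitation change since the Last Glacial Maximum. Effect sizes are
model-averaged over all 2^p predictor subsets with AICc (Akaike) weights and
the zero-fill convention, optionally rescaled by partial standard deviations
to blunt collinearity; relative importance uses the LMG decomposition of R².
Spatial autocorrelation is handled by ML SAR error models
(`u = lambda W u + eps`) on sphere-of-influence neighborhood weights, with
Moran's I diagnostics.

Future extinction risk is a continuous-time Markov chain over the ordered
IUCN Red List categories LC-NT-VU-EN-CR-EX with transitions only between
adjacent ranks. The tridiagonal generator Q is estimated by maximum
likelihood from tables of observed category changes (`sum n_ij log P_ij(t)`
with `P(t) = expm(Qt)`), and the per-category 100-year extinction
probability is `P_i,EX(100)` — the "low" defaunation scenario. A "high"
scenario uses constant per-category rates via `P_ext = 1 - exp(-r t)`.
Extinction is then simulated stochastically (1000 draws of global species
survival), and the fitted fruit-size model converts the decline in simulated
maximum body mass into the fruit-size change required to preserve the size
relationship — the defaunation impact, in cm (negative = shrinkage).

## Worked example

```python
import palmfrug as pf

cfg = pf.PipelineConfig(outdir="out", seed=42)   # synthetic world, defaults
res = pf.run_pipeline(cfg)
r = res["report"]
print("countries:", len(res["summaries"]["current"]))
print("mean max fruit (cm): %.2f" % r["mean_max_fruit_cm"])
for s in ("current", "present_natural"):
    d = r["scenarios"][s]
    print(f"{s}: body coef (std) {d['body_coef_std']:.3f}, R2 {d['r2_full']:.2f}")
for label in ("low", "high"):
    d = r[f"defaunation_{label}"]["p95"]
    print(f"{label}: body decline {d['mean_body_decline_kg']:.2f} kg, "
          f"fruit change {d['mean_impact_cm']:.3f} cm ({d['pct_fruit_change']:.1f}%)")
```

prints

```
countries: 129
mean max fruit (cm): 7.39
current: body coef (std) 0.342, R2 0.83
present_natural: body coef (std) -0.017, R2 0.25
low: body decline 0.74 kg, fruit change -0.822 cm (-11.1%)
high: body decline 1.02 kg, fruit change -1.116 cm (-15.1%)
```

The current-scenario body-size coefficient is strongly positive and the full
model explains most of the cross-country variance, while the
present-natural scenario (extinct megafauna included) explains far less of
*present-day* fruit size — the synthetic world is built with fruit sizes
coupled to the current assemblages, and the analysis recovers exactly that
asymmetry. The defaunation rows give the mean loss of maximum (95th
percentile) body mass across countries under each scenario and the mean
fruit-size change required to stay on the fitted size relationship.

The same stages are exposed as a CLI (`palmfrug simulate|aggregate|fit|ctmc|
defaunate|all --config cfg.yaml`), with every stage output written as CSV
stamped with the config hash.

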