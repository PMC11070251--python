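# moonchorus

Does moonlight change how much nocturnal insects sing?  Passive
acoustic monitoring can answer this *in situ*: recorders sample the
soundscape on a nightly schedule for years, a recognizer scores short
audio segments per species, and the resulting detection counts are
modelled against lunar illumination.  `moonchorus` implements that
pipeline end to end for anyone working with scheduled soundscape
recordings and segment-level recognizer scores — field bioacousticians
evaluating a detector, and ecologists fitting activity models to the
counts it produces.

The pipeline stages (each a module, chained by a CLI):

1. **segdetect** — post-process per-segment scores: merge contiguous
   above-threshold segments into detection events (test mode), or count
   above-threshold segments per 10-min window (field mode, the model's
   response variable).
2. **evalmatch** — precision/recall with temporal-overlap criteria: a
   detection is a true positive if it overlaps ≥ 60 % of an annotation;
   an annotation is recalled if detections cover ≥ 50 % of it.  The
   reference set is tiered (base / + confirmed / + unable-to-reject) to
   bracket true performance, and a focal-species filter (precision
   ≥ 0.84, ≥ 20 calls, recall ≥ 0.3) picks species fit for inference.
3. **moonpred** — a lunar covariate per recording window from date,
   time and site coordinates: phase angle, illuminated fraction
   (1 + cos *i*)/2, topocentric altitude, and a relative ground
   illumination (fraction × distance correction × altitude/extinction
   factor, zero below the horizon).
4. **zicount** — zero-inflated Poisson/negative-binomial mixed models
   of the counts, `log mu = species + moon + species:moon` with random
   intercepts for time block, site, species×site and species×time
   block, fitted by Laplace approximation; three candidate structures
   compared by AIC/ΔAIC/Akaike weights; per-species new-vs-full-moon
   predictions, percent change `100·(new − full)/new`, and a marginal
   pseudo-R².
5. **synthdata** — a generator with known truth at field-realistic
   magnitudes (8 species, 4 sites, rates 0.5–17.6 detections/window,
   ±35 % moonlight effects, excess zeros, overdispersion, crossed
   random effects), plus an event-level soundscape simulator with faint
   calls and false positives for exercising the evaluation tiers.
6. **report** — evaluation grid, model-comparison and species-effect
   tables, and a detections-by-hour-and-night activity grid (missing
   recordings distinct from zeros).

## Worked example

```python
from datetime import date
from moonchorus import (SiteConfig, generate_schedule, default_truth,
                        simulate_counts, fit, ModelSpec, compare,
                        predict_effects, summarize_totals)

sites = {"S0": SiteConfig("S0", 9.15, -79.85, utc_offset=-5,
                          operation_intervals=((date(2019, 2, 1),
                                                date(2019, 3, 28)),))}
schedule = generate_schedule(sites["S0"])          # 13 windows/night
records, truth = simulate_counts(default_truth(seed=1), schedule, sites)
print(f"{len(schedule)} windows, {len(records)} count records, "
      f"{summarize_totals(records)[1]} detections")

full = fit(records, ModelSpec.full(), seed=1)
reduced = fit(records, ModelSpec.no_interaction(), seed=1, start_from=full)
for e in compare([full, reduced]).entries:
    print(f"{e.label:35s} dAIC={e.d_aic:8.1f} df={e.df} weight={e.weight:.3f}")

for eff in predict_effects(full, 0.0, 1.0)[:3]:
    print(f"{eff.species:25s} new={eff.pred_new_moon:5.2f} "
          f"full={eff.pred_full_moon:5.2f} change={eff.percent_change:+.1f}%")
```

prints

```
728 windows, 5824 count records, 38061 detections
species + moon + species:moon       dAIC=     0.0 df=22 weight=0.900
species + moon                      dAIC=     4.4 df=15 weight=0.100
Acantheremus major        new= 7.24 full= 5.81 change=+19.7%
Anaulacomera furcata      new= 0.89 full= 1.34 change=-50.6%
Anaulacomera spatulata    new= 0.26 full= 0.12 change=+55.6%
```

The interaction model wins the AIC comparison (ΔAIC 4.4 over the
common-slope model), meaning species differ in their moonlight
response; the per-species rows give expected detections per 10-min
window at the darkest ("new") and brightest ("full") covariate values
and the percent change between them (positive = less calling under
moonlight).  With a single site and two months of data the per-species
estimates are noisy; the acceptance script below runs the full
four-site, three-month configuration where slope signs are recovered
reliably.

The same pipeline is scriptable from the shell:

```sh
moonchorus simulate  --config config.yaml --out-dir sim/
moonchorus fit       --counts sim/counts.csv --model full --out fit.json
moonchorus compare   --counts sim/counts.csv --out table2.csv
moonchorus moon      --config config.yaml --site S0 \
                     --start 2019-02-01 --end 2019-03-01 --out moon.csv
```

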