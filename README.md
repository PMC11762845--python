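# quadbird

Analysis toolkit for quadrat-based breeding-bird surveys in urbanizing
landscapes. The package answers four linked questions about a grid of
25-hectare survey quadrats spanning an urban–rural gradient:

1. **Was the survey complete?** Non-parametric richness estimators (Chao1,
   first- and second-order jackknife) and a Michaelis–Menten fit to the
   species-accumulation curve give the estimated true species pool, and
   observed richness as a percentage of each estimate.
2. **Is the community environmentally filtered?** A checkerboard (C-score)
   test against a fixed–fixed null model — incidence matrices with the same
   row and column totals, sampled uniformly with the curveball algorithm —
   asks whether species co-occur less than chance would allow. A variant
   excludes a fraction of putatively interacting species to separate
   habitat filtering from competition.
3. **Which land covers drive richness and abundance?** Identity-link Poisson
   additive models relate per-quadrat richness and abundance to the hectares
   of eight land-cover categories, with penalized spline smooths whose
   degrees of freedom are chosen by a dispersion-scaled deviance criterion.
4. **What happens under urban change?** Scenario simulations rewrite quadrat
   land cover — urban expansion replacing peri- and extra-urban quadrats
   with built fabric and roads, or greening that converts continuous urban
   fabric into green urban areas — and report the predicted change in
   richness per quadrat.

A seeded synthetic-community generator produces realistic survey data with
known ground truth (zone-conditional land cover, species-specific land-cover
responses, imperfect detection, late-arriving migrants), so every stage of
the pipeline can be validated against truth.

## Quick start

```python
from quadbird import (
    GeneratorConfig, NullModelConfig, generate_community, incidence,
    estimate_all, filtering_test, fit_additive, landcover_matrix,
    max_response, make_expansion_scenario, predict_scenario,
)

com = generate_community(GeneratorConfig(seed=1))

# 1. sampling completeness, survey session 1
for name, est in estimate_all(incidence(com.sessions[0]), seed=1).items():
    print(f"{name.value:>16}: S_hat = {est.s_hat:6.2f}  "
          f"completeness = {est.completeness_pct:6.2f}%")

# 2. environmental-filtering test
res = filtering_test(incidence(com.sessions[0]), NullModelConfig(m=10_000, seed=1))
print(f"C-score {res.c_obs:.3f}, null {res.null_mean:.3f} ± {res.null_sd:.3f}, "
      f"p = {res.p_value:.4f}")

# 3. additive model for richness
x = landcover_matrix(com.quadrats)
y = max_response(com.sessions).y1_richness
model = fit_additive(x, y, response="richness")
print(f"R^2 = {model.r_squared:.1f}%, dispersion = {model.dispersion:.2f}")

# 4. urban-expansion scenario
out = predict_scenario(model, com.quadrats, make_expansion_scenario("B"))
print(f"expansion B: mean richness change {out.mean_delta:+.2f} "
      f"(sd {out.sd_delta:.2f}) over {len(out.per_quadrat)} quadrats")
```

Output for seed 1:

```
           chao1: S_hat =  29.00  completeness = 100.00%
      jackknife1: S_hat =  29.00  completeness = 100.00%
      jackknife2: S_hat =  29.00  completeness = 100.00%
michaelis_menten: S_hat =  30.81  completeness =  94.12%
C-score 32.355, null 32.501 ± 0.182, p = 0.7889
R^2 = 48.2%, dispersion = 0.16
expansion B: mean richness change +0.53 (sd 0.81) over 20 quadrats
```

## Command line

Every stage is also a `quadbird` subcommand:

```bash
quadbird simulate --seed 3 --out data/            # synthetic survey bundle
quadbird completeness --survey data/survey_session1.csv --out comp.csv
quadbird filtering --survey data/survey_session1.csv --m 10000 --seed 3 --out filt.csv
quadbird fit --landcover data/landcover.csv \
    --survey data/survey_session1.csv --survey data/survey_session2.csv \
    --out model.json
quadbird partials --model model.json --landcover data/landcover.csv --out partials.csv
quadbird scenario --model model.json --landcover data/landcover.csv --name B --out scenB.csv
quadbird run --config run.yaml                    # full pipeline from YAML
```

`quadbird run` writes CSV/JSON outputs plus a manifest with the configuration
hash, seed and package version; two runs with the same configuration and seed
produce byte-identical output bundles.

## Data formats

- **Land-cover table** (`landcover.csv`): one row per quadrat with
  `quadrat_id`, `zone` (`urban` / `peri_urban` / `extra_urban`) and eight
  hectare columns that must sum to the quadrat area (25 ha by default).
- **Survey table** (`survey_session<k>.csv`): species × quadrat count matrix
  with a `species_id` index column; one file per survey session.
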