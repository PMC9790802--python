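# sedcarbon

Estimation of organic-carbon density in coastal "blue carbon" sediments —
mangroves, marshes, seagrass beds — from core samples.

Blue-carbon inventories conventionally estimate the carbon density of a
sediment layer as the product of two laboratory measurements on a core
segment: the **gravimetric bulk density** δ (dry mass / segment volume,
g cm⁻³) and the **carbon fraction** C (proportion of dry mass that is
organic carbon). But δ and C are not independent quantities: organic-rich
sediment is light, mineral sediment is dense, and the relationship follows
the ideal (volume-additive) **mixing model** from soil science

```
δ(O) = δp δm / (δm O + δp (1 − O)),        O = f · C,
```

where δp is the self-packing bulk density of pure peat (≈ 0.085 g cm⁻³),
δm that of pure mineral sediment (≈ 1.65 g cm⁻³), and f ≈ 2.2 converts
carbon fraction to organic-matter proportion (organic matter is ~45%
carbon). Carbon density then follows from the carbon fraction alone:

```
D(C) = C · δ(C),        dD/dC = δ(C)² / δm .
```

This package implements that model and the statistics around it:

- **core_model** — the mixing model, its derivative, corer geometry and
  segment volumes for the four standard instruments (soil probe,
  open-faced corer, Russian peat corer, spade-cut reference cube).
- **fitting** — Gauss–Newton nonlinear least squares for (δp, δm) with
  linearised standard errors, pseudo-R², lack-of-fit vs pure-error
  testing, and the LOI → carbon-fraction calibration of f.
- **survey_stats** — pairwise corer comparison (Pearson r; major-axis
  slope through the origin with jackknifed SE; identity-line test),
  sequential variance decomposition of bulk density, within-site
  replicate-consistency comparison of estimators, and the squared-residual
  heteroscedasticity diagnostic.
- **error_propagation** — the exact variance of a product of independent
  measurements, the delta-method variance of the carbon-fraction-only
  estimator, and a seed-deterministic Monte Carlo comparing the two
  estimators' dispersion and probing parameter-misspecification bias.
- **synthetic_data** — a generator of realistic bay-scale surveys
  (nested locations/sites, depth strata, instrument availability,
  measurement error) so the whole pipeline is testable end to end.
- **io / cli** — CSV reading/writing with strict unit validation, YAML
  configuration, and a thin `sedcarbon` command-line front end
  (`estimate`, `simulate`, `fit`, `compare`, `decompose`, `mc`, `report`).

The punchline the machinery demonstrates: multiplying two noisy
measurements makes the gravimetric estimator's error **grow** with carbon
content (funnel-shaped scatter), while the carbon-fraction-only estimator
becomes **more precise** in peaty sediment — at the price of depending
critically on accurate δp and δm.

## Worked example

```python
from sedcarbon import (MixingParams, SurveySpec, fit_mixing_model,
                       generate_survey, lack_of_fit_test, samples_to_frame)

truth = MixingParams(delta_p=0.09, delta_m=1.75, f=2.2)
frame = samples_to_frame(generate_survey(SurveySpec(true_params=truth, seed=42)))
fit = fit_mixing_model(frame["carbon_fraction"], frame["bulk_density"], f=2.2)
groups = (frame["site"] + "|" + frame["depth_label"]).to_numpy()
lof = lack_of_fit_test(frame["bulk_density"], groups, fit)
```

prints, via `python examples/fit_survey.py`:

```
survey: 52 samples, 7 sites, 4 instruments
delta_p = 0.099 +/- 0.005 g/cm^3 (truth 0.09)
delta_m = 1.724 +/- 0.108 g/cm^3 (truth 1.75)
r^2 = 0.948 in 5 Gauss-Newton iterations
lack of fit: F = 4.23 (df 14, 36), p = 0.000
```

The fit recovers the generating self-packing densities within roughly two
standard errors, and carbon fraction alone explains ~95% of the
bulk-density variation. The significant lack-of-fit F correctly flags the
small corer and site offsets the generator deliberately injects on top of
the pure mixing curve. The other scripts in `examples/` each exercise one
capability — point prediction, corer comparison, closed-form error
propagation, and the Monte Carlo precision comparison — and print a short
interpretation with their numbers.

Command-line equivalent:

```
sedcarbon simulate --out survey.csv --seed 42
sedcarbon report survey.csv
```

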