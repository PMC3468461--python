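# sonoseed

Optimization analysis for ultrasound seed-pretreatment experiments built on a
16-run, four-level orthogonal design. The package covers the complete chain
used to tune sonication time, bath temperature and output power for seed
germination and seedling growth:

- **`sonoseed.design`** — construction, decoding and validation of the
  L16-type orthogonal array (three active factors + a vacancy column that
  estimates experimental error).
- **`sonoseed.synthetic_data`** — simulated germination assays with the
  study's replicate layout (16 treatments x 16 dishes x 100 seeds;
  10 measured seedlings/dish), beta-binomial dish-level overdispersion
  calibrated to published SDs, truncated-normal correlated seedling lengths,
  and logarithmic conductivity series. Ships the published per-treatment
  mean±SD table and conductivity means as CSV fixtures.
- **`sonoseed.summarize`** — Taguchi-style range analysis: per-factor level
  means, ranges R, factor importance ordering, optimal levels, and
  per-treatment summaries.
- **`sonoseed.inference`** — factorial ANOVA (categorical main effects,
  pairwise interactions, experiment blocks, vacancy pseudo-term),
  Student–Newman–Keuls compact letter displays, and MANOVA test statistics
  (Wilks, Pillai, Hotelling–Lawley, Roy) with F approximations.
- **`sonoseed.response_surface`** — pairwise binary quadratic OLS fits on
  physical units, stationary-point extraction and classification, peak
  harvesting, and surface grids for contour plotting.
- **`sonoseed.mode_optimum`** — grouped-frequency mode estimator
  (M = L + d·Δ1/(Δ1+Δ2)) aggregating the six per-factor peaks into final
  recommended conditions, with binning provenance and sensitivity flags.
- **`sonoseed.conductivity`** — electrolyte-leakage fits y = a + b·ln(t) per
  treatment group and per-time SNK group comparison.
- **`sonoseed.cli`** — pipeline orchestration.

## CLI

```bash
sonoseed optimize --out run1            # fixture data -> range tables, 9 fits,
                                        # peaks, grouped-mode final conditions
sonoseed simulate --out sim1 --seed 7   # synthetic dish/seedling/conductivity CSVs
sonoseed analyze --out run2 --simulate  # range analysis + ANOVA on synthetic data
sonoseed surface --out run3             # fits, stationary points, surface grids
sonoseed conductivity --out run4        # leakage fits (+ SNK letters if replicated)
sonoseed report --config cfg.yaml       # optimize + conductivity
```

A YAML config (`--config`) can set `seed`, `alpha`, `outdir`, input CSV paths
(`germination_csv`, `seedling_csv`, `conductivity_csv` in the long formats
written by `simulate`) and per-factor binning overrides, e.g.

```yaml
seed: 42
outdir: run42
binning:
  C: {width: 5.0, origin: 0.0, mode_digits: 0}
```

Each run directory receives the stage outputs as CSV/JSON plus
`provenance.json` (resolved config, seed, version, config hash); reruns with
the same config and seed are byte-identical.

## Notes on fidelity

The analysis reproduces the published level-mean tables (±0.02 from
printed-precision propagation; one provably misprinted cell), factor
orderings, all 18 response-surface peak coordinates at 1-dp precision, and
the temperature/power grouped modes (39.7 °C, 348 W). The published time
mode (22.5 min) is not reproducible under any simple binning and is flagged;
published global ANOVA/MANOVA F values and conductivity R² require raw data
that were never published, so that machinery is verified against independent
oracles and simulations instead.
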