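# changescope

A tested pipeline for change-detection (flicker-paradigm) experiments on
natural-image stimuli. It quantifies image manipulations by two measures —
**local contrast-energy change** (a Gaussian-window-weighted RMS-contrast
statistic) and **subjective-importance change** (the sum of averaged
human-label map values over the changed region) — builds a covariate-balanced
2×2 low/high design by median split, analyses detection reaction times with
an inverse-Gaussian GLM, and tests whether the redundant (high/high)
condition beats the race-model upper bound built from the two
single-property conditions.

Because neither the original stimuli nor the human RT data are
redistributable, the package ships a first-class synthetic-data module that
generates every input with known ground truth: texture image pairs with
independently controllable contrast-energy and importance changes,
multi-observer label maps, and trial-level RTs from shifted-Wald channels
under either a parallel-race or a coactivation architecture.

## Modules

| module | role |
| --- | --- |
| `changescope.image_metrics` | contrast-energy maps, change scores, balancing covariates |
| `changescope.design_balancer` | median-split conditions, balanced selection, presentation subsets |
| `changescope.rt_analysis` | trial classification/exclusion, inverse-Gaussian GLM, distribution fits |
| `changescope.race_model` | quantile-wise race-model inequality test with subject bootstrap |
| `changescope.synthetic_data` | seeded generators for stimuli, label maps and RTs |
| `changescope.io` | PNG/CSV readers and writers for all artefacts |

## CLI

```sh
# generate a complete synthetic dataset (images optional, see config)
changescope simulate --config sim.yaml --out data/

# score real or synthetic image pairs listed in a manifest CSV
changescope score-images --pairs manifest.csv --sigma-px 19.4 --variant rms --out scores.csv

# select a balanced 108-pair design and build 6 subsets of 36
changescope build-design --scores scores.csv --config design.yaml --out design/

# inverse-Gaussian GLM on hit-trial RTs (split or ranked coding)
changescope fit-rt --trials trials.csv --coding split --link log --out glm.json

# race-model inequality test over the 9 deciles, Bonferroni-corrected
changescope race-test --trials trials.csv --n-boot 10000 --seed 7 --out race.json --plot race.png
```

The `score-images` manifest needs columns `pair_id, original_path,
manipulated_path, importance_path[, mask_path]`; without a mask the changed
region is recovered by pixel differencing.

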