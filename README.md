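# netstab

Numerical-uncertainty analysis of brain-network pipelines, at desk scale.

`netstab` simulates Monte Carlo Arithmetic (MCA) perturbations — uniform
random noise at a configurable virtual precision, injected per
floating-point operation — through a synthetic connectome-reconstruction
pipeline, then quantifies the resulting instability at every analytical
level:

- **`netstab.mca`** — simulated MCA: `inexact` perturbation at virtual
  precision *t*, random-rounding (RR) and precision-bounding (PB) modes,
  dense/sparse instrumentation densities, and a seeded operator-dispatch
  layer (`MCAContext`) that pipelines route their arithmetic through.
- **`netstab.cohort`** — synthetic cohorts with subject/session/subsample
  structure and variance components, odd/even subsampling (64 + 9
  baselines = 73 volumes per half at the default design), and a
  perturbable reconstruction chain (normal-equation model fit,
  outer-product edge accumulation, normalization) with deterministic
  (`det-like`) and internally-resampling (`prob-like`) variants.
- **`netstab.stability`** — normalized percent deviation
  (‖A−B‖_F/‖A‖_F), Pearson edge correlation, and significant digits
  (−log10(σ/|μ|), capped at 15.7 for 64-bit data), grouped by what varies
  between compared connectomes (simulation / subsample / session /
  subject).
- **`netstab.discrim`** — the discriminability statistic (probability
  that within-class distances rank at or below cross-class distances over
  all observation triples), block-permutation hypothesis tests (H1:
  subjects distinct; H2: sessions distinct within subject; H3: subsamples
  distinct within session), Wilcoxon condition comparisons with
  Benjamini–Hochberg correction.
- **`netstab.features`** — univariate, nodewise and edgewise weighted
  graph features, Z-score false-positive proportions, and moment-level
  significant digits with fixed-grid CDF summaries.
- **`netstab.phenotype`** — PCA (components chosen as the smallest set
  explaining >90% variance across training folds) + logistic regression
  under stratified k-fold CV, repeated over samplings of perturbed
  connectomes.
- **`netstab.config` / `netstab.orchestrator` / `netstab.cli`** — YAML
  experiment configs, experiment-grid bookkeeping (both study presets
  imply exactly 8,400 executions; the hypothesis grid yields 30 tests),
  and end-to-end execution with per-stage failure isolation.

No external data is required; cohorts are generated synthetically.
Externally supplied connectomes can be evaluated via the delimited-text /
GraphML readers in `netstab.io`.

## CLI

```sh
netstab grid --preset repeated          # execution/test-count arithmetic
netstab generate --preset smoke --seed 1 --out results/
netstab all --preset smoke --seed 1 --out results/   # full pipeline
```

Subcommands: `generate`, `perturb`, `stability`, `discrim`, `features`,
`model`, `all`, `grid`; options `--config <yaml>`, `--preset
{repeated,cross,smoke}`, `--seed`, `--out`.

## Notes

- Instrumented arithmetic is carried in extended precision
  (`numpy.longdouble`) between operations so that sub-ulp perturbations
  at t = 53 are representable and propagate; results are rounded to
  float64 where a chain ends.
- Reference executions (`density='off'`) are bit-identical across reruns;
  perturbed executions are reproducible per (seed, simulation index).
- Connection length uses Euclidean distance between synthetic node
  coordinates — a geometric stand-in, flagged as such.
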