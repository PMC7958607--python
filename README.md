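# rarpipe

Characterize 24-hour rest–activity rhythms (RARs) from minute-epoch wrist
accelerometer counts and relate them to perceived physical fatigability.

The pipeline covers:

- **Epoch I/O** (`rarpipe.epoch_io`): read/write/validate epoch-count CSVs,
  truncate series to whole midnight-to-midnight days, cache `ln(count + 1)`.
- **Wear screening** (`rarpipe.wear`): zero-count-interval non-wear detection
  (≥ 90 min of zeros with a ≤ 2-min interruption allowance flanked by 30-min
  zero streams), valid-day (≥ 10 h wear) and valid-participant (≥ 3 valid
  days) filters.
- **Extended cosine model** (`rarpipe.cosine`): bounded nonlinear least
  squares fit of `f(t) = m + amp·expit(β(cos((t−φ)·2π/24) − α))` to log
  counts, with derived mesor level, up/down-mesor crossing times and a
  pseudo-F rhythmicity statistic.
- **Localized metrics** (`rarpipe.localized`): 4-hour clock-bin means and
  across-day SDs of log activity, with an optional rise-time-aligned
  ("person time") variant.
- **Profiles** (`rarpipe.profiles`): z-scored rhythm features, best-of-restarts
  k-means, elbow/PCA/Ward diagnostics, and deterministic assignment of the
  four semantic profile names (Less Active/Robust, Earlier Risers,
  More Active/Robust, Later RAR).
- **Associations** (`rarpipe.assoc`): 10-item fatigability scale scoring
  (0–50, cut point ≥ 15, person-mean imputation for ≤ 3 missing items),
  median regression solved exactly as a linear program with seeded bootstrap
  inference, a check-loss ratio test for nested quantile models,
  Kruskal–Wallis / pairwise rank-sum tests, logistic odds ratios, Cohen's d.
- **Synthetic cohorts** (`rarpipe.simulate`): seeded minute-level count
  simulation from the cosine model with log-scale (optionally AR(1)) noise,
  injected non-wear blocks, four-archetype populations, covariates and
  outcomes with known coefficients — every stage is testable offline.
- **Orchestration** (`rarpipe.pipeline`, `rarpipe.cli`): one command runs
  simulate → clean → fit → localized → cluster → associate and writes flat
  CSV/JSON artifacts plus a SHA-256 manifest; reruns with the same config
  and seed are byte-identical.

## CLI

```sh
# full synthetic run with defaults
rarpipe run-all --seed 1 --out out/

# individual stages (each runs its prerequisites)
rarpipe simulate --seed 1 --out out/
rarpipe fit --config my.yaml --out out/
rarpipe associate --config my.yaml --out out/
```

Configuration is YAML; see `rarpipe.pipeline.DEFAULT_CONFIG` for all keys
(epoch length, truncation window, non-wear rule parameters, valid-day rules,
bin width, clustering k/restarts, regression quantile and bootstrap size,
scale cut point, simulation block). The resolved config is written next to
the artifacts for provenance.

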