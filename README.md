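# clampkit

Patch-clamp electrophysiology analysis: postsynaptic-current detection,
intrinsic membrane-property extraction, and interneuron classification —
with a ground-truth simulator standing in for raw recordings.

## What it does

- **`clampkit.core`** — neutral data model (`Sweep`, `SweepSet`, protocol
  metadata), a plain-text interchange format (CSV sample matrix + JSON
  sidecar), an optional ABF adapter (needs `pyabf`), Savitzky-Golay
  smoothing (±0.5 ms, order 3, current sweeps only), baseline mean/raw-MAD
  statistics, artifact blanking, and alignment-averaging of events.
- **`clampkit.events`** — three detector families:
  evoked EPSC/IPSCs (25%-subsample median-peak window, 6×MAD baseline
  threshold, ±5/7.5 ms windows, success/failure bookkeeping with the
  all-failure mean-trace fallback), paired-recording unitary EPSCs (6×MAD
  within 3 ms of the presynaptic AP peak), and spontaneous EPSCs (combined
  template + 5×MAD rolling-baseline threshold with a normalized
  charge-integral cutoff). Kinetics: 20–80% risetime, latency/jitter,
  single and weighted-double exponential decay.
- **`clampkit.intrinsic`** — AP detection at the 20 V/s dV/dt crossing and
  the 15 membrane properties from the two 600 ms current-step series
  (−100→+100 pA @ 10 pA; −200→+400 pA @ 25 pA), plus stimulus-response
  (APs/stimulus, V_rest, subthreshold EPSPs) and drug-timecourse ΔV_m.
- **`clampkit.classify`** — z-scoring, Ward clustering with the Thorndike
  largest-gap cut, a CV-pruned decision tree with 500-bootstrap validation,
  and a 10,000-tree random forest with OOB error, Gini importances,
  proximity matrix and 2-D PCA embedding; responder-concordance
  cross-tabulation.
- **`clampkit.groupstats`** — Anderson-Darling-driven test selection
  (t-family/ANOVA+Tukey vs rank tests/Kruskal-Wallis+Mann-Whitney) and
  Benjamini-Hochberg FDR correction.
- **`clampkit.simulate`** — seeded generators for step-protocol voltage
  responses (passive RC, sag, rebound spikes, parametric AP trains),
  evoked Bernoulli success/failure sweep sets, spontaneous Poisson PSC
  trains, and two-class 105×15 feature tables with the class contrast
  concentrated in max firing rate, sag and AP halfwidth. Every generator
  attaches its realized ground truth.
- **`clampkit.cli`** — `simulate | detect | features | cluster | classify |
  stats | report | run-all` with a YAML config surfacing every protocol
  constant.

## CLI

```sh
# simulate a labeled cohort (both current-step series per neuron)
clampkit --seed 1 simulate --out runs/input --n-fs 20 --n-nfs 20

# full pipeline: recordings (or a features.csv) -> features -> clusters ->
# tree/forest validation -> per-property stats
clampkit --seed 1 run-all --input runs/input --out runs/out
clampkit report --run runs/out
```

`run-all` accepts either a directory of interchange recordings
(`<cell>_fine.csv/.json` + `<cell>_coarse.csv/.json`) or a directory
containing `features.csv` with a `cell_id` column plus the 15 property
columns (`clampkit.intrinsic.PROPERTY_NAMES`) — the same schema the
pipeline writes, so published membrane-property tables can be ingested
directly.

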