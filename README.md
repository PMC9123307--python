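# synaptoquant

Quantification toolkit for synaptic neuroscience data, providing a tested,
reusable implementation of six analysis stages plus synthetic-data
generators with ground truth for every stage:

- **coloc** — object-based two-channel puncta colocalization: per-channel
  min-max normalization to 0–255, iterative-threshold connected-component
  detection (cutoff walked from 255 down to 95, components > 25 px,
  intensity-weighted centroids, marker-dependent exclusion margins), and a
  disk-overlap colocalization test (radius 4 px).
- **patch_ephys** — readily-releasable-pool estimation from 20 Hz stimulus
  trains by back-extrapolating an OLS fit of the cumulative amplitude plot
  over stimuli 90–100, with sweep QC (≥ 10 sweeps, ≤ 30 MΩ series
  resistance, AP-flagged sweeps removed); plus automated miniature-event
  detection and frequency/amplitude statistics.
- **lfp_analysis** — multitaper band power (δ 1–3, θ 4–10, α 11–15,
  β 16–30, low γ 31–70, high γ 71–100 Hz) and extracellular spike
  detection by negative-range thresholding (5 × SD, peaks > 30 × SD
  excluded, −0.5 to +3 ms snippets).
- **baystats** — BEST-style Bayesian two-group estimation (t likelihoods
  with shared normality parameter, 100,000 posterior draws by default,
  split-R̂ convergence check), accuracy-based significance calls
  (★ ≥ 80 %, ★★ ≥ 90 %, ★★★ ≥ 95 %), and Monte-Carlo-calibrated
  univariate outlier gating.
- **morphology** — Sholl analysis on SWC trees (6 µm rings to 720 µm),
  spine classification and density, and 50 nm vesicle-distance binning.
- **synthetic_data** — seeded generators for every input: punctate image
  pairs with planted colocalization, depressing trains from a
  vesicle-depletion model with an exact closed form, Poisson miniature
  traces, band-limited LFP with embedded spike templates, heavy-tailed
  group samples with injectable outliers, and random SWC trees.

## Test

```sh
python -m pytest -q tests/
```

The suite includes unit tests per module, hypothesis property tests, and
`tests/test_acceptance.py` with one test per acceptance criterion
(parameter-recovery bounds, brute-force-oracle equivalence, calibrated
false-flag rates). The full run takes a few minutes; the Bayesian
null-replicate criterion dominates.

## CLI

All stages are exposed as `synaptoquant` subcommands. Generators:

```sh
synaptoquant simulate puncta --seed 1 --coloc-fraction 0.3 --out-prefix field
synaptoquant simulate train  --seed 1 --noise-sd 10 --out rec.csv
synaptoquant simulate minis  --seed 1 --out trace.h5
synaptoquant simulate lfp    --seed 1 --out lfp.h5
synaptoquant simulate groups --seed 1 --mu2 2 --out groups.csv
synaptoquant simulate tree   --seed 1 --out neuron.swc
```

Analyses:

```sh
synaptoquant coloc --ref field_a.tif --marker field_b.tif \
    --marker-type vglut1 --out coloc.json
synaptoquant train-pool --in rec.csv --out pools.json
synaptoquant minis --in trace.h5 --out events.csv
synaptoquant lfp --in lfp.h5 --bands --spikes --out lfp_results
synaptoquant best --in groups.csv --seed 7 --out best.json
synaptoquant sholl --in neuron.swc --step 6 --max 720 --out sholl.csv
synaptoquant spines --in spines.csv --dendrite-length 1000 --out classified.csv
synaptoquant vesicle-bins --in distances.csv --out bins.csv
```

Each command writes a `*.manifest.json` sidecar (inputs, parameters,
seed, version) sufficient to reproduce the run byte-identically.

## Notes

- Formats are text-first: TIFF images, CSV/HDF5 traces, 7-column SWC,
  long-format group CSVs, JSON results.
- The mini-event detector and the spine classification rules are
  documented stand-ins (the original acquisition scripts are not public);
  both are validated against synthetic ground truth and fully
  configurable.
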