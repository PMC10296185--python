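# nirsgraph

Graph-closeness intersubject similarity analysis for naturalistic
multichannel fNIRS recordings.

Channel-wise analysis of naturalistic fNIRS drowns in multiple comparisons
(channels × frames), and without a design matrix there is no GLM to fall
back on. `nirsgraph` instead tests a *single* statistic: at every time frame
it builds the complete weighted graph whose nodes are participants and whose
edge weights are Euclidean distances between their multichannel hemodynamic
states, summarizes each frame by the graph's mean closeness centrality, and
averages over frames. Significance comes from circular permutations of each
participant's recording — a null that exactly preserves within-subject
autocorrelation and cross-channel correlation while breaking across-subject
stimulus alignment. After rejection, descriptive post-hoc maps identify the
most inter-individually consistent time points (top closeness frames, with
HRF-delay-corrected stimulus timestamps) and the channels driving them
(leave-one-channel-out closeness drops).

## Components

| module | what it does |
|---|---|
| `nirsgraph.similarity` | per-frame distance graphs, mean closeness, closeness series |
| `nirsgraph.inference` | circular-permutation test, one p-value for the whole recording |
| `nirsgraph.posthoc` | top-closeness frames, stimulus timestamps, channel relevance mapping |
| `nirsgraph.preprocess` | optical density → modified Beer–Lambert → z-score → wavelet spike suppression → 0.01–0.08 Hz band-pass → short-channel regression → unit variance |
| `nirsgraph.synthdata` | synthetic group generator (AR(1) + spatially correlated noise, double-gamma HRF responses, superficial confounds) with ground truth |
| `nirsgraph.io` / `nirsgraph.cli` | delimited-text and SNIRF readers/writers, JSON/TSV results, command line |

## Command line

```sh
# synthetic end-to-end run
nirsgraph simulate --out-dir data/ --seed 1 --config config.json
nirsgraph test --in-dir data/ --out results/test --permutations 1000 --seed 2
nirsgraph map-channels --in-dir data/ --out-prefix results/maps
nirsgraph report --test-json results/test.json \
    --frames-json results/maps.frames.json \
    --channels-tsv results/maps.channels.tsv \
    --trace-tsv results/test.trace.tsv \
    --out results/report.json

# raw dual-wavelength intensities go through the preprocessing chain first
nirsgraph simulate --raw --out-dir raw/ --seed 1 --config config.json
nirsgraph preprocess --in-dir raw/ --out-dir data/
```

Every command accepts `--seed` (drawn and logged when omitted), `--config`
(JSON, keys namespaced by module, e.g. `{"synthdata": {"n_participants": 19}}`)
and `--log-level`. Usage errors exit 2, data errors exit 1 with a one-line
diagnostic.

Input format: one tab-separated file per participant (`time` column in
seconds followed by one column per channel) plus a `manifest.tsv` naming
each channel's role (`long`/`short`) and source–detector separation.
Continuous-wave SNIRF files are read via `nirsgraph.io.read_snirf`.

## Acceptance battery

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

runs the full property-based acceptance battery (closeness-oracle
equivalence, Monte-Carlo p-value granularity, type-I calibration, power and
ground-truth recovery, circular-shift exactness, relevance conservation,
preprocessing roundtrips, CLI determinism) and prints each measured value
with PASS/FAIL. The JSON target report is an empty object: the original
study's headline numbers were computed on participant data that is not
publicly available, so no paper-scale quantity can be recomputed offline —
all acceptance here is property-based on synthetic data with known ground
truth.

## Notes

- Closeness uses the (N−1)-normalized form, `(N−1) / Σ distances`; on
  Euclidean (metric) distance matrices this equals full shortest-path
  closeness, which the tests verify against `networkx`.
- The Monte-Carlo p-value is `(b + 1) / (B + 1)`, one-sided (high closeness
  = similarity); with B = 1000 the minimum attainable p is 1/1001 ≈ 0.001.
- Packaged extinction coefficients (760/850 nm) and DPF = 6.0 are
  replaceable defaults (`PreprocessConfig`); results are insensitive to
  them up to the final per-channel variance normalization.
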