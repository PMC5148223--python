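# cmrpipe

Analysis pipeline for **comodulation masking release (CMR)** experiments in
auditory cortex, rebuilt as a tested, reusable Python package. It covers the
full chain used to quantify masked-tone detection from population spike
trains — without requiring the original recordings:

- **Stimulus modelling** (`cmrpipe.stimuli`): SAM tone maskers in narrowband
  (NB), incoherently (IM) and coherently (CM) modulated broadband
  configurations; precursor/gap/masker trial timeline; tone-pip signals placed
  in masker envelope troughs; the 25 × 8 FRA tone grid; and the
  block-interleaved presentation schedule (30 repeats per masker/signal
  combination, 6 per FRA combination). Optional waveform rendering.
- **Synthetic populations** (`cmrpipe.population`): seeded
  inhomogeneous-Poisson model neurons with log-normal baseline rates,
  log-frequency tuning, onset transients, sustained noise responses, logistic
  signal responses with *planted* per-condition detection thresholds
  (comodulation release, priming and laser-inactivation effects), and a
  signed coupling between onset suppression and masking release — so every
  statistic in the pipeline can be validated by parameter recovery.
- **Spike I/O & PSTHs** (`cmrpipe.io`): plain-CSV spikes/trials interchange
  format, 5 ms PSTHs, window rates.
- **FRA analysis** (`cmrpipe.fra`): 3×3 pyramidal smoothing, dual-criterion
  (30%/15%) response-region extraction with 4-connected components, and
  characteristic-frequency assignment from the largest excitatory region.
- **Signal-response statistics** (`cmrpipe.sr`): the SR statistic
  (signal−noise PSTH difference in pooled-SD units), per-cell and population
  SR/SNR functions with 0.5 SD thresholds, pooled-bootstrap responsiveness
  screening, and CF-subpopulation bootstrap sensitivities (50 draws × 500
  repeats, 0.25 SD criterion).
- **Neurometrics** (`cmrpipe.neurometrics`): ±25% firing-rate votes,
  population proportion correct, and detection thresholds by one-sided exact
  binomial test (p < 0.05, Bonferroni-corrected over measured SNRs).
- **AFI analysis** (`cmrpipe.afi`): across-frequency interaction of
  noise-onset (0–75 ms) responses on an exponential-normalized scale, its
  relation to per-cell masking release (6 equal-count bins + Pearson r) and
  to CF.
- **Pipeline & CLI** (`cmrpipe.pipeline`, `cmr`): simulate → analyze →
  report orchestration with a single master seed, plus a battery of standard
  tests (Friedman, Wilcoxon, sign, K–S, Pearson) from scipy.

## Tests

```
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: a 20-replicate
500-cell parameter-recovery battery (planted threshold orderings and pairwise
differences within ±1.5 dB), oracle-equivalence suites (flood-fill region
extraction over all 4×4 binaries, exact binomial-tail enumeration, independent
fixture recomputation of SR/AFI/window rates), bootstrap type-I calibration,
invariant suites, and AFI/masking-release coupling recovery. The full suite
takes ~5–6 minutes on one CPU (almost all of it in the recovery battery);
everything else runs in seconds.

## CLI

```
cmr simulate --config config.yaml --seed 1 --out-dir data/
cmr analyze all --data data/ --out results/        # or: fra | sr | neurometric | afi
cmr report --config config.yaml --seed 1 --out results/
```

`simulate` writes `spikes.csv`, `trials.csv` and the ground-truth
`truth.csv`; `analyze` emits per-cell CF/SR/AFI tables and JSON threshold
summaries; `report` runs the whole experiment and writes `report.json` with
per-condition neurometric thresholds, masking-release contrasts
(NB vs IM, NB vs CM, long vs short CM, laser vs control) and the test
battery. Reports are byte-identical for a fixed config + seed.

A YAML config mirrors `ExperimentConfig`, e.g.:

```yaml
schedule:
  masker_kinds: [NB, IM, CM_long, CM_short]
  laser_kinds: [CM_long, CM_short]
  n_cycles: 6
population:
  n_cells: 500
  thresholds_db: {NB: 8.0, IM: 6.5, CM_long: 1.0, CM_short: 6.5,
                  CM_long_laser: 6.5, CM_short_laser: 6.5}
```

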