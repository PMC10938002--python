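# pupilnum

Desk-scale toolkit for pupillometry of numerosity adaptation: constrained
dot-array stimulus construction, synthetic eye-tracker sessions, pupil-trace
preprocessing, event-locked feature extraction and mixed-effects inference.

The pipeline mirrors a passive-viewing adaptation paradigm: observers adapt
to a low (10-dot) or high (160-dot) numerosity array, then view brief test
arrays of 10–40 dots whose total bright area — hence luminance — is constant.
Peak pupil constriction to each test is extracted from cleaned, z-scored,
baseline-corrected traces and modelled against numerosity, adaptation
condition and pre-test pupil size; verbal numerosity estimates are modelled
analogously, and the per-participant adaptation effects of the two
modalities are correlated. A synthetic-data module generates raw sample
streams and estimates with the same statistical structure, so every stage is
testable without any recorded data.

## Modules

| module                | role |
|-----------------------|------|
| `pupilnum.stimuli`    | equal-area dot diameters, non-overlapping dot placement, rendering, trial design |
| `pupilnum.simulate`   | synthetic 500 Hz sessions (baseline, drift, constriction kernels, blinks/spikes/saccades) and verbal estimates; fast feature-level cohort generator for simulation batteries |
| `pupilnum.preprocess` | artifact flagging (< 1 mm, > 25 mm/s, blink dilation), saccade-based trial exclusion (> 1 deg), 20 Hz down-sampling, per-participant z-scoring, ±200 ms median baseline correction |
| `pupilnum.features`   | peak constriction (0.3–1.3 s window), pre-test pupil (−200–0 ms), condition averages, per-participant adaptation effects |
| `pupilnum.stats`      | Gaussian mixed models with crossed random intercepts (variance components), type-III Wald F tests, 3-SD outlier rule, Pearson pupil–behaviour correlation |
| `pupilnum.pipeline`   | end-to-end orchestration with derived seeds, attrition ledger and a hashed manifest |

A note on geometry: the published stimulus parameters are internally
inconsistent — 181 deg² of non-overlapping dots cannot lie inside an
11-deg-diameter (≈ 95 deg²) field. `sample_positions` detects infeasible
packings and raises; `feasible_field_diameter` computes a widened field in
which the same dot set can be placed, which the pipeline and CLI use (with a
logged warning) when rendering example stimuli.

## CLI

```bash
pupilnum run --seed 1 --out scratch/run            # full pipeline, 22 participants
pupilnum run --config run.yaml                     # YAML-configured run
pupilnum stimuli --condition low --seed 1 --field-diameter 29 --out scratch/stim
pupilnum simulate --participants 2 --seed 1 --out scratch/raw
pupilnum preprocess --in scratch/raw --out scratch/proc
pupilnum analyze --features F.tsv --estimates E.tsv --trials T.tsv --out scratch/models
```

`pupilnum run` writes the design, processed-trial and feature tables,
model JSONs, correlation results, figures (condition-average traces, peak
constriction vs numerosity, estimates vs numerosity, pupil–behaviour
scatter) and a `manifest.json` with seeds, per-participant attrition and
SHA-256 hashes of every table — identical configs give identical hashes.

## Input formats

Raw sessions are plain TSV: samples `(t_s, pupil_mm, gaze_x_deg,
gaze_y_deg, valid_flag)` and events `(trial, event, t_s)` with events
`adapt_start, topup_start, blank_start, test_on, test_off, trial_end`.
Real recordings exported in this shape can be fed to `pupilnum preprocess`
unchanged.
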