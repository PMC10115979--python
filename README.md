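# eegmicrostates

EEG microstate analysis for comparing task conditions and groups — built for
studies of acupuncture imagery versus real needling, and usable for any
multichannel EEG paradigm with condition markers.

Scalp EEG topographies stay quasi-stable for tens of milliseconds before
switching abruptly; the recurring configurations ("microstates", classically
four classes A–D) and their temporal statistics index large-scale network
dynamics. This package implements the full analysis chain:

* **preprocessing** — zero-phase Hamming FIR band-pass (1–45 Hz), automatic
  ICA artifact removal (ocular via Higuchi fractal dimension, myogenic via
  high-band spectral fraction), average reference, resampling to 200 Hz;
* **segmentation** — global field power
  `GFP(t) = √(Σᵢ (vᵢ(t) − v̄(t))² / n)`, GFP-peak topographies, polarity-
  invariant modified k-means (map `x` joins the template `mₖ` maximising
  `(x·mₖ)²`; templates update to dominant eigenvectors), cluster number
  chosen by the cross-validation criterion
  `CV(K) = σ̂²·((C−1)/(C−1−K))²` over K = 4..8, canonical A–D labelling,
  and per-sample backfitting by largest |spatial correlation|;
* **temporal parameters** — coverage, occurrence (/s), mean duration (ms),
  and Markov transition probabilities per microstate class;
* **group statistics** — one-way ANOVA + Tukey–Kramer within the imagery
  arm, paired t-tests within the needling arm, covariate-adjusted (age, sex,
  resting value) two-sample t between arms, Cohen's d, and
  Benjamini–Hochberg FDR per parameter panel, summarised as a ↗/↘/— table;
* **synthetic ground truth** — a semi-Markov generator (gamma durations,
  planted templates and transition matrices, per-segment polarity flips,
  rectified-sine GFP envelope, exact-SNR 1/f noise, parameterised condition
  effects) so every stage is validated against a known answer.

See `docs/methods.md` for the model, numerical choices, and limitations.

## Worked example

Simulate a cohort with a planted class-A effect (duration and incoming
transitions raised under imagery and needling), run the full pipeline, and
read off the directional summary:

```python
import pandas as pd
import eegmicrostates as ems

plan = ems.CohortPlan(n_ai_subjects=6, n_ra_subjects=6,
                      ai_block_s=15.0, ra_block_s=60.0)
truth = ems.default_truth(snr_db=10.0, seed=42,
                          condition_effects=ems.table2_preset())
cohort = ems.simulate_cohort(plan, truth)
subjects = pd.DataFrame([
    {"subject": s.recording.subject_id, "group": s.recording.group_tag,
     "age": s.age, "sex": s.sex} for s in cohort])

config = ems.PipelineConfig(seed=42, n_restarts=20, max_peak_maps=3000)
result = ems.run_pipeline(config, recordings=[s.recording for s in cohort],
                          subjects=subjects, fixed_k=4)
print("K:", result.manifest["selected_k"],
      " GEV:", round(result.manifest["gev"], 3))
print(result.sign_summary.loc[["coverage:A", "duration_ms:A", "coverage:C"]]
      .to_markdown())
```

prints

```
K: 4  GEV: 0.879
| parameter     | AI:imagery_left vs rest   | AI:imagery_right vs rest   | RA:real_needle vs rest   | AI_imagery vs RA_needle   |
|:--------------|:--------------------------|:---------------------------|:-------------------------|:--------------------------|
| coverage:A    | ↗                         | ↗                          | ↗                        | ↗                         |
| duration_ms:A | ↗                         | ↗                          | ↗                        | —                         |
| coverage:C    | —                         | —                          | ↘                        | —                         |
```

The four fitted maps explain 87.9% of the GFP-weighted topographic variance,
and the planted class-A increases are recovered as significant rising arrows
in every within-arm contrast (class-A coverage rises from 0.248 at rest to
0.308 under needling in this cohort), while unplanted cells stay flat.

A command-line interface mirrors the library
(`eegms simulate | preprocess | microstates fit | microstates backfit |
parameters | stats | run-all`); recordings travel as EDF, delimited text
with an events sidecar, or a native `.npz` format.

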