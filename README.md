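# catrisk

Calcium-transient (CaT) phenotyping and Torsade-de-Pointes (TdP) risk
classification for plate-based cardiomyocyte screens, exercised against a
seeded synthetic CaT generator.

The pipeline:

1. **Registry & I/O** (`catrisk.registry`) — an 11-compound reference
   registry (3 high-, 4 intermediate-, 4 low-risk compounds with clinical
   Cmax and a four-dose grid each), plate maps, and trace CSVs
   (`time_s` + one `well:phase` column per recording).
2. **Synthetic recordings** (`catrisk.synth`) — pulse-train traces with
   two cell-line baselines (control mean P80 ≈ 0.70 s; progeria, the
   "aged" line, ≈ 0.98 s) and per-compound Hill-curve drug effects:
   duration prolongation, amplitude suppression, EAD-like decay humps,
   beat cessation, and cycle-length irregularity. All effect-model
   numbers are synthetic calibration values, not measured pharmacology.
3. **Phenotyping** (`catrisk.phenotyping`) — cycle detection plus six
   per-well parameters: P80 (width at 80% recovery), 8/2 (80%/20% width
   ratio), CL (cycle length), AMP, PN (peak count), CSD (cycle-length
   standard deviation), and pre→post percent changes.
4. **Radial profiles** (`catrisk.transforms`) — a logistic EAD indicator
   on the raw 8/2 ratio (center 3, slope 9), a signed base-10 log-modulus
   on the other axes, and spider plots per compound × cell line.
5. **Predictors** (`catrisk.predictors`) — arrhythmia waveform type
   (None/Other/Type A, ordinal 0/1/2), P80@Cmax (log-dose interpolation,
   clamped at the grid ends), and P80_Max, min–max normalized per line.
6. **Risk model** (`catrisk.risk`) — three-class multinomial logistic
   regression (LBFGS, ridge C=1.0, 1000-iteration cap), per-compound
   probabilities, and the combined high+intermediate probability with
   its 0.8 decision threshold.

## CLI

```bash
catrisk simulate  --seed 0 --out-dir out/            # traces + plate map
catrisk phenotype --traces out/traces.csv --platemap out/platemap.csv \
                  --out out/phenotypes.csv
catrisk radial    --phenotypes out/phenotypes.csv --line control --out out/radial/
catrisk predictors --phenotypes out/phenotypes.csv --line progeria \
                  --out out/predictors.csv
catrisk classify  --phenotypes out/phenotypes.csv --out-dir out/risk/
```

`catrisk classify` fits one model per cell line and predicts
**in-sample** by default (the same 11 compounds it was trained on),
which is faithful to the source analysis but circular as a validation
scheme; pass `--mode loo` for leave-one-out prediction, provided as a
clearly-labeled extension.

## Notes

- Detection settings (smoothing 0.1 s, prominence 0.3 of range, minimum
  peak spacing 0.25 s) and all classification thresholds live in
  `DetectionConfig` / `ClassifierConfig` and can be overridden.
- Recording length (30 s), sampling rate (50 Hz), and noise level are
  configurable defaults; the synthetic calibration was chosen so the
  extracted phenotypes, not just the generator inputs, hit their
  targets.
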