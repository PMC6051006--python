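# eegbands

An EEG subband-energy screening pipeline for separating encephalopathy from
normal recordings:

1. **synth** — synthetic single-channel EEG cohorts (12 s epochs @ 500 Hz by
   default) whose measured relative band energies follow configurable
   per-group means/SDs. Band components are zero-phase band-pass-filtered
   Gaussian noise; a closed-loop calibration pre-compensates the measurement
   chain so group statistics land on target.
2. **denoise** — LPF-TVD: total-variation denoising (λ = 0.8) solved by
   majorization-minimization, combined with a zero-phase Butterworth low-pass
   of the TVD residual.
3. **wavelet** — 6-level Daubechies-4 filter-bank decomposition with
   periodized boundaries (exactly orthonormal: energy is conserved and the
   inverse cascade reconstructs to machine precision). Subbands A6/D6/D5/D4
   map to delta/theta/alpha/beta at 500 Hz.
4. **features** — absolute/relative subband energies per epoch and the cohort
   feature table (percent of total energy).
5. **stats** — per-group summaries and Welch two-sample t-tests, from raw
   samples or from printed summary statistics.
6. **classify** — linear SVM (positive class = encephalopathy) with a
   100/100-per-group train split, confusion-matrix counts and
   sensitivity/specificity/accuracy.
7. **io_formats** — EDF (16-bit, µV) and delimited-text epoch I/O, JSON
   manifests, CSV result tables.

## CLI

```bash
eegbands simulate --seed 1 --out cohort/ --format csv   # 232 + 218 epochs
eegbands denoise  --in cohort/ --out denoised/ --lam 0.8 --fc-hz 40
eegbands decompose --in cohort/ --out subbands/         # one epoch's A6..D1
eegbands features --in cohort/ --out features.csv       # denoise + DWT + energies
eegbands stats    --in features.csv --out stats/        # summary.csv, ttests.csv
eegbands classify --features features.csv --seed 17 --out results/
eegbands pipeline --seed 1 --out run/                   # all of the above
```

`simulate`/`pipeline` accept `--config config.yaml` to override cohort sizes,
band statistics (`band_stats: {group: {band: [mean, sd]}}`), sampling rate,
epoch duration, and the `calibrate` flag.

Note: the train/test split samples epochs, not subjects. On real data where
several epochs come from one patient this inflates performance estimates;
synthetic epochs are independent so the caveat does not apply here.

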