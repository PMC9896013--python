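# neuroprint

Brain fingerprinting from resting-state functional connectivity (FC):
a tested pipeline that goes from multi-channel hemodynamic time series
(fNIRS-style raw intensities or fMRI-style ROI series) to subject
identification accuracy and its saturation behaviour with spatial coverage.

## What is in the box

| module | role |
| --- | --- |
| `neuroprint.cohort` | synthetic multi-subject, multi-run cohorts with known latent correlation signatures, shared global physiology, AR-coloured noise, motion artifacts, anticorrelated HbO/HbR pairs and an inverse Beer–Lambert model for raw intensities |
| `neuroprint.preprocess` | fNIRS cleaning chain: SNR-based quality control (channel pruning, run exclusion, consistent-bad-channel removal), optical-density conversion, hybrid spline+wavelet motion correction, modified Beer–Lambert law (DPF 6, 760/850 nm), 0.009–0.08 Hz zero-phase band-pass, PCA removal of the first across-channel component |
| `neuroprint.connectivity` | per-channel AR prewhitening with BIC order selection, Pearson FC matrices, upper-triangle vectorization |
| `neuroprint.fingerprint` | three identification engines (Pearson matching, affine-invariant geodesic distance on SPD matrices, ridge linear classifier) under a repeated leave-one-out protocol, with variable training runs, random ROI sub-networks and multi-contrast combination |
| `neuroprint.saturation` | accuracy-saturation model `alpha * (1 - exp(-gamma * N))`, chi-square goodness of fit, and the ROI thresholds where the marginal gain drops below a stated rate |
| `neuroprint.stats` | tie-corrected rank-sum test (exact for small samples), Cohen's d with CI, Bonferroni correction, distribution summaries |

Runs and FC matrices are persisted as delimited text with JSON sidecars;
a minimal SNIRF (HDF5) export/import is available for intensity runs.

## CLI

The `neuroprint` entry point mirrors the pipeline stages:

```sh
neuroprint simulate --config cohort.json --out runs/ --seed 1
neuroprint preprocess --in runs/ --out prep/ --qc-snr 8 --band 0.009:0.08
neuroprint connectivity --in prep/ --out fc/ --max-ar-order 30
neuroprint fingerprint --fc fc/ --method geodesic --train-runs all \
    --reps 300 --seed 0 --out result.json
neuroprint fingerprint --fc fc/ --method linear --combine HbR+HbT \
    --train-runs 1 --reps 300 --seed 0 --out combined.json
neuroprint fit-model --accuracy-table table.csv --rates 0.5,0.25 --out fit.json
neuroprint report --results a.json b.json --bonferroni 6 --out cmp.json
```

`cohort.json` holds overrides for `neuroprint.CohortConfig`
(n_subjects, n_runs, duration, sampling_rate, n_channels, modality
`fnirs_raw | fnirs_hb | fmri_roi`, signature_strength, global_amplitude, ...).

## Library example

```python
import neuroprint as npr
from neuroprint import cohort, connectivity, fingerprint

cfg = cohort.default_identification_config(seed=7)
dataset = cohort.generate_cohort(cfg)
fcs = [connectivity.fc_from_run(r) for r in dataset.runs]
fcset = fingerprint.build_fc_set(fcs)
result = fingerprint.run_identification_experiment(
    fcset, method="geodesic", n_train_runs="all", n_reps=300, seed=0
)
print(result.mean_accuracy, result.sd_accuracy)
```
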