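# dkinet

Diffusion kurtosis imaging (DKI) quantifies non-Gaussian water diffusion in
brain tissue, but its scalar maps — fractional anisotropy (FA), mean
diffusivity (MD), mean kurtosis (MK) and kurtosis fractional anisotropy
(KFA) — are notoriously noise-sensitive when estimated by conventional
tensor fitting from short clinical acquisitions. `dkinet` implements and
compares two estimation routes for researchers working on fast DKI
protocols:

1. **Conventional model fit** — two-pass weighted linear least squares
   (WLLS) of the DKI signal model
   `ln S(b,n) = ln S0 − b·D_app(n) + (b²/6)·D_app(n)²·K_app(n)`,
   solving for the 6 diffusion-tensor and 15 kurtosis-tensor components per
   voxel, followed by the standard scalar derivations
   (MD = tr(D)/3, FA from the eigenvalue dispersion of D, MK as the
   spherical mean of the apparent kurtosis K_app(n), and
   KFA = ‖W − W̄ I⁽⁴⁾‖_F / ‖W‖_F).
2. **Hierarchical 3D CNN** — a convolutional network that maps b0-normalized
   diffusion-weighted volumes of a limited two-shell 61-volume acquisition
   directly to the four scalar maps. The shallow output head (FA, MD) taps
   the penultimate hidden layer; the deep head (MK, KFA) taps the final
   layer; the first hidden layer uses a 3×3×3 kernel and a dropout layer
   precedes each head. Training targets are the model fits of paired
   higher-quality three-shell 96-volume acquisitions of the same subjects,
   so the network learns cross-acquisition harmonization without ever
   seeing analytic ground truth.

Because no clinical data ship with the package, a multi-shell numerical
phantom (white-matter bundle, gray-matter shell, CSF core, plantable lesion;
Rician acquisition noise) provides paired degraded/reference scans with
known ground-truth tensors, plus two-group cohorts with planted effects and
synthetic clinical scores. Evaluation uses RMSE / MSE / PSNR over masked
voxels, and the group-analysis stage provides voxelwise unpaired t tests
with max-statistic permutation FWE correction (500 permutations, p < 0.05)
and Shapiro–Wilk-gated Pearson/Spearman clinical correlations with a
Bonferroni-corrected threshold (0.05/3 ≈ 0.016).

## Worked example

```python
from dkinet.experiments import run_paired_training_experiment

res = run_paired_training_experiment(seed=1, shape=(16, 16, 16), epochs=30)
for s in ("FA", "MD", "MK", "KFA"):
    print(f"{s}: cnn rmse {res.cnn_rmse[s]:.4g} vs fit {res.modelfit_rmse[s]:.4g}"
          f" | psnr {res.cnn_psnr[s]:.2f} vs {res.modelfit_psnr[s]:.2f}")
```

prints

```
FA: cnn rmse 0.0651 vs fit 0.1044 | psnr 21.98 vs 17.88
MD: cnn rmse 6.422e-05 vs fit 0.0001075 | psnr 33.59 vs 29.12
MK: cnn rmse 0.06317 vs fit 0.2538 | psnr 24.41 vs 12.33
KFA: cnn rmse 0.1086 vs fit 0.4036 | psnr 17.62 vs 6.22
```

Five phantom "subjects" were scanned twice (61-volume scan at SNR 20,
96-volume scan at SNR 40), the network was trained on the degraded scans
against the model fits of the reference scans, and two held-out subjects
were evaluated against the analytic ground truth. RMSE is in each scalar's
native units (MD in mm²/s), PSNR in dB with s_MAX taken from the
ground-truth map. The kurtosis metrics show the largest gap: the direct
model fit of the degraded scan amplifies noise into MK/KFA, while the CNN
estimates stay close to the reference quality.

Command-line equivalents: `dkinet simulate`, `dkinet fit`, `dkinet train`,
`dkinet predict`, `dkinet evaluate`, `dkinet stats` (see `--help` of each).

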