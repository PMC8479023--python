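# Methods

## Signal model and conventions

The DKI signal model is

    ln S(b, n) = ln S0 − b · D_app(n) + (b²/6) · D_app(n)² · K_app(n)

with apparent diffusivity `D_app(n) = Σ nᵢnⱼ Dᵢⱼ` and apparent kurtosis
`K_app(n) = (MD²/D_app(n)²) · Σ nᵢnⱼnₖnₗ Wᵢⱼₖₗ`, where D is the symmetric
rank-2 diffusion tensor (mm²/s) and W the fully symmetric rank-4 kurtosis
tensor (dimensionless). Because `D_app² K_app = MD² (n⊗⁴ : W)`, the model
is linear in 22 parameters per voxel: ln S0, the 6 unique components of D
(ordered xx, yy, zz, xy, xz, yz) and the 15 unique components of MD²·W
(lexicographic order of the sorted index multisets). Gradient tables use
the FSL bval/bvec dialect, directions in image coordinates, b=0 volumes
first and shells in ascending b.

## Tensor fitting

`fit_dki` is a two-pass weighted linear least squares on log-signals: an
ordinary least-squares pass provides predicted signals whose squares become
the weights of the definitive pass (log-domain noise variance scales as
1/S²). Numerical choices that matter:

* b is internally expressed in ms/µm² so all design-matrix columns are
  O(1); the normal equations square the condition number, and the raw
  s/mm² scaling costs ~6 digits of accuracy.
* Per-voxel weights are normalized to max 1 and floored at 1e-4. At b =
  3000 s/mm² the signal can decay by e⁻²⁰; unfloored squared weights erase
  the high-b rows that carry the kurtosis information and the noiseless
  round trip degrades from ~1e-8 to ~1e-4 relative error.
* Non-positive signals (possible only with Gaussian noise or masks leaking
  into background) are replaced by 1e-6 × median(b0) before the log;
  positive signals are never altered.
* After the fit, negative diffusion-tensor eigenvalues are clipped to zero
  (PSD projection). The kurtosis tensor is left unconstrained; the
  per-direction apparent kurtosis is clipped to [−3/7, 10] only when
  scalars are computed (−3/7 is the minimum attainable by any diffusion
  process; 10 flags gross misfit).
* Degenerate-voxel conventions: FA = 0 where tr(D) = 0, KFA = 0 where
  ‖W‖_F = 0, MK = 0 where MD = 0. These remove 0/0 cases in background
  voxels and are covered by tests.

MK is the numerical mean of K_app over a fixed 1024-point spherical
Fibonacci lattice rather than the exact elliptic-integral expression; the
lattice average agrees with a 10,000-direction oracle to ~0.2% worst-case
on random bounded-kurtosis tensors (a 256-point set errs up to 1%), far
below acquisition noise. KFA uses the
Frobenius decomposition with W̄ = ⟨W, I⁽⁴⁾⟩/‖I⁽⁴⁾‖² (an orthogonal
projection, so KFA ≤ 1 by construction).

## Acquisition schemes

Two protocol builders mirror the paired-acquisition design: a two-shell
61-volume scheme (1 × b0; b = 1000, 2000 s/mm², 30 directions each) and a
three-shell 96-volume scheme (6 × b0; b = 1000, 2000, 3000 s/mm², 30
directions each). Direction sets are spherical Fibonacci lattices per
shell, rotated by a seeded random rotation — deterministic, near-uniform,
with pairwise angular separation >5° up to 60 directions. Both schemes
share one table per shell size; the real gradient tables are not public,
and a near-uniform deterministic set is the standard neutral choice.

## Phantom

The default phantom is 32×32×32 voxels at 2 mm isotropic (tests and the
acceptance script use 10–16³ crops of the same design; sizes are stated
with each experiment). A spherical "brain" contains a CSF core, a
white-matter bundle oriented along z filling the interior, a gray-matter
shell, and an ellipsoidal lesion inside the bundle for planted effects.
Region recipes (eigenvalues in 10⁻³ mm²/s / kurtosis K):

| region | λ | K | FA | MK |
|---|---|---|---|---|
| wm-bundle | 1.7, 0.3, 0.3 | 1.0 | ≈0.80 | 1.0 |
| gm | 0.95, 0.78, 0.72 | 0.8 | ≈0.15 | 0.8 |
| csf | 3.15, 2.95, 2.90 | 0.1 | ≈0.05 | 0.1 |
| lesion | 1.3, 0.6, 0.5 | 0.9 | ≈0.50 | 0.9 |

Kurtosis tensors are constructed as `W = (K/MD²)·sym(D ⊗ D)`, which makes
K_app(n) ≡ K in every direction: MK equals the recipe's K exactly and KFA
inherits the diffusion anisotropy. Within-region dispersion (axis rotations
≤10°, ±5% eigenvalue and K jitter, seeded per subject) prevents degenerate
identical-voxel training data and provides between-subject variability for
the cohort statistics. Regions are painted as a disjoint partition of the
label volume, so overlapping definitions cannot arise.

Acquisition noise is Rician: `S_noisy = √((S+ε₁)² + ε₂²)` with
ε ~ N(0, σ²) and σ = mean(S0 in mask)/SNR, applied to background voxels
too. Defaults: SNR 20 for the degraded 61-volume scan, 40 for the
96-volume reference — no SNR is published for the acquisitions being
emulated, so these are stated assumptions chosen to produce a visible
quality gap between the two fits. Gaussian and noiseless modes exist for
oracle tests.

What the phantom does *not* emulate: realistic anatomy, crossing fibers,
susceptibility distortion, motion, inter-scan misregistration, or
scanner-specific artifacts. Results on the phantom therefore demonstrate
that the estimation and statistics machinery behaves correctly under known
ground truth — not that the CNN's advantage survives registration error or
artifact-laden clinical data.

## CNN estimator

The network maps the 61 b0-normalized channels (each DW volume divided by
the mean b0 volume, clamped to [0, 1.5], zeroed where b0 is at floor or
outside the mask, then centered by per-channel training means) to the four
scalars. Architecture default: six hidden ReLU conv layers —
3×3×3 kernels with 24, 24, 32 filters, then 1×1×1 with 48, 48, 48 — with
the shallow head (FA, MD) attached to the penultimate layer and the deep
head (MK, KFA) to the final layer, and dropout 0.1 before each head. The
printed constraints of the architecture being reproduced (first hidden
layer 3×3×3, hierarchical two-head output, per-head dropout) are honored;
depth and width are not published, and the chosen widths keep
whole-volume CPU training tractable while leaving width configurable in
`NetworkSpec`.

Training: Adam (lr 1e-3), whole volumes as batches (one subject per step),
masked MSE per head with MD rescaled by 1e3 to O(1) µm²/ms units so the
shallow head's channels are commensurate, head weights 1:1, 100 epochs by
default (the paired-training experiments use 30 at 16³, where the loss has
plateaued), no early stopping. Everything — init, data order, dropout —
derives from explicit seeds; convolutions are im2col + GEMM in float32
with analytic gradients (verified against central differences), so
single-threaded reruns are bit-identical. Targets are the *model fits* of
the reference scans, never the analytic truth: the truth is reserved for
evaluation, mirroring the harmonization design where a better acquisition,
not an oracle, defines the training target. A trained estimator stores the
scheme fingerprint of its training data and refuses differently-acquired
inputs unless forced; outputs are clipped to valid ranges (FA, KFA ∈
[0,1]; MD ≥ 0; MK ∈ [−3/7, 10]) and zeroed outside the mask.

## Evaluation metrics

RMSE = √(Σ(ŝᵢ−sᵢ)²/N) over the N masked voxels, MSE = RMSE², PSNR =
10·log₁₀(s_MAX²/MSE) with s_MAX the maximum of the *ground-truth* map
inside the mask — the reference map is the one quantity shared by both
methods, which makes PSNR directly comparable between them. MSE = 0 is
reported as +inf (JSON null, TSV "inf"), not an error.

## Group statistics

The two-group stage is a voxelwise unpaired pooled-variance t test with
max-statistic permutation FWE control: group labels are permuted (all
distinct labelings enumerated when their count does not exceed the
requested permutations; 500 sampled otherwise), the maximum |t| over the
mask is recorded per permutation, and corrected p-values use the
(1+count)/(1+n) estimator, which is never anti-conservative at finite
permutation counts. Max-statistic correction was chosen over
cluster-enhancement schemes because it has exact FWE control under
exchangeability and no tuning parameters; the permutation design (500
permutations, two-sided, p < 0.05 FWE) is retained. Positive t means
group B (patients) > group A (controls). Zero-variance voxels get t = 0
with a warning.

Clinical correlations are gated by Shapiro–Wilk normality (α = 0.05) on
both variables: Pearson when both pass, Spearman otherwise; significance
is Bonferroni-corrected at α/n_tests with n_tests = 3 by default
(0.05/3 ≈ 0.016). The denominator is configurable rather than hard-coded
because the number of comparisons depends on how many scalars and regions
survive the group stage.

The synthetic cohort plants a score–scalar correlation of strength ρ on
the latent scale: the per-subject regional mean is standardized across the
cohort and the score is ρ·z + √(1−ρ²)·ε. A single n = 68 cohort estimates
r with sampling SD ≈ 0.10, so recovery checks average the estimate over
several seeded cohorts instead of requiring each run to land in a narrow
window.

## Problem sizes used by the test suite and acceptance script

Round-trip and oracle checks run on 1,000 and 20 random bounded-kurtosis
tensor pairs (the random generator rescales a random symmetric W so
|K_app| ≤ 2 on a 512-direction lattice, keeping signals physically
decaying). The paired-training experiment runs at 16³ voxels, 5 training
and 2 held-out subjects, 30 epochs, 10 seeded replicates; cohort
experiments use 16³ phantoms with 20/20 (group tests) or 34/34
(correlation) subjects and 500 permutations. These desk-scale sizes were
chosen so the full pipeline — including ten complete CNN trainings — runs
in minutes on a single CPU while leaving every qualitative conclusion
unchanged at larger sizes.

## Known limitations

* The WLLS baseline is a generic unconstrained fit; production pipelines
  add denoising, Gibbs-ringing and Rician-bias corrections, and constrained
  fitting, all deliberately out of scope here. Outputs are labeled
  "model-fit" accordingly.
* The CNN is trained and evaluated on aligned phantom pairs; real paired
  scans require nonlinear registration whose errors are not modeled.
* MK uses a fixed direction lattice; exact rotation invariance holds only
  up to the lattice discretization (≲5e-3 absolute).
* The phantom's within-region dispersion is i.i.d. per voxel; spatial
  autocorrelation of real tissue (and hence cluster-level statistics) is
  not emulated, which is one reason max-statistic rather than cluster-based
  correction is the right tool at this scale.
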