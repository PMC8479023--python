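"""Multi-shell numerical phantom with known ground-truth DKI tensors.

The default phantom is a 32x32x32 "brain" at 2 mm isotropic resolution:
a CSF-like core (high diffusivity, near-zero kurtosis), a white-matter
bundle filling the interior (high FA, MK near 1), a gray-matter shell
(low FA, MK near 0.8) and an ellipsoidal lesion region inside the bundle
used for planting group effects. Within each region, tensors are dispersed
voxel-to-voxel by small random rotations and eigenvalue jitter so that fits
and learned estimators never see degenerate identical training voxels.

Kurtosis tensors are built as W = (K / MD^2) * sym(D (x) D), which makes the
apparent kurtosis exactly K along every direction: MK equals the region's K
by construction, and KFA grows with the diffusion anisotropy of the region.

Acquisition noise follows the magnitude-MRI (Rician) model:
S_noisy = sqrt((S + e1)^2 + e2^2) with e ~ N(0, sigma^2) and
sigma = mean(S0 in mask) / SNR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dki
from .dki import TensorFields, ScalarMaps, compute_scalars
from .schemes import AcquisitionScheme, DWIDataset, scanner_a_scheme, scanner_b_scheme

__all__ = [
    "TissueClass",
    "PhantomSpec",
    "ScoreModel",
    "CohortSpec",
    "generate_truth",
    "simulate_dwi",
    "generate_paired_scans",
    "generate_cohort",
]


@dataclass(frozen=True)
class TissueClass:
    """Ground-truth tensor recipe for one tissue region."""

    eigenvalues: tuple      # diffusion eigenvalues, mm^2/s, descending
    kurtosis: float         # apparent kurtosis K along every direction
    axis: tuple = (0.0, 0.0, 1.0)   # principal diffusion axis


# Defaults chosen to cover the contrast regimes of brain tissue:
# WM bundle FA ~ 0.80 / MK ~ 1.0, GM FA ~ 0.15 / MK ~ 0.8,
# CSF FA ~ 0.05 / MK ~ 0.1, lesion intermediate.
DEFAULT_TISSUES = {
    "wm-bundle": TissueClass((1.7e-3, 0.3e-3, 0.3e-3), 1.0),
    "gm": TissueClass((0.95e-3, 0.78e-3, 0.72e-3), 0.8),
    "csf": TissueClass((3.15e-3, 2.95e-3, 2.90e-3), 0.1),
    "lesion": TissueClass((1.3e-3, 0.6e-3, 0.5e-3), 0.9),
}

REGION_LABELS = {"wm-bundle": 1, "gm": 2, "csf": 3, "lesion": 4}


@dataclass
class PhantomSpec:
    """Geometry, tissue recipes and acquisition noise for one phantom."""

    shape: tuple = (32, 32, 32)
    voxel_size: float = 2.0
    tissues: dict = field(default_factory=lambda: dict(DEFAULT_TISSUES))
    snr: float = 20.0              # scanner-A-like (degraded) b0 SNR
    snr_reference: float = 40.0    # scanner-B-like (reference) b0 SNR
    noise_model: str = "rician"    # {"rician", "gaussian", "none"}
    s0: float = 1000.0
    dispersion_angle: float = 10.0   # max within-region axis rotation, degrees
    eigenvalue_jitter: float = 0.05  # +-5% per-voxel eigenvalue jitter
    seed: int = 0

    def __post_init__(self):
        if self.noise_model not in ("rician", "gaussian", "none"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.noise_model != "none" and (self.snr <= 0 or self.snr_reference <= 0):
            raise ValueError("snr must be positive when noise is on")


@dataclass
class ScoreModel:
    """Linear link between a regional scalar and a synthetic clinical score.

    The score is built as rho * z + sqrt(1 - rho^2) * eps on standardized
    regional means, so the planted population correlation is exactly rho;
    it is then mapped onto a UPDRS-III-like range.
    """

    region: str = "lesion"
    scalar: str = "MK"
    rho: float = -0.4
    score_mean: float = 30.0
    score_sd: float = 10.0


@dataclass
class CohortSpec:
    """A two-group synthetic cohort with planted regional effects."""

    n_group_a: int = 20            # controls
    n_group_b: int = 20            # patients
    # region -> scalar -> relative shift applied to group B (0.2 = +20%)
    effect_map: dict = field(default_factory=dict)
    score_model: ScoreModel = field(default_factory=ScoreModel)
    seed: int = 0

    def __post_init__(self):
        if self.n_group_a < 1 or self.n_group_b < 1:
            raise ValueError("both groups need at least one subject")


def random_tensor_pairs(n: int, seed: int = 0,
                        max_kurtosis: float = 2.0
                        ) -> tuple[np.ndarray, np.ndarray]:
    """n random valid (D, W) pairs: PSD D, apparent kurtosis bounded.

    Diffusion eigenvalues are drawn in a physiological range and randomly
    rotated; a random symmetric W is rescaled so that |K_app| stays within
    ``max_kurtosis`` over a dense direction set, keeping the multi-shell
    signal monotonically decaying as in tissue. Returns (D (n,6), W (n,15)).
    """
    from .schemes import fibonacci_sphere
    rng = np.random.default_rng(seed)
    lam = rng.uniform(0.2e-3, 2.5e-3, (n, 3))
    q, r = np.linalg.qr(rng.standard_normal((n, 3, 3)))
    mats = np.einsum("nik,nk,njk->nij", q, lam, q)
    d6 = dki.matrix_to_dt6(mats)
    w15 = rng.uniform(-1.0, 1.0, (n, 15))
    dirs = fibonacci_sphere(512)
    d_app = d6 @ dki.design_d6(dirs).T
    w_app = w15 @ dki.design_w15(dirs).T
    md = lam.mean(axis=1)
    k_app = (md ** 2)[:, None] * w_app / d_app ** 2
    target = rng.uniform(0.3 * max_kurtosis, max_kurtosis, n)
    scale = target / np.abs(k_app).max(axis=1)
    return d6, w15 * scale[:, None]


def _default_layout(shape) -> np.ndarray:
    """Disjoint region labels: CSF core, GM shell, WM fill, lesion ellipsoid."""
    nx, ny, nz = shape
    c = (np.array(shape) - 1) / 2.0
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    r = np.sqrt((ii - c[0]) ** 2 + (jj - c[1]) ** 2 + (kk - c[2]) ** 2)
    r_brain = 0.45 * min(shape)
    labels = np.zeros(shape, dtype=np.int8)
    brain = r <= r_brain
    labels[brain] = REGION_LABELS["wm-bundle"]
    labels[brain & (r >= 0.78 * r_brain)] = REGION_LABELS["gm"]
    labels[r <= 0.22 * r_brain] = REGION_LABELS["csf"]
    # lesion: small ellipsoid offset into the WM zone
    off = c + np.array([0.45 * r_brain, 0.0, 0.0])
    radii = np.maximum(np.array([0.22, 0.18, 0.18]) * r_brain, 1.5)
    e = (((ii - off[0]) / radii[0]) ** 2 + ((jj - off[1]) / radii[1]) ** 2
         + ((kk - off[2]) / radii[2]) ** 2)
    lesion = (e <= 1.0) & (labels == REGION_LABELS["wm-bundle"])
    labels[lesion] = REGION_LABELS["lesion"]
    return labels


def _small_rotation(rng: np.random.Generator, n: int, max_deg: float) -> np.ndarray:
    """n random rotations with angle uniform in [0, max_deg] about random axes."""
    axes = rng.standard_normal((n, 3))
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    angles = rng.uniform(0.0, np.deg2rad(max_deg), n)
    K = np.zeros((n, 3, 3))
    K[:, 0, 1], K[:, 0, 2], K[:, 1, 2] = -axes[:, 2], axes[:, 1], -axes[:, 0]
    K[:, 1, 0], K[:, 2, 0], K[:, 2, 1] = axes[:, 2], -axes[:, 1], axes[:, 0]
    s = np.sin(angles)[:, None, None]
    c = (1 - np.cos(angles))[:, None, None]
    return np.eye(3) + s * K + c * np.einsum("nij,njk->nik", K, K)


def _sym_outer_d6(d6: np.ndarray) -> np.ndarray:
    """15 unique components of sym(D (x) D); contraction with n^4 = D_app^2."""
    mats = dki.dt6_to_matrix(d6)
    w15 = np.empty(d6.shape[:-1] + (15,))
    for c, idx in enumerate(dki.W_INDEX_SETS):
        i, j, k, l = idx
        w15[..., c] = (mats[..., i, j] * mats[..., k, l]
                       + mats[..., i, k] * mats[..., j, l]
                       + mats[..., i, l] * mats[..., j, k]) / 3.0
    return w15


def _orthonormal_frame(axis) -> np.ndarray:
    """Rotation whose third column is the given unit axis."""
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    helper = np.array([1.0, 0.0, 0.0]) if abs(a[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(a, helper)
    u /= np.linalg.norm(u)
    v = np.cross(a, u)
    return np.column_stack([u, v, a])


def generate_truth(spec: PhantomSpec,
                   labels: np.ndarray | None = None
                   ) -> tuple[TensorFields, ScalarMaps, np.ndarray]:
    """Ground-truth tensor fields, scalar maps and region labels.

    Deterministic for a fixed spec seed. A custom integer label volume may be
    supplied (0 = background); region names then come from spec.tissues keyed
    by REGION_LABELS.
    """
    if labels is None:
        labels = _default_layout(spec.shape)
    else:
        labels = np.asarray(labels)
        if labels.shape != tuple(spec.shape):
            raise ValueError("label volume shape must match spec.shape")
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    mask = labels > 0
    D = np.zeros(shape + (6,))
    W = np.zeros(shape + (15,))
    S0 = np.zeros(shape)
    for name, lab in REGION_LABELS.items():
        if name not in spec.tissues:
            continue
        tissue = spec.tissues[name]
        sel = labels == lab
        n = int(sel.sum())
        if n == 0:
            continue
        lam = np.asarray(tissue.eigenvalues, dtype=float)
        jitter = 1.0 + rng.uniform(-spec.eigenvalue_jitter,
                                   spec.eigenvalue_jitter, (n, 3))
        lams = lam * jitter                                   # (n, 3)
        base = _orthonormal_frame(tissue.axis)[:, ::-1]       # cols: e1,e2,e3
        rots = _small_rotation(rng, n, spec.dispersion_angle) @ base
        mats = np.einsum("nik,nk,njk->nij", rots, lams, rots)
        d6 = dki.matrix_to_dt6(mats)
        md = lams.mean(axis=1)
        k = tissue.kurtosis * (1.0 + rng.uniform(-spec.eigenvalue_jitter,
                                                 spec.eigenvalue_jitter, n))
        D[sel] = d6
        W[sel] = (k / md ** 2)[:, None] * _sym_outer_d6(d6)
        S0[sel] = spec.s0
    fields = TensorFields(S0=S0, D=D, W=W, mask=mask)
    scalars = compute_scalars(fields, method="truth")
    return fields, scalars, labels


def simulate_dwi(truth: TensorFields, scheme: AcquisitionScheme,
                 snr: float = 20.0, noise_model: str = "rician",
                 seed: int = 0, voxel_size: float = 2.0) -> DWIDataset:
    """Simulate one acquisition of the phantom under magnitude-MRI noise.

    sigma = mean(S0 inside mask) / snr; "none" returns the noiseless forward
    signal exactly. Background voxels (S0 = 0) receive the same noise floor,
    as in real magnitude images.
    """
    shape = truth.S0.shape
    signal = np.zeros(shape + (scheme.n_volumes,))
    m = truth.mask
    if np.any(m):
        signal[m] = dki.predict_signal(truth.S0[m], truth.D[m], truth.W[m], scheme)
    if noise_model == "none":
        return DWIDataset(signal=signal, scheme=scheme, mask=m,
                          voxel_size=np.full(3, float(voxel_size)))
    if snr <= 0:
        raise ValueError("snr must be positive when noise is on")
    sigma = truth.S0[m].mean() / snr if np.any(m) else 1.0 / snr
    rng = np.random.default_rng(seed)
    if noise_model == "rician":
        e1 = rng.normal(0.0, sigma, signal.shape)
        e2 = rng.normal(0.0, sigma, signal.shape)
        noisy = np.sqrt((signal + e1) ** 2 + e2 ** 2)
    elif noise_model == "gaussian":
        noisy = np.maximum(signal + rng.normal(0.0, sigma, signal.shape), 0.0)
    else:
        raise ValueError(f"unknown noise model {noise_model!r}")
    return DWIDataset(signal=noisy, scheme=scheme, mask=m,
                      voxel_size=np.full(3, float(voxel_size)))


def generate_paired_scans(spec: PhantomSpec, direction_seed: int = 0
                          ) -> tuple[DWIDataset, DWIDataset, TensorFields]:
    """One subject scanned twice: degraded 61-volume and reference 96-volume.

    Scan 1 uses the two-shell scanner-A protocol at spec.snr; scan 2 the
    three-shell scanner-B protocol at spec.snr_reference. Both sample the
    same ground truth and are perfectly aligned (no misregistration).
    """
    truth, _, _ = generate_truth(spec)
    ss = np.random.SeedSequence(spec.seed)
    s1, s2 = ss.spawn(2)
    scan1 = simulate_dwi(truth, scanner_a_scheme(direction_seed), snr=spec.snr,
                         noise_model=spec.noise_model,
                         seed=int(s1.generate_state(1)[0] % (2 ** 31)),
                         voxel_size=spec.voxel_size)
    scan2 = simulate_dwi(truth, scanner_b_scheme(direction_seed),
                         snr=spec.snr_reference, noise_model=spec.noise_model,
                         seed=int(s2.generate_state(1)[0] % (2 ** 31)),
                         voxel_size=spec.voxel_size)
    return scan1, scan2, truth


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    maps: ScalarMaps
    labels: np.ndarray


def generate_cohort(phantom: PhantomSpec, cohort: CohortSpec
                    ) -> tuple[list, pd.DataFrame]:
    """A two-group cohort of scalar maps plus a clinical covariate table.

    Each subject gets an independent realization of the phantom's
    within-region tensor dispersion (fresh seed per subject). Group B
    additionally carries the planted regional effects of
    ``cohort.effect_map`` (relative shifts on the named scalar in the named
    region). The clinical score follows ``cohort.score_model``; H&Y-like
    ordinal stages are binned from the same latent severity.
    """
    ss = np.random.SeedSequence(cohort.seed)
    n_total = cohort.n_group_a + cohort.n_group_b
    subject_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                     for s in ss.spawn(n_total)]
    rng = np.random.default_rng(int(ss.generate_state(2)[1] % (2 ** 31)))

    subjects = []
    groups = ["A"] * cohort.n_group_a + ["B"] * cohort.n_group_b
    for i, (grp, sseed) in enumerate(zip(groups, subject_seeds)):
        sub_spec = PhantomSpec(**{**phantom.__dict__, "seed": sseed})
        _, maps, labels = generate_truth(sub_spec)
        if grp == "B":
            for region, shifts in cohort.effect_map.items():
                sel = labels == REGION_LABELS[region]
                for scalar, rel in shifts.items():
                    arr = maps[scalar]
                    arr[sel] *= (1.0 + rel)
        subjects.append(SubjectRecord(subject_id=f"sub-{i + 1:03d}", group=grp,
                                      maps=maps, labels=labels))

    sm = cohort.score_model
    sel_lab = REGION_LABELS[sm.region]
    means = np.array([s.maps[sm.scalar][s.labels == sel_lab].mean()
                      for s in subjects])
    z = (means - means.mean()) / (means.std() if means.std() > 0 else 1.0)
    eps = rng.standard_normal(n_total)
    latent = sm.rho * z + np.sqrt(max(0.0, 1.0 - sm.rho ** 2)) * eps
    updrs3 = sm.score_mean + sm.score_sd * latent
    hy = np.clip(np.digitize(latent, [-0.5, 0.5]) + 1, 1, 3)

    table = pd.DataFrame({
        "subject_id": [s.subject_id for s in subjects],
        "group": groups,
        "hy_score": hy,
        "updrs3": np.round(updrs3, 2),
        "age": np.round(rng.normal(62.0, 8.0, n_total), 1),
        "sex": rng.choice(["M", "F"], n_total),
    })
    return subjects, table
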