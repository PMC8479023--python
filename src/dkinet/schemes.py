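"""Acquisition schemes and diffusion-volume I/O.

A multi-shell diffusion protocol is described by one b-value and one unit
gradient direction per acquired volume (FSL bval/bvec convention). Gradient
direction sets are generated on a spherical Fibonacci lattice per shell:
deterministic for a given seed and close to uniform on the hemisphere, which
is what matters for rotationally unbiased tensor estimation.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "AcquisitionScheme",
    "DWIDataset",
    "build_scheme",
    "scanner_a_scheme",
    "scanner_b_scheme",
    "read_dwi",
    "write_dwi",
    "fibonacci_hemisphere",
    "fibonacci_sphere",
]

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


def fibonacci_hemisphere(n: int) -> np.ndarray:
    """n near-uniform unit vectors on the upper hemisphere (z > 0)."""
    i = np.arange(n)
    z = (i + 0.5) / n                       # z in (0, 1)
    r = np.sqrt(1.0 - z * z)
    phi = i * _GOLDEN_ANGLE
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def fibonacci_sphere(n: int) -> np.ndarray:
    """n near-uniform unit vectors over the full sphere."""
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = i * _GOLDEN_ANGLE
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


@dataclass(frozen=True)
class AcquisitionScheme:
    """b-values (s/mm^2) and unit gradient directions, one per volume."""

    b_values: np.ndarray
    directions: np.ndarray
    label: str = ""

    def __post_init__(self):
        b = np.asarray(self.b_values, dtype=float).ravel()
        g = np.asarray(self.directions, dtype=float).reshape(-1, 3)
        if b.shape[0] != g.shape[0]:
            raise ValueError(
                f"{b.shape[0]} b-values but {g.shape[0]} directions"
            )
        if np.any(b < 0):
            raise ValueError("b-values must be non-negative")
        if not np.any(b == 0):
            raise ValueError("scheme must contain at least one b=0 volume")
        dwi = b > 0
        norms = np.linalg.norm(g[dwi], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("directions at b>0 must be unit norm (tol 1e-6)")
        object.__setattr__(self, "b_values", b)
        object.__setattr__(self, "directions", g)

    @property
    def n_volumes(self) -> int:
        return int(self.b_values.shape[0])

    @property
    def b0_mask(self) -> np.ndarray:
        return self.b_values == 0

    @property
    def shells(self) -> np.ndarray:
        """Sorted unique nonzero b-values."""
        return np.unique(self.b_values[self.b_values > 0])

    def fingerprint(self) -> str:
        """Stable hash of the protocol (b-values + directions, rounded)."""
        h = hashlib.sha256()
        h.update(np.round(self.b_values, 3).tobytes())
        h.update(np.round(self.directions, 6).tobytes())
        return h.hexdigest()[:16]


@dataclass
class DWIDataset:
    """A 4D diffusion-weighted volume with its scheme, mask and geometry."""

    signal: np.ndarray
    scheme: AcquisitionScheme
    mask: np.ndarray
    voxel_size: np.ndarray = field(default_factory=lambda: np.array([2.0, 2.0, 2.0]))
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4D (x, y, z, volume)")
        if self.signal.shape[3] != self.scheme.n_volumes:
            raise ValueError(
                f"signal has {self.signal.shape[3]} volumes, "
                f"scheme has {self.scheme.n_volumes}"
            )
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")
        if np.any(self.signal < 0):
            raise ValueError("signal must be non-negative")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.signal.shape[:3]:
            raise ValueError("mask shape must match signal spatial shape")
        self.voxel_size = np.asarray(self.voxel_size, dtype=float).ravel()
        if self.affine is None:
            self.affine = np.diag([*self.voxel_size, 1.0])

    @property
    def spatial_shape(self) -> tuple:
        return self.signal.shape[:3]


def _seeded_rotation(seed: int) -> np.ndarray:
    """A deterministic uniformly-random rotation matrix (QR of a Gaussian)."""
    rng = np.random.default_rng(seed)
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def build_scheme(
    shells: list[tuple[float, int]],
    n_b0: int = 1,
    direction_seed: int = 0,
    label: str = "",
) -> AcquisitionScheme:
    """Build a multi-shell scheme: n_b0 b=0 volumes, then shells in ascending b.

    Each shell's direction set is a spherical Fibonacci hemisphere lattice,
    rotated by a rotation drawn deterministically from ``direction_seed`` so
    that distinct seeds give distinct (still near-uniform) gradient tables.
    Shells with the same number of directions share one table, as is common
    for multi-shell protocols.
    """
    if n_b0 < 1:
        raise ValueError("at least one b=0 volume is required as signal reference")
    for b, n in shells:
        if b <= 0:
            raise ValueError("shell b-values must be positive")
        if n < 1:
            raise ValueError("each shell needs at least one direction")
    rot = _seeded_rotation(direction_seed)
    b_values = [0.0] * n_b0
    directions = [np.zeros(3)] * n_b0
    for b, n in sorted(shells):
        dirs = fibonacci_hemisphere(n) @ rot.T
        b_values.extend([float(b)] * n)
        directions.extend(dirs)
    return AcquisitionScheme(np.array(b_values), np.array(directions), label=label)


def scanner_a_scheme(direction_seed: int = 0) -> AcquisitionScheme:
    """Two-shell 61-volume protocol: b=0 x1, b=1000/2000 s/mm^2 x30 each."""
    return build_scheme([(1000, 30), (2000, 30)], n_b0=1,
                        direction_seed=direction_seed, label="scanner-A")


def scanner_b_scheme(direction_seed: int = 0) -> AcquisitionScheme:
    """Three-shell 96-volume protocol: b=0 x6, b=1000/2000/3000 s/mm^2 x30 each."""
    return build_scheme([(1000, 30), (2000, 30), (3000, 30)], n_b0=6,
                        direction_seed=direction_seed, label="scanner-B")


def _read_fsl_table(bval_path, bvec_path) -> tuple[np.ndarray, np.ndarray]:
    bvals = np.loadtxt(bval_path, dtype=float).ravel()
    bvecs = np.loadtxt(bvec_path, dtype=float)
    if bvecs.ndim != 2 or 3 not in bvecs.shape:
        raise ValueError("bvec file must have three rows (or columns)")
    if bvecs.shape[0] != 3:
        bvecs = bvecs.T
    return bvals, bvecs.T  # (n, 3)


def read_dwi(image_path, bval_path, bvec_path, mask_path=None) -> DWIDataset:
    """Read a 4D NIfTI with FSL-dialect bval/bvec files.

    Directions with norm within 1e-3 of unity are renormalized; anything
    farther off is rejected as a malformed gradient table.
    """
    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError("expected a 4D diffusion image")
    bvals, bvecs = _read_fsl_table(bval_path, bvec_path)
    if bvals.shape[0] != data.shape[3] or bvecs.shape[0] != data.shape[3]:
        raise ValueError(
            f"gradient table length ({bvals.shape[0]}) does not match "
            f"image volume count ({data.shape[3]})"
        )
    norms = np.linalg.norm(bvecs, axis=1)
    dwi = bvals > 0
    bad = dwi & (np.abs(norms - 1.0) > 1e-3)
    if np.any(bad):
        raise ValueError(
            f"{int(bad.sum())} directions at b>0 deviate from unit norm by >1e-3"
        )
    fix = dwi & (norms > 0)
    bvecs[fix] /= norms[fix, None]
    scheme = AcquisitionScheme(bvals, bvecs, label=Path(str(image_path)).name)
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    else:
        mask = np.ones(data.shape[:3], dtype=bool)
    voxel_size = np.asarray(img.header.get_zooms()[:3], dtype=float)
    return DWIDataset(signal=data, scheme=scheme, mask=mask,
                      voxel_size=voxel_size, affine=img.affine)


def write_dwi(dataset: DWIDataset, image_path, bval_path, bvec_path,
              mask_path=None) -> dict:
    """Write a DWIDataset as NIfTI + FSL bval/bvec (and optionally the mask)."""
    img = nib.Nifti1Image(dataset.signal.astype(np.float32), dataset.affine)
    img.header.set_zooms((*dataset.voxel_size, 1.0))
    nib.save(img, str(image_path))
    np.savetxt(bval_path, dataset.scheme.b_values[None, :], fmt="%.6g")
    np.savetxt(bvec_path, dataset.scheme.directions.T, fmt="%.8f")
    paths = {"image": image_path, "bval": bval_path, "bvec": bvec_path}
    if mask_path is not None:
        nib.save(nib.Nifti1Image(dataset.mask.astype(np.uint8), dataset.affine),
                 str(mask_path))
        paths["mask"] = mask_path
    return paths
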