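"""Point spread function handling.

All PSF grids follow the package-wide ``(x, y, z)`` index convention with the
rotation axis on axis 1 (y).  A 3D PSF is reduced to the two kernels the
2D+1D fusion scheme needs:

* a 2D PSF — the central x–z plane, perpendicular to the rotation axis,
  used by the slice-wise 2D multi-view deconvolution;
* a 1D PSF — the central column along y, used by the subsequent 1D
  deconvolution along the rotation axis.

PSF grids must have odd extents on every axis so that the central plane,
column and voxel are unambiguous.  Extracted kernels are renormalized to
unit sum, which keeps the Richardson-Lucy projectors flux preserving.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GaussianPSFModel",
    "normalize_psf",
    "extract_psf2d",
    "extract_psf1d",
    "make_gaussian_psf",
    "rotate_psf_to_view",
]


@dataclass(frozen=True)
class GaussianPSFModel:
    """Separable anisotropic Gaussian model PSF, a synthetic stand-in for a
    measured bead PSF.

    Sigmas are in voxels; ``radius`` is the kernel half-extent in voxels, so
    the kernel has ``2 * radius + 1`` samples per axis.  The radius must be at
    least ``3 * max(sigma)`` so that the truncated mass is below ~1%.
    """

    sigma_x: float
    sigma_y: float
    sigma_z: float
    radius: int

    def __post_init__(self) -> None:
        if min(self.sigma_x, self.sigma_y, self.sigma_z) <= 0:
            raise ValueError("all sigmas must be positive")
        if self.radius < 3 * max(self.sigma_x, self.sigma_y, self.sigma_z):
            raise ValueError(
                "radius must be >= 3 * max(sigma) to keep truncation below 1%"
            )


def _check_odd(shape: tuple[int, ...]) -> None:
    if any(n % 2 == 0 for n in shape):
        raise ValueError(f"PSF extents must be odd, got shape {shape}")


def normalize_psf(psf: np.ndarray) -> np.ndarray:
    """Return ``psf`` scaled to unit sum.  Raises on non-positive total mass."""
    psf = np.asarray(psf, dtype=np.float64)
    if np.any(psf < 0):
        raise ValueError("PSF must be nonnegative")
    total = psf.sum()
    if total <= 0:
        raise ValueError("PSF must have positive total mass")
    return psf / total


def extract_psf2d(psf3d: np.ndarray) -> np.ndarray:
    """Central x–z plane of a 3D PSF (the plane perpendicular to the rotation
    axis), renormalized to unit sum."""
    psf3d = np.asarray(psf3d, dtype=np.float64)
    if psf3d.ndim != 3:
        raise ValueError("expected a 3D PSF")
    _check_odd(psf3d.shape)
    plane = psf3d[:, psf3d.shape[1] // 2, :]
    return normalize_psf(plane)


def extract_psf1d(psf3d: np.ndarray) -> np.ndarray:
    """Central column of a 3D PSF along the rotation axis (y), renormalized."""
    psf3d = np.asarray(psf3d, dtype=np.float64)
    if psf3d.ndim != 3:
        raise ValueError("expected a 3D PSF")
    _check_odd(psf3d.shape)
    column = psf3d[psf3d.shape[0] // 2, :, psf3d.shape[2] // 2]
    return normalize_psf(column)


def make_gaussian_psf(model: GaussianPSFModel) -> np.ndarray:
    """Sample a normalized anisotropic Gaussian at voxel centers.

    Returns a ``(2r+1, 2r+1, 2r+1)`` volume in (x, y, z) order with the peak
    at the central voxel.
    """
    r = model.radius
    coords = np.arange(-r, r + 1, dtype=np.float64)
    gx = np.exp(-0.5 * (coords / model.sigma_x) ** 2)
    gy = np.exp(-0.5 * (coords / model.sigma_y) ** 2)
    gz = np.exp(-0.5 * (coords / model.sigma_z) ** 2)
    psf = gx[:, None, None] * gy[None, :, None] * gz[None, None, :]
    return normalize_psf(psf)


def rotate_psf_to_view(psf3d: np.ndarray, angle: float) -> np.ndarray:
    """Rotate a 3D PSF about the rotation axis (y) by a multiple of 90°.

    Rotations are exact axis permutations/flips in the x–z plane — no
    resampling is performed, so four 90° applications compose to the
    identity.  The central y column is invariant, which is what makes a
    single 1D PSF valid for every view.
    """
    angle = float(angle) % 360.0
    if angle % 90.0 != 0.0:
        raise ValueError("view angles must be multiples of 90 degrees")
    psf3d = np.asarray(psf3d, dtype=np.float64)
    if psf3d.ndim != 3:
        raise ValueError("expected a 3D PSF")
    k = int(angle // 90) % 4
    return np.ascontiguousarray(np.rot90(psf3d, k=k, axes=(0, 2)))
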