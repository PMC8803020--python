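"""Synthetic multi-view light-sheet acquisitions with known ground truth.

The simulator produces the three ingredients every quantitative comparison
of fusion methods needs:

* a ground-truth object — either a "microtubule"-like phantom of straight
  lines emanating from a bright central body, or a field of sub-resolution
  point beads with known centers;
* per-view image formation — rotation into the view frame (exact 90°
  permutations about the rotation axis y), exponential depth attenuation
  along the detection axis to emulate scattering/absorption of the emitted
  fluorescence (excitation-side losses are neglected, as appropriate for
  two-sided illumination), convolution with an anisotropic 3D PSF, and
  rotation back into the common frame — so the delivered views are already
  registered;
* detector statistics — Poisson shot noise at a configurable photon budget
  followed by additive zero-mean Gaussian read noise (default variance
  1.6e-5 on the [0, 1] intensity scale), clipped at zero.

Each view draws from an independent, seed-offset random stream, so runs are
fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .psf import rotate_psf_to_view

__all__ = [
    "GroundTruth",
    "AcquisitionParams",
    "make_lines_phantom",
    "make_bead_phantom",
    "attenuate",
    "simulate_view",
    "simulate_multiview",
]

GAUSSIAN_NOISE_VARIANCE = 1.6e-5


@dataclass
class GroundTruth:
    """Noise-free object on a [0, 1] intensity scale."""

    data: np.ndarray
    kind: str
    meta: dict = field(default_factory=dict)


@dataclass
class AcquisitionParams:
    """Conditions of a simulated multi-view acquisition.

    ``attenuation_length`` is the exponential decay scale (voxels) of the
    detected fluorescence with depth; ``None`` defaults to half the volume
    extent at simulation time.  ``photon_budget`` is the expected photon
    count at intensity 1 (Poisson scale); ``None`` disables shot noise.
    ``gaussian_variance`` is the read-noise variance on the [0, 1] scale.
    """

    psf: np.ndarray | None = None
    angles: Sequence[float] = (0.0, 90.0, 180.0, 270.0)
    attenuation_length: float | None = None
    gaussian_variance: float = GAUSSIAN_NOISE_VARIANCE
    photon_budget: float | None = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.attenuation_length is not None and self.attenuation_length <= 0:
            raise ValueError("attenuation_length must be positive")
        if self.gaussian_variance < 0:
            raise ValueError("gaussian_variance must be nonnegative")
        if self.photon_budget is not None and self.photon_budget <= 0:
            raise ValueError("photon_budget must be positive")


def _rotate_about_y(volume: np.ndarray, quarter_turns: int) -> np.ndarray:
    """Exact rotation about the y axis by ``quarter_turns`` × 90°."""
    return np.rot90(volume, k=quarter_turns % 4, axes=(0, 2))


def make_lines_phantom(extent: int, n_lines: int = 50, seed: int = 0) -> GroundTruth:
    """Straight lines radiating from the center plus a brighter central body.

    Rays point in uniformly random directions on the sphere and are
    rasterized with ~1-voxel-wide anti-aliased (trilinear) profiles at
    amplitude 0.7; the central spherical body has amplitude 1.  The result
    resembles the microtubule aster of a dividing cell.
    """
    if extent < 32:
        raise ValueError("extent must be >= 32")
    rng = np.random.default_rng(seed)
    vol = np.zeros((extent, extent, extent), dtype=np.float64)
    center = (extent - 1) / 2.0
    body_radius = max(2.0, extent / 24.0)

    directions = np.empty((n_lines, 3))
    step = 0.3
    t_max = extent / 2.0 - 1.0
    for i in range(n_lines):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        directions[i] = u
        t = np.arange(body_radius, t_max, step)
        pts = center + t[:, None] * u[None, :]
        _deposit_trilinear(vol, pts, weight=0.7 * step)
    np.clip(vol, 0.0, 0.7, out=vol)

    # central body: solid sphere, amplitude 1
    ax = np.arange(extent, dtype=np.float64) - center
    r2 = ax[:, None, None] ** 2 + ax[None, :, None] ** 2 + ax[None, None, :] ** 2
    vol[r2 <= body_radius**2] = 1.0
    vol /= vol.max()
    return GroundTruth(vol, "lines", {"directions": directions, "body_radius": body_radius})


def _deposit_trilinear(vol: np.ndarray, points: np.ndarray, weight: float) -> None:
    """Accumulate unit deposits at fractional positions with trilinear splats."""
    n = vol.shape
    base = np.floor(points).astype(np.int64)
    frac = points - base
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (
                    (frac[:, 0] if dx else 1 - frac[:, 0])
                    * (frac[:, 1] if dy else 1 - frac[:, 1])
                    * (frac[:, 2] if dz else 1 - frac[:, 2])
                )
                ix, iy, iz = base[:, 0] + dx, base[:, 1] + dy, base[:, 2] + dz
                ok = (
                    (ix >= 0) & (ix < n[0])
                    & (iy >= 0) & (iy < n[1])
                    & (iz >= 0) & (iz < n[2])
                )
                np.add.at(vol, (ix[ok], iy[ok], iz[ok]), weight * w[ok])


def make_bead_phantom(
    extent: int,
    n_beads: int,
    min_separation: float,
    seed: int = 0,
    margin: int | None = None,
) -> tuple[GroundTruth, np.ndarray]:
    """Single-voxel impulses at random positions with a minimum separation.

    Emulates a gel phantom of sub-resolution fluorescent beads.  ``margin``
    keeps beads away from the volume faces (default: a quarter of the
    extent, capped at 16) so their blurred spots stay measurable.  Returns
    the phantom and the ``(n_beads, 3)`` array of true centers.
    """
    if margin is None:
        margin = min(extent // 4, 16)
    lo, hi = margin, extent - margin
    if hi <= lo:
        raise ValueError("margin leaves no room for beads")
    rng = np.random.default_rng(seed)
    centers: list[np.ndarray] = []
    attempts = 0
    while len(centers) < n_beads:
        attempts += 1
        if attempts > 10000 * n_beads:
            raise RuntimeError("bead placement infeasible for these constraints")
        cand = rng.integers(lo, hi, size=3).astype(np.float64)
        if all(np.linalg.norm(cand - c) >= min_separation for c in centers):
            centers.append(cand)
    centers_arr = np.array(centers)
    vol = np.zeros((extent, extent, extent), dtype=np.float64)
    for c in centers_arr.astype(int):
        vol[tuple(c)] = 1.0
    return GroundTruth(vol, "beads", {"centers": centers_arr}), centers_arr


def attenuate(
    volume: np.ndarray, detection_axis: int = 2, direction: int = 1, length: float = 64.0
) -> np.ndarray:
    """Exponential depth attenuation of the detected fluorescence.

    Multiplies by ``exp(-d / length)`` where ``d`` is the depth (voxels)
    from the camera-facing face along ``detection_axis``.  With
    ``direction = +1`` the camera faces the low-index side (depth grows with
    the index); ``-1`` mirrors it.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    volume = np.asarray(volume, dtype=np.float64)
    n = volume.shape[detection_axis]
    depth = np.arange(n, dtype=np.float64)
    if direction < 0:
        depth = depth[::-1]
    factors = np.exp(-depth / length)
    shape = [1] * volume.ndim
    shape[detection_axis] = n
    return volume * factors.reshape(shape)


def _format_view(gt_data: np.ndarray, angle: float, params: AcquisitionParams) -> np.ndarray:
    """Noise-free image formation for one view, in the common frame."""
    from .deconv import convolve

    k = int((float(angle) % 360.0) // 90)
    if float(angle) % 90.0 != 0.0:
        raise ValueError("view angles must be multiples of 90 degrees")
    in_view = _rotate_about_y(gt_data, -k)
    length = params.attenuation_length
    if length is None:
        length = gt_data.shape[2] / 2.0
    in_view = attenuate(in_view, detection_axis=2, direction=1, length=length)
    if params.psf is not None:
        # clip FFT round-off negatives: downstream noise models need i >= 0
        in_view = np.clip(convolve(in_view, params.psf), 0.0, None)
    return np.ascontiguousarray(_rotate_about_y(in_view, k))


def simulate_view(
    gt: GroundTruth, angle: float, params: AcquisitionParams, view_index: int = 0
) -> np.ndarray:
    """Simulate one registered view: rotate, attenuate, blur, add noise.

    The ground truth is rotated by −angle about y into the view frame,
    attenuated along the detection axis (z in the view frame), convolved
    with the acquisition PSF, degraded with Poisson then Gaussian noise, and
    rotated back into the common frame.  The effective PSF of the delivered
    view is ``rotate_psf_to_view(params.psf, angle)``.
    """
    clean = _format_view(gt.data, angle, params)
    rng = np.random.default_rng(params.seed + view_index)
    noisy = clean
    if params.photon_budget is not None:
        noisy = rng.poisson(params.photon_budget * clean) / params.photon_budget
    if params.gaussian_variance > 0:
        noisy = noisy + rng.normal(0.0, np.sqrt(params.gaussian_variance), clean.shape)
    return np.clip(noisy, 0.0, None)


def simulate_multiview(
    gt: GroundTruth, params: AcquisitionParams
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Simulate all views plus the matching per-view PSFs.

    Returns ``(views, psfs)``; view ``v`` uses the independent random stream
    ``seed + v``.  When ``params.psf`` is None the per-view PSF list is
    empty impulse-free (no blur was applied).
    """
    views = [
        simulate_view(gt, angle, params, view_index=v)
        for v, angle in enumerate(params.angles)
    ]
    if params.psf is None:
        psfs = []
    else:
        psfs = [rotate_psf_to_view(params.psf, angle) for angle in params.angles]
    return views, psfs
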