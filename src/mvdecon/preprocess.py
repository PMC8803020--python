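"""Preparation of raw light-sheet stacks for multi-view fusion.

A raw acquisition is a stack of camera slices with lateral pixel size
``voxel_xy`` and a (coarser) axial step ``step_z``.  Before views from
different angles can share a coordinate frame, three steps are needed:

1. camera-offset correction by subtracting a pre-measured dark image,
2. cubic interpolation along the detection axis to isotropic voxel size,
3. zero-padding to a cube so that 90° rotations map the grid onto itself.

Arrays use the package-wide ``(x, y, z)`` index order; the camera plane is
``(x, y)`` and z is the detection/stepping axis.  All outputs are clipped to
be nonnegative, as required by the Poisson imaging model underlying
Richardson-Lucy deconvolution.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "RawStack",
    "IsotropicStack",
    "subtract_dark",
    "interpolate_isotropic",
    "zero_pad_cubic",
    "crop_by_offsets",
]


@dataclass
class RawStack:
    """Raw anisotropic acquisition.

    ``data`` is ``(nx, ny, nz)`` camera counts, ``voxel_xy`` the lateral pixel
    size (µm), ``step_z`` the axial step (µm); ``dark`` is an optional
    ``(nx, ny)`` camera-offset image.
    """

    data: np.ndarray
    voxel_xy: float
    step_z: float
    dark: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("RawStack.data must be 3D (x, y, z)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensities must be finite")
        if self.voxel_xy <= 0 or self.step_z <= 0:
            raise ValueError("voxel_xy and step_z must be positive")
        if self.dark is not None:
            self.dark = np.asarray(self.dark, dtype=np.float64)
            if self.dark.shape != self.data.shape[:2]:
                raise ValueError(
                    f"dark image shape {self.dark.shape} does not match "
                    f"slice shape {self.data.shape[:2]}"
                )


@dataclass
class IsotropicStack:
    """Isotropic-voxel volume in the common frame; rotation axis is y."""

    data: np.ndarray
    voxel: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("IsotropicStack.data must be 3D (x, y, z)")
        if self.voxel <= 0:
            raise ValueError("voxel must be positive")
        if self.data.min() < 0:
            raise ValueError("intensities must be nonnegative")


def subtract_dark(stack: RawStack) -> RawStack:
    """Subtract the dark (camera offset) image from every slice.

    Results are clipped at zero: downstream Richardson-Lucy steps assume
    nonnegative data, and sCMOS read noise routinely pushes low pixels below
    the offset.
    """
    if stack.dark is None:
        raise ValueError("no dark image present")
    corrected = np.clip(stack.data - stack.dark[:, :, None], 0.0, None)
    return replace(stack, data=corrected, dark=None)


def interpolate_isotropic(stack: RawStack) -> IsotropicStack:
    """Resample the axial (z) direction to the lateral pixel size.

    Cubic spline interpolation is applied along z only; lateral planes are
    untouched.  The output has ``round((nz - 1) * step_z / voxel_xy) + 1``
    axial samples, with the first sample at the original first-slice
    position, so constant and polynomial (≤ cubic) axial profiles are
    reproduced exactly.  Interpolation overshoots below zero are clipped.
    """
    if stack.step_z < stack.voxel_xy:
        raise ValueError("expected step_z >= voxel_xy (light-sheet stepping)")
    nz = stack.data.shape[2]
    if nz < 4:
        raise ValueError("need at least 4 slices for cubic interpolation")
    if stack.step_z == stack.voxel_xy:
        return IsotropicStack(data=stack.data.copy(), voxel=stack.voxel_xy)
    ratio = stack.step_z / stack.voxel_xy
    n_out = int(round((nz - 1) * ratio)) + 1
    # new sample positions in units of the input slice index; clip the
    # rounding remainder at the last slice to avoid extrapolation
    t = np.minimum(np.arange(n_out, dtype=np.float64) / ratio, nz - 1)
    spline = CubicSpline(np.arange(nz, dtype=np.float64), stack.data, axis=2)
    data = np.clip(spline(t), 0.0, None)
    return IsotropicStack(data=data, voxel=stack.voxel_xy)


def zero_pad_cubic(stack: IsotropicStack) -> tuple[IsotropicStack, tuple[int, int, int]]:
    """Zero-pad to equal extents on all axes, centering the original data.

    Returns the padded stack and the per-axis offsets of the original volume
    inside it, so results can be cropped back (see :func:`crop_by_offsets`).
    """
    shape = stack.data.shape
    n = max(shape)
    offsets = tuple((n - s) // 2 for s in shape)
    pad = [(off, n - s - off) for s, off in zip(shape, offsets)]
    data = np.pad(stack.data, pad, mode="constant")
    return IsotropicStack(data=data, voxel=stack.voxel), offsets  # type: ignore[return-value]


def crop_by_offsets(
    data: np.ndarray, offsets: tuple[int, int, int], shape: tuple[int, int, int]
) -> np.ndarray:
    """Inverse of :func:`zero_pad_cubic`: crop ``data`` back to ``shape``."""
    sl = tuple(slice(off, off + s) for off, s in zip(offsets, shape))
    return data[sl]
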