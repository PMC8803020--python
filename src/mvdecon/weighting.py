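"""Per-pixel view weights and apodization masks for multi-view fusion.

After registration the views share a coordinate frame, but a given pixel is
imaged through different optical paths in each view and therefore suffers
different amounts of scattering and absorption.  The fusion weights let
high-contrast views dominate:

* intensity weighting — a view's weight is its fractional contribution to
  the pixel intensity summed over all views;
* entropy weighting — the weight is the fractional contribution to the
  local-entropy sum, with H = ½ ln(2πeσ²) computed from the intensity
  variance σ² of a square patch around the pixel (default 11 × 11).

At pixels where the denominator vanishes (no view has content, or all
patches are flat) the weights fall back to the uniform 1/N — any convex
combination is acceptable where no view carries information.

Masks roll intensities and weights smoothly to zero at the content edges so
that the FFT-based convolutions inside Richardson-Lucy do not produce edge
ringing: :func:`binmask` for 2D slices, :func:`blend1d` for columns along
the rotation axis.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d, uniform_filter

__all__ = [
    "ENTROPY_VARIANCE_FLOOR",
    "local_entropy",
    "weights_intensity",
    "weights_entropy",
    "binmask",
    "blend1d",
]

# variance at which H = ½ ln(2πeσ²) crosses zero; σ² is clamped here so that
# entropies (and hence weights) are never negative
ENTROPY_VARIANCE_FLOOR = 1.0 / (2.0 * np.pi * np.e)


def _stack_views(views) -> np.ndarray:
    arrs = [np.asarray(v, dtype=np.float64) for v in views]
    if not arrs:
        raise ValueError("need at least one view")
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise ValueError("views must have identical shapes")
    return np.stack(arrs, axis=0)


def _fractional(contrib: np.ndarray) -> np.ndarray:
    """Normalize per-view contributions to sum 1; uniform where the sum is 0."""
    total = contrib.sum(axis=0)
    n = contrib.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        w = contrib / total
    w[:, total <= 0] = 1.0 / n
    return w


def local_entropy(image: np.ndarray, patch_size: int = 11) -> np.ndarray:
    """Local entropy H = ½ ln(2πeσ²) of a Gaussian with the patch variance.

    σ² is the population variance over a ``patch_size`` square neighborhood
    (mirror-padded at the borders) and is clamped below at
    ``ENTROPY_VARIANCE_FLOOR`` so H ≥ 0; flat patches map to H = 0.
    """
    if patch_size % 2 == 0 or patch_size < 3:
        raise ValueError("patch_size must be odd and >= 3")
    image = np.asarray(image, dtype=np.float64)
    mean = uniform_filter(image, size=patch_size, mode="mirror")
    mean_sq = uniform_filter(image * image, size=patch_size, mode="mirror")
    var = np.maximum(mean_sq - mean * mean, 0.0)
    var = np.maximum(var, ENTROPY_VARIANCE_FLOOR)
    return 0.5 * np.log(2.0 * np.pi * np.e * var)


def weights_intensity(views) -> np.ndarray:
    """Intensity fusion weights, shape ``(n_views, *view_shape)``.

    ``w_v(p) = i_v(p) / Σ_u i_u(p)``; pixels where all views are zero get
    uniform weights.
    """
    stack = _stack_views(views)
    if np.any(stack < 0):
        raise ValueError("views must be nonnegative")
    return _fractional(stack)


def weights_entropy(views, patch_size: int = 11) -> np.ndarray:
    """Local-entropy fusion weights, shape ``(n_views, *view_shape)``.

    ``w_v(p) = H_v(p) / Σ_u H_u(p)`` with the clamped patch entropy of
    :func:`local_entropy`; a flat view gets weight 0 wherever another view
    has texture.
    """
    stack = _stack_views(views)
    if np.any(stack < 0):
        raise ValueError("views must be nonnegative")
    entropies = np.stack([local_entropy(v, patch_size) for v in stack], axis=0)
    return _fractional(entropies)


def binmask(views, blur_sigma: float = 20.0) -> np.ndarray:
    """Smooth content mask for a set of registered 2D slices.

    Ones wherever at least one view contributes (is positive), zeros where
    all views are zero — e.g. in the corners introduced by zero-padding —
    then blurred with a Gaussian (default σ = 20 px) so intensities and
    weights roll off smoothly and FFT edge artifacts are suppressed.
    """
    stack = _stack_views(views)
    mask = (stack > 0).any(axis=0).astype(np.float64)
    if blur_sigma > 0:
        mask = gaussian_filter(mask, sigma=blur_sigma, mode="constant", cval=0.0)
    return np.clip(mask, 0.0, 1.0)


def blend1d(length: int, content_range: tuple[int, int], sigma: float = 5.0) -> np.ndarray:
    """1D apodization profile for deconvolution along the rotation axis.

    ``content_range = (start, stop)`` is the half-open index interval that
    carries data.  The profile is 1 inside it and decays to 0 at its ends
    through a Gaussian blur (default σ = 5 px).
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    start, stop = content_range
    if not (0 <= start < stop <= length):
        raise ValueError("content_range must be a nonempty interval within [0, length]")
    profile = np.zeros(length, dtype=np.float64)
    profile[start:stop] = 1.0
    if sigma > 0:
        profile = gaussian_filter1d(profile, sigma=sigma, mode="constant", cval=0.0)
    return np.clip(profile, 0.0, 1.0)
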