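"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from mvdecon import AcquisitionParams, GaussianPSFModel, make_gaussian_psf, make_lines_phantom, simulate_multiview


def convolve_direct(a: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Brute-force spatial-domain linear convolution (zero boundary, 'same').

    Independent oracle for the FFT path: explicit shift-and-add over every
    kernel tap, no Fourier transforms involved.
    """
    a = np.asarray(a, dtype=np.float64)
    kernel = np.asarray(kernel, dtype=np.float64)
    out = np.zeros_like(a)
    center = tuple(s // 2 for s in kernel.shape)
    for tap in np.ndindex(kernel.shape):
        # out[p] = sum_q k[q] * a[p - (q - c)]: content shifts by q - c
        shift = tuple(q - c for q, c in zip(tap, center))
        src = []
        dst = []
        for s, n in zip(shift, a.shape):
            if s >= 0:
                src.append(slice(0, n - s))
                dst.append(slice(s, n))
            else:
                src.append(slice(-s, n))
                dst.append(slice(0, n + s))
        out[tuple(dst)] += kernel[tap] * a[tuple(src)]
    return out


def rl_step_direct(est, view, f, b):
    """Richardson-Lucy step evaluated with the spatial-domain oracle."""
    blurred = convolve_direct(est, f)
    blurred = np.where(blurred <= 0, 1.0, blurred)
    ratio = np.clip(view, 0.0, None) / blurred
    return est * np.clip(convolve_direct(ratio, b), 0.0, None)


@pytest.fixture(scope="session")
def default_psf():
    """The package's default synthetic acquisition PSF (lateral 1.05 vox,
    axial 5.2 vox, mirroring measured light-sheet bead widths)."""
    return make_gaussian_psf(GaussianPSFModel(1.05, 1.05, 5.2, radius=16))


@pytest.fixture(scope="session")
def small_multiview(default_psf):
    """A 48³ four-view simulated dataset with noise and attenuation."""
    gt = make_lines_phantom(48, n_lines=20, seed=3)
    params = AcquisitionParams(
        psf=default_psf, photon_budget=1000.0, gaussian_variance=1.6e-5,
        attenuation_length=24.0, seed=3,
    )
    views, psfs = simulate_multiview(gt, params)
    return gt, views, psfs
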