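# mvdecon

Multi-view Richardson–Lucy deconvolution for light-sheet fluorescence
microscopy (LSFM), with a fast **2D+1D** approximation to full 3D
multi-view deconvolution.

## The problem

In LSFM the resolution along the detection axis is several times worse than
the lateral resolution, and deep sample regions lose contrast to scattering
and absorption. Multi-view acquisition — imaging the specimen from several
angles (here: four views 90° apart) about a fixed rotation axis — captures
complementary information, and multi-view deconvolution (MVD) fuses the
registered views into a single, near-isotropic volume. Full 3D MVD gives
the best quality but is too slow to keep up with the data stream of
long-term live imaging. This package implements, for users processing
registered multi-view volumes:

* **2D MVD** — Richardson–Lucy fusion applied plane by plane in the x–z
  planes perpendicular to the rotation axis (y), using the central x–z
  plane of the 3D PSF;
* **2D+1D MVD** — 2D MVD followed by a cheap 1D Richardson–Lucy
  deconvolution along the rotation axis with the PSF's central y column,
  which pushes intensity that the 3D PSF spread across neighbouring planes
  back to where it came from;
* **3D MVD** — the full-volume reference method;

plus an acquisition simulator (line/bead phantoms, depth attenuation,
anisotropic PSF blur, Poisson + Gaussian noise) and evaluation machinery
(MSE/PCC vs. ground truth per iteration, bead-based FWHM resolution
analysis).

## The algorithm

One Richardson–Lucy iteration for view *i* with forward projector *f* (the
view's PSF) and back projector *b* is

```
e_{k+1} = e_k · ( ( i / (e_k ∗ f) ) ∗ b )
```

Multi-view fusion starts from the average of all views and, in each
iteration, loops through the views applying the correction `c_v` with a
per-pixel weight: `e ← e·(1 − W_v + W_v·c_v)`. Weights come from each
view's fractional contribution to the local entropy
`H = ½·ln(2πeσ²)` of an 11 × 11 patch (or to the plain intensity),
so high-contrast views dominate; they are rescaled per pixel so the most
informative view applies the full correction. The back projector can be
the mirrored PSF (`matched`), the mirrored PSF convolved with the other
views' PSFs (`opt1`), or a single compound kernel from the product of all
optical transfer functions (`opt2`, fastest convergence; default for the
slice-wise schemes). Gaussian-blurred content masks (σ = 20 px in-plane,
σ = 5 px along y) apodize edges so the FFT-based convolutions do not ring.

## Worked example

```python
import numpy as np
from mvdecon import (AcquisitionParams, FusionConfig, GaussianPSFModel,
                     fuse, make_gaussian_psf, make_lines_phantom, mse, pcc,
                     simulate_multiview)

gt = make_lines_phantom(64, n_lines=30, seed=0)
psf = make_gaussian_psf(GaussianPSFModel(1.05, 1.05, 5.2, radius=16))
params = AcquisitionParams(psf=psf, attenuation_length=32.0, seed=0)
views, psfs = simulate_multiview(gt, params)

print(f"blurred single view : PCC = {pcc(views[0], gt.data):.3f}")
for method in ("2d", "2d1d", "3d"):
    est, _ = fuse(views, psfs, FusionConfig(method=method))
    print(f"{method:>5s} fusion : MSE = {mse(est, gt.data, fit_gain=True):.2e},"
          f"  PCC = {pcc(est, gt.data):.3f}")
```

prints

```
blurred single view : PCC = 0.414
   2d fusion : MSE = 7.58e-04,  PCC = 0.545
 2d1d fusion : MSE = 7.40e-04,  PCC = 0.559
   3d fusion : MSE = 5.00e-04,  PCC = 0.730
```

The phantom is a 64³ aster of lines blurred with an anisotropic PSF
(lateral σ 1.05 vox, axial σ 5.2 vox), attenuated with depth and degraded
with shot and read noise. The fused volumes are compared to the ground
truth after a least-squares intensity gain fit (deconvolution does not fix
the absolute scale). The 1D step improves on 2D-only fusion at almost no
cost, and the full 3D reference is best — the accuracy/cost trade-off the
2D+1D scheme is designed around.

The same pipeline is scriptable from the shell:

```bash
mvdecon simulate --extent 64 --seed 0 --outdir sim/
mvdecon fuse --method 2d1d \
    --views sim/view_000.tif --views sim/view_001.tif \
    --views sim/view_002.tif --views sim/view_003.tif \
    --psf sim/psf_000.tif --psf sim/psf_001.tif \
    --psf sim/psf_002.tif --psf sim/psf_003.tif \
    --out fused.tif
mvdecon metrics --volume fused.tif --ground-truth sim/ground_truth.tif --out quality.json
mvdecon beads --volume fused.tif --voxel 0.806 --out beads.json
```

Volumes are multi-page TIFFs (page axis = z, rows = y = rotation axis,
columns = x); every command writes a JSON run report.

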