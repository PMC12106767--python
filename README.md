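# hepavasc

Quantitative 3-D analysis of liver micro-vasculature and tissue texture in
X-ray phase-contrast CT volumes.

Liver metastases remodel the hepatic microcirculation twice over: the
sinusoid bed (the ~3 µm capillary network carrying blood from the portal
triads to each lobule's central vein) is depleted in the parenchyma distant
from a lesion, while a dense perivascular capillary band forms immediately
around it.  Propagation-based phase-contrast CT of paraffin-embedded liver
resolves the sinusoids without staining, and `hepavasc` turns such volumes
into numbers:

- **Vessel segmentation** — multi-scale Frangi vesselness (scales 1–10
  voxels, α = β = 0.5, C = 0.013, response threshold P > 0.16) for the
  sinusoids, grey-level thresholding for vein-calibre vessels, merged and
  partitioned at a 15 µm local-thickness cutoff.
- **Vascular volume fraction (VVF)** — vessel voxels over tissue voxels, on
  ROIs (default 5·10⁻³ mm³), as a 50-voxel sliding-cube map, and as a
  radial profile in distance shells around a nodule boundary (vessels above
  10 µm excluded).
- **Skeleton statistics** — branch graph in the ImageJ AnalyzeSkeleton
  convention; curved (spline) branch lengths; per-branch diameters from the
  distance transform; nearest-neighbour distances between branch arc-length
  midpoints.
- **Texture RMS** — per-slice RMS of mean-subtracted grey values in
  30-pixel windows, and healthy/metastatic classification by the
  mean ± 1.5 SD band rule.
- **CD31 histology** — 2-D vascular fraction of stained RGB sections by
  colour-range segmentation.
- **Synthetic liver phantom** — a calibrated forward model (tubular
  sinusoid bed, central vein, metastatic nodules with a perivascular
  density gradient, grey-level texture) with ground-truth masks, so every
  estimator is validated by parameter recovery.

See `docs/methods.md` for the models, calibration constants and numerical
choices.

## Worked example

Generate a control-liver phantom and recover its vascular statistics
through the full segmentation pipeline:

```python
import numpy as np
import hepavasc as hv

pre = hv.preset("control", shape=(160, 160, 160), seed=1)  # 112 µm box
phantom = pre.build()
print(f"truth VVF {100 * phantom.truth_vvf():.2f}%")

metrics = hv.analyze_sinusoids(phantom.volume, rng=np.random.default_rng(1))
print(f"VVF  {metrics.vvf_mean_pct:.2f}%   "
      f"NND  {metrics.nnd_weighted_mean_um:.1f} µm   "
      f"length mode {metrics.branch_length_mode_um:.1f} µm   "
      f"diameter mode {metrics.diameter_mode_um:.2f} µm   "
      f"({metrics.n_branches} branches)")
```

prints

```
truth VVF 1.60%
VVF  1.68%   NND  17.3 µm   length mode 4.5 µm   diameter mode 2.75 µm   (189 branches)
```

i.e. the segmented network recovers the generator's targets — a 1.65%
sinusoid volume fraction, 17.8 µm mean spacing between neighbouring
vessels, a branch-length histogram peaking near 5 µm and the 3 µm sinusoid
calibre — from the grey-value volume alone.  The metastatic preset
(`hv.preset("metastatic", ...)`) recovers the depleted condition
(VVF ≈ 0.45%, NND ≈ 32.5 µm, longer branches); the nodule preset adds an
ellipsoidal lesion whose sliding-cube VVF map peaks near 6% beside the
boundary and whose radial profile decays to the ~0.5% far field.

The same functions run on real data: `hepavasc.io.read_volume` reads TIFF
stacks (voxel size from a sidecar) or isotropic NIfTI, and
`hv.run_specimen(config)` executes the whole pipeline from a `RunConfig`
and writes masks, per-ROI tables and a manifest.

A thin CLI wraps the library:

```sh
hepavasc phantom --preset control --seed 42 --shape 160,160,160 --out phantom/
hepavasc quantify phantom/volume.tif --n-rois 5 --seed 7
hepavasc validate --preset metastatic --seeds 1,2,3 --shape 128,128,128
```

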