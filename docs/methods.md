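# Methods

`hepavasc` quantifies the hepatic sinusoid network and tissue texture in
reconstructed X-ray phase-contrast CT volumes of liver, and validates every
estimator by parameter recovery on a calibrated synthetic phantom.  This
note records the models, the committed parameter choices, and the
numerical decisions a maintainer would want to know.

## The measurement pipeline

**Vessel segmentation.**  Sinusoids (~3 µm capillaries) are segmented with
the multi-scale Frangi vesselness filter — Hessian eigenvalue ratios with
plate/blob sensitivities α = β = 0.5, structureness constant C = 0.013,
integer scales 1–10 voxels, dark-tube polarity — thresholded at response
P > 0.16 (strict).  Large vessels (central/portal veins) come from a
grey-level threshold (Otsu by default; the protocol leaves the value open)
followed by a ≥15 µm thickness filter, and the two masks are merged.

The vesselness is computed by `skimage.filters.frangi`, which does *not*
scale-normalise the Hessian (no σ² factor): responses of thin tubes
concentrate at the finest scales.  We verified that the canonical
γ-normalised formulation, combined with the protocol's fixed C = 0.013 and
P > 0.16, saturates the structureness term at every scale and inflates
masks roughly ten-fold regardless of the grey-level contrast, so the
skimage formulation is the one under which the fixed threshold is
meaningful.  Large vessels are in any case covered by the intensity
threshold.

Two cleanup steps make the voxel statistics faithful: connected components
of the vesselness mask smaller than 10 voxels are removed (any resolvable
vessel cross-section spans tens of voxels; smaller components are texture
noise), and thin segmentation halo attached to a large vessel's surface is
absorbed into the large class by a geodesic (within-mask) dilation of up to
5 µm, so it cannot masquerade as sinusoid volume.

**Small/large split.**  A voxel's local diameter is its local thickness:
the diameter of the largest medial-axis sphere covering it (computed by
sphere painting from skeleton voxels in descending distance-transform
radius).  A nearest-centreline lookup is *not* used because voxels on a
vein's surface are often nearer to the skeleton of an attached thin branch
than to the vein's own axis, which misclassifies large-vessel volume
wholesale.  The split is exact: small ∪ large = input, small ∩ large = ∅.
Two cutoffs are exposed separately: 15 µm for the small/large partition and
10 µm for exclusion from VVF accounting.

**Skeleton graph.**  Masks are thinned with `skimage.morphology.skeletonize`
(Lee's 3-D method) and decomposed by the ImageJ AnalyzeSkeleton
classification (slab voxels have two 26-neighbours, end voxels one,
junction voxels three or more; adjacent junction voxels form one junction).
Terminal twigs shorter than 3.5 µm hanging off a junction are pruned and
the graph re-extracted — thinning of noisy tube surfaces produces such
spurs, whose junctions split branches and would systematically depress the
nearest-neighbour statistics.  Isolated branches are never pruned.  Lee
thinning annihilates objects with an exactly even-symmetric two-voxel core
(a measure-zero case for real data); when the skeleton comes back empty the
mask is re-thinned after one dilation, intersected with the original.

**Branch lengths.**  Each branch's voxel path is subsampled every 4 voxels
(endpoints kept) and interpolated with a chord-length-parameterised cubic
spline; the length is the arc length of the fit.  Subsampling suppresses
the quantisation zigzag of digital curves: on a rasterised quarter circle
of radius 20 µm the estimator is within ~3% of πr/2, whereas a spline
through every voxel centre overshoots by ~25%.  Histograms use 1 µm bins
anchored at zero and are normalised to the number of branches.

**Nearest-neighbour distances.**  Each branch is represented by the path
voxel at half its arc length — the centre of mass taken along the curve,
which always lies inside the vessel.  NND(i) is the minimum Euclidean
distance to any other representative point, and the weighted average is the
mean over branches (the weights of the normalised branch-frequency
distribution).

**VVF.**  Vessel voxels divided by tissue voxels (region voxels not flagged
as any vessel), with vessels above the 10 µm exclusion first removed from
the numerator (they still do not count as tissue).  Regions are random
cubic ROIs of 5·10⁻³ mm³ by default (clamped to the volume when it is
smaller, as at desk scale), a 50-voxel sliding cube for maps, or Euclidean
distance shells around a nodule boundary for radial profiles.  Shell
ellipsoids are fit by second moments of the shell's outer-surface voxels;
the reported axis is the major semi-axis (√(3 λ_max) of the coordinate
covariance).

**Texture RMS and classification.**  Per slice, the RMS of mean-subtracted
grey values in a 30-pixel square window over non-excluded pixels
(population normalisation, since the mean is estimated from the same
window).  The default sampling is non-overlapping tiles — identical in
expectation to a dense sliding window and ~900× cheaper; `stride=1` gives
the dense map.  Windows with under 10% valid pixels are undefined.
Classification assigns a window to healthy or metastatic when its RMS falls
within that class's mean ± 1.5 SD; in an overlap the nearer mean in SD
units wins, an exact tie stays unclassified.  Class fractions are reported
over classified windows only.

**CD31 (2-D histology).**  Stained-pixel percentage per ROI by inclusive
HSV colour-range segmentation (defaults bracket DAB brown); no stain
deconvolution, matching the colour-range protocol.

## The synthetic phantom

The phantom emulates a *reconstructed* volume, not the X-ray physics: a
dense bed of dark sinusoids radiating around a 40 µm central vein in a
brighter parenchyma, with band-limited Gaussian texture, rendered at
0.7 µm isotropic voxels (high-resolution geometry) or 3.1 µm
(low-resolution geometry for the texture stages).

Sinusoids are disjoint, gently curved tubes (diameter 3.0 ± 0.25 µm)
placed by rejection sampling: tube midpoints keep a minimum spacing — the
knob that sets the measured NND — and full centrelines keep ~5.6 µm
clearance so segmented tubes stay separate components.  A connected
branching topology was deliberately not used: junction handling would
couple the branch-length, NND and diameter statistics in uncontrollable
ways, and only the summary statistics are specified.  Tube lengths follow
a two-component mixture (a narrow normal component that sets the histogram
mode plus a uniform tail that sets the mean).  Tubes are added until the
voxel-counted sinusoid volume matches the target VVF to ~2% relative (one
tube of granularity); an unreachable combination of density and spacing
raises an explicit error naming the two parameters.

Grey levels: parenchyma 0.55, vessels 0.10, nodule rim 0.68 on a [0, 1]
scale, with a 0.7-voxel linear edge ramp and a 0.6-voxel Gaussian blur
standing in for the imaging point-spread.  The texture is white noise
smoothed to a ~2-voxel correlation length and renormalised so the per-voxel
SD equals `texture_rms` exactly.  The vessel contrast (0.45) is a committed
design constant chosen on single-tube fixtures so that the protocol-fixed
Frangi threshold reproduces tube cross-sections near truth size; with a
noise-free background the response develops a wide supra-threshold halo at
large scales, so the phantom always carries texture (any amplitude
≥ 0.001 suppresses the halo — a property of the response's structureness
term, documented here because it surprised us).

**Presets** (committed calibration constants):

| preset     | VVF    | length mode | NND target | spacing | texture RMS (lo-res / hi-res) |
|------------|--------|-------------|------------|---------|-------------------------------|
| control    | 1.65%  | 5 µm        | 17.8 µm    | 17.0 µm | 0.004 / 0.004                 |
| metastatic | 0.45%  | 12 µm       | 32.5 µm    | 33.0 µm | 0.010 / 0.005                 |
| chemo      | mixed  | 5 µm        | —          | 17.0 µm | 0.004 upper / 0.010 lower     |
| nodule     | radial | 5 µm        | —          | 6.5 µm  | 0.008                         |

The midpoint spacings were tuned by bisection against the *measured*
weighted-mean NND on segmented phantoms and committed.  The short
length-component centre carries a +0.7 µm offset compensating the ~1 voxel
of end retraction that thinning applies to free tube ends, so the measured
modal bin recovers the nominal mode; this mirrors the NND calibration rule.
The class RMS amplitudes are a low-resolution-scan property; high-resolution
geometry uses 0.004/0.005 — the regime in which the fixed vesselness
threshold separates vessels from parenchyma, as it did on the real
high-resolution scans (at 0.010 the threshold segments noise ridges).

The metastatic preset models the *distal* vessel-depleted parenchyma and
carries no nodule; the nodule preset places one ellipsoidal nodule
(vessel-free interior, bright 12 µm desmoplastic-style rim) whose
perivascular capillary density is 6% local VVF at the rim, decaying
linearly to a 0.5% far field; the decay length scales with the volume so
the far field is reached inside the box.  The chemo preset splits the
texture field spatially (upper half healthy-like, lower half
metastatic-like) to emulate a partially responding specimen.

**What the phantom does not emulate:** reconstruction artefacts (rings,
phase-retrieval halos), lobule-scale grey-level gradients, anatomically
realistic branching or tortuosity, portal triads, and anisotropic noise.
Passing recovery tests therefore demonstrates estimator correctness on
geometry with the published summary statistics, not robustness to artefacts
of real reconstructions.

## Problem sizes and determinism

Calibration and validation run at desk scale: 176³ voxels (0.7 µm) for the
homogeneous phantoms in the reproduction script and 192³ for the nodule
phantom, 160–192³ in the test suite, and 16×128² at 3.1 µm for the texture
stages.  Statistics are intensive (densities, spacings, modes), so they are
size-stable apart from a mild edge effect on NND; at 160³–192³ the control
phantom holds 190–360 branches and the metastatic 30–100, which keeps the
seed-to-seed spread of every recovered statistic well inside its acceptance
band.  At sizes below ~150³ the control preset's tube density approaches
the packing limit imposed by the midpoint spacing and the truth VVF can
fall a few hundredths of a point short of 1.65%.

All randomness flows from explicit integer seeds: the tree generator and
the texture field use independent substreams derived from `PhantomSpec.seed`,
ROI sampling from the run seed, and a fixed (spec, seed) pair reproduces a
phantom bit-exactly.

## Known limitations

- The Frangi response is thresholded directly as "probability"; any
  calibration the original protocol may have applied beyond the raw
  response is unknowable from the text and not modelled.
- The intensity threshold for large vessels is not specified by the
  protocol; Otsu is the default and a config override exists.
- Segmented VVF recovery carries a small positive bias (~+0.05 to +0.1
  percentage points on the control preset) from soft tube edges; it is well
  inside the acceptance band and documented rather than tuned away.
- The significance test behind group comparisons is not part of this
  package's scope; the pipeline reports descriptive statistics.
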