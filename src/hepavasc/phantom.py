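"""Synthetic liver phantom: tubular sinusoid bed, central vein, metastatic
nodules and grey-level texture, with ground-truth masks.

The phantom is a forward model of a *reconstructed* phase-contrast CT volume
of murine liver: a dense bed of ~3 µm sinusoids radiating around a central
vein, imaged dark on a brighter parenchyma, with band-limited grey-level
texture whose per-window RMS amplitude separates healthy from metastatic
tissue.  It makes no attempt to simulate X-ray physics; only the statistics
the downstream estimators measure (vascular volume fraction, branch lengths,
nearest-neighbour distances, diameters, texture RMS) are controlled.

Every preset is calibrated so that voxel-counting the truth masks recovers
the preset targets; estimator validation is then parameter recovery against
those targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .volume import NoduleMask, VesselMask, Volume3D, check_aligned

__all__ = [
    "PhantomSpec",
    "NoduleSpec",
    "Tube",
    "Phantom",
    "PhantomError",
    "generate_vessel_tree",
    "rasterize_and_texture",
    "build_phantom",
    "preset",
    "PRESET_NAMES",
]

# Rasterisation / optics constants (committed; see docs/methods.md).
EDGE_SOFTNESS_VOX = 0.7   # linear edge ramp width of a tube wall, in voxels
PSF_SIGMA_VOX = 0.6       # Gaussian blur emulating the imaging point-spread
NOISE_CORR_SIGMA_VOX = 1.0  # texture-field band limit (corr. length ~2 vox)
CENTERLINE_CLEARANCE_PAD_UM = 2.6  # added to the mean diameter for tube/tube clearance


class PhantomError(RuntimeError):
    """Raised when a phantom specification cannot be realised."""


@dataclass(frozen=True)
class NoduleSpec:
    """An ellipsoidal metastatic nodule with a perivascular density profile.

    The azimuthal-average capillary density decays linearly from
    ``boundary_vvf`` at the nodule boundary to ``farfield_vvf`` at
    ``decay_length``; one dense dome-shaped hotspot next to the boundary
    carries ``hotspot_vvf`` locally, so that a sliding-cube VVF map peaks
    near ``rim_peak_vvf`` there while the shell-averaged radial profile
    stays close to the boundary value.  ``rim_thickness``/``rim_grey``
    render the bright desmoplastic-style shell in the grey volume.
    """

    center: tuple[float, float, float]          # voxel coordinates (z, y, x)
    semi_axes: tuple[float, float, float]       # µm
    rim_thickness: float = 12.0                 # µm, bright desmoplastic-style shell
    rim_grey: float = 0.68
    rim_peak_vvf: float = 0.06                  # peak local VVF next to the nodule
    farfield_vvf: float = 0.005
    decay: str = "linear"
    decay_length: float = 80.0                  # µm, where the far field is reached
    boundary_vvf: float = 0.018                 # azimuthal-average VVF at the boundary
    # one dense perivascular patch; a sliding-cube map peaks there while the
    # shell-averaged radial profile stays near boundary_vvf
    hotspot_vvf: float = 0.085
    hotspot_extent: float = 20.0                # µm beyond the boundary
    hotspot_half_angle: float = 50.0            # degrees around hotspot_direction
    hotspot_direction: tuple[float, float, float] = (0.0, 1.0, 0.0)

    def __post_init__(self) -> None:
        if not all(a > 0 for a in self.semi_axes):
            raise ValueError("nodule semi-axes must all be > 0 µm")
        if self.rim_peak_vvf < self.farfield_vvf:
            raise ValueError("rim_peak_vvf must be >= farfield_vvf")
        if self.decay != "linear":
            raise ValueError(f"unsupported decay profile {self.decay!r}")


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one phantom volume.

    The headline fields (``target_vvf``, ``sinusoid_diameter_mean``,
    ``branch_length_mode``, ``min_centerline_spacing``, ``texture_rms``) are
    the quantities the downstream estimators recover.  The trailing block of
    fields are committed calibration constants of the generator: they shape
    the branch-length mixture and compensate documented estimator offsets
    (3-D thinning retracts free tube ends by roughly two voxels), so that the
    *measured* statistics match the headline targets.
    """

    volume_shape: tuple[int, int, int] = (256, 256, 256)  # voxels (z, y, x)
    voxel_size: float = 0.7                               # µm
    target_vvf: float = 0.0165          # sinusoid voxels / tissue voxels
    sinusoid_diameter_mean: float = 3.0  # µm
    sinusoid_diameter_sd: float = 0.25   # µm
    branch_length_mode: float = 5.0      # µm, target modal bin of measured lengths
    min_centerline_spacing: float = 15.0  # µm, min distance between tube midpoints
    central_vein_diameter: float = 40.0  # µm; 0 disables the vein
    texture_rms: float = 0.004          # grey-level fluctuation amplitude
    background_grey: float = 0.55
    vessel_grey: float = 0.10
    seed: int = 0
    # --- committed generator calibration constants -----------------------
    mean_branch_length: float = 22.0    # µm, mean of the full length mixture
    short_fraction: float = 0.45        # weight of the short (modal) component
    short_length_bias: float = 0.7      # µm, thinning end-retraction compensation
    short_length_sd: float = 0.9        # µm
    texture_rms_lower: float | None = None  # split-field RMS for the lower half (chemo)
    centerline_clearance: float | None = None  # µm; default diameter + 2.6

    def __post_init__(self) -> None:
        if not (0 <= self.target_vvf < 0.5):
            raise ValueError(f"target_vvf must lie in [0, 0.5), got {self.target_vvf}")
        if self.target_vvf > 0 and not self.sinusoid_diameter_mean > 0:
            raise ValueError("sinusoid_diameter_mean must be > 0 µm")
        if self.target_vvf > 0 and self.min_centerline_spacing < self.sinusoid_diameter_mean:
            raise ValueError(
                "min_centerline_spacing must be >= sinusoid_diameter_mean "
                f"({self.min_centerline_spacing} < {self.sinusoid_diameter_mean} µm)"
            )
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be > 0 µm")

    @property
    def extent_um(self) -> np.ndarray:
        return np.asarray(self.volume_shape, dtype=float) * self.voxel_size


@dataclass
class Tube:
    """A single vessel centreline: an ordered polyline in µm with a radius."""

    points: np.ndarray  # (n, 3) float, µm, (z, y, x)
    radius: float       # µm
    kind: str = "sinusoid"  # or "vein"

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    @property
    def midpoint(self) -> np.ndarray:
        """Point at half arc length along the polyline."""
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        half = s[-1] / 2.0
        i = int(np.searchsorted(s, half))
        if i == 0:
            return self.points[0].copy()
        t = (half - s[i - 1]) / max(s[i] - s[i - 1], 1e-12)
        return (1 - t) * self.points[i - 1] + t * self.points[i]


@dataclass
class Phantom:
    """A generated phantom volume with its ground truth."""

    volume: Volume3D
    vessel_mask_truth: VesselMask        # all vessels (sinusoids + vein)
    nodule_mask_truth: NoduleMask
    spec: PhantomSpec
    nodules: list[NoduleSpec] = field(default_factory=list)
    sinusoid_mask_truth: VesselMask | None = None
    vein_mask_truth: VesselMask | None = None
    curves: list[Tube] = field(default_factory=list)

    def __post_init__(self) -> None:
        check_aligned(self.volume, self.vessel_mask_truth, self.nodule_mask_truth)
        if np.any(self.vessel_mask_truth.data & self.nodule_mask_truth.data):
            raise ValueError("vessel and nodule truth masks must be disjoint")

    def vessel_exclusion_mask(self, pad_um: float | None = None) -> np.ndarray:
        """Voxels within the vessels' *visible* footprint.

        At coarse voxel sizes the geometric truth mask is dotted (the tube
        radius is sub-voxel) while the rendered grey dip extends over the
        soft edge and the point-spread blur; texture analysis must exclude
        that whole footprint, as a segmentation-derived exclusion would.
        ``pad_um`` defaults to the edge ramp plus three blur sigmas.
        """
        vs = self.volume.voxel_size
        if pad_um is None:
            pad_um = (EDGE_SOFTNESS_VOX / 2 + 3 * PSF_SIGMA_VOX) * vs
        out = np.zeros(self.volume.shape, dtype=bool)
        for tube in self.curves:
            sl, d = _tube_local_distance(tube, vs, self.volume.shape,
                                         pad_um=pad_um)
            out[sl] |= d <= pad_um
        return out

    def truth_vvf(self) -> float:
        """Voxel-counted sinusoid VVF: small-vessel voxels / tissue voxels."""
        sin = self.sinusoid_mask_truth.data if self.sinusoid_mask_truth is not None \
            else self.vessel_mask_truth.data
        tissue = ~self.vessel_mask_truth.data
        return float(sin.sum()) / float(tissue.sum())


# ---------------------------------------------------------------------------
# geometry helpers


def _ellipsoid_radial_distance(pts_um: np.ndarray, nod: NoduleSpec, voxel_size: float) -> np.ndarray:
    """Approximate signed distance (µm) from points to a nodule boundary.

    Uses the radial scaling of the ellipsoid equation; exact for spheres and
    accurate to a few percent for the mildly eccentric nodules used here.
    """
    c = np.asarray(nod.center, dtype=float) * voxel_size
    a = np.asarray(nod.semi_axes, dtype=float)
    d = pts_um - c
    f = np.sqrt(np.sum((d / a) ** 2, axis=-1))
    n = np.linalg.norm(d, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r_dir = np.where(f > 0, n / np.maximum(f, 1e-12), a.min())
    return (f - 1.0) * r_dir


def _perivascular_density(d_um: np.ndarray, nod: NoduleSpec) -> np.ndarray:
    """Azimuthal-average target VVF at distance ``d_um`` from the boundary.

    Linear decay from ``boundary_vvf`` at the boundary to ``farfield_vvf``
    at ``decay_length`` (the hotspot patch is budgeted separately).
    """
    d = np.asarray(d_um, dtype=float)
    frac = np.clip(d / max(nod.decay_length, 1e-6), 0.0, 1.0)
    rho = nod.boundary_vvf + (nod.farfield_vvf - nod.boundary_vvf) * frac
    return np.where(d < 0, 0.0, rho)


def _in_hotspot(pts_um: np.ndarray, nod: NoduleSpec, voxel_size: float,
                d_um: np.ndarray | None = None) -> np.ndarray:
    """Points inside the dense perivascular dome of a nodule."""
    if nod.hotspot_vvf <= 0 or nod.hotspot_extent <= 0:
        return np.zeros(np.shape(pts_um)[:-1], dtype=bool)
    if d_um is None:
        d_um = _ellipsoid_radial_distance(pts_um, nod, voxel_size)
    c = np.asarray(nod.center, dtype=float) * voxel_size
    u = np.asarray(nod.hotspot_direction, dtype=float)
    u = u / np.linalg.norm(u)
    rel = pts_um - c
    n = np.linalg.norm(rel, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.where(n > 0, (rel @ u) / np.maximum(n, 1e-12), 1.0)
    return ((d_um > 0) & (d_um <= nod.hotspot_extent)
            & (cosang >= np.cos(np.deg2rad(nod.hotspot_half_angle))))


def _polyline(rng: np.random.Generator, mid: np.ndarray, direction: np.ndarray,
              length: float, seg_len: float = 3.0) -> np.ndarray:
    """Gently curved polyline of given arc length, centred on ``mid``."""
    n_seg = max(2, int(np.ceil(length / seg_len)))
    step = length / n_seg
    u = direction / np.linalg.norm(direction)
    # random bend about a fixed perpendicular axis, spread across segments
    total_bend = rng.normal(0.0, 0.55)
    perp = np.cross(u, rng.normal(size=3))
    nperp = np.linalg.norm(perp)
    if nperp < 1e-9:
        perp = np.array([u[1], -u[0], 0.0]); nperp = np.linalg.norm(perp) + 1e-12
    k = perp / nperp
    dtheta = total_bend / n_seg
    pts = [np.zeros(3)]
    d = u.copy()
    ct, st = np.cos(dtheta), np.sin(dtheta)
    for _ in range(n_seg):
        # Rodrigues rotation of d about k by dtheta
        d = d * ct + np.cross(k, d) * st + k * np.dot(k, d) * (1 - ct)
        pts.append(pts[-1] + d * step)
    pts = np.asarray(pts)
    # re-centre on the arc midpoint
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    half = s[-1] / 2
    i = int(np.searchsorted(s, half))
    t = (half - s[i - 1]) / max(s[i] - s[i - 1], 1e-12)
    arc_mid = (1 - t) * pts[i - 1] + t * pts[i]
    return pts + (mid - arc_mid)


def _resample(pts: np.ndarray, spacing: float = 1.2) -> np.ndarray:
    """Resample a polyline at roughly uniform spacing (µm)."""
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] < spacing:
        return pts[[0, -1]]
    t = np.arange(0.0, s[-1] + spacing / 2, spacing)
    out = np.empty((len(t), 3))
    for ax in range(3):
        out[:, ax] = np.interp(t, s, pts[:, ax])
    return out


def _tube_local_distance(tube: Tube, voxel_size: float,
                         shape: tuple[int, int, int], pad_um: float,
                         ) -> tuple[tuple[slice, ...], np.ndarray]:
    """Signed distance (µm) to the tube surface on the tube's bounding box.

    Returns the slice tuple into the parent volume and the local distance
    array (``d - radius``; negative inside the tube).
    """
    shp = np.asarray(shape)
    pts = tube.points / voxel_size  # continuous voxel coords
    r_vox = (tube.radius + pad_um) / voxel_size
    lo = np.maximum(np.floor(pts.min(axis=0) - r_vox - 1).astype(int), 0)
    hi = np.minimum(np.ceil(pts.max(axis=0) + r_vox + 1).astype(int) + 1, shp)
    lo = np.minimum(lo, hi - 1)
    sl = tuple(slice(int(l), int(h)) for l, h in zip(lo, hi))
    dmin = np.full(tuple(int(h - l) for l, h in zip(lo, hi)), np.inf, dtype=np.float32)
    # per-segment sub-boxes: cheap even for long, thin, oblique tubes
    for a, b in zip(pts[:-1], pts[1:]):
        slo = np.maximum(np.floor(np.minimum(a, b) - r_vox - 1).astype(int), lo)
        shi = np.minimum(np.ceil(np.maximum(a, b) + r_vox + 1).astype(int) + 1, hi)
        if np.any(slo >= shi):
            continue
        zz, yy, xx = np.meshgrid(*(np.arange(l, h) for l, h in zip(slo, shi)),
                                 indexing="ij", sparse=True)
        p = np.stack(np.broadcast_arrays(zz, yy, xx), axis=-1).astype(np.float64) + 0.5
        v = b - a
        L2 = float(v @ v)
        t = np.clip(((p - a) @ v) / max(L2, 1e-12), 0.0, 1.0)
        proj = a + t[..., None] * v
        d = np.linalg.norm(p - proj, axis=-1).astype(np.float32)
        ssl = tuple(slice(int(l - ll), int(h - ll)) for l, h, ll in zip(slo, shi, lo))
        np.minimum(dmin[ssl], d, out=dmin[ssl])
    return sl, dmin * np.float32(voxel_size) - np.float32(tube.radius)


# ---------------------------------------------------------------------------
# tree generation


def _nodule_distance_field(spec: PhantomSpec, nodules: list[NoduleSpec],
                           coarse: int = 2) -> tuple[np.ndarray, float]:
    """Coarse Euclidean distance (µm) from the union of nodule boundaries."""
    shape = tuple(max(1, s // coarse) for s in spec.volume_shape)
    vs = spec.voxel_size * coarse
    zz, yy, xx = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij", sparse=True)
    pts = np.stack(np.broadcast_arrays(zz, yy, xx), axis=-1).astype(float)
    pts_um = (pts + 0.5) * vs
    d = np.full(shape, np.inf)
    for nod in nodules:
        d = np.minimum(d, _ellipsoid_radial_distance(pts_um, nod, spec.voxel_size))
    return d, vs


def generate_vessel_tree(spec: PhantomSpec, nodules: list[NoduleSpec] | None = None,
                         rng: np.random.Generator | None = None) -> list[Tube]:
    """Place the central vein and a bed of disjoint sinusoid centrelines.

    Sinusoids are gently curved tubes, radially biased around the central
    vein, placed by rejection sampling: tube midpoints keep
    ``spec.min_centerline_spacing`` apart (this is what sets the measured
    nearest-neighbour distance) and full centrelines keep a fixed clearance
    so segmented tubes remain separate connected components.  Tubes are added
    until the voxelised truth volume matches ``target_vvf`` to ~2% relative.

    Raises
    ------
    PhantomError
        If the volume target cannot be met under the spacing constraint.
    """
    nodules = list(nodules or [])
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    ext = spec.extent_um
    vs = spec.voxel_size
    tubes: list[Tube] = []

    vein_r = spec.central_vein_diameter / 2.0
    vein_axis_xy = None
    if spec.central_vein_diameter > 0:
        jitter = rng.uniform(-0.05, 0.05, size=2) * ext[1:]
        cyx = ext[1:] / 2 + jitter
        vein_axis_xy = cyx
        pts = np.array([[0.0, cyx[0], cyx[1]], [ext[0], cyx[0], cyx[1]]])
        tubes.append(Tube(points=pts, radius=vein_r, kind="vein"))

    if spec.target_vvf <= 0:
        return tubes

    # volume bookkeeping (voxel-accurate truth counting)
    truth = np.zeros(spec.volume_shape, dtype=bool)
    vein_vox = 0
    if vein_axis_xy is not None:
        sl0, d0 = _tube_local_distance(tubes[0], vs, spec.volume_shape, pad_um=0.0)
        vein_vox = int((d0 <= 0).sum())
    total_vox = int(np.prod(spec.volume_shape))
    # sinusoid voxels s solving s = vvf * (total - vein - s)
    target_vox = spec.target_vvf * (total_vox - vein_vox) / (1.0 + spec.target_vvf)

    # length mixture (see class docstring)
    mode = spec.branch_length_mode + spec.short_length_bias
    w = spec.short_fraction
    tail_lo = max(12.0, 2.2 * spec.branch_length_mode)
    tail_mean = (spec.mean_branch_length - w * mode) / max(1.0 - w, 1e-9)
    tail_hi = 2.0 * tail_mean - tail_lo
    tail_hi = min(tail_hi, 0.62 * float(ext.min()))
    tail_hi = max(tail_hi, tail_lo + 4.0)

    clearance = (spec.centerline_clearance if spec.centerline_clearance is not None
                 else spec.sinusoid_diameter_mean + CENTERLINE_CLEARANCE_PAD_UM)

    # distance bands for perivascular density around nodules; when nodules
    # are present the radial profile + hotspot, not target_vvf, set the
    # total budget.  The last budget slot is the hotspot dome.
    if nodules:
        dfield, dvs = _nodule_distance_field(spec, nodules)
        shape_c = dfield.shape
        zz, yy, xx = np.meshgrid(*(np.arange(s) for s in shape_c),
                                 indexing="ij", sparse=True)
        pts_c = (np.stack(np.broadcast_arrays(zz, yy, xx), axis=-1) + 0.5) * dvs
        dome = np.zeros(shape_c, dtype=bool)
        for nod in nodules:
            dome |= _in_hotspot(pts_c, nod, vs)
        band_w = 10.0
        n_band = int(np.ceil(dfield.max() / band_w)) + 1
        band_idx = np.clip(np.floor(dfield / band_w), -1, n_band - 1).astype(int)
        band_vol = np.array([
            float(((band_idx == k) & ~dome).sum()) * dvs ** 3 for k in range(n_band)
        ])
        band_rho = np.array([
            max(float(_perivascular_density((k + 0.5) * band_w, nodules[0])), 0.0)
            for k in range(n_band)
        ])
        dome_rho = nodules[0].hotspot_vvf
        dome_vol = float(dome.sum()) * dvs ** 3
        band_budget = np.concatenate([
            band_rho * band_vol / (1.0 + band_rho),
            [dome_rho * dome_vol / (1.0 + dome_rho)],
        ])  # µm³ of vessel per region
        target_vox = band_budget.sum() / vs ** 3
        # region id of every coarse cell (dome wins over its band)
        region_idx = np.where(dome, len(band_budget) - 1, band_idx)
        coarse_f = int(round(dvs / vs))
    else:
        band_budget = None

    mid_tree_pts: list[np.ndarray] = []
    line_pts: list[np.ndarray] = []
    mid_tree = None
    line_tree = None

    def _sample_tube(position_trials: int = 20) -> Tube | None:
        """One rejection-sampling attempt; None if rejected.

        The length is drawn once and the placement geometry retried, so the
        accepted-tube length distribution is not biased towards short tubes
        (long tubes fail margin/clearance checks far more often).
        """
        if rng.random() < w:
            length = float(np.clip(rng.normal(mode, spec.short_length_sd), 2.5, None))
        else:
            length = float(rng.uniform(tail_lo, tail_hi))
        radius = float(np.clip(
            rng.normal(spec.sinusoid_diameter_mean, spec.sinusoid_diameter_sd),
            1.8, spec.sinusoid_diameter_mean + 3 * spec.sinusoid_diameter_sd,
        )) / 2.0
        margin = radius + 1.5 * vs
        for _ in range(position_trials):
            mid = rng.uniform(margin, ext - margin)
            if mid_tree is not None and \
                    mid_tree.query(mid, k=1)[0] < spec.min_centerline_spacing:
                continue
            # radial orientation bias around the vein; near a nodule the
            # tubes run tangentially (wrapping the boundary keeps the local
            # density where it was budgeted)
            iso = rng.normal(size=3)
            iso /= np.linalg.norm(iso)
            direction = iso
            near_nodule = False
            for nod in nodules:
                dmid = float(_ellipsoid_radial_distance(mid[None, :], nod, vs)[0])
                if 0 <= dmid <= nod.hotspot_extent + 10.0:
                    nhat = mid - np.asarray(nod.center, float) * vs
                    nn = np.linalg.norm(nhat)
                    if nn > 1e-9:
                        nhat /= nn
                        tang = iso - 0.85 * np.dot(iso, nhat) * nhat
                        direction = tang / np.linalg.norm(tang)
                        near_nodule = True
                    break
            if not near_nodule and vein_axis_xy is not None:
                radial = np.array([0.0, mid[1] - vein_axis_xy[0],
                                   mid[2] - vein_axis_xy[1]])
                nr = np.linalg.norm(radial)
                radial = radial / nr if nr > 1e-9 else iso
                direction = 0.6 * radial + 1.0 * iso
            pts = _polyline(rng, mid, direction, length)
            if np.any(pts < margin) or np.any(pts > ext - margin):
                continue
            dense = _resample(pts)
            if vein_axis_xy is not None:
                dxy = dense[:, 1:] - vein_axis_xy
                if np.min(np.linalg.norm(dxy, axis=1)) < vein_r + radius + 1.2:
                    continue
            if any(np.min(_ellipsoid_radial_distance(dense, nod, vs)) < radius + 0.5
                   for nod in nodules):
                continue
            if line_tree is not None and \
                    line_tree.query(dense, k=1)[0].min() < clearance:
                continue
            return Tube(points=pts, radius=radius)
        return None

    def _band_of(mid: np.ndarray) -> int:
        if band_budget is None:
            return 0
        for nod in nodules:
            if bool(_in_hotspot(mid[None, :], nod, vs)[0]):
                return len(band_budget) - 1  # the dome slot
        d = min(float(_ellipsoid_radial_distance(mid[None, :], nod, vs)[0])
                for nod in nodules)
        return int(np.clip(np.floor(d / 10.0), 0, len(band_budget) - 2))

    banded = band_budget is not None
    budget = band_budget if banded else np.array([target_vox * vs ** 3])
    placed_vol = np.zeros_like(budget)
    mean_tube_vol = np.pi * (spec.sinusoid_diameter_mean / 2) ** 2 * spec.mean_branch_length
    attempts = 0
    max_attempts = int(4000 + 300 * budget.sum() / max(mean_tube_vol, 1e-9))
    sin_vox = 0

    while attempts < max_attempts:
        if banded:
            # per-region stop: every band within half a tube of its budget
            if np.all(placed_vol >= budget - 0.5 * mean_tube_vol):
                break
        elif sin_vox >= target_vox - 0.5 * mean_tube_vol / vs ** 3:
            break
        attempts += 1
        tube = _sample_tube()
        if tube is None:
            continue
        b = _band_of(tube.midpoint)
        if banded and placed_vol[b] >= budget[b]:
            continue
        # voxelise into the truth grid
        sl, dloc = _tube_local_distance(tube, vs, spec.volume_shape, pad_um=0.0)
        inside = dloc <= 0
        new = inside & ~truth[sl]
        sin_vox += int(new.sum())
        truth[sl] |= inside
        if banded:
            # voxel-accurate per-region accounting (tubes spill over bands)
            zyx = np.argwhere(new)
            zyx += np.array([s.start for s in sl])
            cells = np.minimum(zyx // coarse_f,
                               np.asarray(region_idx.shape) - 1)
            regs = region_idx[tuple(cells.T)]
            np.add.at(placed_vol, regs[regs >= 0], vs ** 3)
        else:
            placed_vol[b] += np.pi * tube.radius ** 2 * tube.length
        tubes.append(tube)
        mid_tree_pts.append(tube.midpoint)
        line_pts.append(_resample(tube.points))
        mid_tree = cKDTree(np.asarray(mid_tree_pts))
        line_tree = cKDTree(np.concatenate(line_pts))

    shortfall = target_vox - sin_vox
    achieved = sin_vox / max(target_vox, 1e-9)
    # one tube of slack: tiny targets are quantised at whole-tube granularity
    if achieved < 0.90 and shortfall > mean_tube_vol / vs ** 3:
        raise PhantomError(
            f"unreachable target_vvf={spec.target_vvf} under "
            f"min_centerline_spacing={spec.min_centerline_spacing} µm: placed only "
            f"{achieved:.0%} of the requested vessel volume"
        )
    return tubes


# ---------------------------------------------------------------------------
# rasterisation + texture


def rasterize_and_texture(curves: list[Tube], spec: PhantomSpec,
                          nodules: list[NoduleSpec] | None = None) -> Phantom:
    """Render centreline curves into a grey-value volume with truth masks.

    Vessels are darker than parenchyma (they are revealed by minimum-intensity
    projections in the real data), nodule rims brighter.  The parenchyma
    carries a band-limited zero-mean Gaussian texture with per-voxel standard
    deviation ``spec.texture_rms`` (correlation length about two voxels).
    """
    nodules = list(nodules or [])
    vs = spec.voxel_size
    shape = spec.volume_shape
    edge_um = EDGE_SOFTNESS_VOX * vs

    dist_sin = np.full(shape, np.float32(np.inf), dtype=np.float32)
    dist_vein = np.full(shape, np.float32(np.inf), dtype=np.float32)
    for tube in curves:
        target = dist_vein if tube.kind == "vein" else dist_sin
        sl, dloc = _tube_local_distance(tube, vs, shape, pad_um=edge_um)
        np.minimum(target[sl], dloc, out=target[sl])

    sin_mask = dist_sin <= 0
    vein_mask = dist_vein <= 0
    sin_mask &= ~vein_mask

    zz, yy, xx = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij", sparse=True)
    grey = np.full(shape, spec.background_grey, dtype=np.float32)
    nodule_mask = np.zeros(shape, dtype=bool)
    for nod in nodules:
        c = np.asarray(nod.center, dtype=float)
        a = np.asarray(nod.semi_axes, dtype=float) / vs  # voxels
        outer = a + (nod.rim_thickness / vs)
        if np.any(c - outer < 0) or np.any(c + outer > np.asarray(shape)):
            warnings.warn(
                f"nodule at {nod.center} exceeds the volume bounds; clipping",
                stacklevel=2,
            )
        f2 = (((zz - c[0]) / a[0]) ** 2 + ((yy - c[1]) / a[1]) ** 2
              + ((xx - c[2]) / a[2]) ** 2)
        f2o = (((zz - c[0]) / outer[0]) ** 2 + ((yy - c[1]) / outer[1]) ** 2
               + ((xx - c[2]) / outer[2]) ** 2)
        interior = f2 <= 1.0
        rim = (~interior) & (f2o <= 1.0)
        nodule_mask |= interior
        grey[rim] = nod.rim_grey
        grey[interior] = 0.5 * (nod.rim_grey + spec.background_grey)

    # vessels: linear soft-edge profile towards vessel_grey
    dmin = np.minimum(dist_sin, dist_vein)
    prof = np.clip((edge_um / 2 - dmin) / edge_um, 0.0, 1.0)
    grey = grey * (1 - prof) + spec.vessel_grey * prof
    del dmin, prof, dist_sin, dist_vein

    grey = ndi.gaussian_filter(grey, PSF_SIGMA_VOX)

    # band-limited texture, calibrated to unit variance before scaling
    noise_rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 7]))
    noise = noise_rng.standard_normal(shape, dtype=np.float32)
    noise = ndi.gaussian_filter(noise, NOISE_CORR_SIGMA_VOX)
    sd = float(noise.std())
    if sd > 0:
        noise /= sd
    if spec.texture_rms_lower is not None:
        amp = np.full(shape, spec.texture_rms, dtype=np.float32)
        amp[:, shape[1] // 2:, :] = spec.texture_rms_lower
        grey = grey + amp * noise
    elif spec.texture_rms > 0:
        grey = grey + spec.texture_rms * noise
    grey = np.clip(grey, 0.0, 1.0)

    sin_mask &= ~nodule_mask
    vein_mask &= ~nodule_mask
    vessel_all = sin_mask | vein_mask
    return Phantom(
        volume=Volume3D(grey, vs),
        vessel_mask_truth=VesselMask(vessel_all, vs, provenance="truth"),
        nodule_mask_truth=NoduleMask(nodule_mask, vs),
        spec=spec,
        nodules=nodules,
        sinusoid_mask_truth=VesselMask(sin_mask, vs, provenance="truth"),
        vein_mask_truth=VesselMask(vein_mask, vs, provenance="truth"),
        curves=curves,
    )


def build_phantom(spec: PhantomSpec, nodules: list[NoduleSpec] | None = None) -> Phantom:
    """Generate the vessel tree and render the phantom in one call."""
    curves = generate_vessel_tree(spec, nodules)
    return rasterize_and_texture(curves, spec, nodules)


# ---------------------------------------------------------------------------
# presets

PRESET_NAMES = ("control", "metastatic", "chemo", "nodule")

# Committed calibration constants (scripts in the repository history tuned
# min_centerline_spacing by bisection against the measured weighted-mean NND
# and mean_branch_length against placement feasibility; see docs/methods.md).
_PRESETS: dict[str, dict] = {
    "control": dict(
        target_vvf=0.0165,
        sinusoid_diameter_mean=3.0,
        branch_length_mode=5.0,
        min_centerline_spacing=17.0,
        texture_rms=0.004,
        mean_branch_length=22.0,
        short_fraction=0.45,
    ),
    "metastatic": dict(
        target_vvf=0.0045,
        sinusoid_diameter_mean=3.0,
        branch_length_mode=12.0,
        min_centerline_spacing=33.0,
        texture_rms=0.010,
        texture_rms_highres=0.005,
        mean_branch_length=30.0,
        short_fraction=0.35,
    ),
    "chemo": dict(
        target_vvf=0.004,
        sinusoid_diameter_mean=3.0,
        branch_length_mode=5.0,
        min_centerline_spacing=17.0,
        texture_rms=0.004,       # upper half healthy-like ...
        texture_rms_lower=0.010,  # ... lower half metastatic-like
        mean_branch_length=22.0,
        short_fraction=0.45,
    ),
}


@dataclass(frozen=True)
class PhantomPreset:
    """A named study condition: a spec plus its nodules."""

    spec: PhantomSpec
    nodules: tuple[NoduleSpec, ...] = ()

    def build(self) -> Phantom:
        return build_phantom(self.spec, list(self.nodules))


def preset(name: str, *, shape: tuple[int, int, int] | None = None,
           voxel_size: float | None = None, seed: int = 0) -> PhantomPreset:
    """Return the calibrated phantom preset for a study condition.

    ``shape`` and ``voxel_size`` override the default geometry (256³ voxels
    at 0.7 µm for the high-resolution conditions; pass e.g. ``(64, 256, 256)``
    at 3.1 µm for low-resolution texture work).  Nodule geometry scales with
    the volume so the radial profile stays resolvable at desk scale.
    """
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; valid presets: {PRESET_NAMES}")
    shape = tuple(shape) if shape is not None else (256, 256, 256)
    voxel_size = float(voxel_size) if voxel_size is not None else 0.7

    if name == "nodule":
        ext = np.asarray(shape, dtype=float) * voxel_size
        # nodule sized to leave room for the radial shells and the hotspot
        semi = float(np.clip(0.14 * ext.min(), 10.0, 40.0))
        semi_axes = (semi, 0.92 * semi, 0.85 * semi)
        room = ext.min() / 2 - semi   # boundary to the nearest volume face
        decay_len = float(np.clip(room - 26.0, 18.0, 80.0))
        nod = NoduleSpec(
            center=tuple(s / 2 for s in shape),
            semi_axes=semi_axes,
            rim_thickness=12.0,
            rim_grey=0.68,
            rim_peak_vvf=0.06,
            boundary_vvf=0.018,
            farfield_vvf=0.005,
            decay_length=decay_len,
            hotspot_vvf=0.085,
            hotspot_extent=float(min(20.0, 0.5 * room)),
            hotspot_half_angle=50.0,
            hotspot_direction=(0.0, 1.0, 0.0),
        )
        spec = PhantomSpec(
            volume_shape=shape, voxel_size=voxel_size,
            target_vvf=0.011,  # informational; the radial profile governs
            sinusoid_diameter_mean=3.0, branch_length_mode=5.0,
            min_centerline_spacing=6.0, central_vein_diameter=0.0,
            texture_rms=0.008, seed=seed,
            mean_branch_length=12.0, short_fraction=0.45,
            centerline_clearance=3.6,
        )
        return PhantomPreset(spec=spec, nodules=(nod,))

    kw = dict(_PRESETS[name])
    # The texture-RMS class amplitudes are a low-resolution-scan property;
    # high-resolution phantoms (where segmentation runs) use the amplitude
    # regime in which the fixed vesselness threshold separates vessels from
    # parenchyma, as it demonstrably did on the real high-resolution scans.
    hires = kw.pop("texture_rms_highres", None)
    if hires is not None and voxel_size < 2.0:
        kw["texture_rms"] = hires
    if voxel_size >= 2.0:
        # at low resolution the sinusoid bed is unresolved ("barely visible");
        # the phantom carries only the sparse traces a low-res scan shows,
        # and the NND spacing (a high-res statistic) relaxes to stay
        # placeable in thin-slab geometries
        kw["target_vvf"] = min(kw["target_vvf"], 0.006)
        kw["min_centerline_spacing"] = min(kw["min_centerline_spacing"], 20.0)
    spec = PhantomSpec(volume_shape=shape, voxel_size=voxel_size,
                       central_vein_diameter=40.0, seed=seed, **kw)
    return PhantomPreset(spec=spec)
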