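"""Quantification of the segmented vascular network.

Implements the vascular volume fraction (VVF) — vessel voxels over tissue
voxels — on regions of interest and sliding cubes, the radial VVF in
distance shells around a metastatic nodule, curved branch lengths from the
skeleton graph, and constrained nearest-neighbour distances between vessel
midpoints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.interpolate import make_interp_spline
from scipy.spatial import cKDTree

from .segmentation import VVF_EXCLUSION_UM, split_by_diameter
from .skeleton import SkeletonGraph
from .volume import NoduleMask, VesselMask

__all__ = [
    "ROISpec",
    "sample_rois",
    "vvf",
    "VVFMap",
    "vvf_map",
    "RadialProfile",
    "radial_vvf",
    "branch_lengths",
    "nearest_neighbour_distances",
    "arc_length",
]

#: Default ROI volume, mm³.
DEFAULT_ROI_VOLUME_MM3 = 5e-3


@dataclass(frozen=True)
class ROISpec:
    """A rectangular region of interest in voxel coordinates."""

    origin: tuple[int, int, int]
    shape: tuple[int, int, int]
    voxel_size: float  # µm

    @property
    def volume_mm3(self) -> float:
        vox_mm3 = (self.voxel_size * 1e-3) ** 3
        return float(np.prod(self.shape)) * vox_mm3

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(o, o + s) for o, s in zip(self.origin, self.shape))

    def within(self, parent_shape: tuple[int, int, int]) -> bool:
        return all(o >= 0 and o + s <= p
                   for o, s, p in zip(self.origin, self.shape, parent_shape))


def sample_rois(parent_shape: tuple[int, int, int], voxel_size: float,
                volume_mm3: float = DEFAULT_ROI_VOLUME_MM3, n: int = 5,
                rng: np.random.Generator | None = None) -> list[ROISpec]:
    """Sample ``n`` random cubic ROIs of the requested physical volume.

    When the requested cube does not fit in the parent volume it is clamped
    to the largest cube that does (the actual ROI volume is recorded on the
    returned specs).
    """
    rng = rng if rng is not None else np.random.default_rng()
    side_vox = int(round((volume_mm3 * 1e9) ** (1 / 3) / voxel_size))
    side_vox = max(1, min(side_vox, min(parent_shape)))
    rois = []
    for _ in range(n):
        origin = tuple(int(rng.integers(0, p - side_vox + 1)) for p in parent_shape)
        rois.append(ROISpec(origin=origin, shape=(side_vox,) * 3, voxel_size=voxel_size))
    return rois


def vvf(mask: VesselMask, region: np.ndarray | ROISpec | None = None,
        exclusion_diameter: float | None = None,
        all_vessels: VesselMask | None = None) -> float:
    """Vascular volume fraction: vessel voxels / tissue voxels in a region.

    Tissue voxels are region voxels not flagged as vessel (by
    ``all_vessels``, defaulting to ``mask`` itself, so that excluded large
    vessels do not count as tissue).  With ``exclusion_diameter`` set,
    vessels of local diameter above it are first removed from the numerator
    via the diameter split.
    """
    counted = mask
    if exclusion_diameter is not None:
        counted, _ = split_by_diameter(mask, exclusion_diameter)
    every = all_vessels if all_vessels is not None else mask

    if region is None:
        vessel = counted.data
        tissue = ~every.data
    elif isinstance(region, ROISpec):
        if not region.within(mask.shape):
            raise ValueError(f"ROI {region} does not fit inside volume {mask.shape}")
        sl = region.slices
        vessel = counted.data[sl]
        tissue = ~every.data[sl]
    else:
        region = np.asarray(region, dtype=bool)
        vessel = counted.data & region
        tissue = region & ~every.data
    n_tissue = int(tissue.sum())
    if n_tissue == 0:
        raise ValueError("region contains zero tissue voxels")
    return float(vessel.sum()) / n_tissue


@dataclass
class VVFMap:
    """Local VVF evaluated on a sliding cubic window.

    ``values[z, y, x]`` is the VVF of the cube centred at voxel
    ``(z, y, x) + cube_side // 2`` of the parent volume (only positions
    where the full cube fits are kept).
    """

    values: np.ndarray
    cube_side: int
    voxel_size: float

    def max(self) -> float:
        return float(np.nanmax(self.values))

    def mean(self) -> float:
        return float(np.nanmean(self.values))


def vvf_map(mask: VesselMask, cube_side: int = 50,
            all_vessels: VesselMask | None = None) -> VVFMap:
    """Sliding-cube VVF map (cube of ``cube_side`` voxels per side)."""
    if any(cube_side > s for s in mask.shape):
        raise ValueError(f"cube of side {cube_side} does not fit in {mask.shape}")
    every = all_vessels if all_vessels is not None else mask
    vessel_frac = ndi.uniform_filter(mask.data.astype(np.float32), size=cube_side)
    tissue_frac = ndi.uniform_filter((~every.data).astype(np.float32), size=cube_side)
    valid = tuple(slice(cube_side // 2, s - (cube_side - 1) // 2) for s in mask.shape)
    v = vessel_frac[valid]
    t = tissue_frac[valid]
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(t > 0, v / t, np.nan)
    return VVFMap(values=out, cube_side=cube_side, voxel_size=mask.voxel_size)


@dataclass
class RadialProfile:
    """VVF in distance shells around a nodule boundary."""

    shell_index: np.ndarray   # (k,)
    inner_um: np.ndarray      # shell inner distance from the boundary
    outer_um: np.ndarray
    vvf: np.ndarray           # fraction per shell
    axis_length_um: np.ndarray  # major semi-axis of the shell's best-fit ellipsoid
    complete: np.ndarray      # bool per shell: entirely inside the volume


def _major_semi_axis(coords_um: np.ndarray) -> float:
    """Major semi-axis of the second-moment (inertia-tensor) ellipsoid fit.

    For points uniform on an ellipsoid surface the second moment along the
    major axis is a²/3, hence a = sqrt(3 λ_max) of the coordinate covariance.
    """
    c = coords_um - coords_um.mean(axis=0)
    cov = (c.T @ c) / len(c)
    lam = np.linalg.eigvalsh(cov)
    return float(np.sqrt(3.0 * max(lam[-1], 0.0)))


def radial_vvf(mask: VesselMask, nodule: NoduleMask, shell_width: float = 10.0,
               n_shells: int = 15, exclusion_diameter: float | None = None,
               all_vessels: VesselMask | None = None) -> RadialProfile:
    """VVF within shells of increasing Euclidean distance from the nodule.

    Shell ``k`` collects voxels whose distance from the nodule boundary lies
    in ``[k·w, (k+1)·w)``; the distance field follows the nodule's own shape
    (distance transform of its complement).  Shells that touch the volume
    border are flagged incomplete and the profile is truncated with a
    warning.
    """
    if not nodule.data.any():
        raise ValueError("nodule mask is empty")
    border = np.zeros(nodule.shape, dtype=bool)
    for ax in range(3):
        sl = [slice(None)] * 3
        for edge_i in (0, -1):
            sl[ax] = edge_i
            border[tuple(sl)] = True
    if np.any(nodule.data & border):
        raise ValueError("nodule must lie strictly inside the volume")

    counted = mask
    if exclusion_diameter is not None:
        counted, _ = split_by_diameter(mask, exclusion_diameter)
    every = all_vessels if all_vessels is not None else mask

    dist = ndi.distance_transform_edt(~nodule.data, sampling=mask.voxel_size)
    vs = mask.voxel_size
    idx, inner, outer, frac, axis, comp = [], [], [], [], [], []
    truncated = False
    for k in range(n_shells):
        lo, hi = k * shell_width, (k + 1) * shell_width
        shell = (dist >= lo) & (dist < hi) & (dist > 0)
        if not shell.any():
            truncated = True
            break
        tissue = shell & ~every.data
        n_t = int(tissue.sum())
        vvf_k = float((counted.data & shell).sum()) / n_t if n_t else np.nan
        outer_layer = shell & (dist >= hi - 1.5 * vs)
        if not outer_layer.any():
            outer_layer = shell
        coords = np.argwhere(outer_layer) * vs
        is_complete = not bool(np.any(shell & border))
        idx.append(k); inner.append(lo); outer.append(hi)
        frac.append(vvf_k); axis.append(_major_semi_axis(coords)); comp.append(is_complete)
        if not is_complete:
            truncated = True
    if truncated:
        warnings.warn("radial profile truncated at the volume edge", stacklevel=2)
    return RadialProfile(
        shell_index=np.asarray(idx), inner_um=np.asarray(inner, float),
        outer_um=np.asarray(outer, float), vvf=np.asarray(frac, float),
        axis_length_um=np.asarray(axis, float), complete=np.asarray(comp, bool),
    )


# ---------------------------------------------------------------------------
# skeleton-derived statistics


def arc_length(path_um: np.ndarray, oversample: int = 12,
               subsample: int = 4) -> float:
    """Arc length of a smooth interpolating curve through ordered points.

    The voxel path is subsampled (every ``subsample``-th point, keeping the
    endpoints) to suppress the quantisation zigzag of digital curves, then a
    chord-length-parameterised cubic spline is fit and its length measured
    by dense sampling; short paths fall back to the polyline length.  A
    single point has length zero.
    """
    pts = np.asarray(path_um, dtype=float)
    if len(pts) < 2:
        return 0.0
    if subsample > 1 and len(pts) >= 2 * subsample:
        idx = list(range(0, len(pts) - 1, subsample)) + [len(pts) - 1]
        pts = pts[idx]
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    keep = np.concatenate([[True], seg > 1e-9])
    pts = pts[keep]
    if len(pts) < 4:
        return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    t = np.concatenate([[0.0], np.cumsum(seg)])
    spline = make_interp_spline(t, pts, k=3)
    tt = np.linspace(0.0, t[-1], oversample * len(pts))
    dense = spline(tt)
    return float(np.linalg.norm(np.diff(dense, axis=0), axis=1).sum())


def branch_lengths(graph: SkeletonGraph, bin_width: float = 1.0,
                   ) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Per-branch curved lengths (µm) and the unit-normalised histogram.

    Each branch's voxel path is interpolated with a cubic spline and the arc
    length of the fit is reported; single-voxel branches have length zero.
    The histogram (bins of ``bin_width`` µm anchored at zero) is normalised
    to the total number of branches.
    """
    if not graph.branches:
        raise ValueError("empty skeleton graph has no branch lengths")
    vs = graph.voxel_size
    lengths = np.array([arc_length(b.path * vs) for b in graph.branches])
    hi = (np.floor(lengths.max() / bin_width) + 1) * bin_width
    edges = np.arange(0.0, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(lengths, bins=edges)
    density = counts / counts.sum()
    return lengths, (density, edges)


def _arc_midpoint(path_um: np.ndarray) -> np.ndarray:
    """The path voxel at half the branch arc length (inside the vessel)."""
    pts = np.asarray(path_um, dtype=float)
    if len(pts) == 1:
        return pts[0]
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    return pts[int(np.argmin(np.abs(s - s[-1] / 2)))]


def nearest_neighbour_distances(graph: SkeletonGraph) -> tuple[np.ndarray, float]:
    """Per-branch nearest-neighbour distance and its weighted average.

    The representative point of each branch is its arc-length midpoint voxel
    (the centre of mass taken along the curve, guaranteed to lie within the
    vessel).  NND(i) is the minimum Euclidean distance to any other branch's
    representative point; the weighted average follows the normalised branch
    frequency distribution, i.e. the plain mean over branches.
    """
    if graph.n_branches < 2:
        raise ValueError("nearest-neighbour distances need at least two branches")
    vs = graph.voxel_size
    mids = np.array([_arc_midpoint(b.path * vs) for b in graph.branches])
    tree = cKDTree(mids)
    d, _ = tree.query(mids, k=2)
    nnd = d[:, 1]
    return nnd, float(nnd.mean())
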