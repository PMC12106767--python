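"""End-to-end pipelines: specimen quantification and phantom validation.

``run_specimen`` ties the stages together on one volume (segmentation →
skeleton statistics → VVF → texture) and writes tables plus a manifest;
``run_validation`` regenerates calibrated phantoms and reports recovered
versus ground-truth statistics, which is also what the acceptance checks
build on.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .config import RunConfig
from .phantom import Phantom, PhantomPreset, preset
from .quantify import (branch_lengths, nearest_neighbour_distances, radial_vvf,
                       sample_rois, vvf, vvf_map)
from .segmentation import (FrangiParams, merge_masks, remove_small_components,
                           segment_large_vessels, segment_small_vessels,
                           split_by_diameter)
from .skeleton import diameter_distribution, modal_bin_center, skeletonize
from .texture import class_fractions, class_stats, classify_tissue, rms_map
from .volume import VesselMask, Volume3D

__all__ = [
    "SegmentationResult",
    "SpecimenMetrics",
    "segment_volume",
    "analyze_sinusoids",
    "analyze_nodule_phantom",
    "run_specimen",
    "run_validation",
]


@dataclass
class SegmentationResult:
    small: VesselMask    # thresholded vesselness response
    large: VesselMask    # intensity-threshold large vessels
    merged: VesselMask
    sinusoids: VesselMask  # merged mask below the diameter split
    above_split: VesselMask


def _frangi_params(config: RunConfig) -> FrangiParams:
    return FrangiParams(
        scales=tuple(config.frangi_scales), alpha=config.frangi_alpha,
        beta=config.frangi_beta, c=config.frangi_c,
        probability_threshold=config.probability_threshold,
        dark_ridges=config.dark_vessels,
    )


def segment_volume(vol: Volume3D, config: RunConfig | None = None) -> SegmentationResult:
    """Full vessel segmentation: vesselness + intensity threshold, merged,
    then split at the small/large diameter cutoff."""
    config = config or RunConfig()
    small = segment_small_vessels(vol, _frangi_params(config))
    small = remove_small_components(small, config.min_component_voxels)
    large = segment_large_vessels(vol, config.grey_threshold,
                                  dark_vessels=config.dark_vessels,
                                  min_diameter=config.diameter_split_um)
    merged = merge_masks(small, large)
    sinusoids, above = split_by_diameter(merged, config.diameter_split_um)
    return SegmentationResult(small=small, large=large, merged=merged,
                              sinusoids=sinusoids, above_split=above)


@dataclass
class SpecimenMetrics:
    """Headline quantities of one specimen/phantom run."""

    vvf_per_roi: list[float]
    vvf_mean_pct: float
    nnd_weighted_mean_um: float
    n_branches: int
    branch_length_mode_um: float
    diameter_mode_um: float
    rms_mean: float | None = None
    rms_p95: float | None = None
    class_percentages: dict | None = None


def analyze_sinusoids(vol: Volume3D, config: RunConfig | None = None,
                      seg: SegmentationResult | None = None,
                      rng: np.random.Generator | None = None) -> SpecimenMetrics:
    """Segment a volume and recover the sinusoid-bed statistics.

    VVF is averaged over random ROIs with vessels above the exclusion
    diameter removed; branch statistics come from the skeleton of the
    small-vessel (below-split) mask.
    """
    config = config or RunConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    seg = seg or segment_volume(vol, config)

    counted, _ = split_by_diameter(seg.merged, config.vvf_exclusion_um)
    rois = sample_rois(vol.shape, vol.voxel_size, config.roi_volume_mm3,
                       config.n_rois, rng)
    per_roi = [vvf(counted, roi, all_vessels=seg.merged) for roi in rois]

    graph = skeletonize(seg.sinusoids)
    if graph.n_branches >= 2:
        _, nnd_mean = nearest_neighbour_distances(graph)
        lengths, (ldens, ledges) = branch_lengths(graph, config.length_bin_um)
        lmode = modal_bin_center(ldens, ledges)
        dcounts, dedges = diameter_distribution(graph, config.diameter_bin_um)
        dmode = modal_bin_center(dcounts, dedges)
    else:
        nnd_mean, lmode, dmode = np.nan, np.nan, np.nan
    return SpecimenMetrics(
        vvf_per_roi=per_roi,
        vvf_mean_pct=100.0 * float(np.mean(per_roi)),
        nnd_weighted_mean_um=float(nnd_mean),
        n_branches=graph.n_branches,
        branch_length_mode_um=float(lmode),
        diameter_mode_um=float(dmode),
    )


def analyze_nodule_phantom(phantom: Phantom, config: RunConfig | None = None,
                           seg: SegmentationResult | None = None,
                           near_boundary_um: float = 30.0) -> dict:
    """Perinodular VVF metrics on a nodule phantom.

    Returns the sliding-cube VVF-map maximum among cube centres within
    ``near_boundary_um`` of the nodule boundary and the mean VVF of the two
    outermost complete radial shells, both in percent.
    """
    config = config or RunConfig()
    vol = phantom.volume
    seg = seg or segment_volume(vol, config)
    counted, _ = split_by_diameter(seg.merged, config.vvf_exclusion_um)

    vmap = vvf_map(counted, config.vvf_cube_side, all_vessels=seg.merged)
    dist = ndi.distance_transform_edt(~phantom.nodule_mask_truth.data,
                                      sampling=vol.voxel_size)
    off = config.vvf_cube_side // 2
    sl = tuple(slice(off, off + s) for s in vmap.values.shape)
    d_center = dist[sl]
    sel = (d_center > 0) & (d_center <= near_boundary_um) & np.isfinite(vmap.values)
    map_max = float(vmap.values[sel].max()) if sel.any() else float("nan")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prof = radial_vvf(counted, phantom.nodule_mask_truth,
                          shell_width=config.shell_width_um,
                          n_shells=config.n_shells, all_vessels=seg.merged)
    complete = prof.vvf[prof.complete]
    outer = complete[-2:] if complete.size >= 2 else complete
    return {
        "map_max_pct": 100.0 * map_max,
        "radial_outer_pct": 100.0 * float(np.mean(outer)),
        "profile": prof,
        "vvf_map": vmap,
    }


def run_specimen(config: RunConfig, phantom: Phantom | None = None,
                 vol: Volume3D | None = None) -> tuple[SpecimenMetrics, dict]:
    """Run the full quantification pipeline and write outputs + manifest.

    The input is a phantom, an in-memory volume, or (via the config) a file
    path.  Missing input is an error before any computation starts.
    """
    from . import io as hio

    if phantom is not None:
        vol = phantom.volume
    elif vol is None:
        if not config.input_volume:
            raise ValueError("no input volume: set config.input_volume or pass one")
        path = Path(config.input_volume)
        if not path.exists():
            raise FileNotFoundError(f"input volume {path} does not exist")
        vol = hio.read_volume(path, config.voxel_size_um or None)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    seg = segment_volume(vol, config)
    metrics = analyze_sinusoids(vol, config, seg=seg, rng=rng)

    exclusion = seg.merged.data
    if phantom is not None:
        exclusion = exclusion | phantom.nodule_mask_truth.data
    rmap = rms_map(vol, exclusion, config.rms_window_px, config.rms_stride)
    finite = rmap.finite_values()
    if finite.size:
        metrics.rms_mean = float(finite.mean())
        metrics.rms_p95 = float(np.percentile(finite, 95))

    hio.write_mask_tiff(out / "vessels_merged.tif", seg.merged)
    hio.write_mask_tiff(out / "vessels_small.tif", seg.sinusoids)
    pd.DataFrame({"roi": range(len(metrics.vvf_per_roi)),
                  "vvf_fraction": metrics.vvf_per_roi}).to_csv(
        out / "vvf_per_roi.csv", index=False)
    manifest = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "input_shape": list(vol.shape),
        "voxel_size_um": vol.voxel_size,
        "metrics": {k: v for k, v in asdict(metrics).items()
                    if not isinstance(v, (list, dict))},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=float)
    return metrics, manifest


def run_validation(seeds: list[int], preset_name: str = "control",
                   shape: tuple[int, int, int] = (160, 160, 160),
                   voxel_size: float = 0.7,
                   config: RunConfig | None = None) -> pd.DataFrame:
    """Parameter-recovery report: truth vs estimate per seed for a preset."""
    if len(seeds) < 1:
        raise ValueError("at least one seed is required")
    config = config or RunConfig()
    rows = []
    for seed in seeds:
        pre = preset(preset_name, shape=shape, voxel_size=voxel_size, seed=seed)
        ph = pre.build()
        metrics = analyze_sinusoids(ph.volume, config,
                                    rng=np.random.default_rng(seed))
        rows.append({
            "preset": preset_name,
            "seed": seed,
            "truth_vvf_pct": 100.0 * ph.truth_vvf(),
            "est_vvf_pct": metrics.vvf_mean_pct,
            "target_vvf_pct": 100.0 * pre.spec.target_vvf,
            "est_nnd_um": metrics.nnd_weighted_mean_um,
            "target_nnd_um": pre.spec.min_centerline_spacing,
            "est_length_mode_um": metrics.branch_length_mode_um,
            "target_length_mode_um": pre.spec.branch_length_mode,
            "est_diameter_mode_um": metrics.diameter_mode_um,
            "target_diameter_um": pre.spec.sinusoid_diameter_mean,
            "n_branches": metrics.n_branches,
        })
    return pd.DataFrame(rows)
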