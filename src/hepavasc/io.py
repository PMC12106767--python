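"""Readers and writers: TIFF stacks, NIfTI volumes, masks, sidecar metadata
and CSV tables."""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .phantom import Phantom
from .skeleton import SkeletonGraph
from .volume import VesselMask, Volume3D

__all__ = [
    "read_volume",
    "write_volume_tiff",
    "write_mask_tiff",
    "read_mask_tiff",
    "write_sidecar",
    "read_sidecar",
    "write_phantom",
    "skeleton_to_csv",
]


def write_volume_tiff(path: str | os.PathLike, vol: Volume3D) -> None:
    """Write a grey volume as a multi-page float32 TIFF."""
    tifffile.imwrite(path, np.asarray(vol.data, dtype=np.float32),
                     photometric="minisblack")


def write_mask_tiff(path: str | os.PathLike, mask) -> None:
    tifffile.imwrite(path, mask.data.astype(np.uint8) * 255,
                     photometric="minisblack")


def read_mask_tiff(path: str | os.PathLike, voxel_size: float,
                   provenance: str = "truth") -> VesselMask:
    data = tifffile.imread(path)
    return VesselMask(data > 0, voxel_size, provenance=provenance)


def read_volume(path: str | os.PathLike, voxel_size: float | None = None) -> Volume3D:
    """Read a TIFF stack or NIfTI volume.

    For TIFF the voxel size (µm) must be given (or present in a sidecar
    written by this package); NIfTI volumes carry their spacing, which must
    be isotropic.
    """
    path = Path(path)
    if path.suffix in (".nii", ".gz") or str(path).endswith(".nii.gz"):
        import nibabel as nib

        img = nib.load(str(path))
        zooms = img.header.get_zooms()[:3]
        if not np.allclose(zooms, zooms[0], rtol=1e-3):
            raise ValueError(f"anisotropic voxel size {zooms} is not supported")
        # NIfTI spacing is in mm by convention; sidecar-declared µm wins
        vs = voxel_size if voxel_size is not None else float(zooms[0]) * 1000.0
        return Volume3D(np.asarray(img.dataobj).astype(np.float32), vs)
    data = tifffile.imread(path)
    if voxel_size is None:
        sidecar = path.with_suffix(".meta.txt")
        if sidecar.exists():
            meta = read_sidecar(sidecar)
            voxel_size = float(meta["voxel_size_um"])
        else:
            raise ValueError(
                "voxel_size is required for TIFF input (none given and no sidecar found)"
            )
    return Volume3D(np.asarray(data, dtype=np.float32), float(voxel_size))


def write_sidecar(path: str | os.PathLike, meta: dict) -> None:
    """Flat ``key = value`` metadata file."""
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"{k} = {v}\n")


def read_sidecar(path: str | os.PathLike) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or "=" not in line:
                continue
            k, v = line.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def write_phantom(out_dir: str | os.PathLike, phantom: Phantom) -> None:
    """Write a phantom as TIFF stacks plus a metadata sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_volume_tiff(out / "volume.tif", phantom.volume)
    write_mask_tiff(out / "vessel_truth.tif", phantom.vessel_mask_truth)
    write_mask_tiff(out / "nodule_truth.tif", phantom.nodule_mask_truth)
    if phantom.sinusoid_mask_truth is not None:
        write_mask_tiff(out / "sinusoid_truth.tif", phantom.sinusoid_mask_truth)
    spec = phantom.spec
    meta = {
        "voxel_size_um": spec.voxel_size,
        "volume_shape": "x".join(map(str, spec.volume_shape)),
        "seed": spec.seed,
    }
    for key in ("target_vvf", "sinusoid_diameter_mean", "sinusoid_diameter_sd",
                "branch_length_mode", "min_centerline_spacing",
                "central_vein_diameter", "texture_rms", "background_grey",
                "vessel_grey"):
        meta[key] = getattr(spec, key)
    write_sidecar(out / "volume.meta.txt", meta)


def skeleton_to_csv(path: str | os.PathLike, graph: SkeletonGraph) -> None:
    """Write the skeleton graph as a long-format CSV edge list."""
    rows = []
    for bid, br in enumerate(graph.branches):
        for order, (z, y, x) in enumerate(br.path):
            rows.append((bid, order, int(z), int(y), int(x), br.radius))
    df = pd.DataFrame(rows, columns=["branch_id", "point_order", "z", "y", "x",
                                     "radius_um"])
    df.to_csv(path, index=False)
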