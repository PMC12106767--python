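"""Run configuration: every stage parameter with its protocol default, flat
key-value (de)serialisation and a stable content hash."""

from __future__ import annotations

import hashlib
import os
from dataclasses import asdict, dataclass, fields

from .segmentation import DIAMETER_SPLIT_UM, VVF_EXCLUSION_UM

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Parameters of one end-to-end specimen run.

    Defaults are the protocol values: Frangi scales 1–10 voxels with
    α = β = 0.5, C = 0.013 and response threshold 0.16; a 30-pixel RMS
    window with ±1.5 SD class bands; 5·10⁻³ mm³ ROIs; a 50-voxel VVF cube;
    a 15 µm small/large vessel split with vessels above 10 µm excluded from
    VVF; 10 µm radial shells.
    """

    input_volume: str = ""
    voxel_size_um: float = 0.7
    output_dir: str = "hepavasc_out"
    seed: int = 0
    # Frangi / segmentation
    frangi_scales: tuple[float, ...] = tuple(range(1, 11))
    frangi_alpha: float = 0.5
    frangi_beta: float = 0.5
    frangi_c: float = 0.013
    probability_threshold: float = 0.16
    dark_vessels: bool = True
    grey_threshold: float | None = None  # None -> Otsu
    diameter_split_um: float = DIAMETER_SPLIT_UM
    vvf_exclusion_um: float = VVF_EXCLUSION_UM
    min_component_voxels: int = 10
    # texture
    rms_window_px: int = 30
    rms_stride: int | None = None  # None -> tiling
    band_k: float = 1.5
    # quantification
    roi_volume_mm3: float = 5e-3
    n_rois: int = 5
    vvf_cube_side: int = 50
    shell_width_um: float = 10.0
    n_shells: int = 15
    length_bin_um: float = 1.0
    diameter_bin_um: float = 0.5

    # -- serialisation ----------------------------------------------------
    def to_file(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            for f in fields(self):
                v = getattr(self, f.name)
                if isinstance(v, tuple):
                    v = ",".join(repr(x) for x in v)
                fh.write(f"{f.name} = {v}\n")

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "RunConfig":
        raw: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or "=" not in line:
                    continue
                k, v = line.split("=", 1)
                raw[k.strip()] = v.strip()
        kwargs = {}
        for f in fields(cls):
            if f.name not in raw:
                continue
            s = raw[f.name]
            if s == "None":
                kwargs[f.name] = None
            elif f.name == "frangi_scales":
                kwargs[f.name] = tuple(float(x) for x in s.split(","))
            elif f.type in ("int", "int | None"):
                kwargs[f.name] = int(s)
            elif f.type in ("float", "float | None"):
                kwargs[f.name] = float(s)
            elif f.type == "bool":
                kwargs[f.name] = s in ("True", "true", "1")
            else:
                kwargs[f.name] = s
        return cls(**kwargs)

    def content_hash(self) -> str:
        canon = repr(sorted(asdict(self).items())).encode()
        return hashlib.sha256(canon).hexdigest()[:16]
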