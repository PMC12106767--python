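"""Shared fixtures: small rasterized tubes and desk-scale phantoms.

Heavy phantom+segmentation fixtures are session-scoped and shared between
the acceptance tests so each phantom is segmented exactly once.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage as ndi

from hepavasc.phantom import Tube
from hepavasc.volume import VesselMask, Volume3D


def rasterize_tubes(tubes: list[Tube], shape: tuple[int, int, int],
                    voxel_size: float = 0.7, background: float = 0.55,
                    vessel: float = 0.10, noise_sd: float = 0.004,
                    seed: int = 0, blur: float = 0.6):
    """Render tubes into a (volume, truth mask) pair the way the phantom does."""
    from hepavasc.phantom import _tube_local_distance

    dist = np.full(shape, np.inf, dtype=np.float32)
    for t in tubes:
        sl, d = _tube_local_distance(t, voxel_size, shape, pad_um=0.7 * voxel_size)
        np.minimum(dist[sl], d, out=dist[sl])
    edge = 0.7 * voxel_size
    prof = np.clip((edge / 2 - dist) / edge, 0.0, 1.0)
    grey = background + (vessel - background) * prof
    grey = ndi.gaussian_filter(grey, blur)
    rng = np.random.default_rng(seed)
    noise = ndi.gaussian_filter(rng.standard_normal(shape, dtype=np.float32), 1.0)
    noise /= noise.std()
    vol = Volume3D(np.clip(grey + noise_sd * noise, 0, 1), voxel_size)
    truth = VesselMask(dist <= 0, voxel_size, provenance="truth")
    return vol, truth


def straight_tube(p0, p1, radius: float, kind: str = "sinusoid") -> Tube:
    return Tube(points=np.array([p0, p1], dtype=float), radius=radius, kind=kind)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


# --------------------------------------------------------------------------
# desk-scale phantoms for the acceptance suite (built once per session)

ACC_SHAPE_HIRES = (160, 160, 160)
ACC_SHAPE_MET = (160, 160, 160)
ACC_SHAPE_NODULE = (192, 192, 192)
ACC_SHAPE_LOWRES = (16, 128, 128)
ACC_SEEDS = (1, 2, 3)


@pytest.fixture(scope="session")
def control_runs():
    """Control phantoms segmented and analysed, one entry per seed."""
    import hepavasc as hv

    runs = []
    for seed in ACC_SEEDS:
        ph = hv.preset("control", shape=ACC_SHAPE_HIRES, seed=seed).build()
        metrics = hv.analyze_sinusoids(ph.volume, rng=np.random.default_rng(seed))
        runs.append((ph, metrics))
    return runs


@pytest.fixture(scope="session")
def metastatic_runs():
    import hepavasc as hv

    runs = []
    for seed in ACC_SEEDS:
        ph = hv.preset("metastatic", shape=ACC_SHAPE_MET, seed=seed).build()
        metrics = hv.analyze_sinusoids(ph.volume, rng=np.random.default_rng(seed))
        runs.append((ph, metrics))
    return runs


@pytest.fixture(scope="session")
def nodule_run():
    import hepavasc as hv

    ph = hv.preset("nodule", shape=ACC_SHAPE_NODULE, seed=1).build()
    out = hv.analyze_nodule_phantom(ph)
    return ph, out


@pytest.fixture(scope="session")
def lowres_phantoms():
    """Low-resolution (3.1 µm) phantoms for the RMS/classification stages."""
    import hepavasc as hv

    out = {}
    for name in ("control", "metastatic", "chemo"):
        out[name] = hv.preset(name, shape=ACC_SHAPE_LOWRES, voxel_size=3.1,
                              seed=1).build()
    return out
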