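"""Vesselness, thresholding, merging and the diameter split."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from hepavasc.segmentation import (FrangiParams, frangi_vesselness, merge_masks,
                                   remove_small_components,
                                   segment_large_vessels, segment_small_vessels,
                                   split_by_diameter)
from hepavasc.volume import VesselMask, Volume3D

from conftest import rasterize_tubes, straight_tube

FAST = FrangiParams(scales=(1, 2, 3, 4))


def _gaussian_tube(shape=(48, 48, 48), sigma=2.0, amp=0.3, vs=1.0):
    """Dark tube along z with Gaussian cross-section of the given SD."""
    _, yy, xx = np.indices(shape)
    cy, cx = shape[1] / 2, shape[2] / 2
    prof = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma ** 2))
    return Volume3D(0.55 - amp * prof, vs)


def test_constant_volume_has_zero_vesselness():
    vol = Volume3D(np.full((48, 48, 48), 0.4), 0.7)
    assert np.all(frangi_vesselness(vol, FAST) == 0)


def test_vesselness_is_invariant_to_grey_offset():
    vol = _gaussian_tube()
    shifted = Volume3D(vol.data + 0.17, vol.voxel_size)
    a = frangi_vesselness(vol, FAST)
    b = frangi_vesselness(shifted, FAST)
    assert np.allclose(a, b, atol=1e-6)


def test_scale_response_concentrates_at_the_tube_width_scale():
    """A thin Gaussian tube responds at the finest scales and decays fast
    for scales much wider than the tube (the implementation weights fine
    scales; see docs/methods.md on scale normalisation)."""
    vol = _gaussian_tube(sigma=2.0)
    centre = (24, 24, 24)
    responses = {s: float(frangi_vesselness(vol, FrangiParams(scales=(s,)))[centre])
                 for s in (1, 2, 4, 6)}
    assert max(responses, key=responses.get) in (1, 2)
    assert responses[6] < 0.1 * max(responses.values())
    # centreline beats any off-tube voxel
    best = frangi_vesselness(vol, FrangiParams(scales=(1, 2)))
    off = best[:, :12, :12]
    assert best[centre] > off.max()


def test_tube_outscores_equal_contrast_blob():
    zz, yy, xx = np.indices((48, 48, 48))
    d2 = (zz - 24) ** 2 + (yy - 24) ** 2 + (xx - 24) ** 2
    blob = Volume3D(0.55 - 0.3 * np.exp(-d2 / (2 * 2.0 ** 2)), 1.0)
    tube = _gaussian_tube(sigma=2.0)
    v_blob = frangi_vesselness(blob, FAST)[24, 24, 24]
    v_tube = frangi_vesselness(tube, FAST)[24, 24, 24]
    assert v_tube > v_blob


def test_vesselness_equivariant_under_axis_rotations():
    tube = straight_tube([8.0, 16.8, 16.8], [25.6, 16.8, 16.8], 1.5)
    vol, _ = rasterize_tubes([tube], (48, 48, 48))
    base = frangi_vesselness(vol, FAST).sum()
    for axes in ((0, 1), (0, 2), (1, 2)):
        rot = Volume3D(np.rot90(vol.data, axes=axes).copy(), vol.voxel_size)
        assert frangi_vesselness(rot, FAST).sum() == pytest.approx(base, rel=0.05)


def test_small_vessel_threshold_is_strict():
    """Mask keeps response > P only: a threshold equal to the field maximum
    yields an empty mask; one ULP below keeps exactly the maximal voxels."""
    vol = _gaussian_tube()
    v = frangi_vesselness(vol, FAST)
    vmax = np.float32(v.max())
    at_max = FrangiParams(scales=(1, 2, 3, 4),
                          probability_threshold=float(vmax))
    assert segment_small_vessels(vol, at_max).count() == 0  # strict >
    below = FrangiParams(scales=(1, 2, 3, 4),
                         probability_threshold=float(np.nextafter(vmax,
                                                                  np.float32(0))))
    barely = segment_small_vessels(vol, below)
    assert barely.count() == int((v == vmax).sum())


def test_constant_volume_segments_empty():
    vol = Volume3D(np.full((48, 48, 48), 0.5), 0.7)
    assert segment_small_vessels(vol, FAST).count() == 0
    assert segment_large_vessels(vol, 0.3).count() == 0


def test_threshold_below_minimum_gives_full_mask():
    rng = np.random.default_rng(0)
    vol = Volume3D(rng.uniform(0.4, 0.6, (24, 24, 24)), 0.7)
    with pytest.warns(UserWarning):
        mask = segment_large_vessels(vol, vol.data.max() + 1, min_diameter=0)
    assert mask.count() == vol.data.size


def test_large_vessel_recovery_of_a_central_vein():
    vein = straight_tube([0.0, 22.4, 22.4], [44.8, 22.4, 22.4], 10.0,
                         kind="vein")
    vol, truth = rasterize_tubes([vein], (64, 64, 64))
    mask = segment_large_vessels(vol, min_diameter=15.0)
    assert mask.count() == pytest.approx(truth.count(), rel=0.15)


def test_merge_identity_idempotence_and_additivity():
    vs = 0.7
    a = np.zeros((8, 8, 8), bool); a[2, 2, 2] = True
    b = np.zeros((8, 8, 8), bool); b[5, 5, 5] = True
    ma = VesselMask(a, vs, "frangi")
    mb = VesselMask(b, vs, "threshold")
    empty = VesselMask(np.zeros_like(a), vs, "threshold")
    assert np.array_equal(merge_masks(ma, empty).data, ma.data)
    assert np.array_equal(merge_masks(ma, ma).data, ma.data)
    assert merge_masks(ma, mb).count() == ma.count() + mb.count()
    assert merge_masks(ma, mb).provenance == "merged"
    with pytest.raises(ValueError):
        merge_masks(ma, VesselMask(np.zeros((4, 4, 4), bool), vs))


def test_split_all_thin_tubes_stay_small():
    tube = straight_tube([5.0, 16.8, 16.8], [28.0, 16.8, 16.8], 1.5)
    _, truth = rasterize_tubes([tube], (48, 48, 48))
    small, large = split_by_diameter(truth, 15.0)
    assert large.count() == 0
    assert np.array_equal(small.data, truth.data)


def test_split_partition_is_exact_and_matches_per_tube_truth():
    thick = straight_tube([5.0, 22.4, 22.4], [61.6, 22.4, 22.4], 20.0, "vein")
    thin = straight_tube([5.0, 56.0, 56.0], [61.6, 56.0, 56.0], 1.5)
    _, truth = rasterize_tubes([thick, thin], (96, 96, 96))
    small, large = split_by_diameter(truth, 15.0)
    assert np.array_equal(small.data | large.data, truth.data)
    assert not np.any(small.data & large.data)
    from hepavasc.phantom import _tube_local_distance
    for tube, mask, other in ((thick, large, small), (thin, small, large)):
        sl, d = _tube_local_distance(tube, 0.7, truth.shape, 0.0)
        inside = d <= 0
        agree = (mask.data[sl] & inside).sum() / inside.sum()
        assert agree >= 0.95


def test_split_cutoff_zero_sends_everything_large():
    tube = straight_tube([5.0, 16.8, 16.8], [28.0, 16.8, 16.8], 1.5)
    _, truth = rasterize_tubes([tube], (48, 48, 48))
    small, large = split_by_diameter(truth, 0.0)
    assert small.count() == 0
    assert large.count() == truth.count()


def test_remove_small_components_keeps_real_structures():
    data = np.zeros((32, 32, 32), bool)
    data[4:20, 10, 10] = True       # a 16-voxel line
    data[28, 28, 28] = True         # a speck
    cleaned = remove_small_components(VesselMask(data, 0.7, "frangi"), 10)
    assert cleaned.count() == 16
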