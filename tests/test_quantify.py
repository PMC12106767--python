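"""VVF accounting, radial profiles, branch lengths and NND oracles."""

import numpy as np
import pytest

from hepavasc.quantify import (ROISpec, arc_length, branch_lengths,
                               nearest_neighbour_distances, radial_vvf,
                               sample_rois, vvf, vvf_map)
from hepavasc.skeleton import Branch, SkeletonGraph
from hepavasc.volume import NoduleMask, VesselMask


def _mask(data, vs=1.0):
    return VesselMask(data, vs, provenance="truth")


def test_vvf_of_empty_mask_is_zero():
    m = _mask(np.zeros((10, 10, 10), bool))
    assert vvf(m) == 0.0


def test_vvf_matches_direct_count():
    data = np.zeros((10, 10, 10), bool)
    data.ravel()[:10] = True
    assert vvf(_mask(data)) == pytest.approx(10 / 990)


def test_vvf_zero_tissue_is_an_error():
    data = np.ones((4, 4, 4), bool)
    with pytest.raises(ValueError, match="tissue"):
        vvf(_mask(data))


def test_vvf_partition_identity_holds_exactly():
    rng = np.random.default_rng(7)
    data = rng.random((24, 24, 24)) < 0.05
    m = _mask(data)
    region = rng.random((24, 24, 24)) < 0.8
    # random 3-way partition of the region
    part = rng.integers(0, 3, size=region.shape)
    total = vvf(m, region)
    num = den = 0.0
    for k in range(3):
        sub = region & (part == k)
        tissue = int((sub & ~data).sum())
        if tissue == 0:
            continue
        num += vvf(m, sub) * tissue
        den += tissue
    assert num / den == pytest.approx(total, abs=1e-12)


def test_vvf_map_empty_mask_is_all_zero():
    m = _mask(np.zeros((30, 30, 30), bool))
    vmap = vvf_map(m, cube_side=10)
    assert np.nanmax(vmap.values) == 0.0


def test_vvf_map_concentrates_at_uniform_density():
    rng = np.random.default_rng(3)
    p = 0.08
    data = rng.random((64, 64, 64)) < p
    vmap = vvf_map(_mask(data), cube_side=32)
    expected = p / (1 - p)
    assert np.nanmean(vmap.values) == pytest.approx(expected, rel=0.05)
    assert np.nanstd(vmap.values) < 0.25 * expected


def test_vvf_map_cube_must_fit():
    with pytest.raises(ValueError):
        vvf_map(_mask(np.zeros((20, 20, 20), bool)), cube_side=50)


def _sphere_nodule(shape, center, radius, vs=1.0):
    zz, yy, xx = np.indices(shape)
    d2 = ((zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2)
    return NoduleMask(d2 <= radius ** 2, vs)


def test_radial_profile_is_flat_under_uniform_vessel_density():
    rng = np.random.default_rng(5)
    shape = (96, 96, 96)
    nod = _sphere_nodule(shape, (48, 48, 48), 14)
    d = 0.05
    vessels = (rng.random(shape) < d) & ~nod.data
    prof = radial_vvf(_mask(vessels), nod, shell_width=6.0, n_shells=5)
    expected = d / (1 - d)
    assert np.all(np.abs(prof.vvf - expected) < 0.30 * expected)


def test_radial_profile_of_empty_mask_is_zero_and_axis_grows():
    shape = (96, 96, 96)
    nod = _sphere_nodule(shape, (48, 48, 48), 14)
    prof = radial_vvf(_mask(np.zeros(shape, bool)), nod, shell_width=6.0,
                      n_shells=4)
    assert np.all(prof.vvf == 0)
    assert np.all(np.diff(prof.axis_length_um) > 0)
    # first shell's outer surface sits near r + w for a sphere
    assert prof.axis_length_um[0] == pytest.approx(14 + 6, rel=0.12)


def test_radial_profile_requires_interior_nodule():
    shape = (40, 40, 40)
    with pytest.raises(ValueError):
        radial_vvf(_mask(np.zeros(shape, bool)),
                   _sphere_nodule(shape, (0, 20, 20), 6), 5.0, 2)
    with pytest.raises(ValueError, match="empty"):
        radial_vvf(_mask(np.zeros(shape, bool)),
                   NoduleMask(np.zeros(shape, bool), 1.0), 5.0, 2)


# --------------------------------------------------------------------------
# branch lengths


def _graph(paths, vs=1.0, radius=1.5):
    branches = [Branch(path=np.asarray(p), radius=radius) for p in paths]
    return SkeletonGraph(branches, np.empty((0, 3), int), np.empty(0, int), vs)


def test_collinear_path_length_is_chord_sum():
    n, s = 9, 0.7
    path = [[0, 0, i] for i in range(n)]
    lengths, _ = branch_lengths(_graph([path], vs=s))
    assert lengths[0] == pytest.approx((n - 1) * s, abs=1e-9)


def test_quarter_circle_arc_length_within_five_percent():
    r_um = 20.0
    theta = np.linspace(0, np.pi / 2, 200)
    pts = np.stack([np.zeros_like(theta), r_um * np.sin(theta),
                    r_um * np.cos(theta)], axis=1)
    vox = np.unique(np.round(pts / 1.0).astype(int), axis=0)
    # order voxels by angle for a clean path
    ang = np.arctan2(vox[:, 1], vox[:, 2])
    vox = vox[np.argsort(ang)]
    measured = arc_length(vox.astype(float) * 1.0)
    assert measured == pytest.approx(np.pi * r_um / 2, rel=0.05)


def test_single_voxel_branch_has_zero_length():
    lengths, (dens, edges) = branch_lengths(_graph([[[3, 3, 3]]]))
    assert lengths[0] == 0.0
    assert dens.sum() == pytest.approx(1.0)


def test_length_histogram_is_normalised():
    paths = [[[0, 0, 0], [0, 0, 5]], [[5, 0, 0], [5, 0, 9]],
             [[9, 9, 0], [9, 9, 3]]]
    _, (dens, edges) = branch_lengths(_graph(paths))
    assert dens.sum() == pytest.approx(1.0)


# --------------------------------------------------------------------------
# nearest-neighbour distances


def test_parallel_tubes_with_aligned_midpoints_have_nnd_equal_separation():
    sep = 7.0
    a = [[0, 0, i] for i in range(11)]
    b = [[0, 7, i] for i in range(11)]
    nnd, wmean = nearest_neighbour_distances(_graph([a, b]))
    assert np.allclose(nnd, sep)
    assert wmean == pytest.approx(sep)


def test_three_collinear_tubes_all_have_nnd_equal_spacing():
    d = 9
    paths = [[[0, 0, k * d + i] for i in range(5)] for k in range(3)]
    # midpoints spaced exactly d apart along z
    nnd, wmean = nearest_neighbour_distances(_graph(paths))
    assert np.allclose(nnd, d)
    assert wmean == pytest.approx(d)


def test_nnd_invariant_under_translation_and_branch_order():
    rng = np.random.default_rng(11)
    paths = [np.cumsum(rng.integers(-1, 2, size=(6, 3)), axis=0) + off
             for off in rng.integers(0, 40, size=(5, 3))]
    g = _graph([p.tolist() for p in paths])
    nnd, _ = nearest_neighbour_distances(g)
    shifted = _graph([(np.asarray(p) + 13).tolist() for p in paths])
    nnd_shift, _ = nearest_neighbour_distances(shifted)
    assert np.allclose(nnd, nnd_shift)
    perm = _graph([paths[i].tolist() for i in (3, 1, 4, 0, 2)])
    nnd_perm, _ = nearest_neighbour_distances(perm)
    assert np.allclose(np.sort(nnd), np.sort(nnd_perm))


def test_nnd_needs_two_branches():
    with pytest.raises(ValueError):
        nearest_neighbour_distances(_graph([[[0, 0, 0], [0, 0, 3]]]))


def test_sampled_rois_fit_and_have_requested_volume():
    rng = np.random.default_rng(0)
    rois = sample_rois((200, 200, 200), 0.7, 5e-5, n=5, rng=rng)
    assert len(rois) == 5
    for roi in rois:
        assert roi.within((200, 200, 200))
        assert roi.volume_mm3 == pytest.approx(5e-5, rel=0.10)
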