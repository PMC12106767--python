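"""Generator contracts: calibration, determinism, truth-mask geometry."""

import numpy as np
import pytest

from hepavasc.phantom import (NoduleSpec, PhantomSpec, Tube, build_phantom,
                              generate_vessel_tree, preset,
                              rasterize_and_texture, PRESET_NAMES)

SMALL = dict(volume_shape=(72, 72, 72), voxel_size=0.7,
             central_vein_diameter=0.0, seed=3)


def test_zero_vvf_yields_empty_tree_and_mask():
    spec = PhantomSpec(target_vvf=0.0, **SMALL)
    curves = generate_vessel_tree(spec)
    assert [t for t in curves if t.kind == "sinusoid"] == []
    ph = rasterize_and_texture(curves, spec)
    assert ph.vessel_mask_truth.count() == 0


def test_forced_straight_tube_matches_analytic_cylinder_volume():
    spec = PhantomSpec(target_vvf=0.0, volume_shape=(160, 48, 48),
                       voxel_size=0.7, central_vein_diameter=0.0, seed=0)
    r, length = 1.5, 100.0
    tube = Tube(points=np.array([[6.0, 16.9, 16.6], [106.0, 16.9, 16.6]]),
                radius=r)
    ph = rasterize_and_texture([tube], spec)
    measured = ph.vessel_mask_truth.count() * spec.voxel_size ** 3
    analytic = np.pi * r ** 2 * length + 4 / 3 * np.pi * r ** 3  # capsule caps
    # digital rasterisation at ~2-voxel radius carries ~±15% boundary error
    assert measured == pytest.approx(analytic, rel=0.15)


def test_flat_texture_and_no_structures_gives_constant_volume():
    spec = PhantomSpec(target_vvf=0.0, texture_rms=0.0, **SMALL)
    ph = rasterize_and_texture([], spec)
    assert np.allclose(ph.volume.data, spec.background_grey, atol=1e-6)


def test_texture_rms_amplitude_recovered_from_generated_field():
    spec = PhantomSpec(target_vvf=0.0, texture_rms=0.006, **SMALL)
    ph = rasterize_and_texture([], spec)
    sd = float(ph.volume.data.std())
    assert sd == pytest.approx(0.006, rel=0.05)


def test_spherical_nodule_mask_matches_analytic_volume():
    spec = PhantomSpec(target_vvf=0.0, volume_shape=(192, 192, 192),
                       voxel_size=0.7, central_vein_diameter=0.0, seed=0)
    nod = NoduleSpec(center=(96, 96, 96), semi_axes=(50.0, 50.0, 50.0),
                     rim_thickness=5.0)
    ph = rasterize_and_texture([], spec, [nod])
    measured = ph.nodule_mask_truth.count() * spec.voxel_size ** 3
    assert measured == pytest.approx(4 / 3 * np.pi * 50.0 ** 3, rel=0.02)


def test_preset_targets_are_the_reported_study_values():
    assert preset("control").spec.target_vvf == pytest.approx(0.0165)
    assert preset("metastatic").spec.target_vvf == pytest.approx(0.0045)
    assert preset("control").spec.branch_length_mode == 5.0
    assert preset("metastatic").spec.branch_length_mode == 12.0
    assert preset("nodule").nodules[0].rim_peak_vvf == pytest.approx(0.06)
    assert preset("nodule").nodules[0].farfield_vvf == pytest.approx(0.005)


def test_unknown_preset_error_lists_valid_names():
    with pytest.raises(ValueError) as err:
        preset("liver")
    for name in PRESET_NAMES:
        assert name in str(err.value)


def test_same_spec_and_seed_reproduce_phantom_bit_exactly():
    spec = PhantomSpec(target_vvf=0.006, min_centerline_spacing=10.0, **SMALL)
    a = build_phantom(spec)
    b = build_phantom(spec)
    assert np.array_equal(a.volume.data, b.volume.data)
    assert np.array_equal(a.vessel_mask_truth.data, b.vessel_mask_truth.data)


def test_truth_vvf_calibration_within_tenth_of_a_point():
    spec = PhantomSpec(target_vvf=0.0165, min_centerline_spacing=10.0, **SMALL)
    ph = build_phantom(spec)
    assert 100 * ph.truth_vvf() == pytest.approx(1.65, abs=0.1)


def test_more_target_vvf_never_means_fewer_truth_voxels():
    lo = build_phantom(PhantomSpec(target_vvf=0.008,
                                   min_centerline_spacing=10.0, **SMALL))
    hi = build_phantom(PhantomSpec(target_vvf=0.016,
                                   min_centerline_spacing=10.0, **SMALL))
    assert hi.vessel_mask_truth.count() >= lo.vessel_mask_truth.count()


def test_truth_masks_are_disjoint_and_aligned_on_nodule_phantom():
    pre = preset("nodule", shape=(128, 128, 128), seed=2)
    ph = pre.build()  # Phantom.__post_init__ asserts disjointness/alignment
    assert ph.nodule_mask_truth.count() > 0
    assert not np.any(ph.vessel_mask_truth.data & ph.nodule_mask_truth.data)


@pytest.mark.parametrize("bad", [
    dict(target_vvf=0.6),
    dict(target_vvf=0.01, min_centerline_spacing=2.0),
    dict(target_vvf=0.01, voxel_size=-1.0),
])
def test_invalid_specs_are_rejected(bad):
    kw = dict(volume_shape=(64, 64, 64), voxel_size=0.7, seed=0)
    kw.update(bad)
    with pytest.raises(ValueError):
        PhantomSpec(**kw)


def test_nodule_invariants():
    with pytest.raises(ValueError):
        NoduleSpec(center=(10, 10, 10), semi_axes=(10, -1, 10))
    with pytest.raises(ValueError):
        NoduleSpec(center=(10, 10, 10), semi_axes=(10, 10, 10),
                   rim_peak_vvf=0.01, farfield_vvf=0.02)


def test_out_of_bounds_nodule_warns_and_clips():
    spec = PhantomSpec(target_vvf=0.0, **SMALL)
    nod = NoduleSpec(center=(5, 5, 5), semi_axes=(20.0, 20.0, 20.0))
    with pytest.warns(UserWarning, match="clipping"):
        ph = rasterize_and_texture([], spec, [nod])
    assert ph.nodule_mask_truth.count() > 0
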