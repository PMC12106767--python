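"""RMS roughness maps and the band-rule tissue classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hepavasc.texture import (LABELS, ClassStats, RMSMap, class_fractions,
                              class_stats, classify_tissue, rms_map)
from hepavasc.volume import Volume3D


def test_constant_slice_has_zero_rms():
    vol = Volume3D(np.full((2, 60, 60), 0.5), 3.1)
    rmap = rms_map(vol, window_side=30)
    assert np.all(rmap.values == 0)


def test_iid_gaussian_noise_rms_matches_population_sd():
    rng = np.random.default_rng(0)
    sigma = 0.01
    vol = Volume3D(0.5 + rng.normal(0, sigma, (4, 300, 300)), 3.1)
    rmap = rms_map(vol, window_side=30)
    vals = rmap.finite_values()
    assert vals.mean() == pytest.approx(sigma, rel=0.02)
    # spread of the window RMS follows the chi sampling law ~ sigma/sqrt(2(n-1))
    assert vals.std() == pytest.approx(sigma / np.sqrt(2 * (900 - 1)), rel=0.25)


def test_fully_excluded_window_is_undefined():
    vol = Volume3D(np.zeros((1, 60, 60)), 3.1)
    excl = np.zeros((1, 60, 60), bool)
    excl[0, :30, :30] = True
    rmap = rms_map(vol, excl, window_side=30)
    assert np.isnan(rmap.values[0, 0, 0])
    assert np.isfinite(rmap.values[0, 1, 1])


def test_window_larger_than_slice_fails():
    vol = Volume3D(np.zeros((1, 20, 20)), 3.1)
    with pytest.raises(ValueError):
        rms_map(vol, window_side=30)


def test_rms_offset_invariance_and_linear_scaling():
    rng = np.random.default_rng(1)
    base = rng.normal(0.5, 0.01, (2, 90, 90))
    a = rms_map(Volume3D(base, 3.1)).values
    b = rms_map(Volume3D(base + 0.2, 3.1)).values
    c = rms_map(Volume3D(base * 3.0, 3.1)).values
    assert np.allclose(a, b, atol=1e-12)
    assert np.allclose(c, 3.0 * a, rtol=1e-9)


def test_class_stats_degenerate_and_underpopulated():
    stats = class_stats({"healthy": np.full(40, 0.004)})
    assert stats["healthy"].mean == pytest.approx(0.004)
    assert stats["healthy"].sd == 0.0
    assert stats["healthy"].band == (0.004, 0.004)
    with pytest.raises(ValueError, match="metastatic"):
        class_stats({"metastatic": np.arange(5)})


def _two_class_stats(mh=0.004, sh=0.0005, mm=0.010, sm=0.001):
    return {"healthy": ClassStats("healthy", mh, sh),
            "metastatic": ClassStats("metastatic", mm, sm)}


def _classify_values(values, stats):
    rmap = RMSMap(values=np.asarray(values, float).reshape(1, 1, -1),
                  window_side=30, stride=30, voxel_size=3.1)
    return classify_tissue(rmap, stats).labels.ravel()


def test_value_at_healthy_mean_is_healthy():
    labels = _classify_values([0.004], _two_class_stats())
    assert labels[0] == LABELS["healthy"]


def test_value_outside_both_bands_is_unclassified():
    labels = _classify_values([0.02, 0.0001], _two_class_stats())
    assert np.all(labels == LABELS["unclassified"])


def test_undefined_windows_are_excluded():
    labels = _classify_values([np.nan], _two_class_stats())
    assert labels[0] == LABELS["excluded"]


@settings(deadline=None, max_examples=60, derandomize=True)
@given(st.floats(0.0005, 0.02))
def test_band_rule_matches_bruteforce_reference(v):
    """Overlapping-band tie-break: nearest mean in SD units wins."""
    stats = _two_class_stats(mh=0.006, sh=0.003, mm=0.010, sm=0.004)
    h, m = stats["healthy"], stats["metastatic"]
    in_h = h.band[0] <= v <= h.band[1]
    in_m = m.band[0] <= v <= m.band[1]
    if in_h and in_m:
        zh, zm = abs(v - h.mean) / h.sd, abs(v - m.mean) / m.sd
        expect = (LABELS["healthy"] if zh < zm
                  else LABELS["metastatic"] if zm < zh
                  else LABELS["unclassified"])
    elif in_h:
        expect = LABELS["healthy"]
    elif in_m:
        expect = LABELS["metastatic"]
    else:
        expect = LABELS["unclassified"]
    assert _classify_values([v], stats)[0] == expect


def test_class_fractions_definition_and_exact_sum():
    vals = [0.004] * 30 + [0.010] * 10 + [0.05] * 60
    labels = _classify_values(vals, _two_class_stats())
    from hepavasc.texture import TissueClassMap

    frac = class_fractions(TissueClassMap(labels=labels, window_side=30,
                                          stride=30))
    assert frac["healthy"] == pytest.approx(75.0)
    assert frac["metastatic"] == pytest.approx(25.0)
    assert frac["healthy"] + frac["metastatic"] == 100.0


def test_class_fractions_without_classified_pixels_fails():
    from hepavasc.texture import TissueClassMap

    labels = np.full((1, 2, 2), LABELS["unclassified"], dtype=np.int8)
    with pytest.raises(ValueError):
        class_fractions(TissueClassMap(labels=labels, window_side=30, stride=30))
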