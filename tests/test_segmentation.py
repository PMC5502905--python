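"""Tests for dual-threshold voxel classification and area bookkeeping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import plaquemap as pm
from plaquemap.relaxometry import T2Map
from plaquemap.segmentation import (CLASS_INVALID, CLASS_LRNC_IPH,
                                    CLASS_LRNC_SHORT, CLASS_OTHER,
                                    CLASS_OUTSIDE, ThresholdPair, WallROI,
                                    classify_voxels, filter_quality,
                                    measure_slice, rasterize_contours,
                                    summarize_plaque)
from plaquemap.phantom import make_tissue_map, simulate_echo_series, wall_roi_from_config
from plaquemap.relaxometry import fit_slice


def _toy_map(t2_grid, valid=None):
    t2 = np.asarray(t2_grid, dtype=float)
    valid = np.ones_like(t2, dtype=bool) if valid is None else valid
    return T2Map(t2=t2, s0=np.ones_like(t2), rsq=np.ones_like(t2),
                 valid=valid, reason=np.zeros(t2.shape, dtype=np.uint8))


def _full_roi(shape, voxel_area=1.0):
    return WallROI(lumen_mask=np.zeros(shape, dtype=bool),
                   outer_mask=np.ones(shape, dtype=bool), voxel_area=voxel_area)


@pytest.mark.parametrize("t2, mode, expected", [
    (30.0, "dual", CLASS_LRNC_SHORT),     # short T2 -> lipid core
    (42.0, "dual", CLASS_OTHER),          # boundary excluded (strict 'below')
    (90.0, "dual", CLASS_OTHER),          # boundary excluded (strict 'above')
    (100.0, "dual", CLASS_LRNC_IPH),      # long T2 -> hemorrhage core
    (100.0, "single_low", CLASS_OTHER),   # single-threshold mode ignores t2h
    (30.0, "single_low", CLASS_LRNC_SHORT),
])
def test_classification_rules(t2, mode, expected):
    m = _toy_map([[t2]])
    cls = classify_voxels(m, _full_roi((1, 1)), ThresholdPair(42.0, 90.0), mode=mode)
    assert cls[0, 0] == expected


def test_invalid_and_outside_voxels():
    m = _toy_map([[30.0, 30.0]], valid=np.array([[True, False]]))
    roi = WallROI(lumen_mask=np.zeros((1, 2), dtype=bool),
                  outer_mask=np.array([[True, True]]))
    cls = classify_voxels(m, roi, ThresholdPair(42.0, 90.0))
    assert cls[0, 0] == CLASS_LRNC_SHORT and cls[0, 1] == CLASS_INVALID
    roi2 = WallROI(lumen_mask=np.zeros((1, 2), dtype=bool),
                   outer_mask=np.array([[True, False]]))
    assert classify_voxels(m, roi2, ThresholdPair(42, 90))[0, 1] == CLASS_OUTSIDE


def test_measure_slice_arithmetic():
    """25 core voxels of 100 wall voxels is 25.0%."""
    cls = np.full((10, 10), CLASS_OTHER, dtype=np.uint8)
    cls.ravel()[:20] = CLASS_LRNC_SHORT
    cls.ravel()[20:25] = CLASS_LRNC_IPH
    m = measure_slice(cls, _full_roi((10, 10), voxel_area=0.5))
    assert m.lipid_area_pct == pytest.approx(25.0)
    assert m.iph_area_pct == pytest.approx(5.0)
    assert m.wall_area_mm2 == pytest.approx(50.0)
    # hemorrhage at exactly the 5% rule is NOT significant (strict >)
    assert m.significant_iph is False


def test_measure_slice_matches_bruteforce_count():
    rng = np.random.default_rng(0)
    cls = rng.integers(0, 5, size=(30, 30)).astype(np.uint8)
    outer = cls != CLASS_OUTSIDE
    roi = WallROI(lumen_mask=np.zeros_like(outer), outer_mask=outer)
    m = measure_slice(cls, roi)
    wall = int(outer.sum())
    n_inv = int((cls == CLASS_INVALID).sum())
    n_core = sum(1 for v in cls.ravel()
                 if v in (CLASS_LRNC_SHORT, CLASS_LRNC_IPH))
    assert m.lipid_area_pct == pytest.approx(100.0 * n_core / (wall - n_inv))


def test_measure_empty_wall_raises():
    cls = np.zeros((4, 4), dtype=np.uint8)
    roi = WallROI(lumen_mask=np.zeros((4, 4), dtype=bool),
                  outer_mask=np.zeros((4, 4), dtype=bool))
    with pytest.raises(ValueError, match="empty wall"):
        measure_slice(cls, roi)


@given(st.integers(0, 2 ** 31 - 1))
def test_partition_property(seed):
    """Core + other + invalid classes always partition the wall exactly."""
    rng = np.random.default_rng(seed)
    t2 = rng.uniform(1, 150, (16, 16))
    valid = rng.uniform(size=(16, 16)) > 0.1
    outer = rng.uniform(size=(16, 16)) > 0.3
    lumen = outer & (rng.uniform(size=(16, 16)) > 0.8)
    roi = WallROI(lumen_mask=lumen, outer_mask=outer)
    cls = classify_voxels(_toy_map(t2, valid), roi, ThresholdPair(42, 90))
    wall = roi.wall_mask.sum()
    counted = sum((cls == c).sum() for c in
                  (CLASS_OTHER, CLASS_LRNC_SHORT, CLASS_LRNC_IPH, CLASS_INVALID))
    assert counted == wall


def test_dual_mode_never_below_single_low():
    rng = np.random.default_rng(1)
    for _ in range(20):
        t2 = rng.uniform(1, 150, (12, 12))
        roi = _full_roi((12, 12))
        m = _toy_map(t2)
        dual = measure_slice(classify_voxels(m, roi, ThresholdPair(42, 90), "dual"), roi)
        single = measure_slice(classify_voxels(m, roi, ThresholdPair(42, 90), "single_low"), roi)
        assert dual.lipid_area_pct >= single.lipid_area_pct


def test_threshold_monotonicity():
    rng = np.random.default_rng(2)
    t2 = rng.uniform(1, 150, (20, 20))
    roi = _full_roi((20, 20))
    m = _toy_map(t2)

    def lipid(t2l, t2h):
        return measure_slice(classify_voxels(m, roi, ThresholdPair(t2l, t2h)), roi).lipid_area_pct

    # lowering t2l never increases lipid %; raising t2h never increases it
    for lo, hi in [(30, 42), (35, 50)]:
        assert lipid(lo, 90) <= lipid(hi, 90)
    for lo, hi in [(80, 90), (90, 110)]:
        assert lipid(42, hi) <= lipid(42, lo)


def test_noiseless_phantom_measures_constructed_fraction(noiseless_config):
    tissue = make_tissue_map(noiseless_config, 22.0, 6.0, seed=3)
    roi = wall_roi_from_config(noiseless_config)
    series = simulate_echo_series(tissue, noiseless_config)
    t2map = fit_slice(series, roi)
    cls = classify_voxels(t2map, roi, ThresholdPair(42.0, 90.0))
    m = measure_slice(cls, roi)
    n_wall = roi.wall_mask.sum()
    assert abs(m.lipid_area_pct - tissue.fraction("lipid", "iph")) <= 100.0 / n_wall


def test_summarize_plaque():
    def sm(lipid, area, pid="P0"):
        return pm.SliceMeasurement(plaque_id=pid, slice_index=0,
                                   lipid_area_pct=lipid, iph_area_pct=0.0,
                                   wall_area_mm2=area, significant_iph=False)

    one = summarize_plaque([sm(20.0, 50.0)], slice_thickness=2.0)
    assert one.mean_lipid_area_pct == 20.0
    two = summarize_plaque([sm(10.0, 50.0), sm(30.0, 50.0)], slice_thickness=2.0)
    assert two.mean_lipid_area_pct == pytest.approx(20.0)
    vol = summarize_plaque([sm(0, 50.0), sm(0, 60.0), sm(0, 70.0)], slice_thickness=2.0)
    assert vol.volume_mm3 == pytest.approx(360.0)
    weighted = summarize_plaque([sm(10.0, 10.0), sm(30.0, 90.0)],
                                slice_thickness=2.0, area_weighted=True)
    assert weighted.mean_lipid_area_pct == pytest.approx(28.0)
    with pytest.raises(ValueError, match="mixed"):
        summarize_plaque([sm(10, 50, "P0"), sm(10, 50, "P1")], slice_thickness=2.0)
    with pytest.raises(ValueError, match="at least one"):
        summarize_plaque([], slice_thickness=2.0)


def test_quality_filter():
    df = pd.DataFrame({"quality": [2, 3, 4], "x": list("abc")})
    kept, excluded = filter_quality(df)
    assert list(kept["quality"]) == [3, 4] and excluded == 1
    # study-scale scenario: 26 of 40 pass
    rng = np.random.default_rng(0)
    scores = np.r_[rng.integers(3, 6, 26), rng.integers(1, 3, 14)]
    kept, excluded = filter_quality(pd.DataFrame({"quality": scores}))
    assert len(kept) == 26 and excluded == 14
    all5, excl = filter_quality(pd.DataFrame({"quality": [5, 5, 5]}))
    assert len(all5) == 3 and excl == 0
    with pytest.raises(ValueError, match="1-5"):
        filter_quality(pd.DataFrame({"quality": [0, 3]}))


def test_wall_roi_validation():
    with pytest.raises(ValueError, match="inside"):
        WallROI(lumen_mask=np.array([[True, False]]),
                outer_mask=np.array([[False, True]]))


def test_rasterize_circular_contours():
    theta = np.linspace(0, 2 * np.pi, 200, endpoint=False)
    outer = np.column_stack([16 + 10 * np.cos(theta), 16 + 10 * np.sin(theta)])
    lumen = np.column_stack([16 + 4 * np.cos(theta), 16 + 4 * np.sin(theta)])
    roi = rasterize_contours(lumen, outer, (32, 32), voxel_area=1.0)
    assert roi.wall_mask.sum() == pytest.approx(np.pi * (10 ** 2 - 4 ** 2), rel=0.06)
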