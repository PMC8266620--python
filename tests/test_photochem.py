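"""First-order photolysis, illumination profile, stray-dose accounting."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import maskless as mk
from maskless.layout import generate_masks
from maskless.photochem import (DEFAULT_GLOBAL_SCATTER, PhotochemParams,
                                calibrate_global_scatter,
                                calibrate_photolysis_rate,
                                illumination_factor, photolysis_yield,
                                scale_insertion_rate, stray_dose)


def test_calibration_closed_form():
    k = calibrate_photolysis_rate(0.95, 3.0)
    assert k == pytest.approx(-math.log(0.05) / 3.0)
    assert k == pytest.approx(0.9986, abs=5e-5)


def test_calibration_rejects_degenerate_yield():
    with pytest.raises(ValueError):
        calibrate_photolysis_rate(0.0, 3.0)
    with pytest.raises(ValueError):
        calibrate_photolysis_rate(1.0, 3.0)
    # yield -> 0 limit gives k -> 0
    assert calibrate_photolysis_rate(1e-9, 3.0) == pytest.approx(0.0, abs=1e-9)


@given(st.floats(0.01, 0.99), st.floats(0.1, 10.0))
@settings(deadline=None)
def test_calibration_round_trip(yield_, exposure):
    k = calibrate_photolysis_rate(yield_, exposure)
    assert photolysis_yield(exposure, k) == pytest.approx(yield_, abs=1e-12)


def test_yield_doubling_exposure_reaches_99_7_percent():
    k = calibrate_photolysis_rate(0.95, 3.0)
    assert photolysis_yield(0.0, k) == 0.0
    assert photolysis_yield(6.0, k) == pytest.approx(0.9975, abs=5e-5)


@given(st.floats(0.05, 0.99), st.floats(0.1, 6.0), st.integers(2, 7))
@settings(deadline=None)
def test_yield_invariant_under_exposure_splitting(yield_, exposure, n):
    """n sub-exposures of E/n deprotect exactly like one exposure of E."""
    k = calibrate_photolysis_rate(yield_, 3.0)
    whole = photolysis_yield(exposure, k)
    left = 1.0
    for _ in range(n):
        left *= 1.0 - photolysis_yield(exposure / n, k)
    assert 1.0 - left == pytest.approx(whole, rel=1e-12)


@pytest.fixture(scope="module")
def grid_layout():
    return mk.build_layout("2SZ", mk.DmdGeometry(rows=90, cols=90))


def test_illumination_profile_geometry(grid_layout):
    lay = grid_layout
    params = PhotochemParams(edge_falloff_amplitude=0.1)
    center = min(lay.features,
                 key=lambda f: lay.normalized_center_distance(f.feature_id,
                                                              "euclid"))
    corner = lay.features[0]
    # an edge-midpoint feature: first cell row, middle column
    edge = next(f for f, (cr, cc) in zip(lay.features, lay.cell_coords)
                if cr == 0 and cc == 7)
    fc = illumination_factor(lay, center.feature_id, params)
    fe = illumination_factor(lay, edge.feature_id, params)
    fk = illumination_factor(lay, corner.feature_id, params)
    assert fk < fe < fc <= 1.0
    flat = PhotochemParams(edge_falloff_amplitude=0.0)
    assert all(illumination_factor(lay, f.feature_id, flat) == 1.0
               for f in lay.features[:10])


def _two_feature_setup():
    # F0 couples A in cycle 0, F1 couples T in cycle 3; cycles 1-2 are empty
    ids = ["o0", "o1"]
    lay = mk.build_layout("2SZ", mk.DmdGeometry(rows=6, cols=12),
                          n_features=2, oligo_ids=ids, seed=0)
    seqs = {lay.oligo_of("F0"): "A", lay.oligo_of("F1"): "T"}
    stack = generate_masks(lay, seqs)
    return lay, stack


def test_stray_dose_formula_and_linearity():
    lay, stack = _two_feature_setup()
    g = 0.01
    params = PhotochemParams(global_scatter_coeff=g, side_leak=0.0,
                             corner_leak=0.0, edge_falloff_amplitude=0.0)
    # cycle 0 (base A): F0 is ON, F1 OFF; f_ON = 16/72
    f_on = stack.on_mirror_fraction(0)
    assert f_on == pytest.approx(16 / 72)
    dose = stray_dose(lay, stack, 0, "F1", params)
    assert dose == pytest.approx(3.0 * g * f_on)
    # linearity: doubling g doubles the global-scatter dose
    params2 = PhotochemParams(global_scatter_coeff=2 * g, side_leak=0.0,
                              corner_leak=0.0, edge_falloff_amplitude=0.0)
    assert stray_dose(lay, stack, 0, "F1", params2) == pytest.approx(2 * dose)


def test_stray_dose_side_neighbor_term():
    lay, stack = _two_feature_setup()
    params = PhotochemParams(global_scatter_coeff=0.0, side_leak=0.005,
                             corner_leak=0.0, edge_falloff_amplitude=0.0)
    # F0 (ON in cycle 0) is the single side neighbor of F1
    assert stray_dose(lay, stack, 0, "F1", params) == \
        pytest.approx(3.0 * 0.005 * 1 / 4)


def test_stray_dose_zero_on_empty_cycle():
    lay, stack = _two_feature_setup()
    params = PhotochemParams(edge_falloff_amplitude=0.0)
    # cycle 1 (base C): nothing couples, mask empty
    assert stack.cycles[1][2] == frozenset()
    assert stray_dose(lay, stack, 1, "F0", params) == 0.0


def test_stray_dose_undefined_for_on_feature():
    lay, stack = _two_feature_setup()
    params = PhotochemParams()
    with pytest.raises(ValueError, match="ON"):
        stray_dose(lay, stack, 0, "F0", params)


def test_reflection_region_dose():
    lay, stack = _two_feature_setup()
    params = PhotochemParams(global_scatter_coeff=0.0, side_leak=0.0,
                             corner_leak=0.0, edge_falloff_amplitude=0.0,
                             reflection_enabled=True,
                             reflection_extra_dose=0.01,
                             reflection_region=(0, 6, 6, 12))
    # F1 sits in the region, F0 does not
    assert stray_dose(lay, stack, 0, "F1", params) == pytest.approx(0.03)
    assert stray_dose(lay, stack, 1, "F0", params) == 0.0


def test_scatter_calibration_and_density_scaling():
    g = calibrate_global_scatter(0.006)
    assert g == pytest.approx(DEFAULT_GLOBAL_SCATTER)
    assert 0.0 < g < 0.01
    # 0.6%/bp at 44% density extrapolates to ~0.68% at 50%
    assert scale_insertion_rate(0.6, 44.0, 50.0) == pytest.approx(0.6818, abs=1e-3)


def test_insertion_pressure_scales_with_mirror_density(panel100):
    """2SZ (44% active) vs 4SZ (11%): insertion rates ~4x apart under pure
    global scatter."""
    from conftest import PERFECT_COUPLING, quick_sim
    photo = mk.PhotochemParams(side_leak=0.0, corner_leak=0.0,
                               edge_falloff_amplitude=0.0)
    kw = {"coupling_efficiency": PERFECT_COUPLING}
    _, _, em2 = quick_sim(panel100, design="2SZ", n_features=225,
                          molecules=60, photo=photo, chem_kw=kw, seed=9)
    _, _, em4 = quick_sim(panel100, design="4SZ", n_features=225,
                          molecules=60, photo=photo, chem_kw=kw, seed=9)
    r2 = mk.per_bp_rates(em2).insertion
    r4 = mk.per_bp_rates(em4).insertion
    assert r2 > r4 > 0
    assert r2 / r4 == pytest.approx(4.0, rel=0.3)


def test_reflection_raises_insertions_only_inside_region(panel100):
    from conftest import PERFECT_COUPLING, quick_sim
    photo = mk.PhotochemParams(
        global_scatter_coeff=0.0, side_leak=0.0, corner_leak=0.0,
        edge_falloff_amplitude=0.0, reflection_enabled=True,
        reflection_extra_dose=0.003, reflection_region=(0, 60, 30, 90))
    lay, _, em = quick_sim(panel100, n_features=225, molecules=60,
                           photo=photo,
                           chem_kw={"coupling_efficiency": PERFECT_COUPLING},
                           seed=10)
    sm = mk.feature_profiles(em, lay)
    inside = sm[(sm.row < 30) & (sm.col >= 60)]
    outside = sm[~((sm.row < 30) & (sm.col >= 60))]
    ri = 100 * inside.n_insertions.sum() / inside.n_ref_bases.sum()
    ro = 100 * outside.n_insertions.sum() / outside.n_ref_bases.sum()
    assert ri > 10 * ro
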