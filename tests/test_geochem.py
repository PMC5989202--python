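"""Unit and property tests for the pore-water/solid-phase computations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from omzsed import geochem
from omzsed.geochem import (CoreProfile, FluxParameters,
                            InsufficientDataError, ValidationError)


# ---------------------------------------------------------------------------
# solid phase
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("tc,tic,expected", [
    (2.5, 1.0, 1.5),
    (1.0, 1.0, 0.0),
    (5.0, 0.0, 5.0),
])
def test_toc_is_tc_minus_tic(tc, tic, expected):
    assert geochem.compute_toc(tc, tic) == pytest.approx(expected)


def test_toc_rejects_tic_above_tc():
    with pytest.raises(ValidationError):
        geochem.compute_toc(1.0, 1.2)


@pytest.mark.parametrize("toc,tn,expected", [
    (1.2, 0.1, (1.2 / 12.011) / (0.1 / 14.007)),  # ~13.996
    (1.0, 1.0, 14.007 / 12.011),                  # ~1.1662
    (0.0, 0.1, 0.0),
])
def test_molar_toc_tn_ratio(toc, tn, expected):
    assert geochem.toc_tn_molar(toc, tn) == pytest.approx(expected, rel=1e-12)


def test_molar_ratio_undefined_for_zero_tn():
    with pytest.raises(ValidationError):
        geochem.toc_tn_molar(1.0, 0.0)


@pytest.mark.parametrize("pw,wet,expected", [(40, 100, 40.0), (0, 100, 0.0),
                                             (100, 100, 100.0)])
def test_porosity_percent(pw, wet, expected):
    assert geochem.compute_porosity(pw, wet) == pytest.approx(expected)


def test_porosity_rejects_porewater_exceeding_wet_volume():
    with pytest.raises(ValidationError):
        geochem.compute_porosity(101, 100)


# ---------------------------------------------------------------------------
# sulfate gradient
# ---------------------------------------------------------------------------

def _linear_profile(top=28.0, gradient=0.1, depths=None):
    depths = np.arange(7.5, 270, 15.0) if depths is None else depths
    return CoreProfile("lin", depths, sulfate=top - gradient * depths)


def test_gradient_exact_on_noiseless_line():
    grad = geochem.estimate_sulfate_gradient(_linear_profile(gradient=0.1))
    assert grad.dcdx == pytest.approx(0.1, abs=1e-12)
    assert grad.slope == pytest.approx(-0.1, abs=1e-12)
    assert grad.stderr == pytest.approx(0.0, abs=1e-10)


def test_gradient_zero_on_constant_profile():
    depths = np.arange(0, 100, 10.0)
    profile = CoreProfile("const", depths, sulfate=np.full(10, 28.0))
    grad = geochem.estimate_sulfate_gradient(profile)
    assert grad.dcdx == 0.0


def test_gradient_respects_window():
    depths = np.arange(0.0, 300.0, 15.0)
    so4 = np.where(depths <= 150, 28.0 - 0.1 * depths, 13.0)
    profile = CoreProfile("kink", depths, sulfate=so4)
    grad = geochem.estimate_sulfate_gradient(profile, window=(0, 150))
    assert grad.dcdx == pytest.approx(0.1, abs=1e-12)
    assert grad.fit_window == (0.0, 150.0)


def test_gradient_needs_three_points():
    profile = CoreProfile("tiny", [0.0, 15.0], sulfate=[28.0, 26.0])
    with pytest.raises(InsufficientDataError):
        geochem.estimate_sulfate_gradient(profile)


def test_gradient_unbiased_over_noisy_replicates():
    """OLS slope mean over noisy replicates is within 2 SE of the truth."""
    depths = np.arange(7.5, 300, 15.0)
    truth = 0.05
    slopes = []
    for seed in range(200):
        rng = np.random.default_rng(seed)
        so4 = np.maximum(28.0 - truth * depths + rng.normal(0, 0.3,
                                                            depths.size), 0)
        grad = geochem.estimate_sulfate_gradient(
            CoreProfile("n", depths, sulfate=so4))
        slopes.append(grad.dcdx)
    mean = np.mean(slopes)
    se = np.std(slopes, ddof=1) / math.sqrt(len(slopes))
    assert abs(mean - truth) < 2 * se + 1e-4


# ---------------------------------------------------------------------------
# diffusivities and flux
# ---------------------------------------------------------------------------

def test_do_constant_when_slope_zero():
    p = FluxParameters(porosity=0.7, bottom_water_temp=10.0,
                       do_intercept=5e-6, do_slope=0.0)
    assert geochem.seawater_diffusivity(3.0, p) == pytest.approx(5e-6)
    assert geochem.seawater_diffusivity(25.0, p) == pytest.approx(5e-6)


def test_do_increases_with_temperature():
    p = FluxParameters(porosity=0.7, bottom_water_temp=10.0)
    assert geochem.seawater_diffusivity(5.0, p) < \
        geochem.seawater_diffusivity(15.0, p)


def test_do_default_coefficients_linear_in_t():
    p = FluxParameters(porosity=0.7, bottom_water_temp=10.0)
    expected = geochem.DEFAULT_DO_INTERCEPT + 10.0 * geochem.DEFAULT_DO_SLOPE
    assert geochem.seawater_diffusivity(10.0, p) == pytest.approx(
        expected, rel=1e-15)


def test_do_out_of_range_raises_when_strict():
    p = FluxParameters(porosity=0.7, bottom_water_temp=10.0)
    with pytest.raises(ValidationError):
        geochem.seawater_diffusivity(-5.0, p)


@pytest.mark.parametrize("phi,n,factor", [
    (1.0, 3.0, 1.0),     # no particles
    (0.5, 3.0, 2.5),     # direct substitution
    (0.3, 0.0, 1.0),     # no tortuosity correction
])
def test_tortuosity_correction(phi, n, factor):
    do = 7.0e-6
    assert geochem.tortuosity_corrected_diffusivity(do, phi, n) == \
        pytest.approx(do / factor, rel=1e-15)


def test_flux_worked_example():
    """phi=0.75, Ds=5e-6 cm2/s, dC/dX=0.05 mM/cm -> 5.913e-3 mmol/cm2/yr."""
    j = geochem.sulfate_flux(0.75, 5.0e-6, 0.05)
    assert j == pytest.approx(5.913e-3, rel=1e-12)


def test_flux_zero_and_linear():
    assert geochem.sulfate_flux(0.0, 5e-6, 0.05) == 0.0
    assert geochem.sulfate_flux(0.75, 5e-6, 0.0) == 0.0
    j1 = geochem.sulfate_flux(0.75, 5e-6, 0.05)
    assert geochem.sulfate_flux(0.75, 5e-6, 0.10) == pytest.approx(2 * j1)


@settings(max_examples=200, derandomize=True, deadline=None)
@given(phi=st.floats(0.01, 1.0), n=st.floats(0.0, 5.0),
       t=st.floats(0.0, 30.0), dcdx=st.floats(0.0, 0.2))
def test_flux_chain_matches_closed_form(phi, n, t, dcdx):
    """Pipeline J equals the single-expression closed form to 1e-12 rel."""
    params = FluxParameters(porosity=phi, bottom_water_temp=t,
                            tortuosity_exponent=n)
    do = geochem.seawater_diffusivity(t, params)
    ds = geochem.tortuosity_corrected_diffusivity(do, phi, n)
    j = geochem.sulfate_flux(phi, ds, dcdx)
    closed = phi * do / (1.0 + n * (1.0 - phi)) * (dcdx * 1e-3) * 3.1536e7
    assert j == pytest.approx(closed, rel=1e-12, abs=1e-300)
    assert 0.0 < ds / do <= 1.0


def test_compute_flux_respects_invariant_and_flags_positive_slope():
    depths = np.arange(7.5, 300, 15.0)
    profile = CoreProfile("inv", depths, sulfate=20.0 + 0.01 * depths)
    params = FluxParameters(porosity=0.7, bottom_water_temp=10.0)
    res = geochem.compute_flux(profile, params)
    assert res.anomalous_positive_slope
    assert res.ds <= res.do
    assert res.flux == pytest.approx(
        0.7 * res.ds * res.gradient.dcdx * 1e-3 * 3.1536e7, rel=1e-14)


# ---------------------------------------------------------------------------
# isotope offsets
# ---------------------------------------------------------------------------

def test_isotope_offset_series_and_summary():
    profile = CoreProfile(
        "iso", [10.0, 20.0],
        d34s_so4=[30.0, 51.0], d34s_hs=[8.0, -8.8],
    )
    res = geochem.sulfur_isotope_offset(profile)
    assert res.offsets == pytest.approx([22.0, 59.8])
    assert res.mean == pytest.approx(40.9)


def test_isotope_offset_skips_incomplete_pairs():
    profile = CoreProfile(
        "iso", [10.0, 20.0, 30.0],
        d34s_so4=[30.0, 31.0, 32.0],
        d34s_hs=[8.0, np.nan, 10.0],
    )
    res = geochem.sulfur_isotope_offset(profile)
    assert res.n_skipped == 1
    assert res.offsets == pytest.approx([22.0, 22.0])


def test_isotope_offset_zero_for_equal_inputs():
    profile = CoreProfile("iso", [10.0], d34s_so4=[25.0], d34s_hs=[25.0])
    assert geochem.sulfur_isotope_offset(profile).offsets[0] == 0.0


# ---------------------------------------------------------------------------
# SMTZ detection
# ---------------------------------------------------------------------------

def _smtz_profile(cross_depth=260.0, depths=None):
    depths = np.arange(7.5, 300, 15.0) if depths is None else depths
    g = 27.0 / cross_depth
    so4 = np.maximum(28.0 - g * depths, 0.0)
    ch4 = 0.002 + 1.5 / (1.0 + np.exp(-(depths - cross_depth) / 7.5))
    return CoreProfile("smtz", depths, sulfate=so4, ch4=ch4)


def test_smtz_bracket_contains_crossing():
    est = geochem.detect_smtz(_smtz_profile(260.0))
    assert est.found
    assert est.upper_depth < 260.0 < est.lower_depth + 15.0
    assert est.lower_depth - est.upper_depth == pytest.approx(15.0)


def test_smtz_none_when_sulfate_never_depleted():
    depths = np.arange(7.5, 300, 15.0)
    profile = CoreProfile("rich", depths,
                          sulfate=np.full(depths.size, 25.0),
                          ch4=np.full(depths.size, 1.0))
    est = geochem.detect_smtz(profile)
    assert not est.found and est.applicable


def test_smtz_interval_starts_at_first_depth_when_depleted_from_surface():
    depths = np.arange(7.5, 300, 15.0)
    ch4 = np.full(depths.size, 5.0)
    ch4[:3] = 0.001  # shallow baseline stays low
    profile = CoreProfile("shallow", depths,
                          sulfate=np.full(depths.size, 0.2), ch4=ch4)
    est = geochem.detect_smtz(profile, shallow_fraction=0.1)
    assert est.found
    assert est.upper_depth == depths[3 - 1] or est.upper_depth == depths[0]


def test_smtz_not_applicable_without_methane():
    depths = np.arange(7.5, 300, 15.0)
    profile = CoreProfile("noch4", depths,
                          sulfate=np.maximum(28 - 0.1 * depths, 0))
    est = geochem.detect_smtz(profile)
    assert not est.applicable and "methane" in est.reason


# ---------------------------------------------------------------------------
# profile validation
# ---------------------------------------------------------------------------

def test_profile_rejects_nonmonotone_depths():
    with pytest.raises(ValidationError):
        CoreProfile("bad", [0.0, 15.0, 15.0], sulfate=[28, 27, 26])


def test_profile_rejects_negative_concentrations():
    with pytest.raises(ValidationError):
        CoreProfile("neg", [0.0, 15.0], sulfate=[28.0, -1.0])
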