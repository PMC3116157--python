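"""Closed-form LEM thermodynamics: free energies, populations, observables."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import moltenfit as mf
from moltenfit.models import GAS_CONSTANT_KCAL, DEFAULT_TEMPERATURE_K

RT = GAS_CONSTANT_KCAL * DEFAULT_TEMPERATURE_K


@pytest.mark.parametrize("dg0, m, conc, expected", [
    (5.7, 6.3, 0.0, 5.7),           # dG in water
    (5.7, 6.3, 5.7 / 6.3, 0.0),     # midpoint by construction
    (7.8, 3.9, 1.0, 3.9),           # direct arithmetic
])
def test_delta_g_is_linear_in_denaturant(dg0, m, conc, expected):
    t = mf.TransitionThermo(dg0, m)
    assert mf.delta_g_at_denaturant(t, conc) == pytest.approx(expected)


def test_delta_g_rejects_negative_concentration():
    with pytest.raises(ValueError):
        mf.delta_g_at_denaturant(mf.TransitionThermo(5.0, 3.0), -0.1)


@pytest.mark.parametrize("dg, expected", [
    (0.0, 1.0),
    (5.7, math.exp(-5.7 / RT)),      # ~6.635e-5
    (-RT * math.log(2.0), 2.0),      # constructed inverse
])
def test_equilibrium_constant(dg, expected):
    assert mf.equilibrium_constant(dg) == pytest.approx(expected, rel=1e-12)


def test_equilibrium_constant_clamps_and_warns():
    with pytest.warns(RuntimeWarning):
        k = mf.equilibrium_constant(1000.0)  # |dG/RT| >> clamp
    assert k == pytest.approx(math.exp(-700.0))


def test_state_fractions_three_state_at_zero_denaturant(pwt_params):
    # frozen oracle: K1 = exp(-5.7/RT), K2 = exp(-7.8/RT), Z = 1+K1+K1K2
    fr = mf.state_fractions_three_state(pwt_params, 0.0)
    assert fr.f_n == pytest.approx(0.9999336497630389, rel=1e-12)
    assert fr.f_i == pytest.approx(6.635010978606922e-05, rel=1e-12)
    assert fr.f_u == pytest.approx(1.271748475802709e-10, rel=1e-12)


def test_equal_populations_at_ni_midpoint_with_stable_iu():
    p = mf.ThreeStateParams(ni=mf.TransitionThermo(6.0, 6.0),
                            iu=mf.TransitionThermo(20.0, 1.0),
                            baseline_n=336, baseline_i=341, baseline_u=355)
    fr = mf.state_fractions_three_state(p, 1.0)  # dG_NI = 0, dG_IU >> RT
    assert fr.f_n == pytest.approx(fr.f_i, rel=1e-6)


def test_two_state_fractions():
    p = mf.TwoStateParams(nu=mf.TransitionThermo(13.5, 10.2),
                          baseline_n=336, baseline_u=355)
    fr0 = mf.state_fractions_two_state(p, 0.0)
    assert fr0.f_u == pytest.approx(1.271832862052738e-10, rel=1e-9)
    assert fr0.f_i == 0.0
    fr_mid = mf.state_fractions_two_state(p, 13.5 / 10.2)
    assert fr_mid.f_n == pytest.approx(0.5, abs=1e-12)
    assert fr_mid.f_u == pytest.approx(0.5, abs=1e-12)


def test_predicted_signal_weighted_sum(pwt_params):
    assert mf.predicted_signal(pwt_params, 0.0) == pytest.approx(
        336.0003317529652, abs=1e-8)
    # f_u -> 1 at high denaturant
    assert mf.predicted_signal(pwt_params, 10.0) == pytest.approx(
        355.0, abs=1e-6)


def test_predicted_signal_degenerate_baselines(pwt_params):
    flat = mf.ThreeStateParams(ni=pwt_params.ni, iu=pwt_params.iu,
                               baseline_n=340, baseline_i=340,
                               baseline_u=340)
    for conc in (0.0, 0.9, 2.0, 3.0):
        assert mf.predicted_signal(flat, conc) == pytest.approx(340.0)


def test_predicted_signal_with_baseline_slopes():
    p = mf.TwoStateParams(nu=mf.TransitionThermo(50.0, 1.0),  # f_n ~ 1
                          baseline_n=336.0, baseline_u=355.0,
                          baseline_slope_n=0.5)
    assert mf.predicted_signal(p, 2.0) == pytest.approx(337.0, abs=1e-10)


@pytest.mark.parametrize("dg0, m, expected", [
    (5.7, 6.3, 5.7 / 6.3), (7.8, 3.9, 2.0), (0.0, 4.0, 0.0)])
def test_midpoint(dg0, m, expected):
    t = mf.TransitionThermo(dg0, m)
    assert mf.midpoint(t) == pytest.approx(expected)


def test_transition_thermo_rejects_nonpositive_m():
    with pytest.raises(ValueError):
        mf.TransitionThermo(5.0, 0.0)
    with pytest.raises(ValueError):
        mf.TransitionThermo(5.0, -1.0)


# ---------------------------------------------------------------------------
# property tests

thermo_st = st.tuples(st.floats(-5, 15), st.floats(0.5, 10))
conc_st = st.floats(0, 6)


@settings(derandomize=True, max_examples=200)
@given(ni=thermo_st, iu=thermo_st, conc=conc_st)
def test_fractions_normalize_and_match_boltzmann_oracle(ni, iu, conc):
    """Fractions sum to 1 and agree with direct Boltzmann weights."""
    p = mf.ThreeStateParams(ni=mf.TransitionThermo(*ni),
                            iu=mf.TransitionThermo(*iu),
                            baseline_n=336, baseline_i=341, baseline_u=355)
    fr = mf.state_fractions_three_state(p, conc)
    assert fr.f_n + fr.f_i + fr.f_u == pytest.approx(1.0, abs=1e-12)
    # independent oracle: unnormalised Boltzmann weights
    dg_ni = ni[0] - ni[1] * conc
    dg_iu = iu[0] - iu[1] * conc
    w = np.array([1.0, math.exp(-dg_ni / RT),
                  math.exp(-(dg_ni + dg_iu) / RT)])
    w /= w.sum()
    assert fr.f_n == pytest.approx(w[0], abs=1e-12)
    assert fr.f_i == pytest.approx(w[1], abs=1e-12)
    assert fr.f_u == pytest.approx(w[2], abs=1e-12)


@settings(derandomize=True, max_examples=50)
@given(ni=thermo_st, iu=thermo_st)
def test_fraction_monotonicity_and_intermediate_unimodality(ni, iu):
    """f_n non-increasing, f_u non-decreasing, f_i unimodal in denaturant."""
    p = mf.ThreeStateParams(ni=mf.TransitionThermo(*ni),
                            iu=mf.TransitionThermo(*iu),
                            baseline_n=336, baseline_i=341, baseline_u=355)
    grid = np.linspace(0, 8, 400)
    f = np.array([[*vars(mf.state_fractions_three_state(p, c)).values()]
                  for c in grid])
    fn, fi, fu = f[:, 0], f[:, 1], f[:, 2]
    assert np.all(np.diff(fn) <= 1e-12)
    assert np.all(np.diff(fu) >= -1e-12)
    # unimodal: signs of the finite-difference derivative switch at most once
    d = np.diff(fi)
    signs = np.sign(d[np.abs(d) > 1e-15])
    switches = np.count_nonzero(np.diff(signs) != 0)
    assert switches <= 1


@settings(derandomize=True, max_examples=100)
@given(ni=thermo_st, conc=conc_st)
def test_two_state_limit_of_three_state(ni, conc):
    """With dG_IU -> +inf (K2 -> 0) the three-state model degenerates to
    two-state on the N<->I transition."""
    p3 = mf.ThreeStateParams(ni=mf.TransitionThermo(*ni),
                             iu=mf.TransitionThermo(300.0, 0.1),
                             baseline_n=336, baseline_i=341, baseline_u=355)
    p2 = mf.TwoStateParams(nu=mf.TransitionThermo(*ni),
                           baseline_n=336, baseline_u=341)
    f3 = mf.state_fractions_three_state(p3, conc)
    f2 = mf.state_fractions_two_state(p2, conc)
    assert f3.f_n == pytest.approx(f2.f_n, abs=1e-9)
    assert f3.f_i == pytest.approx(f2.f_u, abs=1e-9)


@settings(derandomize=True, max_examples=100)
@given(ni=thermo_st, iu=thermo_st, conc=conc_st)
def test_lem_additivity(ni, iu, conc):
    """dG_NU(conc) = dG_NI(conc) + dG_IU(conc) exactly (linearity)."""
    t_ni = mf.TransitionThermo(*ni)
    t_iu = mf.TransitionThermo(*iu)
    t_nu = mf.TransitionThermo(ni[0] + iu[0], ni[1] + iu[1])
    assert mf.delta_g_at_denaturant(t_nu, conc) == pytest.approx(
        mf.delta_g_at_denaturant(t_ni, conc)
        + mf.delta_g_at_denaturant(t_iu, conc), abs=1e-9)
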