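"""Exact forward models: mass action, conservation, QSSA reductions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import expm

from effparam import kinetics
from effparam.kinetics import (
    CARICATURE_BASE_K1,
    CARICATURE_BASE_K2,
    DEFAULT_OBSERVATION_TIMES,
    KAPPA_NOMINAL,
    MSP_BASE,
    MSP_REFERENCE_IC,
    CaricatureParameters,
    EffectiveParameters,
    MSPParameters,
    MSPState,
    effective_parameters,
    k_eff,
    msp_rhs,
    qssa_validity,
    simulate_caricature,
    simulate_msp,
    simulate_reduced,
)

positive_rate = st.floats(1e-3, 1e4)
concentration = st.floats(0.0, 10.0)


class TestMSPRates:
    def test_no_complexes_only_binding_flux(self):
        # with no complexes present, product formation is zero and ES0 forms
        # at the binding rate kf1*E*S0
        state = np.array([0.66, 5.0, 0.0, 0.0, 0.0, 0.0])
        d = msp_rhs(state, MSP_BASE)
        dE, dS0, dS1, dS2, dES0, dES1 = d
        assert dS2 == 0.0
        assert dES0 == pytest.approx(MSP_BASE.kf1 * 0.66 * 5.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        rates=st.lists(positive_rate, min_size=6, max_size=6),
        concs=st.lists(concentration, min_size=6, max_size=6),
    )
    def test_conservation_by_construction(self, rates, concs):
        p = MSPParameters.from_array(np.asarray(rates))
        d = msp_rhs(np.asarray(concs), p)
        dE, dS0, dS1, dS2, dES0, dES1 = d
        assert dE + dES0 + dES1 == pytest.approx(0.0, abs=1e-9)
        assert dS0 + dS1 + dS2 + dES0 + dES1 == pytest.approx(0.0, abs=1e-9)

    def test_rhs_matches_solver_finite_difference(self):
        state = np.array([0.5, 3.0, 0.5, 0.2, 0.1, 0.06])
        ic = MSPState(E=0.5, S0=3.0, S1=0.5, S2=0.2, ES0=0.1, ES1=0.06)
        # one-sided differences carry an O(h) curvature term (the fast rates
        # bend the trajectory immediately), so Richardson-extrapolate it away
        h = 1e-9
        traj = simulate_msp(MSP_BASE, ic, np.array([h, 2 * h]), rtol=1e-12, atol=1e-14)
        fd_h = (traj.states[0] - state) / h
        fd_2h = (traj.states[1] - state) / (2 * h)
        fd = 2 * fd_h - fd_2h
        analytic = msp_rhs(state, MSP_BASE)
        assert np.max(np.abs(fd - analytic)) / np.max(np.abs(analytic)) < 1e-6

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            msp_rhs(np.array([-0.1, 5, 0, 0, 0, 0]), MSP_BASE)
        with pytest.raises(ValueError):
            MSPParameters(kf1=0.0, kr1=1, kcat1=1, kf2=1, kr2=1, kcat2=1)


class TestSimulateMSP:
    def test_reference_trajectory_invariants(self):
        traj = simulate_msp(MSP_BASE)
        E_tot = traj["E"] + traj["ES0"] + traj["ES1"]
        S_tot = traj["S0"] + traj["S1"] + traj["S2"] + traj["ES0"] + traj["ES1"]
        assert np.all(np.abs(E_tot - 0.66) / 0.66 <= 1e-6)
        assert np.all(np.abs(S_tot - 5.0) / 5.0 <= 1e-6)
        assert np.all(np.diff(traj["S2"]) >= -1e-12)  # product never decreases

    def test_s2_zero_at_start_and_full_conversion(self):
        traj = simulate_msp(MSP_BASE, times=np.array([1e-9, 100.0]))
        assert traj["S2"][0] == pytest.approx(0.0, abs=1e-6)
        assert traj["S2"][-1] == pytest.approx(5.0, abs=1e-3)

    def test_full_model_tracks_reduced_in_qssa_regime(self):
        # at the nominal operating point the QSSA holds, so the full-model
        # product trajectory follows the three-state linear reduction closely
        full = simulate_msp(MSP_BASE)["S2"]
        red = simulate_reduced(KAPPA_NOMINAL)["S2"]
        assert np.max(np.abs(full - red) / full) <= 0.02

    def test_bad_time_grid_rejected(self):
        with pytest.raises(ValueError):
            simulate_msp(MSP_BASE, times=np.array([2.0, 1.0]))
        with pytest.raises(ValueError):
            simulate_msp(MSP_BASE, times=np.array([-1.0, 1.0]))


class TestEffectiveParameters:
    def test_kappa1_worked_value(self):
        kap = effective_parameters(MSP_BASE, 0.66)
        assert round(kap.kappa1, 3) == 0.467

    def test_kappa2_pi_close_to_published_nominals(self):
        # direct evaluation gives 0.2312 / 0.3611 vs the published rounding
        # 0.232 / 0.362; the discrepancy stays below 0.5%
        kap = effective_parameters(MSP_BASE, 0.66)
        assert abs(kap.kappa2 - 0.232) / 0.232 < 0.005
        assert abs(kap.pi - 0.362) / 0.362 < 0.005

    def test_pi_tends_to_one_as_release_vanishes(self):
        p = MSPParameters(kf1=1, kr1=1, kcat1=1, kf2=1, kr2=1e-9, kcat2=100.0)
        assert effective_parameters(p, 1.0).pi == pytest.approx(1.0, abs=1e-9)

    def test_kappas_scale_linearly_in_enzyme(self):
        k1 = effective_parameters(MSP_BASE, 0.66)
        k2 = effective_parameters(MSP_BASE, 1.32)
        assert k2.kappa1 == pytest.approx(2 * k1.kappa1)
        assert k2.kappa2 == pytest.approx(2 * k1.kappa2)
        assert k2.pi == pytest.approx(k1.pi)

    def test_printed_vector_assignments(self):
        printed = kinetics.MSPParameters.from_printed_vector(
            [0.71, 19, 6700, 9200, 0.97, 5200], assignment="printed"
        )
        assert printed.kf2 == 9200 and printed.kr2 == 0.97
        assert MSP_BASE.kf2 == 0.97 and MSP_BASE.kr2 == 9200


class TestReducedModel:
    def test_matches_matrix_exponential(self):
        # independent linear-ODE oracle: expm of the rate matrix
        k1, k2, pi = KAPPA_NOMINAL.to_array()
        A = np.array([[-k1, 0, 0], [(1 - pi) * k1, -k2, 0], [pi * k1, k2, 0]])
        for t in DEFAULT_OBSERVATION_TIMES:
            oracle = expm(A * t) @ np.array([5.0, 0.0, 0.0])
            ours = simulate_reduced(KAPPA_NOMINAL, times=np.array([t])).states[0]
            assert np.allclose(ours, oracle, atol=1e-10)

    def test_confluent_rates_limit(self):
        k = EffectiveParameters(kappa1=0.3, kappa2=0.3, pi=0.5)
        A = np.array([[-0.3, 0, 0], [0.5 * 0.3, -0.3, 0], [0.5 * 0.3, 0.3, 0]])
        oracle = expm(A * 7.0) @ np.array([5.0, 0.0, 0.0])
        ours = simulate_reduced(k, times=np.array([7.0])).states[0]
        assert np.allclose(ours, oracle, atol=1e-9)

    def test_kappa2_zero_limit_closed_form(self):
        k = EffectiveParameters(kappa1=0.4, kappa2=1e-12, pi=0.3)
        t = DEFAULT_OBSERVATION_TIMES
        S1 = simulate_reduced(k, times=t)["S1"]
        assert np.allclose(S1, (1 - 0.3) * 5.0 * (1 - np.exp(-0.4 * t)), atol=1e-8)

    def test_pi_one_keeps_intermediate_empty(self):
        k = EffectiveParameters(kappa1=0.4, kappa2=0.2, pi=1 - 1e-13)
        assert np.allclose(simulate_reduced(k)["S1"], 0.0, atol=1e-10)

    def test_total_substrate_conserved_exactly(self):
        traj = simulate_reduced(KAPPA_NOMINAL)
        assert np.allclose(traj.states.sum(axis=1), 5.0, atol=1e-12)


class TestCaricature:
    def test_product_monotone_to_full_conversion(self):
        traj = simulate_caricature(CARICATURE_BASE_K2, times=np.array([2, 4, 6, 8, 10, 200.0]))
        assert np.all(np.diff(traj["S1"]) >= -1e-12)
        assert traj["S1"][-1] == pytest.approx(5.0, abs=1e-3)

    def test_conservation(self):
        traj = simulate_caricature(CARICATURE_BASE_K2)
        assert np.allclose(traj["E"] + traj["ES0"], 0.66, rtol=1e-6)
        assert np.allclose(traj["S0"] + traj["S1"] + traj["ES0"], 5.0, rtol=1e-6)

    def test_vanishing_catalysis_makes_no_product(self):
        k = CaricatureParameters(kf=0.97, kr=7000, kcat=1e-9)
        assert np.all(simulate_caricature(k)["S1"] < 1e-6)

    def test_strong_unbinding_suppresses_production(self):
        slow = simulate_caricature(CaricatureParameters(kf=0.97, kr=1e7, kcat=100))["S1"]
        fast = simulate_caricature(CaricatureParameters(kf=0.97, kr=10, kcat=100))["S1"]
        assert np.all(slow <= fast * 1e-2 + 1e-12)

    def test_k_eff_values(self):
        # negligible unbinding: every encounter converts, k_eff = E_tot * kf
        assert k_eff(CaricatureParameters(kf=2.0, kr=1e-12, kcat=5.0), 0.5) == pytest.approx(1.0)
        # first base point: kcat >> kr, so k_eff/E_tot is within 0.3% of kf
        assert abs(k_eff(CARICATURE_BASE_K1, 1.0) - CARICATURE_BASE_K1.kf) / CARICATURE_BASE_K1.kf < 0.003
        val = k_eff(CARICATURE_BASE_K2, 0.66)
        assert val == pytest.approx(0.66 * 0.97 * 10000 / 17000)


class TestQSSAValidity:
    def test_nominal_regime_valid(self):
        r1, r2, ok1, ok2 = qssa_validity(MSP_BASE, S_tot=5.0)
        assert ok1 and ok2
        assert 0 < r1 < 0.1 and 0 < r2 < 0.1

    def test_zero_substrate_trivially_valid(self):
        r1, r2, ok1, ok2 = qssa_validity(MSP_BASE, S_tot=0.0)
        assert r1 == 0 and r2 == 0 and ok1 and ok2

    def test_fast_binding_invalidates(self):
        p = MSPParameters(kf1=1e9, kr1=19, kcat1=6700, kf2=0.97, kr2=9200, kcat2=5200)
        _, _, ok1, _ = qssa_validity(p, S_tot=5.0)
        assert not ok1

    def test_printed_variant_differs(self):
        r1_m, *_ = qssa_validity(MSP_BASE, 5.0)
        r1_p, *_ = qssa_validity(MSP_BASE, 5.0, as_printed=True)
        assert r1_m != r1_p


class TestTrajectoryContainer:
    def test_csv_round_trip(self, tmp_path):
        import pandas as pd

        traj = simulate_msp(MSP_BASE)
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        frame = pd.read_csv(path)
        assert list(frame.columns) == ["time", "E", "S0", "S1", "S2", "ES0", "ES1"]
        assert np.allclose(frame["S2"].to_numpy(), traj["S2"])

    def test_invalid_shapes_rejected(self):
        with pytest.raises(ValueError):
            kinetics.Trajectory(times=np.array([1.0, 1.0]), states=np.zeros((2, 1)), species=("a",))
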