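"""Ensemble generators: box sampling, refits, delay pairs, the analytic toy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from effparam import kinetics, sampling
from effparam.kinetics import CARICATURE_BASE_K2, MSP_BASE
from effparam.sampling import (
    EnsembleDataset,
    build_jsf_pair,
    build_optimization_dataset,
    build_transient_dataset,
    sample_parameters,
    analytic_toy_dataset,
)


class TestSampleParameters:
    def test_zero_fraction_degenerates_to_base(self):
        rows = sample_parameters(MSP_BASE, 0.0, 5, seed=0)
        assert np.allclose(rows, MSP_BASE.to_array())

    @settings(deadline=None, max_examples=10, derandomize=True)
    @given(fraction=st.floats(0.01, 0.5), seed=st.integers(0, 100))
    def test_bounds_exact(self, fraction, seed):
        base = CARICATURE_BASE_K2.to_array()
        rows = sample_parameters(base, fraction, 200, seed=seed)
        assert np.all(rows >= base * (1 - fraction) - 1e-12)
        assert np.all(rows <= base * (1 + fraction) + 1e-12)

    def test_column_means_near_base(self):
        base = MSP_BASE.to_array()
        rows = sample_parameters(base, 0.1, 10_000, seed=3)
        # uniform on +-10%: sd = 0.1*base/sqrt(3); mean within 3 standard errors
        se = 0.1 * base / np.sqrt(3) / np.sqrt(10_000)
        assert np.all(np.abs(rows.mean(0) - base) < 3 * se)

    def test_deterministic_under_seed(self):
        a = sample_parameters(MSP_BASE, 0.1, 50, seed=9)
        b = sample_parameters(MSP_BASE, 0.1, 50, seed=9)
        assert a.tobytes() == b.tobytes()

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sample_parameters(MSP_BASE, 0.1, 0, seed=0)
        with pytest.raises(ValueError):
            sample_parameters(MSP_BASE, 1.5, 10, seed=0)


class TestTransientDataset:
    def test_single_base_row_is_reference_behavior(self):
        ds = build_transient_dataset(MSP_BASE.to_array()[None, :])
        ref = kinetics.simulate_msp(MSP_BASE)["S2"]
        assert np.allclose(ds.behaviors[0], ref)
        assert ds.behaviors.shape == (1, 10)

    def test_duplicated_parameters_duplicate_behaviors(self):
        rows = np.vstack([MSP_BASE.to_array()] * 2)
        ds = build_transient_dataset(rows)
        assert np.array_equal(ds.behaviors[0], ds.behaviors[1])

    def test_dimension_matches_time_grid(self):
        times = np.array([2.0, 4.0, 6.0])
        ds = build_transient_dataset(MSP_BASE.to_array()[None, :], times=times)
        assert ds.behaviors.shape[1] == times.size


class TestEnsembleIO:
    def test_directory_round_trip(self, tmp_path):
        P = sample_parameters(CARICATURE_BASE_K2, 0.2, 5, seed=2)
        ds = sampling.build_caricature_dataset(
            P, base=CARICATURE_BASE_K2, fraction=0.2, seed=2
        )
        ds.to_dir(tmp_path / "ens")
        back = EnsembleDataset.from_dir(tmp_path / "ens")
        assert np.allclose(back.parameters, ds.parameters)
        assert np.allclose(back.behaviors, ds.behaviors)
        assert back.seed == 2 and back.fraction == 0.2
        assert back.parameter_names == ds.parameter_names

    def test_malformed_csv_reports_error(self, tmp_path):
        P = sample_parameters(CARICATURE_BASE_K2, 0.2, 3, seed=2)
        ds = sampling.build_caricature_dataset(P)
        ds.to_dir(tmp_path / "ens")
        bad = tmp_path / "ens" / "parameters.csv"
        bad.write_text(bad.read_text().replace("0.", "zero.", 1))
        with pytest.raises(ValueError, match="malformed|convert"):
            EnsembleDataset.from_dir(tmp_path / "ens")

    def test_mismatched_rows_rejected(self):
        with pytest.raises(ValueError):
            EnsembleDataset(
                parameters=np.zeros((3, 2)),
                behaviors=np.zeros((2, 4)),
                parameter_names=("a", "b"),
                times=np.arange(4.0),
                observable="y",
            )


class TestOptimizationDataset:
    def test_start_at_base_point_accepted_with_tiny_residual(self):
        ds = build_optimization_dataset(starts=MSP_BASE.to_array()[None, :])
        assert ds.n == 1
        assert ds.meta["residuals"][0] < 1e-6
        # the fit may drift along the (sloppy) level set, but it stays in the
        # neighborhood of the base point rather than wandering decades away
        assert np.allclose(ds.parameters[0], MSP_BASE.to_array(), rtol=0.2)

    def test_accepted_fits_reproduce_reference(self, optimization_dataset):
        ref = kinetics.simulate_msp(MSP_BASE)["S2"]
        dev = np.linalg.norm(optimization_dataset.behaviors - ref, axis=1)
        assert np.all(dev / np.linalg.norm(ref) <= 1e-4)

    def test_level_set_spans_decades_in_sloppy_directions(self, optimization_dataset):
        # equivalent optima wander far along the level set even though every
        # one of them reproduces the reference transient
        spread = np.log10(
            optimization_dataset.parameters.max(0)
            / optimization_dataset.parameters.min(0)
        )
        assert spread.max() > 1.0

    def test_impossible_threshold_raises(self):
        with pytest.raises(RuntimeError, match="threshold"):
            build_optimization_dataset(
                n_fits=2, seed=0, threshold=1e-16, max_nfev=20
            )


class TestKappaDataset:
    def test_behaviors_match_closed_form(self):
        ds = sampling.sample_kappa_dataset(kinetics.KAPPA_NOMINAL, 0.2, 10, seed=4)
        for row, beh in zip(ds.parameters, ds.behaviors):
            ref = kinetics.simulate_reduced(
                kinetics.EffectiveParameters.from_array(row)
            )["S2"]
            assert np.allclose(beh, ref, atol=1e-12)

    def test_fraction_zero_collapses(self):
        ds = sampling.sample_kappa_dataset(kinetics.KAPPA_NOMINAL, 0.0, 3, seed=0)
        assert np.allclose(ds.parameters, kinetics.KAPPA_NOMINAL.to_array())


class TestJSFPair:
    def test_single_species_single_delay_width(self):
        P = CARICATURE_BASE_K2.to_array()[None, :]
        X1, X2 = build_jsf_pair(P, species=("S1",), n_delays=1)
        assert X1.shape == (1, 1)
        assert X2.shape == (1, 3)

    def test_reference_configuration_width_80(self):
        P = sample_parameters(CARICATURE_BASE_K2, 0.2, 3, seed=0)
        X1, _ = build_jsf_pair(P)
        assert X1.shape == (3, 80)

    def test_noise_columns_uncorrelated_with_keff(self, caricature_ensemble, caricature_keff):
        X1, _ = build_jsf_pair(
            caricature_ensemble.parameters, noise_half=True, seed=4
        )
        # the replaced latter half of each species block carries no parameter
        # information: correlation with k_eff stays at noise level
        n_delays = 20
        noise_cols = np.concatenate(
            [np.arange(s * n_delays + 10, (s + 1) * n_delays) for s in range(4)]
        )
        corr = [
            abs(np.corrcoef(X1[:, c], caricature_keff)[0, 1]) for c in noise_cols
        ]
        assert max(corr) < 0.1


class TestToyDataset:
    def test_closed_forms(self, toy_data):
        params, f, phi, psi = toy_data
        assert np.allclose(phi, params[:, 0] * params[:, 1])
        assert np.allclose(psi, params[:, 0] ** 2 - params[:, 1] ** 2)
        assert np.allclose(f, np.exp(-phi / 2))

    def test_level_set_inversion(self):
        # the f = 0.75 level corresponds to the effective combination
        # phi = -2 ln 0.75
        assert np.exp(-(-2 * np.log(0.75)) / 2) == pytest.approx(0.75)

    def test_gradients_exactly_conformal(self, toy_data):
        params, *_ = toy_data
        p1, p2 = params[:, 0], params[:, 1]
        grad_phi = np.column_stack([p2, p1])
        grad_psi = np.column_stack([2 * p1, -2 * p2])
        assert np.allclose((grad_phi * grad_psi).sum(axis=1), 0.0, atol=1e-12)

    def test_deterministic(self):
        a = analytic_toy_dataset(50, seed=1)[0]
        b = analytic_toy_dataset(50, seed=1)[0]
        assert a.tobytes() == b.tobytes()
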