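"""Diffusion maps: kernel construction, nonharmonic selection, extension."""

import numpy as np
import pytest

from effparam import dmaps
from effparam.dmaps import (
    choose_epsilon,
    dmaps_fit,
    intrinsic_dimension,
    nystrom_extend,
    parsimonious_select,
    pca_explained,
)


@pytest.fixture(scope="module")
def circle():
    rng = np.random.default_rng(0)
    theta = rng.uniform(0, 2 * np.pi, 600)
    return np.column_stack([np.cos(theta), np.sin(theta)]), theta


@pytest.fixture(scope="module")
def strip():
    # 5:1 anisotropic rectangle: one long direction, one short
    rng = np.random.default_rng(0)
    return np.column_stack([rng.uniform(0, 5, 800), rng.uniform(0, 1, 800)])


class TestChooseEpsilon:
    def test_equal_distances(self):
        assert choose_epsilon(np.full(10, 2.0)) == pytest.approx(4.0)

    def test_scaling_quadratic(self):
        d = np.random.default_rng(1).uniform(0.5, 2.0, 200)
        assert choose_epsilon(3 * d) == pytest.approx(9 * choose_epsilon(d))

    def test_plateau_below_median_within_fixed_factor(self):
        # the max-slope (plateau) scale sits in the kernel's scaling region,
        # near the nearest-neighbor distance squared, which for a 3-D
        # Gaussian cloud is an order of magnitude below the median squared
        # pairwise distance; both are legitimate scales, the plateau one is
        # finer
        rng = np.random.default_rng(2)
        from scipy.spatial.distance import pdist

        d = pdist(rng.normal(size=(400, 3)))
        med = choose_epsilon(d)
        plat = choose_epsilon(d, rule="plateau")
        assert med / 30 < plat < med


class TestDMapsFit:
    def test_trivial_eigenpair_and_row_stochasticity(self, strip):
        model = dmaps_fit(strip, m=10)
        assert model.eigenvalues[0] == pytest.approx(1.0, abs=1e-10)
        assert np.allclose(model.eigenvectors[:, 0], 1.0)
        # the normalized kernel is Markov: rows sum to one
        W = np.exp(
            -((np.linalg.norm(strip[:, None] - strip[None], axis=2)) ** 2)
            / model.epsilon
        )
        q = W.sum(1)
        Wt = W / np.outer(q, q)
        P = Wt / Wt.sum(1, keepdims=True)
        assert np.allclose(P.sum(1), 1.0, atol=1e-12)
        # and its eigenvectors satisfy P phi = lambda phi
        for k in range(1, 4):
            assert np.allclose(
                P @ model.eigenvectors[:, k],
                model.eigenvalues[k] * model.eigenvectors[:, k],
                atol=1e-8,
            )

    def test_deterministic_signs(self, strip):
        a = dmaps_fit(strip, m=8)
        b = dmaps_fit(strip, m=8)
        assert np.array_equal(a.eigenvectors, b.eigenvectors)

    def test_duplicated_rows_duplicate_entries(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 2))
        X = np.vstack([X, X[:5]])
        model = dmaps_fit(X, m=5)
        assert np.allclose(
            model.eigenvectors[:5], model.eigenvectors[60:], atol=1e-8
        )

    def test_row_permutation_equivariance(self, strip):
        model = dmaps_fit(strip, m=5)
        perm = np.random.default_rng(4).permutation(strip.shape[0])
        permuted = dmaps_fit(strip[perm], m=5)
        # same eigenvalues; eigenvectors permuted identically (up to sign,
        # which the convention re-fixes on the permuted order)
        assert np.allclose(model.eigenvalues, permuted.eigenvalues, atol=1e-10)
        for k in range(1, 5):
            a, b = model.eigenvectors[perm, k], permuted.eigenvectors[:, k]
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8

    def test_tiny_epsilon_conditioning_error(self, strip):
        with pytest.raises(ValueError, match="diagonal"):
            dmaps_fit(strip, epsilon=1e-12, m=5)


class TestParsimoniousSelect:
    def test_circle_needs_two_embedding_coordinates(self, circle):
        # a closed 1-manifold: sin is not a function of cos, so both leading
        # eigenvectors are retained even though the manifold is 1-D
        X, theta = circle
        model = dmaps_fit(X, m=10)
        retained, residuals = parsimonious_select(model.eigenvectors[:, 1:], X)
        assert retained == [0, 1]
        # (phi1, phi2) recover (cos, sin) up to a rotation: a linear map in
        # the pair explains almost all of their variance
        phi = model.eigenvectors[:, 1:3]
        A = np.column_stack([np.ones(len(X)), phi])
        for target in (np.cos(theta), np.sin(theta)):
            beta, *_ = np.linalg.lstsq(A, target, rcond=None)
            resid = target - A @ beta
            assert 1 - resid.var() / target.var() > 0.99

    def test_strip_keeps_one_per_direction(self, strip):
        model = dmaps_fit(strip, m=15)
        retained, residuals = parsimonious_select(model.eigenvectors[:, 1:], strip)
        assert len(retained) == 2
        second = model.eigenvectors[:, 1 + retained[1]]
        assert abs(np.corrcoef(second, strip[:, 1])[0, 1]) > 0.9

    def test_exact_harmonic_dropped(self, strip):
        model = dmaps_fit(strip, m=5)
        phi1 = model.eigenvectors[:, 1]
        V = np.column_stack([phi1, phi1**2])
        retained, residuals = parsimonious_select(V, strip)
        assert retained == [0]
        assert residuals[1] < 0.05

    def test_threshold_validation(self, strip):
        model = dmaps_fit(strip, m=5)
        with pytest.raises(ValueError):
            parsimonious_select(model.eigenvectors[:, 1:], threshold=1.5)


class TestNystrom:
    def test_training_points_reproduced(self, strip):
        model = dmaps_fit(strip, m=8)
        ext = nystrom_extend(model, strip[:20])
        assert np.max(np.abs(ext - model.eigenvectors[:20])) < 1e-8

    def test_midpoint_interpolates_between_neighbors(self):
        X = np.linspace(0, 1, 200)[:, None]
        model = dmaps_fit(X, m=4)
        mid = (X[80] + X[81]) / 2
        val = nystrom_extend(model, mid[None])[0, 1]
        lo, hi = sorted([model.eigenvectors[80, 1], model.eigenvectors[81, 1]])
        assert lo <= val <= hi

    def test_far_outlier_warns(self, strip):
        model = dmaps_fit(strip, m=4)
        with pytest.warns(RuntimeWarning, match="extrapolat"):
            nystrom_extend(model, np.array([[50.0, 50.0]]))


class TestIntrinsicDimension:
    def test_caricature_is_one_dimensional(self, caricature_ensemble):
        dim, model = intrinsic_dimension(caricature_ensemble, "output-informed")
        assert dim == 1

    def test_caricature_count_robust_across_epsilon_decade(self, caricature_ensemble):
        _, model = intrinsic_dimension(caricature_ensemble, "output-informed")
        for mult in (1 / 3, 3.0):
            dim, _ = intrinsic_dimension(
                caricature_ensemble, "output-informed", epsilon=model.epsilon * mult
            )
            assert dim == 1

    def test_observable_choice_does_not_change_the_count(self, msp_ensemble):
        # delay-embedding argument: any time-resolved species carries the
        # same model-manifold dimension as the product concentration
        from effparam import sampling

        ds_s1 = sampling.build_transient_dataset(
            msp_ensemble.parameters, observable="S1"
        )
        dim_s1, _ = intrinsic_dimension(ds_s1, "output-informed")
        dim_s2, _ = intrinsic_dimension(msp_ensemble, "output-informed")
        assert dim_s1 == dim_s2 == 3

    def test_unknown_mode_rejected(self, caricature_ensemble):
        with pytest.raises(ValueError):
            intrinsic_dimension(caricature_ensemble, "sideways")


class TestPCA:
    def test_rank_one(self):
        u = np.random.default_rng(5).normal(size=50)
        Y = np.outer(u, [1.0, 2.0, 3.0])
        ratios = pca_explained(Y)
        assert ratios[0] == pytest.approx(1.0)
        assert np.all(ratios[1:] < 1e-10)

    def test_isotropic_gaussian_nearly_equal(self):
        Y = np.random.default_rng(6).normal(size=(20000, 3))
        ratios = pca_explained(Y)
        assert np.all(np.abs(ratios - 1 / 3) < 0.02)


class TestModelIO:
    def test_save_load_round_trip(self, tmp_path, strip):
        model = dmaps_fit(strip, m=6)
        retained, residuals = parsimonious_select(model.eigenvectors[:, 1:], strip)
        model.retained = [r + 1 for r in retained]
        model.residuals = residuals
        model.save(tmp_path / "model")
        back = dmaps.DiffusionMapModel.load(tmp_path / "model")
        assert back.retained == model.retained
        assert np.allclose(back.eigenvectors, model.eigenvectors)
        assert back.epsilon == pytest.approx(model.epsilon)
        # the loaded model extends new points identically
        x = strip[:3] + 0.01
        assert np.allclose(nystrom_extend(back, x), nystrom_extend(model, x))
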