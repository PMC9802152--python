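"""Shared ensembles for the test suite.

The expensive datasets (ODE ensembles, the least-squares refit set, trained
autoencoders) are session-scoped so every test file works on the same
deterministic objects.
"""

import numpy as np
import pytest

from effparam import cae, kinetics, sampling


@pytest.fixture(scope="session")
def msp_ensemble():
    """3000-sample +-10% box around the nominal MSP rates, [S2] at t=2..20."""
    P = sampling.sample_parameters(kinetics.MSP_BASE, 0.1, 3000, seed=1)
    return sampling.build_transient_dataset(
        P, base=kinetics.MSP_BASE, fraction=0.1, seed=1
    )


@pytest.fixture(scope="session")
def msp_kappas(msp_ensemble):
    return np.array(
        [
            kinetics.effective_parameters(
                kinetics.MSPParameters.from_array(p), kinetics.MSP_REFERENCE_IC.E
            ).to_array()
            for p in msp_ensemble.parameters
        ]
    )


@pytest.fixture(scope="session")
def caricature_ensemble():
    """2000-sample +-20% box around the second caricature base point."""
    P = sampling.sample_parameters(kinetics.CARICATURE_BASE_K2, 0.2, 2000, seed=1)
    return sampling.build_caricature_dataset(
        P, base=kinetics.CARICATURE_BASE_K2, fraction=0.2, seed=1
    )


@pytest.fixture(scope="session")
def caricature_keff(caricature_ensemble):
    E_tot = kinetics.CARICATURE_REFERENCE_IC[1]
    return np.array(
        [
            kinetics.k_eff(kinetics.CaricatureParameters.from_array(p), E_tot)
            for p in caricature_ensemble.parameters
        ]
    )


@pytest.fixture(scope="session")
def kappa_ensemble():
    """5000 effective-parameter triplets +-20% around nominal, reduced model."""
    return sampling.sample_kappa_dataset(kinetics.KAPPA_NOMINAL, 0.2, 5000, seed=3)


@pytest.fixture(scope="session")
def optimization_dataset():
    """Equivalent-optima set: 500 random refit starts of the reference transient."""
    return sampling.build_optimization_dataset(n_fits=500, seed=11)


@pytest.fixture(scope="session")
def toy_data():
    return sampling.analytic_toy_dataset(n=2000, seed=5)


@pytest.fixture(scope="session")
def toy_dataset(toy_data):
    params, f, phi, psi = toy_data
    return sampling.EnsembleDataset(
        parameters=params,
        behaviors=f[:, None],
        parameter_names=("p1", "p2"),
        times=np.array([0.0]),
        observable="f",
        seed=5,
    )


@pytest.fixture(scope="session")
def toy_cae(toy_dataset):
    return cae.train_cae(
        toy_dataset,
        n_eff=1,
        config=cae.CAEConfig(epochs=600, patience=10**9),
        seed=0,
    )


@pytest.fixture(scope="session")
def caricature_cae(caricature_ensemble):
    return cae.train_cae(
        caricature_ensemble,
        n_eff=1,
        config=cae.CAEConfig(epochs=600, patience=10**9),
        seed=2,
    )
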