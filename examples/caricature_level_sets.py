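"""Trace the level sets of constant behavior in full parameter space.

The single-site mechanism S0 + E <-> ES0 -> S1 + E has three rate constants
but, in the QSSA regime, a single effective one:
k_eff = E_tot kf kcat / (kr + kcat).  A conformal autoencoder splits the
latent space into nu1 (one-to-one with k_eff) and (nu2, nu3), which sweep
the 2-D surface of rate constants producing the same transient.
"""

import numpy as np
from scipy.stats import spearmanr

from effparam import cae, dmaps, kinetics, sampling

params = sampling.sample_parameters(kinetics.CARICATURE_BASE_K2, 0.2, 2000, seed=1)
dataset = sampling.build_caricature_dataset(
    params, base=kinetics.CARICATURE_BASE_K2, fraction=0.2, seed=1
)

dim, _ = dmaps.intrinsic_dimension(dataset, "output-informed")
print(f"intrinsic dimension of the caricature ensemble: {dim}")

model = cae.train_cae(
    dataset, n_eff=dim, config=cae.CAEConfig(epochs=600, patience=10**9), seed=2
)
nu = model.encode(params)
keff = np.array(
    [kinetics.k_eff(kinetics.CaricatureParameters.from_array(p), 0.66) for p in params]
)
print(f"|spearman(nu1, k_eff)| = {abs(spearmanr(nu[:, 0], keff).statistic):.4f}")

lo, hi = model.report["nu_min"], model.report["nu_max"]
axes = [
    np.linspace(lo[j] + 0.25 * (hi[j] - lo[j]), lo[j] + 0.75 * (hi[j] - lo[j]), 10)
    for j in (1, 2)
]
mesh = np.meshgrid(*axes, indexing="ij")
grid = np.column_stack([m.ravel() for m in mesh])


def simulate(row):
    return kinetics.simulate_caricature(
        kinetics.CaricatureParameters.from_array(np.clip(row, 1e-9, None))
    )["S1"]


trace = cae.trace_level_set(model, [np.median(nu[:, 0])], grid, simulate=simulate)
print(f"level-set trace over a 10x10 grid in (nu2, nu3):")
print(f"  max behavior deviation     = {100 * trace['max_behavior_deviation']:.3f} %")
print(f"  parameter spread (kf,kr,kcat) = {np.round(100 * trace['parameter_spread'], 1)} %")
print()
print("Decoded rate constants move by tens of percent while the simulated")
print("transient stays put: the grid sweeps a level set of constant behavior.")
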