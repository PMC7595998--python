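"""Six interacting strains: invasion network and slow frequency dynamics.

Draws a random 6x6 co-colonization matrix (mean 1, spread 0.1, R0 = 2),
builds the pairwise invasion fitness matrix, classifies every pair, then
integrates the N-dimensional replicator reduction and the full 43-equation
system and compares the strain frequencies they predict.
"""

import numpy as np

from costrain import (
    EpidemicParameters,
    decompose_interactions,
    generate_random_K,
    integrate_full,
    integrate_replicator,
    invasion_fitness_matrix,
    invasion_network,
    neutral_equilibrium,
    on_manifold_state,
)

params = EpidemicParameters(beta=2.0, gamma=0.5, r=0.5, N=6)
K = generate_random_K(N=6, k=1.0, epsilon=0.1, seed=42)
d = decompose_interactions(K)
eq = neutral_equilibrium(params, d.k)
Lambda = invasion_fitness_matrix(d.A, eq.mu)

print(f"decomposed k = {d.k:.4f}, eps = {d.epsilon:.4f}, mu = {eq.mu:.4f}")
print("\npairwise invasion outcomes (strain indices 1-based):")
net = invasion_network(Lambda)
for _, row in net.iterrows():
    print(
        f"  {int(row.i) + 1} vs {int(row.j) + 1}: {row.outcome:18s} "
        f"(lambda_i^j = {row.lambda_ij:+.3f}, lambda_j^i = {row.lambda_ji:+.3f})"
    )

z0 = np.random.default_rng(0).dirichlet(np.ones(6))
times = np.linspace(0.0, 250.0, 60)
full = integrate_full(on_manifold_state(z0, eq), params, K, times)
red = integrate_replicator(z0, Lambda, Theta=eq.Theta, taus=d.epsilon * times)

zf_full = full.frequencies()[-1]
zf_red = red.final()
print(f"\nstrain frequencies at t = {times[-1]:.0f}:")
print("  full system :", np.array_str(zf_full, precision=4))
print("  replicator  :", np.array_str(zf_red, precision=4))
print(f"  max |difference| over the whole run: "
      f"{np.max(np.abs(full.frequencies() - red.z)):.4f}")
print(
    "\nThe 6-dimensional replicator equation tracks the 43-dimensional"
    "\nepidemiological system to within a few percent (an O(eps) error),"
    "\nwhile exposing which pairwise invasion signs shape the outcome."
)
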