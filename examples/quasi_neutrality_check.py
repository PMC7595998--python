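"""Quasi-neutrality invariants and the accuracy of the reduction vs eps.

Integrates the full N = 6 system for a ladder of deviation scales eps with
the same normalized interaction structure, then reports (i) the two
quasi-neutrality diagnostics — strain shares equalizing across single and
total colonization, and the pair-prevalence product law I_ij =
k R0 [1 + k (R0-1)] I_i I_j — and (ii) the sup-norm frequency error of the
replicator reduction.
"""

import numpy as np

from costrain import (
    EpidemicParameters,
    approximation_error,
    cocolonization_prefactor,
    decompose_interactions,
    generate_random_K,
    integrate_full,
    neutral_equilibrium,
    on_manifold_state,
    quasi_neutrality_test,
)

params = EpidemicParameters(beta=2.0, gamma=0.5, r=0.5, N=6)
d = decompose_interactions(generate_random_K(6, 1.0, 0.1, seed=5))
z0 = np.random.default_rng(2).dirichlet(np.ones(6))
pref = cocolonization_prefactor(params.R0, d.k)
print(f"product-law prefactor k R0 [1 + k(R0-1)] = {pref:.4f} "
      f"(equals D*/I*^2)")

print(f"\n{'eps':>6s} {'share dev':>10s} {'product dev':>12s} {'freq error':>11s}")
for eps in (0.2, 0.1, 0.05):
    K = d.k + eps * d.A
    eq = neutral_equilibrium(params, d.k)
    traj = integrate_full(on_manifold_state(z0, eq), params, K, np.linspace(0, 300, 200))
    rep = quasi_neutrality_test(traj, params, d.k)
    post = rep[rep.post_transient]
    (err,) = approximation_error(params, d.A, d.k, eps, z0, horizon=300.0)
    print(
        f"{eps:6.2f} {post.share_deviation.max():10.4f} "
        f"{post.product_deviation.max():12.4f} {err.frequency_error:11.4f}"
    )

print(
    "\nAll three columns shrink roughly linearly with eps: post-transient,"
    "\nstrain shares equalize across colonization classes and co-colonization"
    "\nprevalence follows the product of single prevalences, up to O(eps) --"
    "\nthe practical quasi-neutrality test for multi-strain prevalence data."
)
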