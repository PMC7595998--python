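"""Canonical invasion structures and the fate of mean fitness Q.

For each canonical class of the pairwise invasion matrix, runs an ensemble
of random replicator trajectories (N = 10, entries uniform in [-1, 1],
Theta = 1, flat-Dirichlet starts) and summarizes how the community mean
invasion fitness Q = z' Lambda z evolves and how many strains survive.
"""

import numpy as np

from costrain import ENSEMBLE_CLASSES, run_canonical_ensemble

print(f"{'class':22s} {'Q(0)':>8s} {'Q(final)':>9s} {'max|Q|':>8s} "
      f"{'monotone Q^':>11s} {'survivors':>9s}")
for cls in ENSEMBLE_CLASSES:
    df = run_canonical_ensemble(cls, N=10, reps=15, seed=3)
    first = df[df.tau == 0.0]
    final = df[df.tau == df.tau.max()]
    monotone = all(
        np.all(np.diff(g.Q.values) >= -1e-7) for _, g in df.groupby("replicate")
    )
    print(
        f"{cls:22s} {first.Q.mean():8.3f} {final.Q.mean():9.3f} "
        f"{df.Q.abs().max():8.1e} {str(monotone):>11s} "
        f"{final.n_extant.median():9.1f}"
    )

print(
    "\nsymmetric: Q climbs monotonically (Fisher-type selection)."
    "\ninvader/resident-driven: hierarchical attack favours coexistence,"
    "\nhierarchical defense favours exclusion with Q -> 0."
    "\nantisymmetric: a zero-sum game, Q = 0 to solver precision, cyclic"
    "\ncoexistence; almost-antisymmetric perturbs the cycles."
)
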