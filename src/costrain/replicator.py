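"""Pairwise invasion fitness and the slow-timescale replicator dynamics.

On the slow time tau = epsilon * t the strain frequencies z obey a
replicator equation on the simplex,

    dz_i/dtau = Theta * z_i * ((Lambda z)_i - z^T Lambda z),

where Lambda = (lambda_i^j) is the pairwise invasion fitness matrix,

    lambda_i^j = alpha_ji - alpha_jj + mu (alpha_ji - alpha_ij),

the rescaled exponential growth rate of a rare invader i introduced at the
single-resident endemic equilibrium of strain j (rows = invader, columns =
resident; the diagonal is zero by construction). mu = I*/D* amplifies the
asymmetric part of the interactions; Theta sets the clock of the slow
dynamics and can be overridden to 1 when only the phase portrait matters.

Three equivalent forms of the right-hand side are exposed (deviation-matrix
form with q(z), payoff-matrix form with M = mu (A^T - A) + A^T, and the
invasion-fitness form above); they agree identically because the quadratic
form of an antisymmetric matrix vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "invasion_fitness_matrix",
    "payoff_matrix_M",
    "replicator_rhs",
    "replicator_rhs_deviation_form",
    "integrate_replicator",
    "ReplicatorTrajectory",
    "mean_fitness_Q",
    "mean_invasion_fitness",
    "effective_k",
    "slow_to_real_time",
    "real_to_slow_time",
]


def invasion_fitness_matrix(A: np.ndarray, mu: float) -> np.ndarray:
    """Lambda from normalized deviations A and prevalence ratio mu:
    lambda_i^j = alpha_ji - alpha_jj + mu (alpha_ji - alpha_ij).

    Entry (i, j) is invader i against resident j; the diagonal is exactly 0.
    """
    if mu <= 0:
        raise ValueError("mu must be > 0")
    A = np.asarray(A, dtype=float)
    Lambda = A.T - np.diag(A)[None, :] + mu * (A.T - A)
    np.fill_diagonal(Lambda, 0.0)
    return Lambda


def payoff_matrix_M(A: np.ndarray, mu: float) -> np.ndarray:
    """Payoff matrix M = mu (A^T - A) + A^T of the deviation-form replicator.

    z^T M z = z^T A z for every z (the antisymmetric part drops out of the
    quadratic form).
    """
    if mu <= 0:
        raise ValueError("mu must be > 0")
    A = np.asarray(A, dtype=float)
    return mu * (A.T - A) + A.T


def _check_simplex(z: np.ndarray, atol: float = 1e-6) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    if np.any(z < -atol) or abs(z.sum() - 1.0) > atol:
        raise ValueError("z must lie on the unit simplex")
    return z


def replicator_rhs(z: np.ndarray, Lambda: np.ndarray, Theta: float = 1.0) -> np.ndarray:
    """dz/dtau = Theta z_i ((Lambda z)_i - z^T Lambda z); components sum to 0."""
    z = np.asarray(z, dtype=float)
    lz = Lambda @ z
    return Theta * z * (lz - z @ lz)


def replicator_rhs_deviation_form(
    z: np.ndarray, A: np.ndarray, mu: float, Theta: float = 1.0
) -> np.ndarray:
    """Replicator right-hand side written with the deviations directly:
    dz_i/dtau = Theta z_i (sum_j [mu (a_ji - a_ij) + a_ji] z_j - q(z)),
    q(z) = z^T A z. Algebraically identical to :func:`replicator_rhs` with
    the matched Lambda."""
    z = np.asarray(z, dtype=float)
    A = np.asarray(A, dtype=float)
    M = payoff_matrix_M(A, mu)
    q = z @ A @ z
    return Theta * z * (M @ z - q)


@dataclass(frozen=True)
class ReplicatorTrajectory:
    """Frequencies on a slow-time grid; z[t] is the simplex vector at taus[t].

    ``n_renormalized`` counts output steps where round-off drift |sum z - 1|
    exceeded 1e-12 and z was renormalized; ``max_sum_drift`` is the largest
    raw |sum z - 1| produced by the solver before any renormalization.
    """

    taus: np.ndarray
    z: np.ndarray = field(repr=False)
    n_renormalized: int = 0
    max_sum_drift: float = 0.0

    def final(self) -> np.ndarray:
        return self.z[-1]


def integrate_replicator(
    z0: np.ndarray,
    Lambda: np.ndarray,
    Theta: float = 1.0,
    taus: np.ndarray | None = None,
    tau_max: float | None = None,
    n_out: int = 200,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    method: str = "LSODA",
    renormalize: bool = True,
) -> ReplicatorTrajectory:
    """Integrate the replicator equation from z0 over a slow-time grid.

    Either ``taus`` or ``tau_max`` must be given. The simplex sum is
    maintained to 1e-9; drift beyond 1e-12 at an output step is renormalized
    and counted (set ``renormalize=False`` to keep the raw solver output,
    e.g. to measure the drift itself). The boundary is absorbing
    analytically; no extinction threshold is imposed.
    """
    z0 = _check_simplex(z0, atol=1e-9)
    Lambda = np.asarray(Lambda, dtype=float)
    if taus is None:
        if tau_max is None:
            raise ValueError("provide taus or tau_max")
        taus = np.linspace(0.0, tau_max, n_out)
    taus = np.asarray(taus, dtype=float)

    def rhs(_tau: float, z: np.ndarray) -> np.ndarray:
        lz = Lambda @ z
        return Theta * z * (lz - z @ lz)

    sol = solve_ivp(
        rhs, (taus[0], taus[-1]), z0, t_eval=taus, method=method, rtol=rtol, atol=atol
    )
    if not sol.success:
        raise RuntimeError(f"replicator integration failed: {sol.message}")
    Z = sol.y.T.copy()
    max_drift = float(np.max(np.abs(Z.sum(axis=1) - 1.0)))
    n_renorm = 0
    if renormalize:
        Z[Z < 0] = 0.0
        sums = Z.sum(axis=1)
        drift = np.abs(sums - 1.0) > 1e-12
        n_renorm = int(drift.sum())
        if n_renorm:
            Z[drift] /= sums[drift, None]
    return ReplicatorTrajectory(
        taus=taus, z=Z, n_renormalized=n_renorm, max_sum_drift=max_drift
    )


def mean_fitness_Q(z: np.ndarray, Lambda: np.ndarray) -> float:
    """Mean pairwise invasion fitness Q = z^T Lambda z.

    Q > 0: each strain's net growth is reduced within the group but the
    community resists outsider invasion; Q < 0 the reverse. Q vanishes
    identically for antisymmetric Lambda (zero-sum game) and at every vertex.
    """
    z = np.asarray(z, dtype=float)
    return float(z @ np.asarray(Lambda, dtype=float) @ z)


def mean_invasion_fitness(z: np.ndarray, Lambda: np.ndarray) -> np.ndarray:
    """Per-strain mean invasion fitness lambda-bar_j = sum_{k != j}
    lambda_j^k z_k; satisfies Q = sum_j lambda-bar_j z_j."""
    return np.asarray(Lambda, dtype=float) @ np.asarray(z, dtype=float)


def effective_k(
    z: np.ndarray, k: float, epsilon: float, A: np.ndarray
) -> tuple[float, float]:
    """Effective mean co-colonization coefficient among extant strains:
    k_eff = k + epsilon q(z) with q(z) = z^T A z.

    Returns ``(k_eff, q)``. A falling q signals a drift toward more
    pairwise inhibition, a rising q toward more facilitation.
    """
    z = np.asarray(z, dtype=float)
    q = float(z @ np.asarray(A, dtype=float) @ z)
    return k + epsilon * q, q


def slow_to_real_time(tau: float | np.ndarray, epsilon: float) -> float | np.ndarray:
    """Convert slow time tau to real time t = tau / epsilon."""
    if epsilon <= 0:
        raise ValueError("time conversion requires epsilon > 0")
    return np.asarray(tau, dtype=float) / epsilon


def real_to_slow_time(t: float | np.ndarray, epsilon: float) -> float | np.ndarray:
    """Convert real time t to slow time tau = epsilon * t."""
    if epsilon <= 0:
        raise ValueError("time conversion requires epsilon > 0")
    return np.asarray(t, dtype=float) * epsilon
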