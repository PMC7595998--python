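"""Reconstruction of epidemiological variables from strain frequencies and
validation of the slow-fast reduction against the full system.

On the slow timescale the aggregated prevalences are conserved at the
neutral equilibrium while strain composition drifts:

    S(t) = S*,  T(t) = T*,  I_i(t) = I* z_i(eps t),  I_ij(t) = D* z_i z_j.

Two quasi-neutrality signatures follow: (i) strain shares equalize across
single and total colonization (I_i/I = J_i/T), and (ii) pair prevalence
follows a product law with an explicit prefactor,

    I_ij = k R0 [1 + k (R0 - 1)] I_i I_j,

where the prefactor equals D*/I*^2. Both serve as practical tests of
quasi-neutrality on real or simulated multi-strain prevalence data, and the
discrepancy between full and reduced trajectories quantifies the
approximation error as a function of epsilon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .full_system import FullState, FullTrajectory, aggregate, integrate_full, on_manifold_state
from .neutral import NeutralEquilibrium, neutral_equilibrium
from .params import EpidemicParameters
from .replicator import ReplicatorTrajectory, integrate_replicator, invasion_fitness_matrix

__all__ = [
    "reconstruct_epidemiology",
    "cocolonization_prefactor",
    "cocolonization_product_law",
    "quasi_neutrality_test",
    "reduced_frequencies",
    "approximation_error",
    "ApproximationError",
]


def reconstruct_epidemiology(
    z_traj: ReplicatorTrajectory, eq: NeutralEquilibrium, epsilon: float
) -> FullTrajectory:
    """Map a replicator frequency trajectory back to full compartments.

    Each slow time tau maps to real time t = tau/epsilon; the reconstructed
    state has S = S*, I_i = I* z_i, I_ij = D* z_i z_j, so the totals satisfy
    sum I_i = I*, sum I_ij = D* and host conservation exactly.
    """
    if epsilon <= 0:
        raise ValueError("time mapping requires epsilon > 0")
    times = z_traj.taus / epsilon
    states = [
        FullState(S=eq.S_star, Ivec=eq.I_star * z, Icc=eq.D_star * np.outer(z, z))
        for z in z_traj.z
    ]
    return FullTrajectory(times=times, states=states)


def cocolonization_prefactor(R0: float, k: float) -> float:
    """Prefactor k R0 [1 + k (R0 - 1)] of the product law; equals D*/I*^2."""
    return k * R0 * (1.0 + k * (R0 - 1.0))


def cocolonization_product_law(I_i: float, I_j: float, R0: float, k: float) -> float:
    """Predicted pair prevalence I_ij = k R0 [1 + k (R0 - 1)] I_i I_j."""
    if R0 <= 1 or k <= 0:
        raise ValueError("product law requires R0 > 1 and k > 0")
    return cocolonization_prefactor(R0, k) * I_i * I_j


def quasi_neutrality_test(
    full_traj: FullTrajectory,
    params: EpidemicParameters,
    k: float,
    transient_window: float | None = None,
) -> pd.DataFrame:
    """Quasi-neutrality deviations along a full-system trajectory.

    Per time point, reports (a) ``share_deviation`` = max_i |I_i/I - J_i/T|
    (strain shares equalize across colonization classes) and (b)
    ``product_deviation`` = max_ij |I_ij - prefactor I_i I_j| / (D/N^2)
    (pair prevalence follows the product law), with ``post_transient``
    flagging times past the fast transient (default window 5/xi).
    """
    eq = neutral_equilibrium(params, k)
    if transient_window is None:
        transient_window = 5.0 / eq.xi
    pref = cocolonization_prefactor(params.R0, k)
    t0 = full_traj.times[0]
    if full_traj.times[-1] - t0 <= transient_window:
        warnings.warn(
            "trajectory does not extend past the fast transient window; "
            "all points flagged pre-transient",
            stacklevel=2,
        )
    rows = []
    for t, s in zip(full_traj.times, full_traj.states):
        agg = aggregate(s)
        N = s.N
        if agg.Isingle > 0 and agg.T > 0:
            share_dev = float(np.max(np.abs(s.Ivec / agg.Isingle - agg.Jvec / agg.T)))
        else:
            share_dev = np.nan
        if agg.D > 0:
            pred = pref * np.outer(s.Ivec, s.Ivec)
            prod_dev = float(np.max(np.abs(s.Icc - pred)) / (agg.D / N**2))
        else:
            prod_dev = np.nan
        rows.append(
            {
                "time": t,
                "share_deviation": share_dev,
                "product_deviation": prod_dev,
                "post_transient": bool(t - t0 >= transient_window),
            }
        )
    return pd.DataFrame(rows)


def reduced_frequencies(
    z0: np.ndarray,
    A: np.ndarray,
    params: EpidemicParameters,
    k: float,
    epsilon: float,
    times: np.ndarray,
    rtol: float = 1e-10,
) -> np.ndarray:
    """Frequencies of the reduced pipeline (neutral equilibrium + replicator)
    evaluated at real times ``times``."""
    eq = neutral_equilibrium(params, k)
    Lambda = invasion_fitness_matrix(A, eq.mu)
    taus = epsilon * np.asarray(times, dtype=float)
    traj = integrate_replicator(z0, Lambda, Theta=eq.Theta, taus=taus, rtol=rtol)
    return traj.z


@dataclass(frozen=True)
class ApproximationError:
    """Full-vs-reduced discrepancy summary for one epsilon.

    ``frequency_error``: sup over output times of max_i |z_i^full -
    z_i^reduced| with z^full = J_i/T. ``compartment_error``: same sup-norm
    over (S, I_i, I_ij) between full and reconstructed trajectories.
    """

    epsilon: float
    frequency_error: float
    compartment_error: float
    times: np.ndarray = field(repr=False)
    frequency_error_t: np.ndarray = field(repr=False)


def approximation_error(
    params: EpidemicParameters,
    A: np.ndarray,
    k: float,
    epsilon: float | np.ndarray,
    z0: np.ndarray,
    horizon: float,
    n_out: int = 120,
    rtol_full: float = 1e-8,
    atol_full: float = 1e-10,
) -> list[ApproximationError]:
    """Integrate the full system and the reduced pipeline from matched
    (slow-manifold) initial conditions and report error norms.

    ``epsilon`` may be a scalar or a descending ladder; for each value the
    interaction matrix is K = k + epsilon A with the same normalized
    deviations A, so errors are comparable across the ladder. ``horizon``
    is in real time.
    """
    params.require_endemic()
    z0 = np.asarray(z0, dtype=float)
    A = np.asarray(A, dtype=float)
    eps_values = np.atleast_1d(np.asarray(epsilon, dtype=float))
    eq = neutral_equilibrium(params, k)
    times = np.linspace(0.0, horizon, n_out)
    out = []
    for eps in eps_values:
        K = k + eps * A
        if np.any(K < 0):
            raise ValueError(f"K = k + eps*A has negative entries at eps = {eps}")
        initial = on_manifold_state(z0, eq)
        full = integrate_full(initial, params, K, times, rtol=rtol_full, atol=atol_full)
        z_full = full.frequencies()
        if eps > 0:
            z_red = reduced_frequencies(z0, A, params, k, eps, times)
        else:
            z_red = np.tile(z0, (len(times), 1))
        freq_err_t = np.max(np.abs(z_full - z_red), axis=1)
        comp_err = 0.0
        for idx, s_full in enumerate(full.states):
            z = z_red[idx]
            recon = np.concatenate(
                ([eq.S_star], eq.I_star * z, (eq.D_star * np.outer(z, z)).ravel())
            )
            comp_err = max(comp_err, float(np.max(np.abs(s_full.to_vector() - recon))))
        out.append(
            ApproximationError(
                epsilon=float(eps),
                frequency_error=float(freq_err_t.max()),
                compartment_error=comp_err,
                times=times,
                frequency_error_t=freq_err_t,
            )
        )
    return out
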