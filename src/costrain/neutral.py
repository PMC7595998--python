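"""Closed-form quantities of the neutral (epsilon = 0) model.

With identical interaction coefficients K_ij = k the strains are
exchangeable and the aggregated dynamics close on themselves. For R0 > 1
the system settles at

    S* = 1/R0,  T* = 1 - 1/R0,
    I* = m T* / (m + beta k T*) = T* / (1 + R0 k T*),  D* = T* - I*,

with mu = I*/D* = 1/(k (R0 - 1)) the single-to-co-colonization prevalence
ratio, and the slow-dynamics clock

    Theta = beta T* I* D* / (2 T*^2 - I* D*)
          = beta (1 - 1/R0) mu / (2 (mu + 1)^2 - mu).

Per strain, the pair (I_i, J_i) obeys a linear fast subsystem with matrix
A0 whose eigenvalues are 0 (the conserved slow direction) and -xi < 0 (the
fast decay). The fast coordinates (H_i, z_i) diagonalize it: H_i measures
the gap between strain i's share of single colonization and of total
carriage and decays like exp(-xi t); z_i is the conserved strain frequency.

Note on A0's (2,1) entry: linearizing the aggregated equations at I = I*
gives -beta k T* / 2 (negative), which is what makes det(A0) = 0; some
renderings of the matrix drop the sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import EpidemicParameters

__all__ = [
    "NeutralEquilibrium",
    "FastCoordinates",
    "neutral_equilibrium",
    "neutral_A0",
    "fast_coordinates",
    "neutral_single_prevalence",
]


@dataclass(frozen=True)
class NeutralEquilibrium:
    """Endemic equilibrium of the neutral model and its derived rates."""

    S_star: float
    T_star: float
    I_star: float
    D_star: float
    mu: float
    Theta: float
    xi: float

    def as_dict(self) -> dict:
        return {
            "S_star": self.S_star,
            "T_star": self.T_star,
            "I_star": self.I_star,
            "D_star": self.D_star,
            "mu": self.mu,
            "Theta": self.Theta,
            "xi": self.xi,
        }


@dataclass(frozen=True)
class FastCoordinates:
    """Per-strain fast coordinates: decaying H and conserved frequencies z."""

    H: np.ndarray = field(repr=False)
    z: np.ndarray = field(repr=False)


def neutral_equilibrium(params: EpidemicParameters, k: float) -> NeutralEquilibrium:
    """Closed-form neutral endemic equilibrium for reference interaction k.

    Raises if R0 <= 1 (no endemic equilibrium) or k <= 0. The two algebraic
    forms of Theta are cross-checked internally.
    """
    params.require_endemic()
    if k <= 0:
        raise ValueError("reference interaction k must be > 0")
    beta, m, R0 = params.beta, params.m, params.R0
    S_star = 1.0 / R0
    T_star = 1.0 - S_star
    I_star = m * T_star / (m + beta * k * T_star)
    D_star = T_star - I_star
    mu = I_star / D_star
    Theta = beta * T_star * I_star * D_star / (2.0 * T_star**2 - I_star * D_star)
    Theta_mu_form = beta * (1.0 - 1.0 / R0) * mu / (2.0 * (mu + 1.0) ** 2 - mu)
    assert abs(Theta - Theta_mu_form) <= 1e-10 * max(1.0, abs(Theta))
    xi = (m + beta * k * T_star) - beta * k * I_star / 2.0
    return NeutralEquilibrium(
        S_star=S_star,
        T_star=T_star,
        I_star=I_star,
        D_star=D_star,
        mu=mu,
        Theta=Theta,
        xi=xi,
    )


def neutral_A0(params: EpidemicParameters, k: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Linearization of the per-strain (I_i, J_i) neutral subsystem at the
    neutral equilibrium, with its eigen-decomposition.

    Returns ``(A0, eigenvalues, eigenvectors)`` where A0 =
    [[-(m + beta k T*), m], [-beta k T*/2, beta k I*/2]]. A0 is singular:
    its eigenvalues are 0 (slow direction, eigenvector proportional to
    (I*, T*)) and tr(A0) = -xi < 0 (fast decay). Eigenvalues are sorted in
    decreasing order.
    """
    eq = neutral_equilibrium(params, k)
    beta, m = params.beta, params.m
    A0 = np.array(
        [
            [-(m + beta * k * eq.T_star), m],
            [-beta * k * eq.T_star / 2.0, beta * k * eq.I_star / 2.0],
        ]
    )
    eigvals, eigvecs = np.linalg.eig(A0)
    order = np.argsort(eigvals)[::-1]
    return A0, eigvals[order].real, eigvecs[:, order].real


def fast_coordinates(
    Ivec: np.ndarray, Jvec: np.ndarray, eq: NeutralEquilibrium
) -> FastCoordinates:
    """Fast coordinates (H_i, z_i) from per-strain (I_i, J_i).

    Obtained by inverting the change of basis [[2 T*, I*], [D*, T*]]:

        H_i = (T* I_i - I* J_i) / (2 T*^2 - D* I*)
        z_i = (2 T* J_i - D* I_i) / (2 T*^2 - D* I*)

    H_i -> 0 on the fast timescale; when the input sits on the slow
    manifold (I_i = I* w_i, J_i = T* w_i) this returns H = 0, z = w.
    """
    Ivec = np.asarray(Ivec, dtype=float)
    Jvec = np.asarray(Jvec, dtype=float)
    if Ivec.shape != Jvec.shape:
        raise ValueError("Ivec and Jvec must have the same length")
    det = 2.0 * eq.T_star**2 - eq.D_star * eq.I_star
    assert det > 0, "change of basis degenerate; requires R0 > 1, k > 0"
    H = (eq.T_star * Ivec - eq.I_star * Jvec) / det
    z = (2.0 * eq.T_star * Jvec - eq.D_star * Ivec) / det
    return FastCoordinates(H=H, z=z)


def neutral_single_prevalence(
    t: float | np.ndarray,
    I0: float,
    eq: NeutralEquilibrium,
    params: EpidemicParameters,
    k: float,
) -> float | np.ndarray:
    """Closed-form single-colonization prevalence of the neutral model:
    I(t) = I* + exp(-t (m + beta k T*)) (I0 - I*)."""
    rate = params.m + params.beta * k * eq.T_star
    return eq.I_star + np.exp(-np.asarray(t, dtype=float) * rate) * (I0 - eq.I_star)
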