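"""The full 1 + N + N^2 compartmental SIS co-colonization system.

Host compartments: susceptibles S, singly colonized I_i, and co-colonized
I_ij where the host first acquired strain i and then strain j (both
orderings and same-strain pairs I_ii are tracked). With recruitment equal
to mortality the compartments stay on the unit simplex:

    dS/dt    = m (1 - S) - S * sum_j F_j
    dI_i/dt  = F_i S - I_i sum_j K_ij F_j - m I_i
    dI_ij/dt = I_i K_ij F_j - m I_ij

where m = gamma + d and F_i = beta (I_i + (1/2) sum_j (I_ij + I_ji)) =
beta J_i is the force of infection of strain i (each co-colonized host
transmits either of its two strains with probability 1/2).

The integrator state vector is [S, I_1..I_N, I_11, I_12, ..., I_NN]
(co-colonization block row-major); this ordering is stable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .interactions import validate_interaction_matrix
from .params import EpidemicParameters

__all__ = [
    "FullState",
    "AggregatedState",
    "force_of_infection",
    "full_rhs",
    "integrate_full",
    "aggregate",
    "on_manifold_state",
    "uniform_seed_state",
    "FullTrajectory",
]


@dataclass(frozen=True)
class FullState:
    """One point of the full system: (S, I_i, I_ij)."""

    S: float
    Ivec: np.ndarray = field(repr=False)
    Icc: np.ndarray = field(repr=False)

    @property
    def N(self) -> int:
        return self.Ivec.shape[0]

    @property
    def total(self) -> float:
        """Total host fraction; 1 on the simplex."""
        return float(self.S + self.Ivec.sum() + self.Icc.sum())

    def to_vector(self) -> np.ndarray:
        """Flatten to the stable integrator ordering [S, I_i..., I_ij...]."""
        return np.concatenate(([self.S], self.Ivec, self.Icc.ravel()))

    @classmethod
    def from_vector(cls, y: np.ndarray, N: int) -> "FullState":
        y = np.asarray(y, dtype=float)
        if y.size != 1 + N + N * N:
            raise ValueError(f"state vector has {y.size} entries, expected {1 + N + N * N}")
        return cls(S=float(y[0]), Ivec=y[1 : 1 + N].copy(), Icc=y[1 + N :].reshape(N, N).copy())

    def validate(self, atol: float = 1e-8) -> None:
        if self.Icc.shape != (self.N, self.N):
            raise ValueError("Icc must be N x N")
        comps = self.to_vector()
        if not np.all(np.isfinite(comps)):
            raise ValueError("state contains non-finite components")
        if np.any(comps < -atol):
            raise ValueError("state has negative components")
        if abs(self.total - 1.0) > atol:
            raise ValueError(f"state off the unit simplex: total = {self.total!r}")


@dataclass(frozen=True)
class AggregatedState:
    """Aggregates J_i (fraction transmitting strain i), I, D and T = I + D."""

    Jvec: np.ndarray = field(repr=False)
    Isingle: float
    D: float
    T: float


def aggregate(state: FullState) -> AggregatedState:
    """Aggregate a full state: J_i = I_i + (1/2) sum_j (I_ij + I_ji),
    I = sum I_i, D = sum_ij I_ij, T = I + D."""
    J = state.Ivec + 0.5 * (state.Icc.sum(axis=1) + state.Icc.sum(axis=0))
    I = float(state.Ivec.sum())
    D = float(state.Icc.sum())
    return AggregatedState(Jvec=J, Isingle=I, D=D, T=I + D)


def force_of_infection(state: FullState, params: EpidemicParameters) -> np.ndarray:
    """F_i = beta * J_i for every strain i."""
    return params.beta * aggregate(state).Jvec


def full_rhs(
    state: FullState, params: EpidemicParameters, K: np.ndarray
) -> FullState:
    """Time derivative of the full system at ``state``.

    The component sum of the returned derivative is zero whenever the state
    components sum to one (host conservation with r = d).
    """
    K = np.asarray(K, dtype=float)
    if K.shape != (state.N, state.N):
        raise ValueError(f"K shape {K.shape} does not match N = {state.N}")
    m = params.m
    F = force_of_infection(state, params)
    dS = m * (1.0 - state.S) - state.S * F.sum()
    dI = F * state.S - state.Ivec * (K @ F) - m * state.Ivec
    dIcc = state.Ivec[:, None] * K * F[None, :] - m * state.Icc
    return FullState(S=float(dS), Ivec=dI, Icc=dIcc)


def on_manifold_state(
    z0: np.ndarray, eq, N: int | None = None
) -> FullState:
    """Build a full state on the slow manifold from target frequencies z0.

    Places hosts at the neutral endemic proportions: S = S*, I_i = I* z0_i,
    I_ij = D* z0_i z0_j. ``eq`` is a :class:`~costrain.neutral.NeutralEquilibrium`.
    """
    z0 = np.asarray(z0, dtype=float)
    if N is not None and z0.shape[0] != N:
        raise ValueError("z0 length does not match N")
    if np.any(z0 < 0) or abs(z0.sum() - 1.0) > 1e-9:
        raise ValueError("z0 must lie on the unit simplex")
    return FullState(
        S=eq.S_star,
        Ivec=eq.I_star * z0,
        Icc=eq.D_star * np.outer(z0, z0),
    )


def uniform_seed_state(N: int, infected: float = 0.01) -> FullState:
    """An off-manifold start: small uniform single colonization, no
    co-colonization; exercises the fast transient."""
    Ivec = np.full(N, infected / N)
    return FullState(S=1.0 - infected, Ivec=Ivec, Icc=np.zeros((N, N)))


@dataclass(frozen=True)
class FullTrajectory:
    """Trajectory of the full system on a fixed time grid.

    ``states[t]`` is the (possibly clamped) FullState at ``times[t]``;
    ``n_clamped`` counts negative-undershoot components clamped to zero on
    output (the RHS itself is never clamped).
    """

    times: np.ndarray
    states: list
    n_clamped: int = 0

    def __len__(self) -> int:
        return len(self.states)

    def aggregates(self) -> pd.DataFrame:
        rows = []
        for t, s in zip(self.times, self.states):
            agg = aggregate(s)
            rows.append({"time": t, "S": s.S, "I": agg.Isingle, "D": agg.D, "T": agg.T})
        return pd.DataFrame(rows)

    def frequencies(self) -> np.ndarray:
        """Strain frequencies z_i := J_i / T at each time (rows = times)."""
        out = np.empty((len(self.times), self.states[0].N))
        for row, s in enumerate(self.states):
            agg = aggregate(s)
            out[row] = agg.Jvec / agg.T if agg.T > 0 else np.nan
        return out

    def to_frame(self) -> pd.DataFrame:
        """Long-form table (time, compartment, value) with labels S, I_i, I_i_j."""
        N = self.states[0].N
        labels = (
            ["S"]
            + [f"I_{i + 1}" for i in range(N)]
            + [f"I_{i + 1}_{j + 1}" for i in range(N) for j in range(N)]
        )
        records = []
        for t, s in zip(self.times, self.states):
            for lab, v in zip(labels, s.to_vector()):
                records.append((t, lab, v))
        return pd.DataFrame(records, columns=["time", "compartment", "value"])


def integrate_full(
    initial: FullState,
    params: EpidemicParameters,
    K: np.ndarray,
    times: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> FullTrajectory:
    """Integrate the full system and return the trajectory at ``times``.

    The initial state must lie on the unit simplex; host conservation is
    checked along the output (|1 - total| <= 1e-8). Small negative solver
    undershoots are clamped to zero on output only and counted.
    """
    K = validate_interaction_matrix(K)
    initial.validate()
    N = initial.N
    if K.shape[0] != N:
        raise ValueError(f"K shape {K.shape} does not match state N = {N}")
    times = np.asarray(times, dtype=float)
    m, beta = params.m, params.beta

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        S = y[0]
        Ivec = y[1 : 1 + N]
        Icc = y[1 + N :].reshape(N, N)
        J = Ivec + 0.5 * (Icc.sum(axis=1) + Icc.sum(axis=0))
        F = beta * J
        dS = m * (1.0 - S) - S * F.sum()
        dI = F * S - Ivec * (K @ F) - m * Ivec
        dIcc = Ivec[:, None] * K * F[None, :] - m * Icc
        return np.concatenate(([dS], dI, dIcc.ravel()))

    sol = solve_ivp(
        rhs,
        (times[0], times[-1]),
        initial.to_vector(),
        t_eval=times,
        method=method,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"full-system integration failed: {sol.message}")

    n_clamped = 0
    states = []
    for col in sol.y.T:
        neg = col < 0
        if np.any(neg):
            n_clamped += int(neg.sum())
            col = np.where(neg, 0.0, col)
        states.append(FullState.from_vector(col, N))
        total = states[-1].total
        if abs(total - 1.0) > 1e-6:
            warnings.warn(
                f"host conservation drift |1-total| = {abs(total - 1.0):.2e}",
                stacklevel=2,
            )
    return FullTrajectory(times=times, states=states, n_clamped=n_clamped)
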