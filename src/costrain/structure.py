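"""Classification of pairwise invasion outcomes and Lambda structures.

For any ordered pair the signs of (lambda_i^j, lambda_j^i) decide the
two-strain outcome: (+,+) stable coexistence, (-,-) bistability (priority
effect), (+,-) strain i excludes j, (-,+) j excludes i. A fitness within
tolerance of zero makes the edge "marginal" (the four-class taxonomy
assumes the product is nonzero).

Whole-matrix structure falls into canonical classes that shape the
collective dynamics: symmetric Lambda gives monotonically increasing mean
fitness Q (the replicator analogue of Fisher's fundamental theorem);
invader-driven (equal columns) favours coexistence hierarchies;
resident-driven (equal rows) favours competitive exclusion with Q -> 0;
antisymmetric Lambda is a zero-sum game with Q identically 0 and cyclic
coexistence; almost-antisymmetric perturbs the center into limit-cycle-like
behaviour. Ensembles of random matrices from each class reproduce these
signatures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .replicator import integrate_replicator, mean_fitness_Q

__all__ = [
    "EdgeOutcome",
    "StructureClass",
    "classify_edge",
    "classify_structure",
    "invasion_network",
    "random_lambda",
    "run_canonical_ensemble",
    "ENSEMBLE_CLASSES",
]


@dataclass(frozen=True)
class EdgeOutcome:
    """Pairwise invasion outcome between strains i and j (0-based)."""

    i: int
    j: int
    outcome: str
    lambda_ij: float
    lambda_ji: float


def classify_edge(lam_ij: float, lam_ji: float, tol: float = 0.0) -> str:
    """Classify a pair from the signs of the two mutual invasion fitnesses.

    Returns one of ``coexistence``, ``bistability``, ``exclusion_i_wins``,
    ``exclusion_j_wins``; ``marginal`` if either fitness is within tol of 0.
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    if abs(lam_ij) <= tol or abs(lam_ji) <= tol:
        return "marginal"
    if lam_ij > 0 and lam_ji > 0:
        return "coexistence"
    if lam_ij < 0 and lam_ji < 0:
        return "bistability"
    return "exclusion_i_wins" if lam_ij > 0 else "exclusion_j_wins"


@dataclass(frozen=True)
class StructureClass:
    """Canonical class label for a Lambda matrix plus per-class deviations.

    ``deviations`` maps candidate class name to its relative deviation in
    Frobenius norm (0 = exact member).
    """

    label: str
    deviations: dict = field(repr=False)


def _offdiag_rel(num: float, scale: float) -> float:
    return num / scale if scale > 0 else 0.0


def classify_structure(
    Lambda: np.ndarray, tol: float = 1e-9, almost_antisym_tol: float = 0.1
) -> StructureClass:
    """Assign a Lambda matrix to its canonical structure class.

    Tested in order: antisymmetric, symmetric, invader_driven (equal
    columns), resident_driven (equal rows), almost_antisymmetric (looser
    threshold), else general. Deviations are relative Frobenius norms. A
    zero matrix (simultaneously symmetric and antisymmetric) is reported as
    ``neutral/degenerate``.
    """
    L = np.asarray(Lambda, dtype=float)
    N = L.shape[0]
    scale = float(np.linalg.norm(L))
    off = ~np.eye(N, dtype=bool)

    # constancy checks use off-diagonal entries only: the zero diagonal is
    # structural, not part of the invader/resident signature.
    # invader_driven: lambda_i^j depends only on invader i (all columns are
    # the same vector, i.e. each row is constant off-diagonal);
    # resident_driven: depends only on resident j (all rows equal, each
    # column constant off-diagonal).
    invader_dev = 0.0
    resident_dev = 0.0
    if N > 1:
        vals = np.where(off, L, np.nan)
        per_invader = np.nanmean(vals, axis=1)
        invader_dev = float(np.sqrt(np.nansum((vals - per_invader[:, None]) ** 2)))
        per_resident = np.nanmean(vals, axis=0)
        resident_dev = float(np.sqrt(np.nansum((vals - per_resident[None, :]) ** 2)))

    deviations = {
        "antisymmetric": _offdiag_rel(float(np.linalg.norm(L + L.T)), scale),
        "symmetric": _offdiag_rel(float(np.linalg.norm(L - L.T)), scale),
        "invader_driven": _offdiag_rel(invader_dev, scale),
        "resident_driven": _offdiag_rel(resident_dev, scale),
    }
    if scale == 0.0:
        return StructureClass(label="neutral/degenerate", deviations=deviations)
    for label in ("antisymmetric", "symmetric", "invader_driven", "resident_driven"):
        if deviations[label] <= tol:
            return StructureClass(label=label, deviations=deviations)
    if deviations["antisymmetric"] <= almost_antisym_tol:
        return StructureClass(label="almost_antisymmetric", deviations=deviations)
    return StructureClass(label="general", deviations=deviations)


def invasion_network(Lambda: np.ndarray, tol: float = 0.0) -> pd.DataFrame:
    """Classify all N(N-1)/2 unordered pairs of the invasion network.

    Returns a table with columns (i, j, lambda_ij, lambda_ji, outcome);
    indices are 0-based with i < j.
    """
    L = np.asarray(Lambda, dtype=float)
    N = L.shape[0]
    rows = []
    for i in range(N):
        for j in range(i + 1, N):
            rows.append(
                {
                    "i": i,
                    "j": j,
                    "lambda_ij": L[i, j],
                    "lambda_ji": L[j, i],
                    "outcome": classify_edge(L[i, j], L[j, i], tol),
                }
            )
    return pd.DataFrame(rows, columns=["i", "j", "lambda_ij", "lambda_ji", "outcome"])


#: Canonical ensemble class names.
ENSEMBLE_CLASSES = (
    "symmetric",
    "invader_driven",
    "resident_driven",
    "antisymmetric",
    "almost_antisymmetric",
    "random",
)


def random_lambda(
    class_name: str,
    N: int,
    rng: np.random.Generator,
    perturbation: float = 0.04,
) -> np.ndarray:
    """Draw a random Lambda of the given canonical class with entries in
    [-1, 1] (uniform) and zero diagonal.

    ``perturbation`` scales the symmetric noise added in the
    almost_antisymmetric class; the default keeps the relative deviation
    from pure antisymmetry (about 2x the perturbation) inside the
    classifier's almost-antisymmetric band of 0.1.
    """
    if class_name not in ENSEMBLE_CLASSES:
        raise ValueError(f"unknown class {class_name!r}; choose from {ENSEMBLE_CLASSES}")
    U = rng.uniform(-1.0, 1.0, size=(N, N))
    if class_name == "symmetric":
        L = np.triu(U, 1)
        L = L + L.T
    elif class_name == "invader_driven":
        L = np.repeat(rng.uniform(-1.0, 1.0, size=(N, 1)), N, axis=1)
    elif class_name == "resident_driven":
        L = np.repeat(rng.uniform(-1.0, 1.0, size=(1, N)), N, axis=0)
    elif class_name == "antisymmetric":
        L = np.triu(U, 1)
        L = L - L.T
    elif class_name == "almost_antisymmetric":
        L = np.triu(U, 1)
        L = L - L.T
        P = rng.uniform(-1.0, 1.0, size=(N, N))
        P = np.triu(P, 1)
        L = L + perturbation * (P + P.T)
    else:  # random
        L = U.copy()
    np.fill_diagonal(L, 0.0)
    return L


def run_canonical_ensemble(
    class_name: str,
    N: int = 10,
    reps: int = 30,
    seed: int | np.random.Generator | None = None,
    tau_grid: np.ndarray | None = None,
    Theta: float = 1.0,
    extinction_threshold: float = 1e-3,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> pd.DataFrame:
    """Replicator ensemble for one canonical Lambda class.

    Each replicate draws a Lambda of the class (uniform entries in [-1, 1]),
    a flat-Dirichlet simplex start, integrates with the given Theta and
    records the mean fitness Q(tau) and the number of extant strains
    (z_i > extinction_threshold). Returns a long-form table with columns
    (replicate, tau, Q, n_extant).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    if tau_grid is None:
        tau_grid = np.linspace(0.0, 30.0, 121)
    tau_grid = np.asarray(tau_grid, dtype=float)
    records = []
    for rep in range(reps):
        L = random_lambda(class_name, N, rng)
        z0 = rng.dirichlet(np.ones(N))
        traj = integrate_replicator(
            z0, L, Theta=Theta, taus=tau_grid, rtol=rtol, atol=atol
        )
        for tau, z in zip(traj.taus, traj.z):
            records.append(
                {
                    "replicate": rep,
                    "tau": tau,
                    "Q": mean_fitness_Q(z, L),
                    "n_extant": int(np.sum(z > extinction_threshold)),
                }
            )
    return pd.DataFrame(records, columns=["replicate", "tau", "Q", "n_extant"])
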