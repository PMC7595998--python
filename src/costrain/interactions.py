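"""Co-colonization interaction matrices and their similarity decomposition.

The matrix K holds the altered-susceptibility factors K_ij: a host already
colonized by strain i acquires co-colonizer j at rate K_ij * F_j instead of
F_j. Rows index the resident/colonizer strain i, columns the incoming
co-colonizer j. K_ij > 1 is facilitation, K_ij < 1 inhibition.

Because the strains are similar, every entry can be written relative to a
common reference k::

    K_ij = k + epsilon * alpha_ij

with k the mean interaction strength, epsilon >= 0 a small deviation scale
and A = (alpha_ij) the normalized deviation matrix. With k the entrywise
mean and epsilon the entrywise root-mean-square deviation, A automatically
has zero mean and Frobenius norm N. This decomposition is the basis of the
slow-fast reduction: epsilon measures how far the community is from the
neutral (all-equal) model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SimilarityDecomposition",
    "validate_interaction_matrix",
    "decompose_interactions",
    "recompose",
    "generate_random_K",
    "generate_structured_K",
    "STRUCTURES",
]


def validate_interaction_matrix(K: np.ndarray) -> np.ndarray:
    """Check that K is a finite, non-negative, square 2-D array.

    Returns the validated matrix as a float ndarray.
    """
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError(f"K must be square, got shape {K.shape}")
    if not np.all(np.isfinite(K)):
        raise ValueError("K contains non-finite entries")
    if np.any(K < 0):
        raise ValueError("K contains negative entries (unphysical susceptibility factor)")
    return K


@dataclass(frozen=True)
class SimilarityDecomposition:
    """K = k + epsilon * A with mean-zero A of Frobenius norm N.

    ``neutral`` is True for the degenerate epsilon = 0 case (constant K),
    where A is the zero matrix by convention and all strain frequencies are
    frozen on the slow timescale.
    """

    k: float
    epsilon: float
    A: np.ndarray = field(repr=False)

    @property
    def N(self) -> int:
        return self.A.shape[0]

    @property
    def neutral(self) -> bool:
        return self.epsilon == 0.0


def decompose_interactions(
    K: np.ndarray, k: float | None = None
) -> SimilarityDecomposition:
    """Split K into reference k, scale epsilon and normalized deviations A.

    By default k is the mean of all N^2 entries and epsilon the root mean
    square of (K_ij - k); then A = (K - k)/epsilon has entrywise mean 0 and
    Frobenius norm N. The reference is mathematically non-unique: an
    explicit ``k`` may be supplied, in which case epsilon is recomputed as
    the RMS distance from that reference (A then has norm N but not
    necessarily zero mean).

    For a constant matrix epsilon = 0 and A is set to zero (neutral model).
    """
    K = validate_interaction_matrix(K)
    if k is None:
        k = float(K.mean())
    else:
        k = float(k)
    epsilon = float(np.sqrt(np.mean((K - k) ** 2)))
    if epsilon == 0.0:
        A = np.zeros_like(K)
    else:
        A = (K - k) / epsilon
    return SimilarityDecomposition(k=k, epsilon=epsilon, A=A)


def recompose(d: SimilarityDecomposition) -> np.ndarray:
    """Inverse of :func:`decompose_interactions`: return k + epsilon * A."""
    return d.k + d.epsilon * np.asarray(d.A, dtype=float)


def generate_random_K(
    N: int,
    k: float = 1.0,
    epsilon: float = 0.1,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw a random interaction matrix with mean k and spread epsilon.

    Entries are i.i.d. Normal(k, epsilon), the natural reading of a random
    matrix "with mean k and standard deviation epsilon". Negative draws are
    clipped at 0 with a warning (clipping shifts the sample moments, so
    report the decomposed k-hat / epsilon-hat rather than the nominal ones).
    """
    if N < 2:
        raise ValueError("random K generation requires N >= 2")
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    rng = np.random.default_rng(seed)
    K = rng.normal(loc=k, scale=epsilon, size=(N, N))
    n_neg = int(np.sum(K < 0))
    if n_neg:
        if n_neg == N * N:
            raise ValueError(
                "all sampled entries are negative; choose k and epsilon with "
                "k - a few epsilon >= 0"
            )
        warnings.warn(
            f"{n_neg} negative draws clipped to 0; sample moments are shifted "
            "(use decompose_interactions for the realized k, epsilon)",
            stacklevel=2,
        )
        K = np.clip(K, 0.0, None)
    return K


#: Structure names accepted by :func:`generate_structured_K`, matching the
#: canonical interaction structures that map onto special invasion-fitness
#: classes (see :mod:`costrain.structure`).
STRUCTURES = (
    "symmetric_general",
    "symmetric_special1",
    "symmetric_special2",
    "diagonal",
    "colonizer_driven",
    "cocolonizer_driven",
    "antisymmetric",
)


def generate_structured_K(
    N: int,
    structure: str,
    k: float = 1.0,
    epsilon: float = 0.1,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw a random K satisfying one of the canonical structural identities.

    structure:
      - ``symmetric_general``: K_ij = K_ji
      - ``symmetric_special1``: K_ij = K_ji and K_ii = k
      - ``symmetric_special2``: K_ij = K_ii + K_jj - k for i != j (symmetric)
      - ``diagonal``: K_ij = k off-diagonal, free diagonal
      - ``colonizer_driven``: K_ij = k_i (constant rows)
      - ``cocolonizer_driven``: K_ij = k_j (constant columns)
      - ``antisymmetric``: (K_ij + K_ji)/2 = k

    The free entries are Normal(k, epsilon) draws (deviations Normal(0,
    epsilon) where the identity dictates the location); results are clipped
    at 0 with a warning if a draw lands negative.
    """
    if structure not in STRUCTURES:
        raise ValueError(f"unknown structure {structure!r}; choose from {STRUCTURES}")
    if N < 2:
        raise ValueError("structured K generation requires N >= 2")
    rng = np.random.default_rng(seed)

    if structure == "symmetric_general":
        K = rng.normal(k, epsilon, size=(N, N))
        K = (K + K.T) / 2.0
    elif structure == "symmetric_special1":
        K = rng.normal(k, epsilon, size=(N, N))
        K = (K + K.T) / 2.0
        np.fill_diagonal(K, k)
    elif structure == "symmetric_special2":
        diag = rng.normal(k, epsilon, size=N)
        K = diag[:, None] + diag[None, :] - k
        np.fill_diagonal(K, diag)
    elif structure == "diagonal":
        K = np.full((N, N), float(k))
        np.fill_diagonal(K, rng.normal(k, epsilon, size=N))
    elif structure == "colonizer_driven":
        K = np.repeat(rng.normal(k, epsilon, size=(N, 1)), N, axis=1)
    elif structure == "cocolonizer_driven":
        K = np.repeat(rng.normal(k, epsilon, size=(1, N)), N, axis=0)
    elif structure == "antisymmetric":
        dev = rng.normal(0.0, epsilon, size=(N, N))
        dev = np.triu(dev, 1)
        K = k + dev - dev.T
    else:  # pragma: no cover - guarded above
        raise AssertionError

    if np.any(K < 0):
        warnings.warn(
            f"structured K ({structure}) had negative entries clipped to 0; "
            "the defining identity may be broken at the clipped entries",
            stacklevel=2,
        )
        K = np.clip(K, 0.0, None)
    return K
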