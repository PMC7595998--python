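"""Global epidemiological parameters shared by all strains.

All strains share transmission rate ``beta``, clearance rate ``gamma`` and
host turnover rate ``r`` (recruitment equals mortality, so population size
is constant). Strain identity enters the model only through the
co-colonization interaction matrix K.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class EpidemicParameters:
    """Shared rates of the multi-strain SIS system.

    Parameters
    ----------
    beta : float
        Transmission rate (1/time), equal for all strains.
    gamma : float
        Clearance rate (1/time), equal for single and co-colonization.
    r : float
        Host turnover rate (1/time); recruitment of susceptibles equals
        mortality ``d = r``, keeping total host fraction at 1.
    N : int
        Number of strains.

    Derived quantities: ``m = gamma + r`` (total rate of returning to the
    susceptible pool) and the basic reproduction number ``R0 = beta / m``.
    """

    beta: float
    gamma: float
    r: float
    N: int = 1

    def __post_init__(self) -> None:
        if self.beta <= 0 or self.gamma <= 0 or self.r <= 0:
            raise ValueError("beta, gamma and r must be strictly positive")
        if int(self.N) != self.N or self.N < 1:
            raise ValueError(f"N must be an integer >= 1, got {self.N!r}")

    @property
    def d(self) -> float:
        """Mortality rate; equals recruitment ``r`` by construction."""
        return self.r

    @property
    def m(self) -> float:
        """Clearance plus mortality, gamma + r."""
        return self.gamma + self.r

    @property
    def R0(self) -> float:
        """Basic reproduction number beta / (gamma + r)."""
        return self.beta / self.m

    def require_endemic(self) -> None:
        """Raise if there is no endemic equilibrium (R0 <= 1)."""
        if self.R0 <= 1:
            raise ValueError(
                f"no endemic equilibrium: R0 = {self.R0:.6g} <= 1 "
                f"(beta={self.beta}, gamma+r={self.m})"
            )
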