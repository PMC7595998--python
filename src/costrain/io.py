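"""File I/O and reproducible configured runs.

Interaction matrices travel as dense CSV (N rows x N columns, optional
single header row of strain labels; values round-trip at 15 significant
digits, row = resident/colonizer, column = incoming co-colonizer).
Run configuration is a flat JSON object; `run_from_config` executes one of
the run modes and writes trajectory CSVs, JSON reports and a provenance
file so any artifact can be regenerated from its config and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .full_system import integrate_full, on_manifold_state
from .interactions import (
    STRUCTURES,
    decompose_interactions,
    generate_random_K,
    generate_structured_K,
)
from .neutral import neutral_equilibrium
from .params import EpidemicParameters
from .replicator import integrate_replicator, invasion_fitness_matrix
from .structure import invasion_network, run_canonical_ensemble
from .validation import approximation_error

logger = logging.getLogger("costrain")

__all__ = ["read_matrix", "write_matrix", "RunConfig", "run_from_config"]


def write_matrix(path, K: np.ndarray, labels: list[str] | None = None) -> None:
    """Write a dense matrix as CSV, optionally with strain labels as header."""
    K = np.asarray(K, dtype=float)
    df = pd.DataFrame(K, columns=labels)
    df.to_csv(path, index=False, header=labels is not None, float_format="%.15g")


def read_matrix(path) -> tuple[np.ndarray, list[str] | None]:
    """Read a dense square CSV matrix; returns (matrix, labels-or-None).

    A header row is detected when the first row contains any non-numeric
    cell. Ragged rows, non-numeric data cells and non-square shapes raise
    with the offending location named.
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ValueError(f"{path}: empty matrix file")
    rows = [ln.split(",") for ln in lines]
    labels: list[str] | None = None

    def _is_number(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    if not all(_is_number(tok) for tok in rows[0]):
        labels = [tok.strip() for tok in rows[0]]
        rows = rows[1:]
    ncols = len(rows[0])
    data = np.empty((len(rows), ncols))
    for r, row in enumerate(rows):
        if len(row) != ncols:
            raise ValueError(f"{path}: ragged row {r + 1} ({len(row)} cells, expected {ncols})")
        for c, tok in enumerate(row):
            if not _is_number(tok):
                raise ValueError(f"{path}: non-numeric cell at row {r + 1}, column {c + 1}: {tok!r}")
            data[r, c] = float(tok)
    if data.shape[0] != data.shape[1]:
        raise ValueError(f"{path}: matrix is {data.shape[0]}x{data.shape[1]}, expected square")
    if labels is not None and len(labels) != data.shape[1]:
        raise ValueError(f"{path}: {len(labels)} header labels for {data.shape[1]} columns")
    return data, labels


_MODES = ("full", "neutral", "replicator", "validate", "ensemble", "network")


@dataclass(frozen=True)
class RunConfig:
    """Flat configuration for one reproducible run.

    Exactly one matrix source: ``matrix_file`` or a generator spec
    (``structure`` of 'random' or a structured name, with k/epsilon/seed).
    """

    mode: str
    beta: float = 2.0
    gamma: float = 0.5
    r: float = 0.5
    N: int = 2
    k: float = 1.0
    epsilon: float = 0.1
    seed: int = 0
    structure: str | None = None
    matrix_file: str | None = None
    t_max: float = 100.0
    tau_max: float = 20.0
    n_out: int = 201
    outdir: str = "costrain_run"

    def __post_init__(self) -> None:
        problems = []
        if self.mode not in _MODES:
            problems.append(f"mode must be one of {_MODES}, got {self.mode!r}")
        if (self.structure is None) == (self.matrix_file is None):
            problems.append("exactly one of structure / matrix_file must be set")
        if self.structure is not None and self.structure not in ("random",) + STRUCTURES:
            problems.append(f"unknown structure {self.structure!r}")
        for name in ("beta", "gamma", "r"):
            if getattr(self, name) <= 0:
                problems.append(f"{name} must be > 0")
        if self.N < 1:
            problems.append("N must be >= 1")
        if problems:
            raise ValueError("invalid config: " + "; ".join(problems))

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def _resolve_matrix(config: RunConfig) -> np.ndarray:
    if config.matrix_file is not None:
        K, _ = read_matrix(config.matrix_file)
        return K
    if config.structure == "random":
        return generate_random_K(config.N, config.k, config.epsilon, seed=config.seed)
    return generate_structured_K(
        config.N, config.structure, config.k, config.epsilon, seed=config.seed
    )


def run_from_config(config: RunConfig) -> Path:
    """Execute one run and write its artifacts; returns the output directory.

    Deterministic given config + seed; every artifact directory carries a
    provenance.json echoing the config and the package version.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = EpidemicParameters(beta=config.beta, gamma=config.gamma, r=config.r, N=config.N)
    logger.info("run mode=%s outdir=%s seed=%d", config.mode, outdir, config.seed)

    if config.mode == "neutral":
        eq = neutral_equilibrium(params, config.k)
        (outdir / "neutral_equilibrium.json").write_text(json.dumps(eq.as_dict(), indent=2))
    else:
        K = _resolve_matrix(config)
        write_matrix(outdir / "K.csv", K)
        dec = decompose_interactions(K)
        eq = neutral_equilibrium(params, dec.k)
        Lambda = invasion_fitness_matrix(dec.A, eq.mu)

        if config.mode == "full":
            rng = np.random.default_rng(config.seed)
            z0 = rng.dirichlet(np.ones(K.shape[0]))
            initial = on_manifold_state(z0, eq)
            times = np.linspace(0.0, config.t_max, config.n_out)
            traj = integrate_full(initial, params, K, times)
            traj.to_frame().to_csv(outdir / "trajectory.csv", index=False)
        elif config.mode == "replicator":
            rng = np.random.default_rng(config.seed)
            z0 = rng.dirichlet(np.ones(K.shape[0]))
            taus = np.linspace(0.0, config.tau_max, config.n_out)
            traj = integrate_replicator(z0, Lambda, Theta=eq.Theta, taus=taus)
            pd.DataFrame(
                traj.z, columns=[f"z_{i + 1}" for i in range(K.shape[0])]
            ).assign(tau=traj.taus).to_csv(outdir / "frequencies.csv", index=False)
        elif config.mode == "network":
            write_matrix(outdir / "Lambda.csv", Lambda)
            invasion_network(Lambda).to_csv(outdir / "network.csv", index=False)
        elif config.mode == "ensemble":
            summary = run_canonical_ensemble(
                "random", N=config.N, reps=10, seed=config.seed
            )
            summary.to_csv(outdir / "ensemble.csv", index=False)
        elif config.mode == "validate":
            rng = np.random.default_rng(config.seed)
            z0 = rng.dirichlet(np.ones(K.shape[0]))
            errors = approximation_error(
                params, dec.A, dec.k, dec.epsilon, z0, horizon=config.t_max
            )
            report = [
                {
                    "epsilon": e.epsilon,
                    "frequency_error": e.frequency_error,
                    "compartment_error": e.compartment_error,
                }
                for e in errors
            ]
            (outdir / "validation.json").write_text(json.dumps(report, indent=2))

    provenance = {"config": {**config.__dict__}, "version": __version__}
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return outdir
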