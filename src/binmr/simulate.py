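"""Confounded binary instrument/exposure/outcome simulator.

The data-generating process is a single binary instrumental variable Z,
a latent standard-normal confounder U, and binary exposure X and outcome Y
drawn from Bernoulli laws with logistic link:

    Z_i ~ Bernoulli(pZ)
    U_i ~ Normal(0, 1)
    X_i ~ Bernoulli(expit(alpha0 + alpha1 * Z_i + cx * U_i))
    Y_i ~ Bernoulli(expit(beta0  + beta1  * X_i + cy * U_i))

``beta1`` is the true causal effect of X on Y on the log-odds scale;
``alpha1`` is the instrument strength; ``cx``/``cy`` control confounding.
U is retained in :class:`Dataset` for diagnostics only — estimators never
see it, mirroring the unobserved-confounder setting.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit as _expit

__all__ = [
    "SimulationConfig",
    "Dataset",
    "ScenarioGrid",
    "expit",
    "draw_dataset",
    "build_core_grid",
    "build_sensitivity_grid",
    "prevalence_summary",
    "CORE_ALPHA1",
    "CORE_SCENARIOS",
]

#: instrument strengths used by the main scenario tables
CORE_ALPHA1: tuple[float, ...] = (0.01, 0.05, 0.1, 0.5, 0.7)

#: core scenario label -> (beta1, confounder effect cx = cy)
CORE_SCENARIOS: dict[str, tuple[float, float]] = {
    "A": (0.0, 0.01),
    "B": (0.0, 1.5),
    "C": (1.0, 0.01),
    "D": (1.0, 1.5),
}


def expit(t):
    """Inverse-logit ``1 / (1 + exp(-t))``, numerically stable for large ``|t|``."""
    return _expit(t)


@dataclass(frozen=True)
class SimulationConfig:
    """One cell of the simulation parameter grid.

    All effect parameters are on the log-odds scale.
    """

    alpha0: float = 0.0
    alpha1: float = 0.01
    beta0: float = 0.0
    beta1: float = 0.0
    cx: float = 0.01
    cy: float = 0.01
    pZ: float = 0.2
    n: int = 1000
    n_reps: int = 8000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha0", "alpha1", "beta0", "beta1", "cx", "cy"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if not 0.0 < self.pZ < 1.0:
            raise ValueError(f"pZ must be in (0, 1), got {self.pZ!r}")
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n!r}")
        if self.n_reps < 1:
            raise ValueError(f"n_reps must be >= 1, got {self.n_reps!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    def label(self) -> str:
        """Compact, unique cell description for output tables."""
        return (
            f"a0={self.alpha0:g},a1={self.alpha1:g},b0={self.beta0:g},"
            f"b1={self.beta1:g},cx={self.cx:g},cy={self.cy:g},"
            f"pZ={self.pZ:g},n={self.n}"
        )


@dataclass
class Dataset:
    """Per-subject binary vectors plus the latent confounder.

    ``U`` is kept only for diagnostics; estimators receive ``(Z, X, Y)``.
    """

    Z: np.ndarray
    X: np.ndarray
    Y: np.ndarray
    U: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.Z)
        if not (len(self.X) == len(self.Y) == len(self.U) == n):
            raise ValueError("Z, X, Y, U must share the same length")

    @property
    def n(self) -> int:
        return len(self.Z)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"Z": self.Z, "X": self.X, "Y": self.Y, "U": self.U})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Dataset":
        df = pd.read_csv(path)
        return cls(
            Z=df["Z"].to_numpy(dtype=np.int8),
            X=df["X"].to_numpy(dtype=np.int8),
            Y=df["Y"].to_numpy(dtype=np.int8),
            U=df["U"].to_numpy(dtype=float),
        )


def draw_dataset(cfg: SimulationConfig, rep_index: int = 0) -> Dataset:
    """Draw one replicate dataset from ``cfg``.

    The random stream is a deterministic function of ``(cfg.seed, rep_index)``
    (a ``SeedSequence`` keyed on both), so any replicate can be regenerated in
    isolation and distinct replicates use statistically independent streams.
    """
    if not 0 <= rep_index < cfg.n_reps:
        raise IndexError(
            f"rep_index {rep_index} outside [0, n_reps={cfg.n_reps})"
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), int(rep_index)]))
    Z = (rng.random(cfg.n) < cfg.pZ).astype(np.int8)
    U = rng.standard_normal(cfg.n)
    px = _expit(cfg.alpha0 + cfg.alpha1 * Z + cfg.cx * U)
    X = (rng.random(cfg.n) < px).astype(np.int8)
    py = _expit(cfg.beta0 + cfg.beta1 * X + cfg.cy * U)
    Y = (rng.random(cfg.n) < py).astype(np.int8)
    return Dataset(Z=Z, X=X, Y=Y, U=U)


@dataclass
class ScenarioGrid:
    """A labelled, ordered collection of simulation cells."""

    label: str
    cells: list[SimulationConfig] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.cells)

    def __iter__(self) -> Iterator[SimulationConfig]:
        return iter(self.cells)

    def to_json(self, path=None) -> str:
        payload = {"label": self.label, "cells": [c.to_dict() for c in self.cells]}
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ScenarioGrid":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            label=payload["label"],
            cells=[SimulationConfig(**c) for c in payload["cells"]],
        )


def _cell_seeds(master_seed: int, count: int) -> np.ndarray:
    # stable per-cell substream seeds, each < 2**31
    state = np.random.SeedSequence(int(master_seed)).generate_state(count)
    return state % np.uint32(2**31)


def build_core_grid(
    alpha1_values: Sequence[float] = CORE_ALPHA1,
    *,
    n: int = 1000,
    pZ: float = 0.2,
    n_reps: int = 8000,
    seed: int = 0,
) -> list[ScenarioGrid]:
    """Scenario grids A-D crossed with the instrument strengths.

    A and B are null-effect (beta1 = 0) with weak / strong confounding;
    C and D have beta1 = 1. Defaults: n = 1000, pZ = 0.2, alpha0 = beta0 = 0,
    8000 replicates.
    """
    alpha1_values = list(alpha1_values)
    if not alpha1_values:
        raise ValueError("alpha1_values must be nonempty")
    seeds = _cell_seeds(seed, len(CORE_SCENARIOS) * len(alpha1_values))
    grids: list[ScenarioGrid] = []
    k = 0
    for label, (beta1, c) in CORE_SCENARIOS.items():
        cells = []
        for a1 in alpha1_values:
            cells.append(
                SimulationConfig(
                    alpha0=0.0, alpha1=a1, beta0=0.0, beta1=beta1,
                    cx=c, cy=c, pZ=pZ, n=n, n_reps=n_reps, seed=int(seeds[k]),
                )
            )
            k += 1
        grids.append(ScenarioGrid(label=label, cells=cells))
    return grids


def build_sensitivity_grid(
    which: int, *, n_reps: int = 8000, seed: int = 0
) -> ScenarioGrid:
    """One of the four sensitivity grids.

    1. sample size n in {50, 200, 500, 1000, 1500}
    2. instrument prevalence pZ in {0.1, 0.2, 0.5, 0.8}
    3. exposure/outcome prevalence via (alpha0, beta0) in
       {(0,0), (1,1), (3,3), (-2,-2)}, crossed with the five instrument
       strengths
    4. confounder effect cx = cy in {0.01, 0.1, 0.5, 1, 1.5, 2}

    Each grid is additionally crossed with beta1 in {0, 1} and (except grid 4)
    cx = cy in {0.01, 1.5}. Unvaried parameters take the defaults
    alpha1 = 0.01, n = 1000, pZ = 0.2, alpha0 = beta0 = 0.
    """
    beta1_values = (0.0, 1.0)
    conf_values = (0.01, 1.5)
    cells_spec: list[dict] = []
    if which == 1:
        for b1 in beta1_values:
            for c in conf_values:
                for n in (50, 200, 500, 1000, 1500):
                    cells_spec.append(dict(beta1=b1, cx=c, cy=c, n=n))
    elif which == 2:
        for b1 in beta1_values:
            for c in conf_values:
                for pz in (0.1, 0.2, 0.5, 0.8):
                    cells_spec.append(dict(beta1=b1, cx=c, cy=c, pZ=pz))
    elif which == 3:
        for b1 in beta1_values:
            for c in conf_values:
                for a1 in CORE_ALPHA1:
                    for a0b0 in (0.0, 1.0, 3.0, -2.0):
                        cells_spec.append(
                            dict(beta1=b1, cx=c, cy=c, alpha1=a1,
                                 alpha0=a0b0, beta0=a0b0)
                        )
    elif which == 4:
        for b1 in beta1_values:
            for c in (0.01, 0.1, 0.5, 1.0, 1.5, 2.0):
                cells_spec.append(dict(beta1=b1, cx=c, cy=c))
    else:
        raise ValueError(f"unknown sensitivity grid {which!r}; expected 1-4")

    seeds = _cell_seeds(seed, len(cells_spec))
    cells = [
        SimulationConfig(n_reps=n_reps, seed=int(s), **spec)
        for spec, s in zip(cells_spec, seeds)
    ]
    return ScenarioGrid(label=f"sens{which}", cells=cells)


def prevalence_summary(
    cfg: SimulationConfig, n_large: int = 100_000
) -> tuple[float, float]:
    """Monte-Carlo estimates of P(X = 1) and P(Y = 1) under ``cfg``.

    Regenerates the per-configuration prevalence table from the model itself
    instead of hard-coding it.
    """
    if n_large < 10_000:
        raise ValueError("n_large must be >= 10000 for a stable estimate")
    big = replace(cfg, n=int(n_large), n_reps=1)
    ds = draw_dataset(big, 0)
    return float(ds.X.mean()), float(ds.Y.mean())
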