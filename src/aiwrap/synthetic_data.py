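"""Simulated high-dimensional regression datasets with a correlated feature block.

Features are multivariate normal with unit variances; the first ``min(15, p)``
features share a compound-symmetry correlation ``rho_block`` and the rest are
independent. The outcome is linear in the features, optionally with explicit
two-way interaction effects, plus Gaussian noise:

    y = beta0 + sum_i beta_i * x_i + sum_{i<j} beta_ij * x_i * x_j + eps,
    eps ~ N(0, sigma^2)

The seven standard scenarios (four marginal, three with interactions) put
alternating coefficients +-0.5 on the first ten features and, for interaction
scenarios, on the nine adjacent pairs (x_i, x_{i+1}), i = 1..9.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Dataset",
    "SimulationScenario",
    "TargetSet",
    "build_covariance",
    "simulate_dataset",
    "standard_scenarios",
    "get_scenario",
    "interaction_label",
]

#: Size of the correlated leading block of features.
BLOCK_SIZE = 15


def interaction_label(i: int, j: int) -> str:
    """Canonical label for the product of features i and j (1-based, i < j)."""
    if not 1 <= i < j:
        raise ValueError(f"interaction indices must satisfy 1 <= i < j, got ({i}, {j})")
    return f"x{i}:x{j}"


@dataclass
class Dataset:
    """A feature matrix with a continuous outcome.

    Columns of ``X`` are named ``x1 .. xp``; ``y`` is the outcome.
    """

    X: pd.DataFrame
    y: pd.Series
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.X) != len(self.y):
            raise ValueError("X and y have different numbers of rows")
        if self.X.isna().any().any() or self.y.isna().any():
            raise ValueError("dataset contains missing values")

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    def to_frame(self) -> pd.DataFrame:
        out = self.X.copy()
        out["y"] = self.y.to_numpy()
        return out

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class TargetSet:
    """The labels carrying true (nonzero) effects in a simulation scenario."""

    marginal_targets: frozenset[str]
    interaction_targets: frozenset[str] = frozenset()

    @property
    def all_targets(self) -> frozenset[str]:
        return self.marginal_targets | self.interaction_targets

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "marginal_targets": sorted(self.marginal_targets),
                    "interaction_targets": sorted(self.interaction_targets),
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "TargetSet":
        d = json.loads(Path(path).read_text())
        return cls(
            frozenset(d["marginal_targets"]), frozenset(d.get("interaction_targets", []))
        )


@dataclass(frozen=True)
class SimulationScenario:
    """Full parameterization of one simulated data-generating process.

    ``beta_marginal`` has length ``p`` (zeros for noise features);
    ``beta_interaction`` maps 1-based ordered pairs (i, j), i < j, to slopes on
    the product x_i * x_j. ``rho_block`` is the common correlation among the
    first ``min(15, p)`` features.
    """

    name: str
    p: int
    n_train: int
    n_test: int
    sigma: float
    beta_marginal: tuple[float, ...]
    beta_interaction: tuple[tuple[int, int, float], ...] = ()
    beta0: float = 0.0
    rho_block: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p < 1:
            raise ValueError("p must be >= 1")
        if self.n_train < 1 or self.n_test < 1:
            raise ValueError("sample sizes must be >= 1")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not 0 <= self.rho_block < 1:
            raise ValueError("rho_block must lie in [0, 1)")
        if len(self.beta_marginal) != self.p:
            raise ValueError("beta_marginal must have length p")
        for i, j, _ in self.beta_interaction:
            if not (1 <= i < j <= self.p):
                raise ValueError(f"interaction pair ({i}, {j}) out of range for p={self.p}")

    def with_seed(self, seed: int) -> "SimulationScenario":
        return SimulationScenario(
            name=self.name,
            p=self.p,
            n_train=self.n_train,
            n_test=self.n_test,
            sigma=self.sigma,
            beta_marginal=self.beta_marginal,
            beta_interaction=self.beta_interaction,
            beta0=self.beta0,
            rho_block=self.rho_block,
            seed=seed,
        )

    def targets(self) -> TargetSet:
        marg = frozenset(
            f"x{i + 1}" for i, b in enumerate(self.beta_marginal) if b != 0.0
        )
        inter = frozenset(
            interaction_label(i, j) for i, j, b in self.beta_interaction if b != 0.0
        )
        return TargetSet(marg, inter)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "p": self.p,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "sigma": self.sigma,
            "beta0": self.beta0,
            "beta_marginal": list(self.beta_marginal),
            "beta_interaction": [[i, j, b] for i, j, b in self.beta_interaction],
            "rho_block": self.rho_block,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationScenario":
        return cls(
            name=d["name"],
            p=d["p"],
            n_train=d["n_train"],
            n_test=d["n_test"],
            sigma=d["sigma"],
            beta_marginal=tuple(d["beta_marginal"]),
            beta_interaction=tuple((i, j, b) for i, j, b in d.get("beta_interaction", [])),
            beta0=d.get("beta0", 0.0),
            rho_block=d.get("rho_block", 0.5),
            seed=d.get("seed", 0),
        )


def build_covariance(p: int, rho_block: float) -> np.ndarray:
    """Covariance of the feature vector: compound-symmetry block, identity outside.

    Unit diagonal; entries ``rho_block`` for i != j within the first
    ``min(15, p)`` features; zero elsewhere. Positive definite for
    0 <= rho_block < 1.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    if not 0 <= rho_block < 1:
        raise ValueError("rho_block must lie in [0, 1) to form a correlation matrix")
    sigma = np.eye(p)
    b = min(BLOCK_SIZE, p)
    block = np.full((b, b), rho_block)
    np.fill_diagonal(block, 1.0)
    sigma[:b, :b] = block
    return sigma


def _alternating(k: int, magnitude: float = 0.5) -> list[float]:
    # +m, -m, +m, ... starting positive
    return [magnitude * (-1.0) ** i for i in range(k)]


def _draw(rng: np.random.Generator, n: int, chol: np.ndarray) -> np.ndarray:
    z = rng.standard_normal((n, chol.shape[0]))
    return z @ chol.T


def _outcome(
    rng: np.random.Generator, X: np.ndarray, scenario: SimulationScenario
) -> np.ndarray:
    beta = np.asarray(scenario.beta_marginal)
    y = scenario.beta0 + X @ beta
    for i, j, b in scenario.beta_interaction:
        y = y + b * X[:, i - 1] * X[:, j - 1]
    if scenario.sigma > 0:
        y = y + rng.normal(0.0, scenario.sigma, size=len(y))
    return y


def simulate_dataset(
    scenario: SimulationScenario,
) -> tuple[Dataset, Dataset, TargetSet]:
    """Draw independent train and test sets from one scenario.

    Train is drawn first, then test, from a single seeded RNG stream, so a
    given seed yields bit-identical data.
    """
    rng = np.random.default_rng(scenario.seed)
    chol = np.linalg.cholesky(build_covariance(scenario.p, scenario.rho_block))
    cols = [f"x{i + 1}" for i in range(scenario.p)]

    def make(n: int, tag: str) -> Dataset:
        X = _draw(rng, n, chol)
        y = _outcome(rng, X, scenario)
        return Dataset(
            X=pd.DataFrame(X, columns=cols),
            y=pd.Series(y, name="y"),
            name=f"{scenario.name}_{tag}" if scenario.name else tag,
        )

    train = make(scenario.n_train, "train")
    test = make(scenario.n_test, "test")
    return train, test, scenario.targets()


# (p, n_train) per named scenario; n_test = 500 and sigma = 0.25 throughout.
_SCENARIO_SHAPES: dict[str, tuple[int, int, bool]] = {
    "1_M": (50, 50, False),
    "2_M": (50, 100, False),
    "3_M": (100, 75, False),
    "4_M": (100, 100, False),
    "1_I": (15, 100, True),
    "2_I": (25, 100, True),
    "3_I": (50, 100, True),
}


def standard_scenarios(rho_block: float = 0.5, seed: int = 0) -> list[SimulationScenario]:
    """The seven standard scenarios: 1_M-4_M (marginal) and 1_I-3_I (interaction).

    Ten marginal targets with alternating coefficients +-0.5 on x1..x10; for
    interaction scenarios additionally nine adjacent-pair interaction effects
    on (x_i, x_{i+1}), i = 1..9, again alternating starting at +0.5. Noise
    sigma = 0.25, test size 500 everywhere.
    """
    scenarios = []
    for name, (p, n_train, interactions) in _SCENARIO_SHAPES.items():
        beta = [0.0] * p
        beta[:10] = _alternating(10)
        inter: tuple[tuple[int, int, float], ...] = ()
        if interactions:
            pair_betas = _alternating(9)
            inter = tuple((i, i + 1, pair_betas[i - 1]) for i in range(1, 10))
        scenarios.append(
            SimulationScenario(
                name=name,
                p=p,
                n_train=n_train,
                n_test=500,
                sigma=0.25,
                beta_marginal=tuple(beta),
                beta_interaction=inter,
                rho_block=rho_block,
                seed=seed,
            )
        )
    return scenarios


def get_scenario(name: str, rho_block: float = 0.5, seed: int = 0) -> SimulationScenario:
    """Look up one standard scenario by name (e.g. ``"1_I"``)."""
    for s in standard_scenarios(rho_block=rho_block, seed=seed):
        if s.name == name:
            return s
    raise KeyError(f"unknown scenario {name!r}; known: {sorted(_SCENARIO_SHAPES)}")
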