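"""Performance Prediction Model: a random-forest surrogate over feature subsets.

The surrogate maps a binary feature-membership vector to the expected
performance c of a LASSO model built on that subset (by default its 10-fold
CV RMSE; the tuned model's training RMSE is available via
``CVConfig.c_metric``). Its training table ``D_perf``
is seeded with k = 15 * p random subsets whose performance is measured for
real, and grows during the wrapper search as gate-passing candidates earn
real fits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .model_core import CVConfig, fit_model
from .synthetic_data import Dataset

logger = logging.getLogger(__name__)

__all__ = [
    "PPM",
    "PPMConfig",
    "PerformanceDataset",
    "sample_random_subsets",
    "build_performance_dataset",
    "train_ppm",
    "predict_performance",
    "mask_to_labels",
    "labels_to_mask",
]


def mask_to_labels(mask: np.ndarray, feature_names: list[str]) -> list[str]:
    return [f for f, m in zip(feature_names, mask) if m]


def labels_to_mask(labels, feature_names: list[str]) -> np.ndarray:
    idx = {f: i for i, f in enumerate(feature_names)}
    mask = np.zeros(len(feature_names), dtype=np.uint8)
    for lab in labels:
        mask[idx[lab]] = 1
    return mask


@dataclass(frozen=True)
class PPMConfig:
    """Surrogate hyperparameters.

    ``k_multiplier`` sets the initial training-table size k = multiplier * p.
    ``subset_law`` is the random-subset size law: "uniform" draws the subset
    size uniformly from {1..p} then features without replacement; "bernoulli"
    includes each feature independently with probability 1/2.
    """

    k_multiplier: int = 15
    subset_law: str = "uniform"
    n_trees: int = 500
    max_features: float = 1 / 3
    seed: int = 0

    def k(self, p: int) -> int:
        return max(1, self.k_multiplier * p)


def sample_random_subsets(
    p: int, k: int, seed: int | np.random.Generator = 0, law: str = "uniform"
) -> np.ndarray:
    """Draw k nonempty random feature subsets as a (k, p) binary matrix."""
    if p < 1 or k < 1:
        raise ValueError("p and k must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    masks = np.zeros((k, p), dtype=np.uint8)
    for r in range(k):
        if law == "uniform":
            s = int(rng.integers(1, p + 1))
            masks[r, rng.choice(p, size=s, replace=False)] = 1
        elif law == "bernoulli":
            row = rng.integers(0, 2, size=p).astype(np.uint8)
            if row.sum() == 0:
                row[rng.integers(p)] = 1
            masks[r] = row
        else:
            raise ValueError(f"unknown subset law {law!r}")
    return masks


class PerformanceDataset:
    """The surrogate's training table: (membership mask, measured performance c).

    Masks are deduplicated: re-validating a mask keeps the first recorded c.
    Each row carries a provenance flag ("initial" random sample vs "wrapper"
    validated candidate) so one can audit that no test data entered the table.
    """

    def __init__(self, p: int, feature_names: list[str] | None = None):
        self.p = p
        self.feature_names = feature_names or [f"x{i + 1}" for i in range(p)]
        self._masks: list[np.ndarray] = []
        self._perf: list[float] = []
        self._prov: list[str] = []
        self._index: dict[bytes, int] = {}

    def __len__(self) -> int:
        return len(self._perf)

    @property
    def masks(self) -> np.ndarray:
        return np.array(self._masks, dtype=np.uint8).reshape(len(self._perf), self.p)

    @property
    def performances(self) -> np.ndarray:
        return np.asarray(self._perf, dtype=float)

    @property
    def provenance(self) -> list[str]:
        return list(self._prov)

    def contains(self, mask: np.ndarray) -> bool:
        return np.asarray(mask, dtype=np.uint8).tobytes() in self._index

    def lookup(self, mask: np.ndarray) -> float:
        return self._perf[self._index[np.asarray(mask, dtype=np.uint8).tobytes()]]

    def add(self, mask: np.ndarray, c: float, provenance: str = "initial") -> bool:
        """Append one row; returns False (no-op) if the mask is already present."""
        mask = np.asarray(mask, dtype=np.uint8)
        if mask.shape != (self.p,):
            raise ValueError(f"mask has shape {mask.shape}, expected ({self.p},)")
        if c < 0:
            raise ValueError("performance c must be >= 0")
        key = mask.tobytes()
        if key in self._index:
            return False
        self._index[key] = len(self._perf)
        self._masks.append(mask.copy())
        self._perf.append(float(c))
        self._prov.append(provenance)
        return True

    def best(self) -> tuple[np.ndarray, float]:
        """The mask with the smallest measured performance."""
        if not self._perf:
            raise ValueError("empty performance dataset")
        i = int(np.argmin(self._perf))
        return self._masks[i].copy(), self._perf[i]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.masks, columns=self.feature_names)
        df["c"] = self.performances
        df["provenance"] = self.provenance
        return df

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "PerformanceDataset":
        df = pd.read_csv(path)
        names = [c for c in df.columns if c not in ("c", "provenance")]
        out = cls(p=len(names), feature_names=names)
        prov = df["provenance"] if "provenance" in df else ["initial"] * len(df)
        for mask, c, pv in zip(df[names].to_numpy(), df["c"], prov):
            out.add(np.asarray(mask, dtype=np.uint8), float(c), str(pv))
        return out


def build_performance_dataset(
    train: Dataset,
    subsets: np.ndarray,
    cv: CVConfig | None = None,
    provenance: str = "initial",
    fit_counter: list | None = None,
) -> PerformanceDataset:
    """Fit a LASSO base model per subset and record its performance as c.

    A base-model failure is recorded with the fallback c = sd(y) (the
    intercept-only level) and logged rather than aborting the table build.
    """
    subsets = np.asarray(subsets, dtype=np.uint8)
    if subsets.ndim != 2 or subsets.shape[0] == 0:
        raise ValueError("subsets must be a nonempty (k, p) matrix")
    cv = cv or CVConfig()
    dperf = PerformanceDataset(p=train.p, feature_names=train.feature_names)
    y = train.y.to_numpy()
    sd_y = float(np.std(y))
    for mask in subsets:
        if dperf.contains(mask):
            continue
        cols = mask_to_labels(mask, train.feature_names)
        try:
            model = fit_model(train.X[cols], y, technique="lasso", cv=cv)
            c = model.performance(cv.c_metric)
            if fit_counter is not None:
                fit_counter[0] += 1
        except Exception as exc:  # pragma: no cover - defensive fallback
            logger.warning("base model failed on subset %s: %s; using c=sd(y)", cols, exc)
            c = sd_y
        dperf.add(mask, c, provenance)
    return dperf


@dataclass
class PPM:
    """Trained surrogate; predicts subset performance without any model fitting."""

    forest: RandomForestRegressor
    p: int
    n_training_rows: int
    config: PPMConfig

    def predict(self, masks: np.ndarray) -> np.ndarray:
        masks = np.asarray(masks, dtype=float)
        if masks.size == 0:
            return np.zeros(0)
        if masks.ndim == 1:
            masks = masks.reshape(1, -1)
        if masks.shape[1] != self.p:
            raise ValueError(f"masks have dimension {masks.shape[1]}, expected {self.p}")
        return self.forest.predict(masks)


def train_ppm(dperf: PerformanceDataset, config: PPMConfig | None = None) -> PPM:
    """Train (or retrain from scratch) the random-forest surrogate on D_perf."""
    config = config or PPMConfig()
    if len(dperf) < 1:
        raise ValueError("cannot train PPM on an empty performance dataset")
    forest = RandomForestRegressor(
        n_estimators=config.n_trees,
        max_features=config.max_features,
        bootstrap=True,
        random_state=config.seed,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        forest.fit(dperf.masks.astype(float), dperf.performances)
    return PPM(forest=forest, p=dperf.p, n_training_rows=len(dperf), config=config)


def predict_performance(ppm: PPM, subsets: np.ndarray) -> np.ndarray:
    """Score subsets with the surrogate; performs zero base-model fits."""
    return ppm.predict(subsets)
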