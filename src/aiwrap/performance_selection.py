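"""Performance-based final filter on q_embed.

For each feature l in q_embed, ridge models lacking l are fitted on B
bootstrap resamples and scored by R^2 on the out-of-bag rows; the coefficient
of variation (sd/mean) of those B values is the importance of l — a large
value means the fit destabilizes when l is absent. A genetic algorithm then
searches the (finite) space of cutoffs on the importance scores; each cutoff
keeps the features at or above it, fits the requested technique, and is
scored by mean bootstrap OOB R^2, with ties (within 1e-6) broken toward the
smaller feature set. The winning set q_best is refitted as the final model:
plain linear regression (LLr variant) or CV-tuned ridge (LR variant).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_core import CVConfig, FittedModel, fit_model, r_squared
from .wrapper_search import GAConfig

logger = logging.getLogger(__name__)

__all__ = [
    "ImportanceRecord",
    "ThresholdSearchResult",
    "loo_importance",
    "threshold_search",
    "fit_final_model",
]

#: two cutoffs whose performance differs by less than this are tied
TIE_TOL = 1e-6


@dataclass
class ImportanceRecord:
    """Leave-one-feature-out importance of one feature.

    ``oob_r2`` holds the B bootstrap OOB R^2 values of the model *lacking*
    the feature; ``score`` is their coefficient of variation. A non-positive
    mean R^2 (removal is catastrophic) is flagged and scored +inf.
    """

    feature: str
    oob_r2: np.ndarray
    score: float
    degenerate: bool = False


def _bootstrap_indices(
    rng: np.random.Generator, n: int, max_redraws: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    for _ in range(max_redraws):
        idx = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), idx)
        if oob.size > 1:
            return idx, oob
        logger.debug("bootstrap with empty/degenerate OOB set redrawn")
    raise RuntimeError("could not draw a bootstrap with a usable OOB set")


def _oob_r2_samples(
    X: pd.DataFrame,
    y: np.ndarray,
    B: int,
    rng: np.random.Generator,
    cv: CVConfig,
    technique: str = "ridge",
) -> np.ndarray:
    vals = np.empty(B)
    for b in range(B):
        idx, oob = _bootstrap_indices(rng, len(y))
        if np.ptp(y[oob]) == 0:  # constant OOB outcome: R^2 undefined, redraw
            idx, oob = _bootstrap_indices(rng, len(y))
        tech = technique
        if tech == "ols" and X.shape[1] >= len(idx):
            tech = "ridge"
        model = fit_model(X.iloc[idx], y[idx], technique=tech, cv=cv)
        vals[b] = r_squared(y[oob], model.predict(X.iloc[oob]))
    return vals


def coefficient_of_variation(values: np.ndarray) -> tuple[float, bool]:
    """sd/mean of the values; (+inf, degenerate=True) when the mean is <= 0."""
    mean = float(np.mean(values))
    if mean <= 0:
        return float("inf"), True
    return float(np.std(values, ddof=1) / mean), False


def loo_importance(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    B: int = 100,
    seed: int = 0,
    cv: CVConfig | None = None,
) -> list[ImportanceRecord]:
    """Leave-one-feature-out bootstrap importance for every column of X.

    X must be restricted to q_embed (at least two columns) so each reduced
    model retains at least one feature.
    """
    if X.shape[1] < 2:
        raise ValueError("need at least two features for leave-one-out importance")
    if B < 2:
        raise ValueError("need at least two bootstrap resamples")
    cv = cv or CVConfig()
    y = np.asarray(y, dtype=float)
    records = []
    for k, feature in enumerate(X.columns):
        rng = np.random.default_rng(np.random.SeedSequence([seed, k]))
        reduced = X.drop(columns=[feature])
        vals = _oob_r2_samples(reduced, y, B, rng, cv)
        score, degenerate = coefficient_of_variation(vals)
        records.append(
            ImportanceRecord(feature=feature, oob_r2=vals, score=score, degenerate=degenerate)
        )
    return records


def importance_table(records: list[ImportanceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature": [r.feature for r in records],
            "mean_r2": [float(np.mean(r.oob_r2)) for r in records],
            "sd_r2": [float(np.std(r.oob_r2, ddof=1)) for r in records],
            "cv_score": [r.score for r in records],
        }
    )


@dataclass
class ThresholdSearchResult:
    """The chosen cutoff, the surviving features and the winning performance."""

    c_cutoff: float
    q_best: list[str]
    c_best: float
    technique: str
    trace: pd.DataFrame


def _candidate_cutoffs(scores: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive distinct scores, plus one below the minimum.

    Keeping features with score >= cutoff, these cutoffs enumerate every
    distinct surviving set except the empty one.
    """
    finite = np.unique(scores[np.isfinite(scores)])
    if finite.size == 0:  # all +inf: only the full set exists
        return np.array([0.0])
    cuts = [finite[0] - 1.0]
    cuts.extend((finite[i] + finite[i + 1]) / 2.0 for i in range(finite.size - 1))
    if np.any(~np.isfinite(scores)):
        cuts.append(finite[-1] + 1.0)  # keep only the +inf-scored features
    return np.asarray(cuts)


def prefer(perf_a: float, size_a: int, perf_b: float, size_b: int) -> bool:
    """Is candidate a strictly preferable to b? Maximize performance; within
    the tie tolerance the smaller feature set wins."""
    if perf_a > perf_b + TIE_TOL:
        return True
    if perf_b > perf_a + TIE_TOL:
        return False
    return size_a < size_b


def threshold_search(
    records: list[ImportanceRecord],
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    ga: GAConfig | None = None,
    technique: str = "ridge",
    B_eval: int = 50,
    seed: int = 0,
    cv: CVConfig | None = None,
) -> ThresholdSearchResult:
    """GA search over importance cutoffs for the best small surviving set.

    Each chromosome is a real-valued cutoff snapped onto the finite grid of
    midpoints between consecutive sorted scores. A cutoff keeps features with
    score >= cutoff, fits the requested technique (plain regression falls back
    to ridge whenever the surviving set is not small relative to n), and is
    scored by mean OOB R^2 over ``B_eval`` bootstraps (memoized per distinct
    set). Ties within tolerance go to the smaller set; an empty surviving set
    is never returned.
    """
    if not records:
        raise ValueError("no importance records supplied")
    ga = ga or GAConfig(pop_size=16, generations=15)
    cv = cv or CVConfig()
    y = np.asarray(y, dtype=float)
    scores = np.array([r.score for r in records])
    features = [r.feature for r in records]
    cutoffs = _candidate_cutoffs(scores)

    cache: dict[frozenset, float] = {}
    evaluated: list[dict] = []

    def survivors(cut: float) -> list[str]:
        return [f for f, s in zip(features, scores) if s >= cut]

    def evaluate(cut: float) -> tuple[float, int]:
        kept = survivors(cut)
        if not kept:  # never return the empty set
            return -np.inf, 0
        key = frozenset(kept)
        if key not in cache:
            rng = np.random.default_rng(np.random.SeedSequence([seed, len(cache)]))
            vals = _oob_r2_samples(X[kept], y, B_eval, rng, cv, technique=technique)
            cache[key] = float(np.mean(vals))
            evaluated.append({"cutoff": cut, "n_features": len(kept), "mean_oob_r2": cache[key]})
        return cache[key], len(kept)

    rng = np.random.default_rng(seed)
    if len(cutoffs) <= ga.pop_size:
        genes = cutoffs.copy()
    else:
        genes = rng.choice(cutoffs, size=ga.pop_size, replace=False)

    best_cut, best_perf, best_size = None, -np.inf, np.inf
    lo, hi = float(cutoffs.min()), float(cutoffs.max())
    for _ in range(ga.generations):
        perfs = np.empty(len(genes))
        sizes = np.empty(len(genes), dtype=int)
        for i, cut in enumerate(genes):
            snapped = cutoffs[np.argmin(np.abs(cutoffs - cut))]
            perfs[i], sizes[i] = evaluate(float(snapped))
            if prefer(perfs[i], sizes[i], best_perf, best_size):
                best_cut, best_perf, best_size = float(snapped), perfs[i], int(sizes[i])
        if len(cache) >= len(cutoffs):
            break  # whole finite space evaluated; nothing left to search
        # rank by (performance, then parsimony) and breed real-valued genes
        order = sorted(
            range(len(genes)), key=lambda i: (-perfs[i], sizes[i])
        )
        parents = [genes[i] for i in order[: max(2, len(genes) // 2)]]
        children = [best_cut]
        while len(children) < len(genes):
            a, b = rng.choice(len(parents), size=2, replace=True)
            w = rng.random()
            child = w * parents[a] + (1 - w) * parents[b]
            if rng.random() < 0.2:
                child += rng.normal(0, (hi - lo + 1e-12) * 0.1)
            children.append(float(np.clip(child, lo, hi)))
        genes = np.asarray(children)

    q_best = survivors(best_cut)
    return ThresholdSearchResult(
        c_cutoff=float(best_cut),
        q_best=q_best,
        c_best=float(best_perf),
        technique=technique,
        trace=pd.DataFrame(evaluated),
    )


def fit_final_model(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    q_best: list[str],
    variant: str,
    cv: CVConfig | None = None,
) -> FittedModel:
    """Fit the final predictive model on q_best.

    ``variant`` "LLr" is non-penalized linear regression (requires
    |q_best| < n); "LR" is ridge with a CV-tuned penalty. An empty q_best
    under LR yields the intercept-only model.
    """
    y = np.asarray(y, dtype=float)
    if variant not in ("LLr", "LR"):
        raise ValueError("variant must be 'LLr' or 'LR'")
    if variant == "LLr":
        if not q_best:
            raise ValueError("LLr requires a nonempty feature set")
        if len(q_best) >= len(y):
            raise ValueError(
                f"LLr (OLS) needs |q_best| < n but got {len(q_best)} >= {len(y)}; use LR"
            )
        return fit_model(X[q_best], y, technique="ols", cv=cv)
    return fit_model(X[q_best] if q_best else X[[]], y, technique="ridge", cv=cv)
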