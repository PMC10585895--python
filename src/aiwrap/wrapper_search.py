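"""Genetic-algorithm coarse search over feature subsets.

Two search modes share one engine:

* surrogate-gated (AIWrap): every candidate is scored by the surrogate; only
  candidates whose predicted performance falls in the best quartile of the
  performances measured so far earn a real model fit, which is appended to
  D_perf and the surrogate retrained once per generation;
* standard wrapper (StW): every candidate gets a real fit, no surrogate.

With the surrogate bypassed the gated mode reduces exactly to StW — same RNG
stream, same trace — which is the reference the economy claims are audited
against.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_core import CVConfig, fit_model
from .ppm import (
    PPM,
    PPMConfig,
    PerformanceDataset,
    mask_to_labels,
    sample_random_subsets,
    train_ppm,
)
from .synthetic_data import Dataset

logger = logging.getLogger(__name__)

__all__ = ["GAConfig", "WrapperResult", "validation_threshold", "ga_wrapper_search", "stw_search"]


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings for the binary feature-mask search.

    Defaults: population 50, at most 100 generations, tournament selection of
    size 3, uniform crossover with probability 0.8, per-bit mutation rate 1/p,
    elitism 1. ``val_quantile`` is the fraction of best measured performances
    that defines the validation gate.
    """

    pop_size: int = 50
    generations: int = 100
    crossover_prob: float = 0.8
    mutation_rate: float | None = None  # None -> 1/p
    tournament_size: int = 3
    elitism: int = 1
    seed: int = 0
    val_quantile: float = 0.25
    patience: int | None = None  # generations without improvement; None = run to the cap

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if not 0 <= self.crossover_prob <= 1:
            raise ValueError("crossover_prob must be in [0, 1]")
        if not 0 < self.val_quantile < 1:
            raise ValueError("val_quantile must be in (0, 1)")


@dataclass
class WrapperResult:
    """Outcome of one wrapper search: the best validated subset and its audit trail."""

    q_wrap: np.ndarray
    q_wrap_labels: list[str]
    best_c_true: float
    dperf: PerformanceDataset
    trace: pd.DataFrame
    n_fits_search: int
    n_fits_initial: int
    forced_validations: int = 0

    @property
    def n_fits_total(self) -> int:
        return self.n_fits_search + self.n_fits_initial


def validation_threshold(performances: np.ndarray, quantile: float = 0.25) -> float:
    """The gate level: the interpolated ``quantile`` percentile of measured RMSEs.

    Lower RMSE is better, so the "top quartile" is the best quarter; a
    candidate validates when its predicted performance is at or below this.
    """
    performances = np.asarray(performances, dtype=float)
    if performances.size == 0:
        raise ValueError("cannot compute a validation threshold from no performances")
    return float(np.percentile(performances, 100 * quantile))


def _init_population(p: int, pop_size: int, rng: np.random.Generator) -> np.ndarray:
    return sample_random_subsets(p, pop_size, seed=rng, law="uniform")


def _repair(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if mask.sum() == 0:
        mask[rng.integers(len(mask))] = 1
    return mask


def _next_generation(
    population: np.ndarray, fitness: np.ndarray, ga: GAConfig, rng: np.random.Generator
) -> np.ndarray:
    pop, p = population.shape
    mut = ga.mutation_rate if ga.mutation_rate is not None else 1.0 / p
    order = np.argsort(fitness, kind="stable")
    children: list[np.ndarray] = [population[order[i]].copy() for i in range(ga.elitism)]

    def tournament() -> np.ndarray:
        idx = rng.integers(0, pop, size=ga.tournament_size)
        return population[idx[np.argmin(fitness[idx])]]

    while len(children) < pop:
        a, b = tournament().copy(), tournament().copy()
        if rng.random() < ga.crossover_prob:
            swap = rng.random(p) < 0.5
            a[swap], b[swap] = b[swap], a[swap]
        for child in (a, b):
            flips = rng.random(p) < mut
            child[flips] ^= 1
            children.append(_repair(child, rng))
            if len(children) == pop:
                break
    return np.array(children, dtype=np.uint8)


def _fit_c(train: Dataset, mask: np.ndarray, cv: CVConfig) -> float:
    cols = mask_to_labels(mask, train.feature_names)
    model = fit_model(train.X[cols], train.y.to_numpy(), technique="lasso", cv=cv)
    return model.performance(cv.c_metric)


def ga_wrapper_search(
    train: Dataset,
    dperf: PerformanceDataset | None,
    ppm: PPM | None,
    ga: GAConfig | None = None,
    cv: CVConfig | None = None,
    ppm_config: PPMConfig | None = None,
    bypass_ppm: bool = False,
) -> WrapperResult:
    """Run the surrogate-gated GA wrapper search.

    Per generation: (1) the surrogate scores the population; (2) candidates
    whose prediction beats the quartile gate over all measured performances
    get a real fit, D_perf gains those rows and the surrogate retrains;
    (3) tournament selection, uniform crossover and bit-flip mutation produce
    the next population, with measured performance used as fitness where
    available and the prediction otherwise. If a generation validates nothing,
    its best-predicted unseen candidate is force-validated so a best subset
    always exists. With ``bypass_ppm=True`` the surrogate and gate are skipped
    and every candidate is fitted (the StW behaviour).

    Returns the best validated subset over the whole run (for the gated mode
    this is the argmin over the final D_perf, including the initial random
    sample).
    """
    ga = ga or GAConfig()
    cv = cv or CVConfig()
    p = train.p
    rng = np.random.default_rng(ga.seed)

    if not bypass_ppm:
        if dperf is None or len(dperf) == 0:
            raise ValueError("gated search requires a seeded performance dataset")
        if ppm is None:
            ppm = train_ppm(dperf, ppm_config)
        n_initial = len(dperf)
    else:
        dperf = PerformanceDataset(p=p, feature_names=train.feature_names)
        n_initial = 0

    population = _init_population(p, ga.pop_size, rng)
    trace_rows = []
    n_fits = 0
    forced = 0
    best_c = np.inf
    best_mask = population[0].copy()
    stale = 0

    for gen in range(ga.generations):
        improved = False
        if bypass_ppm:
            fitness = np.empty(ga.pop_size)
            for i, mask in enumerate(population):
                c = _fit_c(train, mask, cv)
                n_fits += 1
                fitness[i] = c
                dperf.add(mask, c, provenance="wrapper")
                if c < best_c:
                    best_c, best_mask, improved = c, mask.copy(), True
            n_validated = ga.pop_size
            best_pred = float(fitness.min())
        else:
            preds = ppm.predict(population)
            thr = validation_threshold(dperf.performances, ga.val_quantile)
            candidates = [
                i
                for i in range(ga.pop_size)
                if preds[i] <= thr and not dperf.contains(population[i])
            ]
            if not candidates:
                unseen = [
                    i for i in range(ga.pop_size) if not dperf.contains(population[i])
                ]
                if unseen:
                    pick = min(unseen, key=lambda i: preds[i])
                    candidates = [pick]
                    forced += 1
                    logger.debug("generation %d: gate empty, force-validating best-predicted", gen)
            n_validated = len(candidates)
            for i in candidates:
                c = _fit_c(train, population[i], cv)
                n_fits += 1
                dperf.add(population[i], c, provenance="wrapper")
            if candidates:
                ppm = train_ppm(dperf, ppm_config or ppm.config)
            fitness = preds.copy()
            for i, mask in enumerate(population):
                if dperf.contains(mask):
                    fitness[i] = dperf.lookup(mask)
            gen_best_mask, gen_best_c = dperf.best()
            if gen_best_c < best_c:
                best_c, best_mask, improved = gen_best_c, gen_best_mask, True
            best_pred = float(preds.min())

        trace_rows.append(
            {
                "generation": gen,
                "best_pred": best_pred,
                "best_true": best_c,
                "n_validated": n_validated,
                "n_fits": n_fits,
            }
        )
        stale = 0 if improved else stale + 1
        if ga.patience is not None and stale >= ga.patience:
            break
        if gen < ga.generations - 1:
            population = _next_generation(population, fitness, ga, rng)

    return WrapperResult(
        q_wrap=best_mask,
        q_wrap_labels=mask_to_labels(best_mask, train.feature_names),
        best_c_true=float(best_c),
        dperf=dperf,
        trace=pd.DataFrame(trace_rows),
        n_fits_search=n_fits,
        n_fits_initial=n_initial,
        forced_validations=forced,
    )


def stw_search(
    train: Dataset, ga: GAConfig | None = None, cv: CVConfig | None = None
) -> WrapperResult:
    """Standard wrapper: the identical GA with a real model fit for every candidate."""
    return ga_wrapper_search(train, dperf=None, ppm=None, ga=ga, cv=cv, bypass_ppm=True)
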