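"""Orchestration of the four selection stages into the pipeline variants.

Variants:

* ``L``   — surrogate-gated wrapper search, then embedded LASSO with two-way
            interaction expansion; the embedded model is final.
* ``LLr`` — additionally the performance-based filter; final model is plain
            linear regression on q_best.
* ``LR``  — as LLr but the final model is CV-tuned ridge.
* StW     — the standard wrapper baseline (no surrogate) followed by the same
            embedded step.

One master seed deterministically derives every stage seed, so a full run is
reproducible bit for bit. Selection stages see only the training data.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np

from .embedded_selection import EmbeddedResult, embedded_select, expand_with_interactions
from .model_core import CVConfig, FittedModel
from .performance_selection import (
    ThresholdSearchResult,
    fit_final_model,
    loo_importance,
    threshold_search,
)
from .ppm import PPMConfig, build_performance_dataset, sample_random_subsets, train_ppm
from .synthetic_data import Dataset
from .wrapper_search import GAConfig, WrapperResult, ga_wrapper_search, stw_search

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "SelectionResult", "run_aiwrap", "run_stw"]

VARIANTS = ("L", "LLr", "LR")

_STAGES = ("subsets", "cv", "ppm", "ga", "importance", "threshold")


def derive_seeds(master_seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds (< 2^31) from one master seed."""
    children = np.random.SeedSequence(master_seed).spawn(len(_STAGES))
    return {
        stage: int(child.generate_state(1)[0] % (2**31))
        for stage, child in zip(_STAGES, children)
    }


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one run needs; stage seeds are derived from ``seed``."""

    variant: str = "LR"
    interactions: bool = True
    ppm: PPMConfig = field(default_factory=PPMConfig)
    ga: GAConfig = field(default_factory=GAConfig)
    cv: CVConfig = field(default_factory=CVConfig)
    threshold_ga: GAConfig = field(default_factory=lambda: GAConfig(pop_size=16, generations=15))
    importance_technique: str = "ridge"
    final_ridge: str = "ridge"  # or "adaptive_ridge"
    b_importance: int = 100
    b_eval: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")


@dataclass
class SelectionResult:
    """The nested selections, the final fitted model and the audit counters."""

    method: str
    variant: str
    q_wrap: list[str]
    q_embed: list[str]
    q_final: list[str]
    model: FittedModel
    embedded_model: FittedModel
    wrapper: WrapperResult
    embedded: EmbeddedResult
    threshold: ThresholdSearchResult | None
    seeds: dict[str, int]
    timings: dict[str, float]

    @property
    def n_fits_total(self) -> int:
        return self.wrapper.n_fits_total

    def to_dict(self) -> dict:
        return {
            "schema": 1,
            "method": self.method,
            "variant": self.variant,
            "q_wrap": self.q_wrap,
            "q_embed": self.q_embed,
            "q_final": self.q_final,
            "n_fits_search": self.wrapper.n_fits_search,
            "n_fits_initial": self.wrapper.n_fits_initial,
            "seeds": self.seeds,
            "model": {
                "technique": self.model.technique,
                "intercept": self.model.intercept,
                "coefficients": self.model.coefficients,
                "cv_performance": self.model.cv_performance,
            },
        }


def _finalize(
    method: str,
    config: PipelineConfig,
    train: Dataset,
    wrapper: WrapperResult,
    seeds: dict[str, int],
    timings: dict[str, float],
) -> SelectionResult:
    cv = replace(config.cv, seed=seeds["cv"])
    q_wrap = wrapper.q_wrap_labels
    if not q_wrap:  # cannot happen via the GA (empty masks are repaired) but be safe
        q_wrap = train.feature_names
        logger.warning("empty q_wrap; falling back to the full feature set")

    t0 = time.perf_counter()
    design = expand_with_interactions(train, q_wrap, include_interactions=config.interactions)
    embedded = embedded_select(design, train.y, cv=cv)
    timings["embedded"] = time.perf_counter() - t0

    q_embed = embedded.q_embed
    if not q_embed:
        logger.warning("empty q_embed; falling back to q_wrap")
        q_embed = list(q_wrap)

    threshold_result: ThresholdSearchResult | None = None
    if config.variant == "L" or method == "stw":
        final_model = embedded.model
        q_final = embedded.q_embed or q_embed
    else:
        t0 = time.perf_counter()
        if len(q_embed) >= 2:
            records = loo_importance(
                design.X[q_embed],
                train.y,
                B=config.b_importance,
                seed=seeds["importance"],
                cv=cv,
            )
            threshold_result = threshold_search(
                records,
                design.X,
                train.y,
                ga=config.threshold_ga,
                technique=config.importance_technique,
                B_eval=config.b_eval,
                seed=seeds["threshold"],
                cv=cv,
            )
            q_final = threshold_result.q_best
        else:
            q_final = list(q_embed)
        if not q_final:
            logger.warning("empty q_final; falling back to q_embed")
            q_final = list(q_embed)
        if config.variant == "LLr" and len(q_final) >= train.n:
            logger.warning("LLr infeasible with |q_final| >= n; using ridge final model")
            final_model = fit_final_model(design.X, train.y, q_final, "LR", cv=cv)
        else:
            final_model = fit_final_model(design.X, train.y, q_final, config.variant, cv=cv)
        timings["performance_filter"] = time.perf_counter() - t0

    return SelectionResult(
        method=method,
        variant=config.variant,
        q_wrap=list(q_wrap),
        q_embed=list(embedded.q_embed),
        q_final=list(q_final),
        model=final_model,
        embedded_model=embedded.model,
        wrapper=wrapper,
        embedded=embedded,
        threshold=threshold_result,
        seeds=seeds,
        timings=timings,
    )


def run_aiwrap(train: Dataset, config: PipelineConfig | None = None) -> SelectionResult:
    """Full surrogate-assisted pipeline on one training set."""
    config = config or PipelineConfig()
    if train.p < 2:
        raise ValueError("need at least two candidate features")
    if train.n < 10:
        raise ValueError("need at least ten training samples")
    seeds = derive_seeds(config.seed)
    cv = replace(config.cv, seed=seeds["cv"])
    ppm_cfg = replace(config.ppm, seed=seeds["ppm"])
    ga = replace(config.ga, seed=seeds["ga"])
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    subsets = sample_random_subsets(
        train.p, ppm_cfg.k(train.p), seed=seeds["subsets"], law=ppm_cfg.subset_law
    )
    dperf = build_performance_dataset(train, subsets, cv=cv)
    ppm = train_ppm(dperf, ppm_cfg)
    timings["ppm_build"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    wrapper = ga_wrapper_search(train, dperf, ppm, ga=ga, cv=cv, ppm_config=ppm_cfg)
    timings["wrapper_search"] = time.perf_counter() - t0

    return _finalize("aiwrap", config, train, wrapper, seeds, timings)


def run_stw(train: Dataset, config: PipelineConfig | None = None) -> SelectionResult:
    """Standard-wrapper baseline: all-real-fit GA, then the embedded step."""
    config = config or PipelineConfig(variant="L")
    seeds = derive_seeds(config.seed)
    cv = replace(config.cv, seed=seeds["cv"])
    ga = replace(config.ga, seed=seeds["ga"])
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    wrapper = stw_search(train, ga=ga, cv=cv)
    timings["wrapper_search"] = time.perf_counter() - t0
    return _finalize("stw", config, train, wrapper, seeds, timings)
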