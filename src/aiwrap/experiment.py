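"""Replicated simulation experiments and evaluation metrics.

Metrics follow the simulation-study design: F1 of the selected label set
against the scenario's true (target) labels, with interaction labels counted
as features; test-set RMSE of each variant's predictive model; feature-count
summaries (mean and range); selection frequency per feature across trials and
its ROC AUC as a target/noise discriminator.

F1 is reported both for the embedded-stage selection (the algorithm-level
comparison) and for each variant's final set.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .embedded_selection import embedded_select, expand_with_interactions, interaction_columns
from .model_core import rmse
from .pipeline import PipelineConfig, run_aiwrap, run_stw
from .synthetic_data import Dataset, SimulationScenario, TargetSet, simulate_dataset

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationReport",
    "f1_selection",
    "selection_auc",
    "replicate_experiment",
    "KNOWN_METHODS",
]

KNOWN_METHODS = ("aiwrap-l", "aiwrap-llr", "aiwrap-lr", "stw", "lasso")


def f1_selection(selected, targets: TargetSet | set) -> float:
    """F1 of a selected label set against the target labels.

    Precision is 0 for an empty selection; F1 is 0 when precision + recall
    is 0. Interaction labels ("xi:xj") count as ordinary features.
    """
    target_set = targets.all_targets if isinstance(targets, TargetSet) else set(targets)
    if not target_set:
        raise ValueError("target set must be nonempty")
    sel = set(selected)
    hit = len(sel & target_set)
    precision = hit / len(sel) if sel else 0.0
    recall = hit / len(target_set)
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def selection_auc(frequencies: dict[str, float], targets: TargetSet | set) -> float:
    """ROC AUC of selection frequency as a score for target membership.

    Ties receive half credit (rank / Mann-Whitney formulation). All-equal
    frequencies give 0.5 by construction.
    """
    target_set = targets.all_targets if isinstance(targets, TargetSet) else set(targets)
    labels = np.array([1 if f in target_set else 0 for f in frequencies])
    if labels.min() == labels.max():
        raise ValueError("need at least one target and one noise feature")
    scores = np.array(list(frequencies.values()), dtype=float)
    if np.ptp(scores) == 0:
        return 0.5
    return float(roc_auc_score(labels, scores))


@dataclass
class EvaluationReport:
    """Per-trial records plus pooled summaries for one scenario."""

    scenario: str
    trials: pd.DataFrame
    n_trials: int
    scaled_down: bool = False

    def summary(self) -> pd.DataFrame:
        """Mean, range and 95% CI (mean +/- 1.96 se across trials) per method."""
        rows = []
        for method, g in self.trials.groupby("method", sort=False):
            row: dict = {"method": method, "n_trials": len(g)}
            for col in ("f1_embedded", "f1_final", "test_rmse", "n_selected_final",
                        "n_marginal_final", "n_interaction_final", "n_fits"):
                vals = g[col].dropna().to_numpy(dtype=float)
                if vals.size == 0:
                    continue
                m = float(vals.mean())
                row[f"{col}_mean"] = m
                row[f"{col}_min"] = float(vals.min())
                row[f"{col}_max"] = float(vals.max())
                if vals.size > 1:
                    se = float(vals.std(ddof=1) / np.sqrt(vals.size))
                    row[f"{col}_ci_lo"] = m - 1.96 * se
                    row[f"{col}_ci_hi"] = m + 1.96 * se
                else:
                    row[f"{col}_ci_lo"] = row[f"{col}_ci_hi"] = m
            rows.append(row)
        return pd.DataFrame(rows)

    def selection_frequencies(self, method: str, stage: str = "final") -> dict[str, int]:
        col = "selected_final" if stage == "final" else "selected_embedded"
        g = self.trials[self.trials["method"] == method]
        freq: dict[str, int] = {}
        for labels in g[col]:
            for lab in json.loads(labels) if isinstance(labels, str) else labels:
                freq[lab] = freq.get(lab, 0) + 1
        return freq

    def auc(self, method: str, targets: TargetSet, candidates: list[str]) -> float:
        freq = self.selection_frequencies(method)
        full = {c: float(freq.get(c, 0)) for c in candidates}
        return selection_auc(full, targets)

    def write_csv(self, path: str | Path) -> None:
        self.trials.to_csv(path, index=False)

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "schema": 1,
                    "scenario": self.scenario,
                    "n_trials": self.n_trials,
                    "scaled_down": self.scaled_down,
                    "trials": self.trials.to_dict(orient="records"),
                },
                indent=2,
            )
        )

    @classmethod
    def read_json(cls, path: str | Path) -> "EvaluationReport":
        d = json.loads(Path(path).read_text())
        return cls(
            scenario=d["scenario"],
            trials=pd.DataFrame(d["trials"]),
            n_trials=d["n_trials"],
            scaled_down=d.get("scaled_down", False),
        )


def _labels_json(labels) -> str:
    return json.dumps(sorted(labels))


def _evaluate_on_test(model, test: Dataset, needed_labels: list[str]) -> float:
    X = test.X
    inter = [l for l in needed_labels if ":" in l and l not in X.columns]
    if inter:
        base = sorted({part for lab in inter for part in lab.split(":")})
        X = pd.concat([X, interaction_columns(X, base)], axis=1)
    return rmse(test.y.to_numpy(), model.predict(X))


def _run_method(
    method: str,
    train: Dataset,
    test: Dataset,
    targets: TargetSet,
    config: PipelineConfig,
) -> dict:
    interactions = bool(targets.interaction_targets) and config.interactions
    if method == "lasso":
        if interactions:
            design = expand_with_interactions(train, train.feature_names, True)
        else:
            design = expand_with_interactions(train, train.feature_names, False)
        res = embedded_select(design, train.y, cv=config.cv)
        selected = res.q_embed
        test_rmse = _evaluate_on_test(res.model, test, res.model.feature_names)
        return {
            "selected_embedded": _labels_json(selected),
            "selected_final": _labels_json(selected),
            "f1_embedded": f1_selection(selected, targets),
            "f1_final": f1_selection(selected, targets),
            "test_rmse": test_rmse,
            "n_selected_final": len(selected),
            "n_marginal_final": sum(":" not in f for f in selected),
            "n_interaction_final": sum(":" in f for f in selected),
            "n_fits": 1,
        }

    if method == "stw":
        result = run_stw(train, replace(config, variant="L", interactions=interactions))
    else:
        variant = {"aiwrap-l": "L", "aiwrap-llr": "LLr", "aiwrap-lr": "LR"}[method]
        result = run_aiwrap(train, replace(config, variant=variant, interactions=interactions))
    test_rmse = _evaluate_on_test(result.model, test, result.model.feature_names)
    return {
        "selected_embedded": _labels_json(result.q_embed),
        "selected_final": _labels_json(result.q_final),
        "f1_embedded": f1_selection(result.q_embed, targets),
        "f1_final": f1_selection(result.q_final, targets),
        "test_rmse": test_rmse,
        "n_selected_final": len(result.q_final),
        "n_marginal_final": sum(":" not in f for f in result.q_final),
        "n_interaction_final": sum(":" in f for f in result.q_final),
        "n_fits": result.n_fits_total,
    }


def replicate_experiment(
    scenario: SimulationScenario,
    methods: list[str],
    n_trials: int = 10,
    master_seed: int = 0,
    config: PipelineConfig | None = None,
) -> EvaluationReport:
    """Run each method on fresh seeded train/test draws and pool the metrics.

    Each trial draws an independent train/test pair; all methods in a trial
    share that pair. A failed method run is recorded with NaN metrics and
    excluded from pooled summaries.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    unknown = [m for m in methods if m not in KNOWN_METHODS]
    if unknown:
        raise ValueError(f"unknown methods {unknown}; known: {KNOWN_METHODS}")
    base_config = config or PipelineConfig()
    rows = []
    trial_seeds = np.random.SeedSequence(master_seed).spawn(n_trials)
    for t, tseed in enumerate(trial_seeds):
        data_seed, run_seed = (int(s % (2**31)) for s in tseed.generate_state(2))
        train, test, targets = simulate_dataset(scenario.with_seed(data_seed))
        for method in methods:
            cfg = replace(base_config, seed=run_seed)
            try:
                rec = _run_method(method, train, test, targets, cfg)
            except Exception as exc:
                logger.warning("trial %d method %s failed: %s", t, method, exc)
                rec = {
                    "selected_embedded": "[]",
                    "selected_final": "[]",
                    "f1_embedded": np.nan,
                    "f1_final": np.nan,
                    "test_rmse": np.nan,
                    "n_selected_final": np.nan,
                    "n_marginal_final": np.nan,
                    "n_interaction_final": np.nan,
                    "n_fits": np.nan,
                }
            rec.update({"trial": t, "method": method, "scenario": scenario.name,
                        "data_seed": data_seed, "run_seed": run_seed})
            rows.append(rec)
    trials = pd.DataFrame(rows)
    return EvaluationReport(
        scenario=scenario.name,
        trials=trials,
        n_trials=n_trials,
        scaled_down=n_trials < 10,
    )
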