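"""Embedded LASSO selection over the wrapper's subset plus two-way interactions.

The coarse subset q_wrap is expanded with all pairwise product features
x_i * x_j (i < j within q_wrap, labelled "xi:xj"), built from the raw
(unstandardized) columns; the whole augmented design is then standardized
inside the penalized fit. Features with nonzero CV-tuned LASSO coefficients
form q_embed, and the fitted model is the AIWrap-L predictive model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .model_core import SELECTION_TOL, CVConfig, FittedModel, fit_model
from .synthetic_data import Dataset

__all__ = ["AugmentedDesign", "EmbeddedResult", "expand_with_interactions", "embedded_select"]


@dataclass
class AugmentedDesign:
    """Base columns plus their pairwise-product interaction columns."""

    X: pd.DataFrame
    base_labels: list[str]
    interaction_labels: list[str]

    @property
    def labels(self) -> list[str]:
        return self.base_labels + self.interaction_labels


def interaction_columns(X: pd.DataFrame, labels: list[str]) -> pd.DataFrame:
    """Pairwise products among ``labels`` in canonical (lower index first) order."""

    def key(lab: str) -> int:
        # canonical order follows position in the design, "x7" -> 7 when numeric
        return X.columns.get_loc(lab)

    ordered = sorted(labels, key=key)
    cols = {}
    for a, b in combinations(ordered, 2):
        cols[f"{a}:{b}"] = X[a].to_numpy() * X[b].to_numpy()
    return pd.DataFrame(cols, index=X.index)


def expand_with_interactions(
    data: Dataset | pd.DataFrame, q_wrap: list[str], include_interactions: bool = True
) -> AugmentedDesign:
    """Build the augmented design on q_wrap: m base columns + m(m-1)/2 products.

    With ``include_interactions=False`` (marginal-model runs) the design is
    just the base columns.
    """
    X = data.X if isinstance(data, Dataset) else data
    if len(q_wrap) < 1:
        raise ValueError("q_wrap must contain at least one feature")
    missing = [f for f in q_wrap if f not in X.columns]
    if missing:
        raise KeyError(f"q_wrap features not in data: {missing}")
    ordered = [c for c in X.columns if c in set(q_wrap)]
    base = X[ordered].copy()
    if include_interactions and len(ordered) > 1:
        inter = interaction_columns(X, ordered)
        design = pd.concat([base, inter], axis=1)
        return AugmentedDesign(X=design, base_labels=ordered, interaction_labels=list(inter.columns))
    return AugmentedDesign(X=base, base_labels=ordered, interaction_labels=[])


@dataclass
class EmbeddedResult:
    """q_embed (nonzero-coefficient labels) and the AIWrap-L model carrying them."""

    q_embed: list[str]
    model: FittedModel

    @property
    def q_embed_marginal(self) -> list[str]:
        return [f for f in self.q_embed if ":" not in f]

    @property
    def q_embed_interaction(self) -> list[str]:
        return [f for f in self.q_embed if ":" in f]


def embedded_select(
    design: AugmentedDesign, y: pd.Series | np.ndarray, cv: CVConfig | None = None
) -> EmbeddedResult:
    """LASSO with 10-fold-CV penalty on the augmented design.

    q_embed is the set of labels with |coefficient| above the selection
    tolerance; an all-zero fit yields an empty q_embed and an intercept-level
    model, with a warning.
    """
    if design.X.shape[1] == 0:
        raise ValueError("augmented design has no columns")
    model = fit_model(design.X, np.asarray(y, dtype=float), technique="lasso", cv=cv)
    q_embed = model.selected_features(SELECTION_TOL)
    if not q_embed:
        warnings.warn("embedded LASSO selected no features; q_embed is empty")
    return EmbeddedResult(q_embed=q_embed, model=model)
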