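"""Table and configuration I/O.

CSV/TSV in (comma/tab inferred from the extension, header mandatory, "."
decimal); JSON/CSV out; YAML run configuration. Rows with missing values are
rejected with a count rather than silently dropped.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
import yaml

from .model_core import CVConfig
from .pipeline import PipelineConfig
from .ppm import PPMConfig
from .synthetic_data import Dataset
from .wrapper_search import GAConfig

logger = logging.getLogger(__name__)

__all__ = ["read_table", "write_table", "load_run_config"]


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_table(path: str | Path, outcome: str = "y") -> Dataset:
    """Read a delimited table into a Dataset, separating the outcome column."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    if df.shape[0] == 0:
        raise ValueError(f"{path} contains no data rows")
    if outcome not in df.columns:
        raise KeyError(f"outcome column {outcome!r} not found in {path}")
    n_missing = int(df.isna().any(axis=1).sum())
    if n_missing:
        raise ValueError(f"{path} has {n_missing} rows with missing values; remove them first")
    non_numeric = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if non_numeric:
        raise ValueError(f"non-numeric columns in {path}: {non_numeric}")
    y = df[outcome]
    X = df.drop(columns=[outcome])
    return Dataset(X=X, y=y, name=path.stem)


def write_table(dataset: Dataset, path: str | Path) -> None:
    path = Path(path)
    dataset.to_frame().to_csv(path, index=False, sep=_sep_for(path))


_KNOWN_KEYS = {
    "variant", "interactions", "seed", "ppm", "ga", "cv", "threshold_ga",
    "importance_technique", "final_ridge", "b_importance", "b_eval",
}


def load_run_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file plus keyword overrides.

    Unknown keys are rejected so typos fail before any compute starts.
    """
    raw: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    raw.update(overrides)
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise KeyError(f"unknown config keys: {sorted(unknown)}")
    sub = {}
    if "ppm" in raw:
        sub["ppm"] = PPMConfig(**raw.pop("ppm"))
    if "ga" in raw:
        sub["ga"] = GAConfig(**raw.pop("ga"))
    if "threshold_ga" in raw:
        sub["threshold_ga"] = GAConfig(**raw.pop("threshold_ga"))
    if "cv" in raw:
        sub["cv"] = CVConfig(**raw.pop("cv"))
    return PipelineConfig(**raw, **sub)
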