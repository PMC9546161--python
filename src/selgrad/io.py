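"""Tabular input, JSON reports, and run configuration.

Trait-fitness tables are read from delimited text (CSV/TSV, header
required); analysis results are written as JSON reports that record
everything needed to regenerate them (coefficients, covariances in the
canonical order, standardization, seed, package version).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .estimators import TraitFitnessTable

logger = logging.getLogger("selgrad")

__all__ = ["RunConfig", "read_trait_fitness", "write_report", "read_report",
           "MissingColumn", "NonNumericFitness", "EmptyTable"]


class MissingColumn(ValueError):
    """A configured column is absent from the input header."""


class NonNumericFitness(ValueError):
    """The fitness column could not be coerced to non-negative numbers."""


class EmptyTable(ValueError):
    """No data rows remain after cleaning."""


@dataclass
class RunConfig:
    """Configuration of one estimation run."""

    input_path: str
    trait_cols: list[str]
    fitness_col: str
    family: str = "poisson"
    standardize: str = "none"
    se_method: str = "delta"  # delta | bootstrap | both
    boot_reps: int = 1000
    seed: int | None = None
    out_path: str | None = None
    delimiter: str | None = None
    verbosity: str = "info"

    def __post_init__(self) -> None:
        if self.se_method not in ("delta", "bootstrap", "both"):
            raise ValueError("se_method must be delta, bootstrap, or both")
        if self.se_method in ("bootstrap", "both") and self.boot_reps < 2:
            raise ValueError("boot_reps must be >= 2 when bootstrapping")


def _infer_delimiter(path: str | Path, override: str | None) -> str:
    if override:
        return override
    suffix = Path(path).suffix.lower()
    return "\t" if suffix in (".tsv", ".tab", ".txt") else ","


def read_trait_fitness(path: str | Path, trait_cols: list[str],
                       fitness_col: str,
                       delimiter: str | None = None) -> TraitFitnessTable:
    """Load a trait-fitness table from a delimited text file.

    Rows with any missing trait or fitness value are dropped (the count is
    logged); fitness is coerced to numeric and must be non-negative.
    """
    sep = _infer_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep)
    for col in list(trait_cols) + [fitness_col]:
        if col not in df.columns:
            raise MissingColumn(
                f"column {col!r} not in header {list(df.columns)}")
    sub = df[list(trait_cols) + [fitness_col]].apply(
        pd.to_numeric, errors="coerce")
    n_before = len(sub)
    sub = sub.dropna()
    n_dropped = n_before - len(sub)
    if n_dropped:
        logger.warning("dropped %d row(s) with missing or non-numeric values",
                       n_dropped)
    if sub.empty:
        raise EmptyTable("no usable rows after dropping missing values")
    fitness = sub[fitness_col].to_numpy(dtype=float)
    if np.any(fitness < 0):
        raise NonNumericFitness("fitness contains negative values")
    return TraitFitnessTable(traits=sub[list(trait_cols)].to_numpy(dtype=float),
                             fitness=fitness,
                             trait_names=tuple(trait_cols))


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def write_report(report: dict, path: str | Path) -> None:
    """Write an analysis report as pretty-printed JSON."""
    Path(path).write_text(json.dumps(_jsonify(report), indent=2) + "\n")


def read_report(path: str | Path) -> dict:
    """Read a JSON report back."""
    return json.loads(Path(path).read_text())
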