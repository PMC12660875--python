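"""Tabular input/output for the command-line interface and scripts."""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import pandas as pd

from .dataset import Dataset

__all__ = ["read_table", "load_mtcars", "write_json"]


def read_table(path: str | Path, response: str) -> Dataset:
    """Read a CSV/TSV file with a header row into a :class:`Dataset`.

    Numeric columns are parsed as real predictors, everything else as
    categorical. Missing values are rejected with cell diagnostics rather
    than silently dropped.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    frame = pd.read_csv(path, sep=sep)
    if response not in frame.columns:
        raise KeyError(
            f"response column {response!r} not found in {path.name} "
            f"(columns: {list(frame.columns)})"
        )
    na = frame.isna()
    if na.any().any():
        cells = [f"row {i + 2}, column {c!r}"  # +2: header line and 1-based rows
                 for c in frame.columns for i in frame.index[na[c]][:5]]
        raise ValueError(f"missing values in {path.name}: " + "; ".join(cells))
    return Dataset.from_frame(frame, response)


def load_mtcars() -> Dataset:
    """The vendored 32-car Motor Trend fuel-economy table (response: mpg)."""
    with resources.files("splitwise.data").joinpath("mtcars.csv").open() as fh:
        frame = pd.read_csv(fh)
    frame = frame.drop(columns=["model"])
    return Dataset.from_frame(frame, "mpg")


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
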