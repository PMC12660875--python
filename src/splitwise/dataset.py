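"""Tabular regression data: a named response plus a typed predictor table."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NUMERIC = "numeric"
CATEGORICAL = "categorical"


@dataclass
class Dataset:
    """A response vector and a predictor table with per-column kind.

    Parameters
    ----------
    predictors
        Predictor table (no response column). Numeric columns are eligible
        for threshold transformation; everything else is categorical.
    y
        Response values, aligned with ``predictors``.
    response
        Name of the response variable (used in reports).
    kinds
        Mapping column -> {"numeric", "categorical"}; inferred from dtypes
        when omitted.
    """

    predictors: pd.DataFrame
    y: pd.Series
    response: str = "y"
    kinds: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.predictors) != len(self.y):
            raise ValueError(
                f"predictors have {len(self.predictors)} rows but response has {len(self.y)}"
            )
        if not self.kinds:
            self.kinds = {
                c: NUMERIC if pd.api.types.is_numeric_dtype(self.predictors[c]) else CATEGORICAL
                for c in self.predictors.columns
            }
        missing = set(self.predictors.columns) - set(self.kinds)
        if missing:
            raise ValueError(f"kinds missing for columns: {sorted(missing)}")
        if not pd.api.types.is_numeric_dtype(self.y):
            raise TypeError(f"response {self.response!r} must be numeric")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, response: str) -> "Dataset":
        """Split a full table into predictors and a designated response column."""
        if response not in frame.columns:
            raise KeyError(f"response column {response!r} not found")
        y = frame[response]
        return cls(frame.drop(columns=[response]), y, response=response)

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def predictor_names(self) -> list[str]:
        return list(self.predictors.columns)

    def numeric_predictors(self) -> list[str]:
        return [c for c in self.predictors.columns if self.kinds[c] == NUMERIC]

    def subset(self, idx: np.ndarray) -> "Dataset":
        """Row subset (positional indices), preserving column kinds."""
        return Dataset(
            self.predictors.iloc[idx].reset_index(drop=True),
            self.y.iloc[idx].reset_index(drop=True),
            response=self.response,
            kinds=dict(self.kinds),
        )

    def train_test_split(self, train_frac: float, rng: np.random.Generator):
        """Random row partition into (train, test) with ``train_frac`` in train."""
        perm = rng.permutation(self.n)
        n_train = int(round(train_frac * self.n))
        return self.subset(perm[:n_train]), self.subset(perm[n_train:])
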