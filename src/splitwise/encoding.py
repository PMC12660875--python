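"""Predictor encodings: excluded, linear, or threshold (dummy) representations.

A numeric predictor may enter the model as a linear term, as a single
indicator I(x > c), or as a two-cutpoint ("double split") encoding with three
ordered segments S1 = {x <= c1}, S2 = {c1 < x <= c2}, S3 = {x > c2}. The
lowest segment S1 is the reference category; indicators are emitted for S2
and S3. Single splits are coded I(x > c) (strict), so segments are
left-closed at the cutpoint. Categorical predictors enter via reference
coding and are never threshold-transformed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import CATEGORICAL, NUMERIC, Dataset
from .linmod import INTERCEPT, DesignMatrix

__all__ = [
    "Encoding",
    "EncodingMap",
    "DegenerateEncodingError",
    "encode_single",
    "encode_double",
    "build_design",
    "segment_support",
    "EXCLUDED",
    "LINEAR",
    "SINGLE_SPLIT",
    "DOUBLE_SPLIT",
]

EXCLUDED = "excluded"
LINEAR = "linear"
SINGLE_SPLIT = "single_split"
DOUBLE_SPLIT = "double_split"

_N_CUTPOINTS = {EXCLUDED: 0, LINEAR: 0, SINGLE_SPLIT: 1, DOUBLE_SPLIT: 2}


class DegenerateEncodingError(ValueError):
    """A threshold encoding produced a constant or empty indicator column."""


@dataclass(frozen=True)
class Encoding:
    """How one predictor is represented in the design matrix."""

    kind: str
    source: str
    cutpoints: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in _N_CUTPOINTS:
            raise ValueError(f"unknown encoding kind {self.kind!r}")
        if len(self.cutpoints) != _N_CUTPOINTS[self.kind]:
            raise ValueError(
                f"{self.kind} encoding requires {_N_CUTPOINTS[self.kind]} cutpoints, "
                f"got {len(self.cutpoints)}"
            )
        if len(self.cutpoints) == 2 and not self.cutpoints[0] < self.cutpoints[1]:
            raise ValueError("cutpoints must be strictly increasing")

    @property
    def is_split(self) -> bool:
        return self.kind in (SINGLE_SPLIT, DOUBLE_SPLIT)

    def describe(self) -> str:
        """Plain-language form, e.g. ``disp > 101.55``."""
        x = self.source
        if self.kind == SINGLE_SPLIT:
            return f"{x} > {self.cutpoints[0]:g}"
        if self.kind == DOUBLE_SPLIT:
            c1, c2 = self.cutpoints
            return f"{c1:g} < {x} <= {c2:g}; {x} > {c2:g} (ref: {x} <= {c1:g})"
        return self.kind


@dataclass
class EncodingMap:
    """One Encoding per predictor plus a transformability flag per column."""

    encodings: dict[str, Encoding]
    eligible: dict[str, bool] = field(default_factory=dict)

    def __getitem__(self, source: str) -> Encoding:
        return self.encodings[source]

    def __setitem__(self, source: str, enc: Encoding) -> None:
        self.encodings[source] = enc

    def __contains__(self, source: str) -> bool:
        return source in self.encodings

    def items(self):
        return self.encodings.items()

    @classmethod
    def all_linear(cls, data: Dataset, transformable: list[str] | None = None) -> "EncodingMap":
        """Every predictor in its untransformed form (categoricals included)."""
        enc = {c: Encoding(LINEAR, c) for c in data.predictor_names}
        elig = {
            c: data.kinds[c] == NUMERIC and (transformable is None or c in transformable)
            for c in data.predictor_names
        }
        return cls(enc, elig)


def encode_single(x: np.ndarray | pd.Series, c: float) -> np.ndarray:
    """Indicator I(x > c) as a float column."""
    xv = np.asarray(x, dtype=float)
    col = (xv > c).astype(float)
    if col.min() == col.max():
        raise DegenerateEncodingError(
            f"cutpoint {c:g} leaves the indicator constant (outside the observed range)"
        )
    return col


def encode_double(x: np.ndarray | pd.Series, c1: float, c2: float) -> tuple[np.ndarray, np.ndarray]:
    """Indicators for segments S2 = (c1, c2] and S3 = (c2, inf); S1 is the reference."""
    if not c1 < c2:
        raise ValueError(f"cutpoints must satisfy c1 < c2, got {c1:g} >= {c2:g}")
    xv = np.asarray(x, dtype=float)
    s2 = ((xv > c1) & (xv <= c2)).astype(float)
    s3 = (xv > c2).astype(float)
    s1 = 1.0 - s2 - s3
    if s1.sum() == 0 or s2.sum() == 0 or s3.sum() == 0:
        raise DegenerateEncodingError(
            f"cutpoints ({c1:g}, {c2:g}) leave an empty segment"
        )
    return s2, s3


def segment_support(x: np.ndarray | pd.Series, cutpoints: list[float]) -> np.ndarray:
    """Fraction of observations in each segment induced by sorted cutpoints.

    Returns ``len(cutpoints) + 1`` fractions summing to 1; the minimum is the
    quantity tested against ``min_support``.
    """
    xv = np.asarray(x, dtype=float)
    cps = list(cutpoints)
    if any(cps[i] >= cps[i + 1] for i in range(len(cps) - 1)):
        raise ValueError("cutpoints must be sorted strictly increasing")
    edges = np.concatenate(([-np.inf], cps, [np.inf]))
    counts = np.array(
        [np.sum((xv > lo) & (xv <= hi)) for lo, hi in zip(edges[:-1], edges[1:])],
        dtype=float,
    )
    return counts / len(xv)


def encoding_columns(x: np.ndarray | pd.Series, enc: Encoding) -> dict[str, np.ndarray]:
    """Design columns (name -> values) for one numeric predictor's encoding."""
    src = enc.source
    if enc.kind == EXCLUDED:
        return {}
    if enc.kind == LINEAR:
        return {src: np.asarray(x, dtype=float)}
    if enc.kind == SINGLE_SPLIT:
        return {f"{src}_dummy": encode_single(x, enc.cutpoints[0])}
    s2, s3 = encode_double(x, *enc.cutpoints)
    return {f"{src}_dummy1": s2, f"{src}_dummy2": s3}


def categorical_columns(x: pd.Series, source: str,
                        levels: list | None = None) -> tuple[dict[str, np.ndarray], list]:
    """Reference-coded indicator columns for a categorical predictor.

    The first (sorted) level is the reference. When ``levels`` is given (at
    prediction time) the training levels are reused without re-estimation.
    """
    if levels is None:
        levels = sorted(pd.unique(x.astype(str)))
    vals = x.astype(str)
    cols = {f"{source}[{lev}]": (vals == lev).to_numpy(dtype=float) for lev in levels[1:]}
    return cols, levels


def build_design(data: Dataset, enc_map: EncodingMap,
                 categorical_levels: dict[str, list] | None = None) -> DesignMatrix:
    """Assemble the intercept + encoded-predictor design matrix.

    Excluded predictors are absent; categoricals expand to reference-coded
    indicators. Degenerate encodings raise.
    """
    levels = categorical_levels if categorical_levels is not None else {}
    cols: dict[str, np.ndarray] = {INTERCEPT: np.ones(data.n)}
    term_map: dict[str, tuple[str, str]] = {INTERCEPT: ("", "intercept")}
    for name in data.predictor_names:
        enc = enc_map[name] if name in enc_map else Encoding(LINEAR, name)
        if enc.kind == EXCLUDED:
            continue
        if data.kinds[name] == CATEGORICAL:
            ccols, lv = categorical_columns(data.predictors[name], name, levels.get(name))
            levels.setdefault(name, lv)
            for cname, cvals in ccols.items():
                cols[cname] = cvals
                term_map[cname] = (name, "categorical")
            continue
        ecols = encoding_columns(data.predictors[name], enc)
        role = "linear" if enc.kind == LINEAR else "dummy"
        for cname, cvals in ecols.items():
            cols[cname] = cvals
            term_map[cname] = (name, role)
    frame = pd.DataFrame(cols, index=data.predictors.index)
    return DesignMatrix(frame, term_map)
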