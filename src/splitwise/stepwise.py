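"""Greedy criterion-driven stepwise selection over grouped candidate terms.

A *term* is an atomic group of design columns that enter or leave the model
jointly: a linear column, a single dummy, the two indicator columns of a
double split, or the reference-coded block of a categorical predictor. At
each step every legal single-term move (additions in forward/both, removals
in backward/both) is scored by refitting, and the best move is taken iff it
strictly lowers the criterion. Ties prefer removals over additions, then the
lexicographically smallest term name, biasing toward sparse, deterministic
solutions. Collinear candidates are rejected, not aliased.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .linmod import (
    DegenerateDesignError,
    DesignMatrix,
    FittedLinearModel,
    fit_ols,
    information_criterion,
)

__all__ = ["Term", "TermSet", "StepRecord", "stepwise_select"]

DIRECTIONS = ("forward", "backward", "both")


@dataclass(frozen=True)
class Term:
    """A named, atomic group of design-matrix columns from one predictor."""

    name: str
    columns: tuple[str, ...]
    source: str


@dataclass
class TermSet:
    """Candidate terms plus the subset currently in the model."""

    candidates: list[Term]
    selected: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [t.name for t in self.candidates]
        if len(set(names)) != len(names):
            raise ValueError("candidate term names must be unique")
        unknown = set(self.selected) - set(names)
        if unknown:
            raise ValueError(f"selected terms not among candidates: {sorted(unknown)}")

    def by_name(self, name: str) -> Term:
        for t in self.candidates:
            if t.name == name:
                return t
        raise KeyError(name)


@dataclass(frozen=True)
class StepRecord:
    """One accepted move of the greedy search."""

    action: str  # "add" | "remove" | "start"
    term: str
    criterion: float


def _columns(terms: TermSet, selected: list[str]) -> list[str]:
    cols: list[str] = []
    for name in selected:
        cols.extend(terms.by_name(name).columns)
    return cols


def _fit_selection(terms: TermSet, design: DesignMatrix, y: np.ndarray,
                   selected: list[str]) -> FittedLinearModel:
    return fit_ols(design.select(_columns(terms, selected)), y)


def _drop_aliased(terms: TermSet, design: DesignMatrix, y: np.ndarray,
                  selected: list[str]) -> list[str]:
    """Greedily keep terms while the design stays full rank (input order)."""
    kept: list[str] = []
    dropped: list[str] = []
    for name in selected:
        try:
            _fit_selection(terms, design, y, kept + [name])
            kept.append(name)
        except DegenerateDesignError:
            dropped.append(name)
    if dropped:
        warnings.warn(
            f"dropping aliased terms from the starting model: {dropped}",
            UserWarning,
            stacklevel=3,
        )
    return kept


def stepwise_select(
    terms: TermSet,
    design: DesignMatrix,
    y: np.ndarray,
    direction: str = "both",
    criterion: str = "aic",
    start: list[str] | None = None,
    trace: list[StepRecord] | None = None,
) -> tuple[FittedLinearModel, list[str]]:
    """Run greedy stepwise selection to convergence.

    Parameters
    ----------
    terms
        Candidate term set; ``terms.selected`` is ignored in favour of
        ``start`` when the latter is given.
    design
        Candidate design matrix containing the columns of every candidate.
    direction
        ``forward`` (additions from the given start, default intercept-only),
        ``backward`` (removals from the full candidate model), or ``both``.
    start
        Starting selection; defaults to empty for forward and the full
        candidate set for backward/both.

    Returns
    -------
    (final fitted model, list of selected term names)
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}, got {direction!r}")
    yv = np.asarray(y, dtype=float)
    if start is None:
        start = [] if direction == "forward" else [t.name for t in terms.candidates]
    selected = _drop_aliased(terms, design, yv, list(start))
    current = _fit_selection(terms, design, yv, selected)
    crit = information_criterion(current, criterion)
    if trace is not None:
        trace.append(StepRecord("start", ",".join(selected) or "(intercept)", crit))

    cache: dict[frozenset, float] = {frozenset(selected): crit}
    while True:
        moves: list[tuple[float, int, str, str]] = []  # (crit, 0=remove/1=add, name, action)
        if direction in ("backward", "both"):
            for name in selected:
                moves.append((_score(terms, design, yv, [s for s in selected if s != name],
                                     criterion, cache), 0, name, "remove"))
        if direction in ("forward", "both"):
            for t in terms.candidates:
                if t.name not in selected:
                    moves.append((_score(terms, design, yv, selected + [t.name],
                                         criterion, cache), 1, t.name, "add"))
        if not moves:
            break
        moves.sort(key=lambda m: (m[0], m[1], m[2]))
        best_crit, _, best_name, action = moves[0]
        if not best_crit < crit:
            break
        if action == "remove":
            selected = [s for s in selected if s != best_name]
        else:
            selected = selected + [best_name]
        crit = best_crit
        if trace is not None:
            trace.append(StepRecord(action, best_name, crit))
    final = _fit_selection(terms, design, yv, selected)
    return final, selected


def _score(terms: TermSet, design: DesignMatrix, y: np.ndarray, selection: list[str],
           criterion: str, cache: dict[frozenset, float]) -> float:
    key = frozenset(selection)
    if key not in cache:
        try:
            cache[key] = information_criterion(
                _fit_selection(terms, design, y, selection), criterion
            )
        except DegenerateDesignError:
            cache[key] = np.inf  # collinear candidate: rejected
    return cache[key]
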