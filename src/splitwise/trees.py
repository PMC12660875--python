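"""Deterministic shallow CART used only to propose threshold candidates.

A depth-<=2 regression tree on a single predictor, grown with the classic
CART rules: candidate thresholds are midpoints between consecutive distinct
sorted values, each split minimises the summed within-child SSE, a split is
kept only when its SSE reduction reaches ``cp`` times the root-node SSE
(cost-complexity pruning, the usual CART convention), and no retained leaf may hold
fewer than ``ceil(min_support * n)`` observations, with n the full sample
size at every node.

Because the thresholds are chosen to maximise in-sample SSE reduction over
many candidates, a "best" split exists even for pure noise. The candidate
extraction therefore additionally prunes by K-fold cross-validation (the
pruning step of the usual CART workflow): a single- or double-split
proposal is offered only when re-estimating that structure on each
training fold predicts the held-out fold better than the fold mean does.
The fold assignment is derived from one fixed internal seed, so the whole
procedure is deterministic: identical inputs give identical trees and
candidates on every platform; ties between equally good thresholds go to
the smallest cutpoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np

__all__ = ["Split", "ShallowTree", "CutpointCandidates", "grow_tree", "extract_candidates"]

#: fixed seed for the cross-validation fold assignment (determinism)
_CV_SEED = 20

#: folds used by cross-validation pruning
CV_FOLDS = 10


@dataclass(frozen=True)
class Split:
    cutpoint: float
    improvement: float  # absolute SSE reduction, >= 0
    n_left: int
    n_right: int


@dataclass
class ShallowTree:
    """Root split plus at most one split per child (depth <= 2).

    ``single_cv_ok`` / ``double_cv_ok`` record whether the one- and
    two-cutpoint structures survived cross-validation pruning; the splits
    themselves always reflect the in-sample SSE optimum.
    """

    root: Split | None
    left: Split | None  # split of the {x <= root.cutpoint} node
    right: Split | None  # split of the {x > root.cutpoint} node
    n: int
    total_sse: float
    single_cv_ok: bool = True
    double_cv_ok: bool = True

    @property
    def is_empty(self) -> bool:
        return self.root is None


@dataclass(frozen=True)
class CutpointCandidates:
    """Threshold proposals extracted from a tree: one single, one ordered pair."""

    single: float | None = None
    double: tuple[float, float] | None = None


def _best_split(x: np.ndarray, t: np.ndarray, min_count: int, min_improvement: float) -> Split | None:
    """SSE-minimising threshold on one node; None if no admissible split.

    Vectorised scan over midpoints of consecutive distinct sorted values
    using prefix sums; O(n log n). First occurrence wins ties, which in the
    ascending scan is the smallest cutpoint.
    """
    n = len(x)
    if n < 2 * min_count:
        return None
    order = np.argsort(x, kind="stable")
    xs, ts = x[order], t[order]
    # boundary after position i is admissible when values differ across it
    distinct = xs[:-1] < xs[1:]
    m = np.arange(1, n)  # left-child sizes
    valid = distinct & (m >= min_count) & (n - m >= min_count)
    if not valid.any():
        return None
    c1 = np.cumsum(ts)[:-1]
    c2 = np.cumsum(ts * ts)[:-1]
    tot1, tot2 = c1[-1] + ts[-1], c2[-1] + ts[-1] * ts[-1]
    sse_total = tot2 - tot1 * tot1 / n
    sse_left = c2 - c1 * c1 / m
    sse_right = (tot2 - c2) - (tot1 - c1) ** 2 / (n - m)
    gain = np.where(valid, sse_total - (sse_left + sse_right), -np.inf)
    best = int(np.argmax(gain))
    if gain[best] < min_improvement or gain[best] <= 0:
        return None
    cut = 0.5 * (xs[best] + xs[best + 1])
    return Split(float(cut), float(gain[best]), int(m[best]), int(n - m[best]))


def _grow_raw(xv: np.ndarray, tv: np.ndarray, min_count: int, cp: float) -> ShallowTree:
    n = len(xv)
    tot = tv - tv.mean()
    total_sse = float(tot @ tot)
    if total_sse == 0.0 or n == 0 or np.min(xv) == np.max(xv):
        return ShallowTree(None, None, None, n, total_sse)
    threshold = cp * total_sse
    root = _best_split(xv, tv, min_count, threshold)
    if root is None:
        return ShallowTree(None, None, None, n, total_sse)
    mask = xv <= root.cutpoint
    left = _best_split(xv[mask], tv[mask], min_count, threshold)
    right = _best_split(xv[~mask], tv[~mask], min_count, threshold)
    return ShallowTree(root, left, right, n, total_sse)


def _double_cutpoints(tree: ShallowTree) -> tuple[float, float] | None:
    """Root plus the child split with the larger SSE gain, sorted."""
    if tree.root is None:
        return None
    children = [s for s in (tree.left, tree.right) if s is not None]
    if not children:
        return None
    children.sort(key=lambda s: (-s.improvement, s.cutpoint))
    c1, c2 = sorted((tree.root.cutpoint, children[0].cutpoint))
    return c1, c2


def _segment_means_predict(x_tr, t_tr, x_te, cuts: list[float]) -> np.ndarray:
    """Piecewise-constant prediction with segment means; empty segments fall
    back to the training mean."""
    edges = np.concatenate(([-np.inf], cuts, [np.inf]))
    pred = np.full(len(x_te), t_tr.mean())
    for lo, hi in zip(edges[:-1], edges[1:]):
        m_tr = (x_tr > lo) & (x_tr <= hi)
        if m_tr.any():
            pred[(x_te > lo) & (x_te <= hi)] = t_tr[m_tr].mean()
    return pred


def _cv_gates(xv: np.ndarray, tv: np.ndarray, min_support: float, cp: float,
              folds: int) -> tuple[bool, bool]:
    """Cross-validated pruning decision for the 1- and 2-cutpoint structures.

    Each fold re-grows the tree on the training part and predicts the held
    fold with the fold's own thresholds and segment means, exactly as the
    structure would be estimated on fresh data. A structure is offered when
    its cross-validated risk beats the fold-mean (null) model's — the
    minimum-risk pruning rule. The sharper one-standard-error rule is
    deliberately not used: the downstream information criterion and
    ``min_improvement`` margin already penalise complexity, and the
    one-SE band suppresses genuinely weak structure the criterion should
    be allowed to judge.
    """
    n = len(xv)
    if folds < 2 or n < 2 * folds:
        return True, True
    rng = np.random.default_rng(_CV_SEED)
    fold_id = rng.permutation(n) % folds
    fold_mse = np.zeros((folds, 3))  # columns: null, single, double
    for k in range(folds):
        te = fold_id == k
        x_tr, t_tr, x_te, t_te = xv[~te], tv[~te], xv[te], tv[te]
        min_count = max(1, ceil(min_support * len(x_tr)))
        ft = _grow_raw(x_tr, t_tr, min_count, cp)
        single_cuts = [ft.root.cutpoint] if ft.root is not None else []
        pred1 = _segment_means_predict(x_tr, t_tr, x_te, single_cuts)
        dcuts = _double_cutpoints(ft)
        pred2 = _segment_means_predict(x_tr, t_tr, x_te, list(dcuts)) if dcuts else pred1
        fold_mse[k, 0] = np.mean((t_te - t_tr.mean()) ** 2)
        fold_mse[k, 1] = np.mean((t_te - pred1) ** 2)
        fold_mse[k, 2] = np.mean((t_te - pred2) ** 2)
    risk = fold_mse.mean(axis=0)
    return bool(risk[1] < risk[0]), bool(risk[2] < risk[0])


def grow_tree(x: np.ndarray, target: np.ndarray, min_support: float = 0.2,
              cp: float = 0.01, cv_folds: int = CV_FOLDS) -> ShallowTree:
    """Grow the depth-<=2 tree of ``target`` on the single predictor ``x``.

    ``cp`` prunes any split improving SSE by less than ``cp * total_sse``;
    ``min_support`` bounds every leaf below by ``ceil(min_support * n)``
    observations. A constant ``x`` or constant target yields an empty tree.
    ``cv_folds`` > 1 additionally runs cross-validation pruning (see module
    docstring); set it to 0 to disable.
    """
    xv = np.asarray(x, dtype=float)
    tv = np.asarray(target, dtype=float)
    if xv.shape != tv.shape:
        raise ValueError("x and target must have equal length")
    min_count = max(1, ceil(min_support * len(xv)))
    tree = _grow_raw(xv, tv, min_count, cp)
    if tree.root is not None and cv_folds and cv_folds > 1:
        tree.single_cv_ok, tree.double_cv_ok = _cv_gates(
            xv, tv, min_support, cp, cv_folds)
    return tree


def extract_candidates(tree: ShallowTree, x: np.ndarray,
                       min_support: float = 0.2) -> CutpointCandidates:
    """Single- and double-split proposals from a grown tree.

    The single candidate is the root cutpoint. The double candidate pairs
    the root with whichever child split improves SSE more (ties to the
    smaller cutpoint), provided all three induced segments keep at least
    ``ceil(min_support * n)`` observations; with no surviving child split
    the double candidate is absent. Structures pruned away by
    cross-validation are not offered.
    """
    if tree.is_empty:
        return CutpointCandidates()
    single = tree.root.cutpoint if tree.single_cv_ok else None
    dcuts = _double_cutpoints(tree)
    if dcuts is None or not tree.double_cv_ok:
        return CutpointCandidates(single=single)
    c1, c2 = dcuts
    xv = np.asarray(x, dtype=float)
    min_count = max(1, ceil(min_support * len(xv)))
    counts = np.array([
        np.sum(xv <= c1),
        np.sum((xv > c1) & (xv <= c2)),
        np.sum(xv > c2),
    ])
    if counts.min() < min_count:
        return CutpointCandidates(single=single)
    return CutpointCandidates(single=single, double=(c1, c2))
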