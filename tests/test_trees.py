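"""Shallow-tree threshold discovery against brute-force and sklearn oracles."""

import numpy as np
import pytest
from itertools import combinations

from splitwise.trees import extract_candidates, grow_tree


def brute_force_root(x, t, min_count):
    """Independent O(n*u) scan over all midpoints between distinct values."""
    x = np.asarray(x, float)
    t = np.asarray(t, float)
    xs = np.unique(x)
    best = None
    for c in (xs[:-1] + xs[1:]) / 2:
        left, right = t[x <= c], t[x > c]
        if len(left) < min_count or len(right) < min_count:
            continue
        s = _sse(left) + _sse(right)
        if best is None or s < best[0] - 1e-12:
            best = (s, c)
    return best


def _sse(v):
    return float(((v - v.mean()) ** 2).sum()) if len(v) else 0.0


def test_constant_target_yields_empty_tree():
    tree = grow_tree(np.arange(10.0), np.ones(10))
    assert tree.is_empty
    assert extract_candidates(tree, np.arange(10.0)).single is None


def test_constant_x_yields_empty_tree():
    tree = grow_tree(np.ones(10), np.arange(10.0))
    assert tree.is_empty


def test_step_target_recovers_midpoint_cutpoint():
    x = np.arange(1.0, 11.0)
    t = (x > 5).astype(float)
    tree = grow_tree(x, t, min_support=0.2)
    assert tree.root.cutpoint == pytest.approx(5.5)
    cands = extract_candidates(tree, x, min_support=0.2)
    assert cands.single == pytest.approx(5.5)
    # a perfect step leaves no child improvement, so no double candidate
    assert cands.double is None


def test_v_shaped_target_matches_exhaustive_two_cutpoint_oracle():
    x = np.arange(1.0, 11.0)
    t = np.array([3, 2, 1, 0, 0, 0, 0, 1, 2, 3], dtype=float)
    tree = grow_tree(x, t, min_support=0.2)
    cands = extract_candidates(tree, x, min_support=0.2)
    # frozen from the exhaustive scan over all two-cutpoint partitions with
    # every segment >= 2 observations: optimum (2.5, 8.5), SSE = 7/3
    assert cands.double == pytest.approx((2.5, 8.5))
    best = None
    mids = (x[:-1] + x[1:]) / 2
    for c1, c2 in combinations(mids, 2):
        seg = [t[x <= c1], t[(x > c1) & (x <= c2)], t[x > c2]]
        if min(len(s) for s in seg) < 2:
            continue
        s = sum(_sse(v) for v in seg)
        if best is None or s < best[0] - 1e-12:
            best = (s, (c1, c2))
    assert cands.double == pytest.approx(best[1])


@pytest.mark.parametrize("seed", range(20))
def test_root_cutpoint_equals_brute_force_scan(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(20, 201))
    x = rng.standard_normal(n) if seed % 2 else rng.integers(0, 8, n).astype(float)
    t = rng.standard_normal(n) + (x > np.median(x)) * rng.uniform(0, 3)
    min_support = 0.15
    min_count = int(np.ceil(min_support * n))
    tree = grow_tree(x, t, min_support=min_support, cp=0.0, cv_folds=0)
    oracle = brute_force_root(x, t, min_count)
    if tree.root is None:
        assert oracle is None or oracle[0] >= _sse(t) - 1e-9
    else:
        assert tree.root.cutpoint == pytest.approx(oracle[1])


@pytest.mark.parametrize("seed", [0, 7])
def test_root_split_matches_sklearn_cart(seed):
    """Cross-check threshold choice against an established CART implementation."""
    sklearn_tree = pytest.importorskip("sklearn.tree")
    rng = np.random.default_rng(seed)
    n = 120
    x = rng.standard_normal(n)
    t = 2.0 * (x > 0.3) + rng.normal(0, 0.4, n)
    min_count = int(np.ceil(0.2 * n))
    ours = grow_tree(x, t, min_support=0.2, cv_folds=0)
    ref = sklearn_tree.DecisionTreeRegressor(
        max_depth=1, min_samples_leaf=min_count, random_state=0
    ).fit(x.reshape(-1, 1), t)
    assert ours.root.cutpoint == pytest.approx(ref.tree_.threshold[0], abs=1e-8)


def test_min_support_respected_in_all_segments():
    rng = np.random.default_rng(3)
    for _ in range(10):
        n = int(rng.integers(30, 150))
        x = rng.standard_normal(n)
        t = np.sin(3 * x) + rng.normal(0, 0.3, n)
        min_support = 0.2
        min_count = int(np.ceil(min_support * n))
        tree = grow_tree(x, t, min_support=min_support)
        cands = extract_candidates(tree, x, min_support=min_support)
        if cands.single is not None:
            assert min((x <= cands.single).sum(), (x > cands.single).sum()) >= min_count
        if cands.double is not None:
            c1, c2 = cands.double
            seg = [(x <= c1).sum(), ((x > c1) & (x <= c2)).sum(), (x > c2).sum()]
            assert min(seg) >= min_count


def test_determinism_across_runs():
    rng = np.random.default_rng(11)
    x = rng.standard_normal(200)
    t = (x > 0.1).astype(float) + rng.normal(0, 0.5, 200)
    t1 = grow_tree(x, t)
    t2 = grow_tree(x, t)
    assert t1.root.cutpoint == t2.root.cutpoint
    assert t1.single_cv_ok == t2.single_cv_ok and t1.double_cv_ok == t2.double_cv_ok


def test_cv_pruning_drops_noise_but_keeps_signal():
    rng = np.random.default_rng(5)
    n = 300
    x = rng.standard_normal(n)
    signal = (x > 0.2).astype(float) + rng.normal(0, 0.45, n)
    strong = grow_tree(x, signal)
    assert strong.single_cv_ok
    assert extract_candidates(strong, x).single is not None
    # pure noise: over several draws the CV gate must reject most proposals
    offered = 0
    for s in range(20):
        r = np.random.default_rng(1000 + s)
        xn, tn = r.standard_normal(n), r.standard_normal(n)
        cands = extract_candidates(grow_tree(xn, tn), xn)
        offered += cands.single is not None or cands.double is not None
    assert offered <= 6  # without CV pruning nearly every draw offers a split


def test_cp_pruning_blocks_weak_splits():
    rng = np.random.default_rng(9)
    x = rng.standard_normal(400)
    t = 0.05 * (x > 0) + rng.normal(0, 1.0, 400)
    # with a large cp the tiny SSE gain cannot clear the pruning threshold
    assert grow_tree(x, t, cp=0.5, cv_folds=0).is_empty
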