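"""Repeated-split benchmark harness and variable-selection metrics.

The synthetic path regenerates a fresh dataset for every replication (seed =
master seed + replication index) and splits it 70/30; the fixed-dataset path
keeps the data constant and resamples the split. Methods plug in through a
small adapter interface so external implementations can be compared on
identical replications; per-replication metrics (test RMSE/MAE, number of
selected predictors and, when the truth is known, the Matthews correlation
of the selection) are summarised by medians and standard deviations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import Dataset
from .model import SplitWiseConfig, SplitWiseModel, splitwise_fit
from .synthetic import ScenarioSpec, generate_scenario

__all__ = [
    "SelectionConfusion",
    "mcc",
    "selection_confusion",
    "BenchmarkResult",
    "run_benchmark",
    "select_mode",
    "SplitWiseAdapter",
    "StepwiseAdapter",
]

_SEED_MOD = 2**31


@dataclass(frozen=True)
class SelectionConfusion:
    """Counts of a variable-selection outcome over p predictors."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def mcc(c: SelectionConfusion) -> float:
    """Matthews correlation coefficient; 0 when any denominator factor is 0."""
    denom = ((c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn))
    if denom == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)


def selection_confusion(selected, truth: set[str], p: int,
                        all_predictors: list[str] | None = None) -> SelectionConfusion:
    """Confusion counts of selected source predictors against the truth set.

    ``selected`` may be a :class:`SplitWiseModel` or any iterable of source
    predictor names; a predictor counts as selected when any of its
    encodings (linear or dummy) appears in the final model.
    """
    if isinstance(selected, SplitWiseModel):
        chosen = selected.selected_sources()
    else:
        chosen = set(selected)
    tp = len(chosen & truth)
    fp = len(chosen - truth)
    fn = len(truth - chosen)
    tn = p - tp - fp - fn
    if tn < 0:
        raise ValueError("selected set inconsistent with p")
    return SelectionConfusion(tp=tp, tn=tn, fp=fp, fn=fn)


class SplitWiseAdapter:
    """Fits SplitWise with a fixed configuration."""

    def __init__(self, config: SplitWiseConfig):
        self.config = config

    def fit(self, train: Dataset) -> SplitWiseModel:
        return splitwise_fit(train, SplitWiseConfig(**{**self.config.__dict__}))


class StepwiseAdapter:
    """Plain stepwise linear regression over untransformed predictors."""

    def __init__(self, direction: str = "forward", criterion: str = "aic"):
        self.direction = direction
        self.criterion = criterion

    def fit(self, train: Dataset) -> SplitWiseModel:
        cfg = SplitWiseConfig(mode="iterative", direction=self.direction,
                              criterion=self.criterion,
                              min_improvement=float("inf"), transformable=[])
        return splitwise_fit(train, cfg)


@dataclass
class BenchmarkResult:
    """Per-replication metrics and their median/SD summaries."""

    per_replication: pd.DataFrame
    summary: pd.DataFrame
    config: dict
    n_failures: int = 0

    def median(self, method: str, metric: str) -> float:
        return float(self.summary.loc[(method, metric), "median"])


def _evaluate_one(adapter, train: Dataset, test: Dataset,
                  truth: set[str] | None, p: int) -> dict:
    fitted = adapter.fit(train)
    pred = fitted.predict(test.predictors)
    err = test.y.to_numpy(dtype=float) - pred
    row = {
        "rmse": float(np.sqrt(np.mean(err**2))),
        "mae": float(np.mean(np.abs(err))),
        "n_selected": len(fitted.selected_sources()),
    }
    if truth is not None:
        row["mcc"] = mcc(selection_confusion(fitted, truth, p))
    return row


def run_benchmark(
    adapters: dict[str, object],
    spec: ScenarioSpec | Dataset,
    reps: int = 100,
    train_frac: float = 0.7,
    seed: int = 0,
    truth: set[str] | None = None,
) -> BenchmarkResult:
    """Run the repeated-split protocol for every method adapter.

    Synthetic path (``spec`` a :class:`ScenarioSpec`): replication i uses a
    freshly generated dataset with seed ``(seed + i) % 2**31`` and one 70/30
    split; the truth set comes from the scenario. Fixed-dataset path
    (``spec`` a :class:`Dataset`): the data are constant and only the split
    is resampled. All methods see identical replications (paired design).
    Adapter failures are recorded and excluded from summaries.
    """
    rows: list[dict] = []
    n_failures = 0
    synthetic = isinstance(spec, ScenarioSpec)
    for i in range(reps):
        rep_seed = (seed + i) % _SEED_MOD
        if synthetic:
            data, rep_truth, _ = generate_scenario(spec.with_seed(rep_seed))
        else:
            data, rep_truth = spec, truth
        rng = np.random.default_rng(rep_seed + 1)
        train, test = data.train_test_split(train_frac, rng)
        for name, adapter in adapters.items():
            try:
                row = _evaluate_one(adapter, train, test, rep_truth,
                                    len(data.predictor_names))
            except Exception as exc:  # adapter failure: record, keep going
                n_failures += 1
                rows.append({"replication": i, "seed": rep_seed, "method": name,
                             "failed": True, "error": str(exc)})
                continue
            rows.append({"replication": i, "seed": rep_seed, "method": name,
                         "failed": False, **row})
    per_rep = pd.DataFrame(rows)
    ok = per_rep[~per_rep["failed"]]
    metrics = [c for c in ("rmse", "mae", "mcc", "n_selected") if c in ok.columns]
    melted = ok.melt(id_vars=["method"], value_vars=metrics,
                     var_name="metric", value_name="value")
    summary = melted.groupby(["method", "metric"])["value"].agg(
        median="median", sd=lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
        n="count").astype(float)
    cfg = {
        "reps": reps, "train_frac": train_frac, "seed": seed,
        "scenario": spec.scenario if synthetic else "fixed_dataset",
        "methods": sorted(adapters),
    }
    return BenchmarkResult(per_rep, summary, cfg, n_failures)


def select_mode(spec: ScenarioSpec, config: SplitWiseConfig,
                seed: int | None = None, train_frac: float = 0.7) -> str:
    """Pick the SplitWise mode (univariate vs iterative) by training RMSE.

    One preliminary replication is drawn, both modes are fit on its training
    part and the mode with lower training RMSE is returned (ties favour the
    cheaper univariate mode). No test-set information is used.
    """
    pre_seed = (spec.seed if seed is None else seed) % _SEED_MOD
    data, _, _ = generate_scenario(spec.with_seed(pre_seed))
    rng = np.random.default_rng(pre_seed + 1)
    train, _ = data.train_test_split(train_frac, rng)
    rmse = {}
    for mode in ("univariate", "iterative"):
        cfg = SplitWiseConfig(**{**config.__dict__, "mode": mode})
        fitted = splitwise_fit(train, cfg)
        resid = train.y.to_numpy(dtype=float) - fitted.predict(train.predictors)
        rmse[mode] = float(np.sqrt(np.mean(resid**2)))
    return "univariate" if rmse["univariate"] <= rmse["iterative"] else "iterative"
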