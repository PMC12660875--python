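"""SplitWise orchestration: transformation search, final model, reporting.

Two search modes decide how each numeric predictor is represented:

``univariate``
    Each predictor is screened independently against the response under four
    single-predictor models (null, linear, single split, double split, with
    cutpoints proposed by a shallow tree on (x, y)). A split form is eligible
    only when it beats the linear form by at least ``min_improvement``
    criterion points and keeps every segment above ``min_support``; a
    predictor whose best form is the null model is excluded. A global
    stepwise selection over the transformed candidate set then builds the
    final model.

``iterative``
    The search alternates classic stepwise passes (any strict criterion
    improvement) with transformation passes in which, for every numeric
    predictor not currently dummy-encoded in the model, a shallow tree on
    that predictor's partial residuals proposes single/double-split
    encodings; the best proposal is accepted only when it lowers the
    criterion by at least ``min_improvement`` with all segments above
    ``min_support``. The loop stops when a full pass changes nothing, after
    which a final global stepwise selection runs over the transformed
    candidate set.

Either way the result is one additive linear equation whose terms are
original predictors or their threshold indicators.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import Dataset
from .encoding import (
    DOUBLE_SPLIT,
    EXCLUDED,
    LINEAR,
    SINGLE_SPLIT,
    DegenerateEncodingError,
    Encoding,
    EncodingMap,
    build_design,
)
from .linmod import (
    INTERCEPT,
    DegenerateDesignError,
    DesignMatrix,
    FittedLinearModel,
    fit_ols,
    information_criterion,
)
from .stepwise import Term, TermSet, stepwise_select
from .trees import extract_candidates, grow_tree

__all__ = [
    "SplitWiseConfig",
    "SplitWiseModel",
    "TraceEvent",
    "partial_residuals",
    "univariate_transform",
    "iterative_search",
    "splitwise_fit",
    "splitwise",
]


@dataclass
class SplitWiseConfig:
    """Tuning knobs of the SplitWise search.

    min_support
        Minimum fraction of observations required in every segment of an
        accepted split (and every leaf of the proposal trees), in (0, 0.5].
    min_improvement
        Minimum criterion decrease required to accept a dummy transformation.
        Plain additions/removals of untransformed terms are exempt: any
        strict improvement suffices, as in classic stepwise.
    cp
        Cost-complexity parameter of the proposal trees (fraction of the
        root SSE a split must recover to survive pruning).
    """

    mode: str = "iterative"
    direction: str = "both"
    criterion: str = "aic"
    min_support: float = 0.2
    min_improvement: float = 3.0
    cp: float = 0.01
    cv_folds: int = 10
    max_iterations: int = 20
    transformable: list[str] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("univariate", "iterative"):
            raise ValueError(f"mode must be 'univariate' or 'iterative', got {self.mode!r}")
        if self.direction not in ("forward", "backward", "both"):
            raise ValueError(f"invalid direction {self.direction!r}")
        self.criterion = self.criterion.lower()
        if self.criterion not in ("aic", "bic"):
            raise ValueError(f"criterion must be AIC or BIC, got {self.criterion!r}")
        if not 0.0 < self.min_support <= 0.5:
            raise ValueError("min_support must lie in (0, 0.5]")
        if self.min_improvement < 0:
            raise ValueError("min_improvement must be >= 0")

    def validate_for(self, data: Dataset) -> None:
        if self.min_support * data.n < 1:
            raise ValueError(
                f"min_support * n = {self.min_support * data.n:.3g} < 1; "
                "no segment could ever satisfy the support constraint"
            )


@dataclass(frozen=True)
class TraceEvent:
    """One considered action of the search, accepted or not."""

    action: str
    detail: str
    criterion_before: float
    criterion_after: float
    accepted: bool


def _candidate_terms(design: DesignMatrix, data: Dataset, enc_map: EncodingMap) -> TermSet:
    terms = []
    for src in data.predictor_names:
        if src in enc_map and enc_map[src].kind == EXCLUDED:
            continue
        cols = tuple(design.columns_for(src))
        if cols:
            terms.append(Term(src, cols, src))
    return TermSet(terms)


def partial_residuals(model: FittedLinearModel, data: Dataset, predictor: str) -> np.ndarray:
    """Residuals plus the fitted contribution of one predictor's terms.

    Equals the ordinary residuals when no term of ``predictor`` is in the
    model; for an intercept-only model this is the centred response.
    """
    if predictor not in data.predictor_names:
        raise KeyError(f"unknown predictor {predictor!r}")
    cols = [c for c in model.design.frame.columns
            if model.design.term_map.get(c, ("", ""))[0] == predictor]
    resid = model.residuals.copy()
    if cols:
        contrib = model.design.frame[cols].to_numpy(dtype=float) @ model.params[cols].to_numpy()
        resid = resid + contrib
    return resid


def _single_predictor_criterion(x_cols: dict[str, np.ndarray], y: np.ndarray,
                                n: int, criterion: str) -> float:
    frame = pd.DataFrame({INTERCEPT: np.ones(n), **x_cols})
    tm = {INTERCEPT: ("", "intercept")}
    tm.update({c: ("x", "linear") for c in x_cols})
    try:
        return information_criterion(fit_ols(DesignMatrix(frame, tm), y), criterion)
    except DegenerateDesignError:
        return np.inf


def _split_encodings_from_tree(x: np.ndarray, target: np.ndarray, src: str,
                               config: SplitWiseConfig) -> list[Encoding]:
    tree = grow_tree(x, target, min_support=config.min_support, cp=config.cp,
                     cv_folds=config.cv_folds)
    cands = extract_candidates(tree, x, min_support=config.min_support)
    out: list[Encoding] = []
    if cands.single is not None:
        out.append(Encoding(SINGLE_SPLIT, src, (cands.single,)))
    if cands.double is not None:
        out.append(Encoding(DOUBLE_SPLIT, src, cands.double))
    return out


def univariate_transform(data: Dataset, config: SplitWiseConfig) -> EncodingMap:
    """Choose each predictor's representation independently against y.

    For every transformable numeric predictor, the null, linear, single-split
    and double-split single-predictor models are scored by the configured
    criterion. Split forms compete only when they beat the linear form by at
    least ``min_improvement``; predictors whose best form is the null model
    are excluded. Ties go to the simpler form.
    """
    config.validate_for(data)
    y = data.y.to_numpy(dtype=float)
    n = data.n
    enc_map = EncodingMap.all_linear(data, config.transformable)
    null_crit = _single_predictor_criterion({}, y, n, config.criterion)
    for src in data.predictor_names:
        linear_cols = _predictor_columns(data, src, Encoding(LINEAR, src))
        linear_crit = _single_predictor_criterion(linear_cols, y, n, config.criterion)
        # (criterion, complexity) options; lowest criterion wins, then simpler
        options: list[tuple[float, int, Encoding]] = [
            (null_crit, 0, Encoding(EXCLUDED, src)),
            (linear_crit, 1, Encoding(LINEAR, src)),
        ]
        if enc_map.eligible.get(src, False):
            x = data.predictors[src].to_numpy(dtype=float)
            for enc in _split_encodings_from_tree(x, y, src, config):
                try:
                    cols = _predictor_columns(data, src, enc)
                except DegenerateEncodingError:
                    continue
                crit = _single_predictor_criterion(cols, y, n, config.criterion)
                if crit <= linear_crit - config.min_improvement:
                    options.append((crit, 2 if enc.kind == SINGLE_SPLIT else 3, enc))
        options.sort(key=lambda o: (o[0], o[1]))
        enc_map[src] = options[0][2]
    return enc_map


def _predictor_columns(data: Dataset, src: str, enc: Encoding) -> dict[str, np.ndarray]:
    """Design columns of one predictor under one encoding (categoricals as-is)."""
    from .encoding import categorical_columns, encoding_columns

    if data.kinds[src] == "categorical":
        cols, _ = categorical_columns(data.predictors[src], src)
        return cols
    return encoding_columns(data.predictors[src], enc)


def iterative_search(
    data: Dataset, config: SplitWiseConfig
) -> tuple[EncodingMap, FittedLinearModel, list[str], list[TraceEvent]]:
    """Model-aware alternation of stepwise passes and transformation passes.

    Returns the final encoding map, fitted model, selected term names and
    the search trace.
    """
    config.validate_for(data)
    y = data.y.to_numpy(dtype=float)
    trace: list[TraceEvent] = []
    enc_map = EncodingMap.all_linear(data, config.transformable)
    design = build_design(data, enc_map)
    terms = _candidate_terms(design, data, enc_map)
    selected = [] if config.direction == "forward" else [t.name for t in terms.candidates]

    model, selected = stepwise_select(terms, design, y, config.direction,
                                      config.criterion, start=selected)
    crit = information_criterion(model, config.criterion)
    converged = False
    for _ in range(config.max_iterations):
        changed = False
        # (a) classic stepwise pass: strict improvements only
        prev = set(selected)
        model, selected = stepwise_select(terms, design, y, config.direction,
                                          config.criterion, start=selected)
        new_crit = information_criterion(model, config.criterion)
        if set(selected) != prev:
            trace.append(TraceEvent("stepwise_pass", ",".join(sorted(selected)) or "(intercept)",
                                    crit, new_crit, True))
            changed = True
        crit = new_crit
        # (b) transformation pass
        for src in data.numeric_predictors():
            if not enc_map.eligible.get(src, False):
                continue
            if enc_map[src].is_split and src in selected:
                continue  # already dummy-encoded in the model
            x = data.predictors[src].to_numpy(dtype=float)
            target = partial_residuals(model, data, src) if src in selected else model.residuals
            proposals = _split_encodings_from_tree(x, target, src, config)
            if not proposals:
                continue
            best: tuple[float, Encoding, DesignMatrix, TermSet, list[str]] | None = None
            for enc in proposals:
                trial_map = EncodingMap(dict(enc_map.encodings), dict(enc_map.eligible))
                trial_map[src] = enc
                try:
                    trial_design = build_design(data, trial_map)
                except DegenerateEncodingError:
                    continue
                trial_terms = _candidate_terms(trial_design, data, trial_map)
                trial_sel = selected if src in selected else selected + [src]
                try:
                    trial_model = fit_ols(
                        trial_design.select(_selection_columns(trial_terms, trial_sel)), y)
                except DegenerateDesignError:
                    continue
                c = information_criterion(trial_model, config.criterion)
                if best is None or c < best[0]:
                    best = (c, enc, trial_design, trial_terms, list(trial_sel))
            if best is None:
                continue
            c_best, enc_best, d_best, t_best, s_best = best
            accepted = crit - c_best >= config.min_improvement
            trace.append(TraceEvent("transform", f"{src}: {enc_best.describe()}",
                                    crit, c_best, accepted))
            if accepted:
                enc_map[src] = enc_best
                design, terms, selected = d_best, t_best, s_best
                model = fit_ols(design.select(_selection_columns(terms, selected)), y)
                crit = information_criterion(model, config.criterion)
                changed = True
        if not changed:
            converged = True
            break
    if not converged:
        warnings.warn("iterative search hit max_iterations before convergence", UserWarning)
        trace.append(TraceEvent("warning", "max_iterations reached", crit, crit, False))

    # final global stepwise selection over the transformed candidate set
    final_model, final_selected = stepwise_select(terms, design, y, config.direction,
                                                  config.criterion)
    final_crit = information_criterion(final_model, config.criterion)
    if final_crit > crit:
        # greedy restart ended worse than the incumbent: keep the incumbent
        trace.append(TraceEvent("final_selection", "kept incumbent model",
                                final_crit, crit, False))
        final_model, final_selected, final_crit = model, selected, crit
    else:
        trace.append(TraceEvent("final_selection", ",".join(sorted(final_selected)) or "(intercept)",
                                crit, final_crit, True))
    return enc_map, final_model, final_selected, trace


def _selection_columns(terms: TermSet, selected: list[str]) -> list[str]:
    cols: list[str] = []
    for name in selected:
        cols.extend(terms.by_name(name).columns)
    return cols


@dataclass
class SplitWiseModel:
    """Final model, encoding map and search trace of one SplitWise fit."""

    fit: FittedLinearModel
    encodings: EncodingMap
    selected: list[str]
    trace: list[TraceEvent]
    config: SplitWiseConfig
    response: str
    kinds: dict[str, str]
    categorical_levels: dict[str, list] = field(default_factory=dict)

    # -- introspection -------------------------------------------------
    def selected_sources(self) -> set[str]:
        """Source predictors with at least one term in the final model."""
        return {src for src, enc in self.encodings.items()
                if enc.kind != EXCLUDED and src in self.selected}

    def dummy_encodings(self) -> list[Encoding]:
        return [enc for src, enc in self.encodings.items()
                if src in self.selected and enc.is_split]

    @property
    def coefficients(self) -> pd.Series:
        return self.fit.params

    # -- prediction ----------------------------------------------------
    def predict(self, newdata: pd.DataFrame) -> np.ndarray:
        """Predict from a predictor table using the stored thresholds.

        Thresholds and categorical levels are applied as stored; values
        outside the training range still encode deterministically.
        """
        needed = {src for src in self.selected}
        missing = needed - set(newdata.columns)
        if missing:
            raise KeyError(f"newdata is missing predictor columns: {sorted(missing)}")
        n = len(newdata)
        cols: dict[str, np.ndarray] = {INTERCEPT: np.ones(n)}
        for src in self.selected:
            enc = self.encodings[src]
            if self.kinds.get(src) == "categorical":
                vals = newdata[src].astype(str)
                for lev in self.categorical_levels[src][1:]:
                    cols[f"{src}[{lev}]"] = (vals == lev).to_numpy(dtype=float)
                continue
            x = pd.to_numeric(newdata[src], errors="raise").to_numpy(dtype=float)
            if enc.kind == LINEAR:
                cols[src] = x
            elif enc.kind == SINGLE_SPLIT:
                cols[f"{src}_dummy"] = (x > enc.cutpoints[0]).astype(float)
            elif enc.kind == DOUBLE_SPLIT:
                c1, c2 = enc.cutpoints
                cols[f"{src}_dummy1"] = ((x > c1) & (x <= c2)).astype(float)
                cols[f"{src}_dummy2"] = (x > c2).astype(float)
        X = np.column_stack([cols[c] for c in self.fit.params.index])
        return X @ self.fit.params.to_numpy()

    # -- reporting -----------------------------------------------------
    def coefficient_table(self) -> pd.DataFrame:
        """Estimates with standard errors, t statistics and p-values."""
        X = self.fit.design.frame.to_numpy(dtype=float)
        xtx_inv = np.linalg.inv(X.T @ X)
        se = np.sqrt(np.diag(xtx_inv) * self.fit.sigma2)
        est = self.fit.params.to_numpy()
        t = est / se
        p = 2.0 * stats.t.sf(np.abs(t), self.fit.df_resid)
        return pd.DataFrame(
            {"estimate": est, "std_error": se, "t_value": t, "p_value": p},
            index=self.fit.params.index,
        )

    def r_squared(self) -> tuple[float, float]:
        y = self.fit.fitted + self.fit.residuals
        tss = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - self.fit.rss / tss if tss > 0 else np.nan
        n, k = self.fit.n, self.fit.k_params
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k) if n > k else np.nan
        return r2, adj

    def summary(self) -> str:
        """Human-readable report in the style of an R model summary."""
        tab = self.coefficient_table()
        r2, adj = self.r_squared()
        rse = float(np.sqrt(self.fit.sigma2))
        lines = [
            f"SplitWise linear model (mode={self.config.mode}, "
            f"direction={self.config.direction}, criterion={self.config.criterion.upper()})",
            f"Response: {self.response}",
            "",
            "Coefficients:",
        ]
        with pd.option_context("display.float_format", lambda v: f"{v: .5g}"):
            lines.append(tab.to_string())
        lines += [
            "",
            f"Residual standard error: {rse:.4g} on {self.fit.df_resid} degrees of freedom",
            f"Multiple R-squared: {r2:.4f},  Adjusted R-squared: {adj:.4f}",
            f"AIC: {self.fit.aic:.2f}  BIC: {self.fit.bic:.2f}  "
            f"(RSS-convention AIC: {self.fit.aic_rss:.2f})",
            "",
            "Dummy transformations:",
        ]
        dummies = self.dummy_encodings()
        if dummies:
            for enc in dummies:
                lines.append(f"  {enc.source}_dummy: {enc.describe()}")
        else:
            lines.append("  (none)")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-serialisable report: coefficients, thresholds, trace, config."""
        r2, adj = self.r_squared()
        return {
            "response": self.response,
            "coefficients": {k: float(v) for k, v in self.fit.params.items()},
            "selected": list(self.selected),
            "encodings": {
                src: {"kind": enc.kind, "cutpoints": list(enc.cutpoints)}
                for src, enc in self.encodings.items()
            },
            "aic": float(self.fit.aic),
            "bic": float(self.fit.bic),
            "aic_rss_convention": float(self.fit.aic_rss),
            "r_squared": float(r2),
            "adj_r_squared": float(adj),
            "residual_std_error": float(np.sqrt(self.fit.sigma2)),
            "trace": [asdict(ev) for ev in self.trace],
            "config": {**asdict(self.config)},
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def splitwise_fit(data: Dataset, config: SplitWiseConfig | None = None) -> SplitWiseModel:
    """Entry point: run the configured SplitWise search on a dataset."""
    config = config or SplitWiseConfig()
    config.validate_for(data)
    trace: list[TraceEvent] = []
    if config.mode == "univariate":
        enc_map = univariate_transform(data, config)
        design = build_design(data, enc_map)
        terms = _candidate_terms(design, data, enc_map)
        for src, enc in enc_map.items():
            if enc.kind != LINEAR:
                trace.append(TraceEvent("univariate_transform",
                                        f"{src}: {enc.describe()}", np.nan, np.nan, True))
        model, selected = stepwise_select(terms, design, data.y.to_numpy(dtype=float),
                                          config.direction, config.criterion)
        trace.append(TraceEvent("final_selection",
                                ",".join(sorted(selected)) or "(intercept)",
                                np.nan, information_criterion(model, config.criterion), True))
    else:
        enc_map, model, selected, trace = iterative_search(data, config)

    final_map = EncodingMap(
        {src: (enc if src in selected else Encoding(EXCLUDED, src))
         for src, enc in enc_map.items()},
        dict(enc_map.eligible),
    )
    levels = {
        src: sorted(pd.unique(data.predictors[src].astype(str)))
        for src in data.predictor_names if data.kinds[src] == "categorical"
    }
    return SplitWiseModel(
        fit=model,
        encodings=final_map,
        selected=list(selected),
        trace=trace,
        config=config,
        response=data.response,
        kinds=dict(data.kinds),
        categorical_levels=levels,
    )


def splitwise(frame: pd.DataFrame, response: str, **config_kwargs) -> SplitWiseModel:
    """Convenience wrapper: fit SplitWise on a full table with a named response."""
    return splitwise_fit(Dataset.from_frame(frame, response), SplitWiseConfig(**config_kwargs))
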