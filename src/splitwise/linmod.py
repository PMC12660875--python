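"""Ordinary least squares and the information criteria driving the search.

All model comparisons in the package go through :func:`fit_ols` and
:func:`information_criterion`. The log-likelihood is the Gaussian likelihood
evaluated at the MLE of the error variance,

    loglik = -n/2 * (log(2*pi) + log(rss/n) + 1),

and the criteria count the error variance as a free parameter:

    AIC = -2*loglik + 2*(k+1),    BIC = -2*loglik + log(n)*(k+1),

where k is the number of regression coefficients (intercept included). R's
``extractAIC`` drops the additive constant (it uses n*log(rss/n) + 2*k);
criterion *differences* between models on the same data are identical under
either convention, so selection decisions do not depend on the choice. The
RSS-based value is kept on the fitted model (``aic_rss``) for auditability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DesignMatrix",
    "FittedLinearModel",
    "DegenerateDesignError",
    "PerfectFitWarning",
    "fit_ols",
    "information_criterion",
]

INTERCEPT = "(Intercept)"

#: sentinel criterion for zero-residual fits; sorts below every finite value
PERFECT_FIT_CRITERION = -np.inf


class DegenerateDesignError(ValueError):
    """Raised when a design matrix is rank deficient (collinear candidate)."""


class PerfectFitWarning(UserWarning):
    """A model reproduced the response exactly (rss = 0)."""


@dataclass
class DesignMatrix:
    """A named n x k real matrix with exactly one intercept column.

    ``term_map`` records, for every column, the source predictor and its
    encoding role (``intercept``, ``linear``, ``dummy`` or ``categorical``)
    so that fitted models stay traceable to original variables.
    """

    frame: pd.DataFrame
    term_map: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cols = list(self.frame.columns)
        if len(set(cols)) != len(cols):
            raise ValueError("design matrix column names must be unique")
        n_icpt = sum(1 for c in cols if self.term_map.get(c, ("", ""))[1] == "intercept")
        if INTERCEPT in cols and not self.term_map:
            n_icpt = 1
        if n_icpt != 1:
            raise ValueError("design matrix must contain exactly one intercept column")

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def k(self) -> int:
        return self.frame.shape[1]

    def columns_for(self, source: str) -> list[str]:
        """All design columns contributed by one source predictor."""
        return [c for c, (src, role) in self.term_map.items()
                if src == source and role != "intercept" and c in self.frame.columns]

    def select(self, columns: list[str]) -> "DesignMatrix":
        """Column subset, always retaining the intercept."""
        keep = [c for c in self.frame.columns if c == INTERCEPT or c in columns]
        return DesignMatrix(self.frame[keep], {c: self.term_map[c] for c in keep})


@dataclass
class FittedLinearModel:
    """An OLS fit with the quantities needed for criterion-driven search."""

    params: pd.Series
    rss: float
    n: int
    k_params: int
    loglik: float
    aic: float
    bic: float
    fitted: np.ndarray
    residuals: np.ndarray
    design: DesignMatrix
    perfect: bool = False
    #: R-style extractAIC value (RSS convention, no constant): n*log(rss/n) + 2*k
    aic_rss: float = np.nan

    @property
    def df_resid(self) -> int:
        return self.n - self.k_params

    @property
    def sigma2(self) -> float:
        """Unbiased residual variance estimate (rss / (n - k))."""
        return self.rss / self.df_resid if self.df_resid > 0 else np.nan


def fit_ols(design: DesignMatrix, y: np.ndarray | pd.Series) -> FittedLinearModel:
    """Least-squares fit of ``y`` on ``design``.

    Raises
    ------
    DegenerateDesignError
        If the design is rank deficient; callers treat the candidate as
        invalid rather than silently aliasing columns.
    """
    X = design.frame.to_numpy(dtype=float)
    yv = np.asarray(y, dtype=float)
    n, k = X.shape
    if n != yv.shape[0]:
        raise ValueError(f"design has {n} rows but y has {yv.shape[0]}")
    if n < k:
        raise DegenerateDesignError(f"n = {n} < k = {k}")
    beta, _, rank, _ = np.linalg.lstsq(X, yv, rcond=None)
    if rank < k:
        raise DegenerateDesignError(f"design rank {rank} < {k} columns")
    fitted = X @ beta
    resid = yv - fitted
    rss = float(resid @ resid)
    tss = float(yv @ yv)
    perfect = rss <= max(1e-12 * max(tss, 1.0), 1e-300)
    if perfect:
        warnings.warn(
            "perfect fit (rss = 0); information criteria degenerate to -inf",
            PerfectFitWarning,
            stacklevel=2,
        )
        loglik = np.inf
        aic = bic = aic_rss = PERFECT_FIT_CRITERION
    else:
        loglik = -0.5 * n * (np.log(2.0 * np.pi) + np.log(rss / n) + 1.0)
        df = k + 1  # error variance counted
        aic = -2.0 * loglik + 2.0 * df
        bic = -2.0 * loglik + np.log(n) * df
        aic_rss = n * np.log(rss / n) + 2.0 * k
    return FittedLinearModel(
        params=pd.Series(beta, index=design.frame.columns),
        rss=rss,
        n=n,
        k_params=k,
        loglik=loglik,
        aic=aic,
        bic=bic,
        fitted=fitted,
        residuals=resid,
        design=design,
        perfect=perfect,
        aic_rss=aic_rss,
    )


def information_criterion(model: FittedLinearModel, criterion: str) -> float:
    """AIC or BIC of a fitted model; -inf sentinel for perfect fits."""
    if model.perfect:
        return PERFECT_FIT_CRITERION
    crit = criterion.lower()
    if crit == "aic":
        return model.aic
    if crit == "bic":
        return model.bic
    raise ValueError(f"unknown criterion {criterion!r} (expected 'AIC' or 'BIC')")
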