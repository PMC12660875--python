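"""Synthetic regression scenarios with linear, step and U-shaped signal.

Each dataset has n i.i.d. standard-normal predictors X1..Xp and response

    y = b1*X1 + b2*I(X2 > tau) + b3*[-8*(X3s - 0.5)^2 + 2] + eps,

where X3s is X3 min-max rescaled to [0, 1] within the realised sample, so
the quadratic term ranges over [0, 2] with its peak at the sample midpoint.
The noise eps ~ N(0, sigma^2) is calibrated per realised draw so that
Var(signal)/sigma^2 equals the requested signal-to-noise ratio (sample
variance of the constructed signal, ddof=1), making the SNR exact for every
generated dataset. Four scenarios toggle the signal components:

    linear    b2=0, b3=0 (relevant: X1)
    step      b2=1, b3=0 (relevant: X1, X2)
    u_shape   b2=0, b3=1 (relevant: X1, X3)
    complete  b2=1, b3=1 (relevant: X1, X2, X3)

All non-zero coefficients are 1, tau = 0.2 and SNR = 5 by default; the
remaining predictors are pure noise included to probe variable selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .dataset import Dataset

__all__ = ["ScenarioSpec", "SCENARIOS", "calibrate_noise", "generate_scenario"]

#: scenario name -> (beta2, beta3); beta1 is always 1
SCENARIOS: dict[str, tuple[float, float]] = {
    "linear": (0.0, 0.0),
    "step": (1.0, 0.0),
    "u_shape": (0.0, 1.0),
    "complete": (1.0, 1.0),
}

_ALIASES = {"a": "linear", "b": "step", "c": "u_shape", "d": "complete"}


def canonical_scenario(name: str) -> str:
    key = name.strip().lower().replace("-", "_")
    key = _ALIASES.get(key, key)
    if key not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; expected one of {sorted(SCENARIOS)}")
    return key


@dataclass(frozen=True)
class ScenarioSpec:
    """Configuration of one synthetic draw."""

    scenario: str = "complete"
    n: int = 500
    p: int = 20
    tau: float = 0.2
    snr: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "scenario", canonical_scenario(self.scenario))
        if self.p < 3:
            raise ValueError("p must be >= 3 (X1..X3 carry the signal)")

    @property
    def betas(self) -> tuple[float, float, float]:
        b2, b3 = SCENARIOS[self.scenario]
        return 1.0, b2, b3

    @property
    def truth(self) -> set[str]:
        """Predictors truly associated with the response."""
        b1, b2, b3 = self.betas
        out = {"X1"}
        if b2 != 0:
            out.add("X2")
        if b3 != 0:
            out.add("X3")
        return out

    def with_seed(self, seed: int) -> "ScenarioSpec":
        return replace(self, seed=seed)


def calibrate_noise(signal: np.ndarray, snr: float) -> float:
    """Noise variance giving the requested SNR for one realised signal.

    sigma^2 = Var(signal) / snr with Var the sample variance (ddof=1).
    A constant signal yields sigma^2 = 0 with a warning.
    """
    if snr <= 0:
        raise ValueError("snr must be > 0")
    sig = np.asarray(signal, dtype=float)
    var = float(np.var(sig, ddof=1)) if sig.size > 1 else 0.0
    if var == 0.0:
        warnings.warn("constant signal: calibrated noise variance is 0", UserWarning)
        return 0.0
    return var / snr


def generate_scenario(spec: ScenarioSpec) -> tuple[Dataset, set[str], dict]:
    """Draw one dataset; returns (data, truth set, generation metadata)."""
    rng = np.random.default_rng(spec.seed)
    b1, b2, b3 = spec.betas
    X = rng.standard_normal((spec.n, spec.p))
    x1, x2, x3 = X[:, 0], X[:, 1], X[:, 2]
    x3s = (x3 - x3.min()) / (x3.max() - x3.min())
    quad = -8.0 * (x3s - 0.5) ** 2 + 2.0
    signal = b1 * x1 + b2 * (x2 > spec.tau).astype(float) + b3 * quad
    sigma2 = calibrate_noise(signal, spec.snr)
    y = signal + rng.normal(0.0, np.sqrt(sigma2), size=spec.n)
    frame = pd.DataFrame(X, columns=[f"X{j + 1}" for j in range(spec.p)])
    data = Dataset(frame, pd.Series(y, name="y"), response="y")
    meta = {"sigma2": sigma2, "signal_variance": float(np.var(signal, ddof=1)),
            "spec": spec}
    return data, spec.truth, meta
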