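"""Binomial likelihood, maximum-likelihood fits, AICc, and model selection.

Each transition limb is fitted by treating the male count at every
incubation temperature as a binomial draw with success probability given by
the reaction norm.  Binomial coefficients are omitted from the
log-likelihood throughout: they are constant in the parameters and cancel
in every AICc difference and Akaike weight.

The effective sample size ``n`` entering the AICc small-sample correction
is the total number of sexed individuals on the limb, not the number of
temperature groups: a limb typically has only three temperatures, which
would leave the correction undefined for a two-parameter model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .reaction_norms import FlexitNorm, LogisticNorm, sex_ratio

__all__ = [
    "BinomialDataset",
    "FitResult",
    "ModelSelection",
    "SmallSampleError",
    "log_likelihood",
    "fit_mle",
    "aic",
    "aicc",
    "akaike_weights",
    "select_model",
]

_LIK_EPS = 1e-12
MODELS = ("logistic", "flexit")


class SmallSampleError(ValueError):
    """Too few sexed individuals for the AICc correction (n - k - 1 <= 0)."""


@dataclass(frozen=True)
class BinomialDataset:
    """Grouped binomial counts for one transition limb.

    ``totals`` are sexed hatchlings only (females + males); unidentified
    individuals never enter the likelihood.
    """

    temperatures: np.ndarray
    males: np.ndarray
    totals: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        m = np.asarray(self.males, dtype=float)
        n = np.asarray(self.totals, dtype=float)
        if not (t.shape == m.shape == n.shape) or t.ndim != 1 or t.size < 2:
            raise ValueError("temperatures/males/totals must be equal-length 1-D, >= 2")
        if np.unique(t).size < 2:
            raise ValueError("at least two distinct temperatures are required")
        if np.any(m != np.round(m)) or np.any(n != np.round(n)):
            raise ValueError("counts must be integer-valued")
        if np.any(m < 0) or np.any(n <= 0) or np.any(m > n):
            raise ValueError("require 0 <= males <= totals and totals > 0")
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "males", m)
        object.__setattr__(self, "totals", n)

    @property
    def n(self) -> int:
        """Total sexed individuals across the limb."""
        return int(self.totals.sum())

    @property
    def male_proportions(self) -> np.ndarray:
        return self.males / self.totals


@dataclass(frozen=True)
class FitResult:
    """A maximum-likelihood fit of one candidate model to one limb."""

    model: str
    params: LogisticNorm | FlexitNorm
    logLik: float
    k: int
    n: int
    aic: float
    aicc: float
    converged: bool


@dataclass(frozen=True)
class ModelSelection:
    """AICc comparison of the candidate models on one limb."""

    fits: dict[str, FitResult]
    delta_aicc: dict[str, float]
    akaike_weight: dict[str, float]
    best: str
    dropped: tuple[str, ...] = field(default_factory=tuple)


def log_likelihood(
    norm: LogisticNorm | FlexitNorm, data: BinomialDataset
) -> float:
    """Grouped binomial log-likelihood (binomial coefficients omitted)."""
    sr = np.clip(sex_ratio(norm, data.temperatures), _LIK_EPS, 1.0 - _LIK_EPS)
    return float(
        data.males @ np.log(sr) + (data.totals - data.males) @ np.log1p(-sr)
    )


def aic(logLik: float, k: int) -> float:
    return -2.0 * logLik + 2.0 * k


def aicc(logLik: float, k: int, n: int) -> float:
    """Small-sample-corrected AIC: AIC + 2k(k+1)/(n - k - 1)."""
    if n - k - 1 <= 0:
        raise SmallSampleError(
            f"AICc undefined for n={n}, k={k} (need n - k - 1 > 0)"
        )
    return aic(logLik, k) + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def akaike_weights(aiccs: Sequence[float]) -> list[float]:
    """Normalised exp(-delta/2) relative supports; invariant to common shifts."""
    arr = np.asarray(aiccs, dtype=float)
    if arr.size == 0 or not np.all(np.isfinite(arr)):
        raise ValueError("aiccs must be non-empty and finite")
    rel = np.exp(-(arr - arr.min()) / 2.0)
    return list(rel / rel.sum())


def _direction_sign(direction: str) -> float:
    if direction == "FM":
        return 1.0
    if direction == "MF":
        return -1.0
    raise ValueError(f"direction must be 'FM' or 'MF', got {direction!r}")


_LOG_BOUND = 15.0  # |log scale| cap inside the optimiser reparameterisation


def _fit_logistic(data: BinomialDataset, sign: float) -> tuple[LogisticNorm, float, bool]:
    t_lo, t_hi = data.temperatures.min(), data.temperatures.max()

    def nll(x: np.ndarray) -> float:
        s = sign * math.exp(float(np.clip(x[1], -_LOG_BOUND, _LOG_BOUND)))
        return -log_likelihood(LogisticNorm(float(x[0]), s), data)

    starts = [
        (p0, math.log(s0))
        for p0 in np.linspace(t_lo - 2.0, t_hi + 2.0, 5)
        for s0 in (0.7, 2.0)
    ]
    best = None
    ok = False
    for x0 in starts:
        res = minimize(nll, np.asarray(x0), method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
            ok = bool(res.success)
    s_hat = sign * math.exp(float(np.clip(best.x[1], -_LOG_BOUND, _LOG_BOUND)))
    norm = LogisticNorm(float(best.x[0]), s_hat)
    return norm, -float(best.fun), ok


def _fit_flexit(data: BinomialDataset, sign: float) -> tuple[FlexitNorm, float, bool]:
    # Seed from the logistic solution: slope at pivot = 1/(4|S|).
    log_norm, _, _ = _fit_logistic(data, sign)
    p0 = log_norm.P
    log_slope0 = math.log(1.0 / (4.0 * abs(log_norm.S)))

    def nll(x: np.ndarray) -> float:
        slope = sign * math.exp(float(np.clip(x[1], -_LOG_BOUND, _LOG_BOUND)))
        k1 = math.exp(float(np.clip(x[2], -5.0, 5.0)))
        k2 = math.exp(float(np.clip(x[3], -5.0, 5.0)))
        return -log_likelihood(FlexitNorm(float(x[0]), slope, k1, k2), data)

    k_pairs = [(1.0, 1.0), (0.3, 1.0), (1.0, 0.3), (3.0, 1.0), (1.0, 3.0), (3.0, 0.3)]
    best = None
    ok = False
    for k1, k2 in k_pairs:
        x0 = np.asarray([p0, log_slope0, math.log(k1), math.log(k2)])
        res = minimize(nll, x0, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
            ok = bool(res.success)
    slope = sign * math.exp(float(np.clip(best.x[1], -_LOG_BOUND, _LOG_BOUND)))
    k1 = math.exp(float(np.clip(best.x[2], -5.0, 5.0)))
    k2 = math.exp(float(np.clip(best.x[3], -5.0, 5.0)))
    norm = FlexitNorm(float(best.x[0]), slope, k1, k2)
    return norm, -float(best.fun), ok


def fit_mle(
    data: BinomialDataset, model: str = "logistic", direction: str = "FM"
) -> FitResult:
    """Maximum-likelihood fit of one candidate model to one limb.

    The sign of the scale (logistic) or pivot slope (flexit) is constrained
    by ``direction``: positive for FM (male proportion increasing with
    temperature), negative for MF.  Multi-start Nelder-Mead is used; the
    best of all starts is returned.

    An all-male or all-female limb has its maximum on the parameter
    boundary (the scale estimate diverges); it returns a result flagged
    ``converged=False`` rather than raising.
    """
    sign = _direction_sign(direction)
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}, got {model!r}")
    k = 2 if model == "logistic" else 4

    if data.males.sum() == 0 or (data.totals - data.males).sum() == 0:
        # Degenerate limb: likelihood increases without bound as the curve
        # approaches a step; report a steep placeholder, flagged.
        p_edge = float(np.median(data.temperatures))
        if model == "logistic":
            params: LogisticNorm | FlexitNorm = LogisticNorm(p_edge, sign * 1e-3)
        else:
            params = FlexitNorm(p_edge, sign * 250.0, 1.0, 1.0)
        ll = log_likelihood(params, data)
        return FitResult(model, params, ll, k, data.n, aic(ll, k),
                         aicc(ll, k, data.n), converged=False)

    if model == "logistic":
        params, ll, ok = _fit_logistic(data, sign)
    else:
        params, ll, ok = _fit_flexit(data, sign)
    return FitResult(model, params, ll, k, data.n, aic(ll, k),
                     aicc(ll, k, data.n), converged=ok)


def select_model(
    data: BinomialDataset,
    direction: str = "FM",
    candidates: Sequence[str] = MODELS,
) -> ModelSelection:
    """Fit every candidate model and rank by AICc (ties favour fewer parameters).

    A candidate whose AICc correction is undefined on this limb (too few
    sexed individuals) is dropped with a warning, provided at least one
    candidate survives.
    """
    fits: dict[str, FitResult] = {}
    dropped: list[str] = []
    for model in candidates:
        try:
            fits[model] = fit_mle(data, model=model, direction=direction)
        except SmallSampleError as exc:
            dropped.append(model)
            warnings.warn(f"dropping {model} candidate: {exc}", stacklevel=2)
    if not fits:
        raise SmallSampleError("no candidate model admits an AICc on this limb")
    names = list(fits)
    aiccs = [fits[m].aicc for m in names]
    best_aicc = min(aiccs)
    deltas = {m: fits[m].aicc - best_aicc for m in names}
    weights = dict(zip(names, akaike_weights(aiccs)))
    # Tie-break toward the smaller model (candidate order is small-to-large).
    best = min(names, key=lambda m: (fits[m].aicc, fits[m].k))
    return ModelSelection(fits=fits, delta_aicc=deltas, akaike_weight=weights,
                          best=best, dropped=tuple(dropped))
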