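"""Sex-ratio-versus-temperature reaction norms for a single monotone transition.

Convention used everywhere in this package: a reaction norm returns the
**male** proportion among sexed hatchlings at a constant incubation
temperature T.  Under this convention a female-to-male (FM) limb is
increasing in T and has a positive scale/slope parameter, while a
male-to-female (MF) limb is decreasing and has a negative one.

Two curve families are provided:

* :class:`LogisticNorm` -- the classic two-parameter logistic dose-response
  curve, ``sr(T) = 1 / (1 + exp((P - T) / S))``, with pivotal temperature
  ``P`` (where sr = 1/2) and signed scale ``S`` in degC.
* :class:`FlexitNorm` -- an asymmetric generalisation with independent shape
  constants ``K1`` (below the pivot) and ``K2`` (above it), parameterised by
  the pivotal temperature ``P`` and the signed slope of the curve at the
  pivot, ``S_slope`` (per degC).  At ``K1 = K2 = 1`` it coincides with the
  logistic curve having ``S = 1 / (4 * S_slope)``.

The transitional range of temperatures (TRT) is the width of the temperature
interval producing sex ratios between ``l`` and ``1 - l`` (default 5%-95%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "LogisticNorm",
    "FlexitNorm",
    "logistic_sr",
    "flexit_sr",
    "temperature_at_sr",
    "trt",
]

# Exponent arguments are clipped here before exponentiation so that any
# finite temperature yields a finite, strictly interior sex ratio.
_EXP_CLIP = 500.0
_SR_EPS = 1e-15


@dataclass(frozen=True)
class LogisticNorm:
    """Logistic reaction norm: pivotal temperature ``P`` and signed scale ``S``.

    ``sr(P) = 0.5`` exactly; the curve is increasing in T when ``S > 0``
    (FM limb) and decreasing when ``S < 0`` (MF limb).  |S| sets the TRT:
    ``TRT = 2 |S| ln((1-l)/l)``.
    """

    P: float
    S: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.P) and math.isfinite(self.S)):
            raise ValueError("LogisticNorm parameters must be finite")
        if self.S == 0.0:
            raise ValueError("LogisticNorm scale S must be nonzero")


@dataclass(frozen=True)
class FlexitNorm:
    """Asymmetric reaction norm pinned to ``sr(P) = 0.5`` with slope ``S_slope`` at P.

    ``K1`` shapes the approach to the asymptote below the pivot and ``K2``
    above it (both dimensionless, > 0).  Below the pivot::

        sr(T) = (1 + (2**K1 - 1) * exp(4*S1*(P - T))) ** (-1/K1),
        S1 = S_slope * K1 / (2 * (1 - 2**(-K1)))

    and symmetrically above it with ``K2``/``S2`` on ``1 - sr``.  The two
    halves meet continuously at ``(P, 0.5)`` with derivative ``S_slope``.
    """

    P: float
    S_slope: float
    K1: float = 1.0
    K2: float = 1.0

    def __post_init__(self) -> None:
        if not all(
            math.isfinite(v) for v in (self.P, self.S_slope, self.K1, self.K2)
        ):
            raise ValueError("FlexitNorm parameters must be finite")
        if self.S_slope == 0.0:
            raise ValueError("FlexitNorm slope S_slope must be nonzero")
        if self.K1 <= 0 or self.K2 <= 0:
            raise ValueError("FlexitNorm shape constants K1, K2 must be > 0")


def _limb_scale(s_slope: float, k: float) -> float:
    # Chosen so the derivative at the pivot is exactly s_slope.
    return s_slope * k / (2.0 * (1.0 - 2.0 ** (-k)))


def _finish(values: np.ndarray, scalar: bool) -> float | np.ndarray:
    out = np.clip(values, _SR_EPS, 1.0 - _SR_EPS)
    return float(out) if scalar else out


def logistic_sr(norm: LogisticNorm, T: float | np.ndarray) -> float | np.ndarray:
    """Male proportion at temperature(s) ``T`` under a logistic norm."""
    arr = np.asarray(T, dtype=float)
    z = np.clip((norm.P - arr) / norm.S, -_EXP_CLIP, _EXP_CLIP)
    return _finish(1.0 / (1.0 + np.exp(z)), arr.ndim == 0)


def flexit_sr(norm: FlexitNorm, T: float | np.ndarray) -> float | np.ndarray:
    """Male proportion at temperature(s) ``T`` under a flexit norm."""
    arr = np.asarray(T, dtype=float)
    s1 = _limb_scale(norm.S_slope, norm.K1)
    s2 = _limb_scale(norm.S_slope, norm.K2)
    # log(2**K - 1) via expm1 keeps precision for small K.
    log_a1 = math.log(math.expm1(norm.K1 * math.log(2.0)))
    log_a2 = math.log(math.expm1(norm.K2 * math.log(2.0)))
    x1 = np.clip(4.0 * s1 * (norm.P - arr), -_EXP_CLIP, _EXP_CLIP)
    x2 = np.clip(4.0 * s2 * (arr - norm.P), -_EXP_CLIP, _EXP_CLIP)
    # (1 + a e^x)^(-1/K) computed as exp(-log1p(a e^x)/K) for stability.
    lower = np.exp(-np.logaddexp(0.0, log_a1 + x1) / norm.K1)
    upper = 1.0 - np.exp(-np.logaddexp(0.0, log_a2 + x2) / norm.K2)
    return _finish(np.where(arr < norm.P, lower, upper), arr.ndim == 0)


def sex_ratio(norm: LogisticNorm | FlexitNorm, T: float | np.ndarray):
    """Dispatch to the right curve family for ``norm``."""
    if isinstance(norm, LogisticNorm):
        return logistic_sr(norm, T)
    if isinstance(norm, FlexitNorm):
        return flexit_sr(norm, T)
    raise TypeError(f"unsupported norm type: {type(norm).__name__}")


def temperature_at_sr(norm: LogisticNorm | FlexitNorm, target: float) -> float:
    """Temperature at which the norm produces male proportion ``target``.

    Logistic norms invert in closed form, ``T = P - S ln((1-target)/target)``;
    flexit norms are inverted by bracketed root-finding (the curve is strictly
    monotone, so the root is unique).
    """
    if not 0.0 < target < 1.0:
        raise ValueError(f"target proportion must be in (0, 1), got {target!r}")
    if isinstance(norm, LogisticNorm):
        return norm.P - norm.S * math.log((1.0 - target) / target)
    if not isinstance(norm, FlexitNorm):
        raise TypeError(f"unsupported norm type: {type(norm).__name__}")
    if target == 0.5:
        return norm.P

    def f(T: float) -> float:
        return flexit_sr(norm, T) - target

    half = 1.0
    lo, hi = norm.P - half, norm.P + half
    while f(lo) * f(hi) > 0.0:
        half *= 2.0
        if half > 1e7:
            raise ValueError(
                f"could not bracket sr = {target} (curve saturates before reaching it)"
            )
        lo, hi = norm.P - half, norm.P + half
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=8.881784197001252e-16))


def trt(norm: LogisticNorm | FlexitNorm, l: float = 0.05) -> float:
    """Transitional range of temperatures between sex ratios ``l`` and ``1 - l``.

    ``TRT = |T(1-l) - T(l)|``.  Closed forms are used for both families:
    logistic ``2 |S| ln((1-l)/l)``; flexit as the sum of the two limb
    offsets obtained by inverting each half analytically.
    """
    if not 0.0 < l < 0.5:
        raise ValueError(f"TRT threshold l must be in (0, 0.5), got {l!r}")
    if isinstance(norm, LogisticNorm):
        return 2.0 * abs(norm.S) * math.log((1.0 - l) / l)
    if not isinstance(norm, FlexitNorm):
        raise TypeError(f"unsupported norm type: {type(norm).__name__}")
    s1 = _limb_scale(norm.S_slope, norm.K1)
    s2 = _limb_scale(norm.S_slope, norm.K2)
    a1 = math.expm1(norm.K1 * math.log(2.0))
    a2 = math.expm1(norm.K2 * math.log(2.0))
    # Which of the two target levels sits on the low-temperature side depends
    # on the curve's direction; the two halves are not mirror images.
    low_target = l if norm.S_slope > 0 else 1.0 - l
    high_target = 1.0 - low_target
    t_low = norm.P - math.log((low_target ** (-norm.K1) - 1.0) / a1) / (4.0 * s1)
    t_high = norm.P + math.log(
        ((1.0 - high_target) ** (-norm.K2) - 1.0) / a2
    ) / (4.0 * s2)
    return abs(t_high - t_low)
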