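"""Metropolis-Hastings posteriors for pivotal temperature and TRT.

A single-chain, component-wise Gaussian random-walk sampler over the
reaction-norm parameters with flat (uniform, bounded) priors.  The pivotal
temperature is the ``P`` parameter itself; the transitional range of
temperatures (TRT) is a derived quantity computed per retained draw and
then summarised, so its posterior quantiles are automatically ordered.

Default priors are weakly informative for constant-temperature incubation
designs in the high-20s degC: P ~ Uniform(20, 35) degC, and |S| half-normal
with scale 1.0 degC (sign fixed by the limb direction, truncated at
|S| = 5).  The half-normal keeps the TRT prior concentrated on widths a
constant-temperature experiment spanning 8 degC can actually resolve
(prior median TRT ~ 4 degC) while leaving appreciable mass out to ~ 13 degC;
a flat prior on the scale instead puts half its mass on TRT > 14.7 degC,
which two- or three-temperature limbs can rarely rule out.  Set
``S_scale=None`` for a fully uniform prior.

Defaults: 60,000 iterations, 10,000 burn-in, thinning 5, proposal standard
deviations 0.3 degC (P) and 0.2 degC (S).  The seed must always be given
explicitly; a fixed seed reproduces the chain bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from .ml_fitting import BinomialDataset, fit_mle, log_likelihood
from .reaction_norms import FlexitNorm, LogisticNorm

__all__ = [
    "PriorSpec",
    "McmcConfig",
    "ParameterChain",
    "PosteriorSummary",
    "DiagnosticReport",
    "default_prior",
    "run_mcmc",
    "summarize_posterior",
    "effective_diagnostics",
    "write_chain",
]

_QUANTS = (0.025, 0.5, 0.975)


@dataclass(frozen=True)
class PriorSpec:
    """Independent uniform priors: box bounds per parameter.

    ``S_bounds`` must be direction-consistent: (0, S_max) for an FM limb,
    (-S_max, 0) for an MF limb.  ``S_scale``, when set, places a half-normal
    density with that scale (in degC) on the logistic |S| inside the bounds;
    ``S_scale=None`` makes the S prior uniform on its box.  The scale prior
    applies to the logistic scale parameter only; a flexit pivot slope uses
    the uniform box.  ``K_bounds`` applies to both flexit shape constants
    and is ignored for the logistic model.
    """

    P_bounds: tuple[float, float] = (20.0, 35.0)
    S_bounds: tuple[float, float] = (0.0, 5.0)
    K_bounds: tuple[float, float] | None = None
    S_scale: float | None = 1.0

    def __post_init__(self) -> None:
        for name in ("P_bounds", "S_bounds", "K_bounds"):
            bounds = getattr(self, name)
            if bounds is None:
                continue
            lo, hi = bounds
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise ValueError(f"{name} must be finite with low < high, got {bounds}")
        if self.S_scale is not None and not self.S_scale > 0:
            raise ValueError(f"S_scale must be positive or None, got {self.S_scale}")

    @property
    def direction(self) -> str:
        return "FM" if self.S_bounds[0] >= 0.0 else "MF"


def default_prior(direction: str = "FM", model: str = "logistic") -> PriorSpec:
    """The package's default prior for one limb of the given direction."""
    if direction == "FM":
        s_bounds = (0.0, 5.0)
    elif direction == "MF":
        s_bounds = (-5.0, 0.0)
    else:
        raise ValueError(f"direction must be 'FM' or 'MF', got {direction!r}")
    k_bounds = (0.1, 10.0) if model == "flexit" else None
    return PriorSpec(
        P_bounds=(20.0, 35.0), S_bounds=s_bounds, K_bounds=k_bounds, S_scale=1.0
    )


@dataclass(frozen=True)
class McmcConfig:
    """Sampler settings; the seed is mandatory."""

    seed: int
    n_iterations: int = 60_000
    burn_in: int = 10_000
    thin: int = 5
    proposal_sd: tuple[float, ...] = (0.3, 0.2)

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iterations:
            raise ValueError("require 0 <= burn_in < n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if any(sd <= 0 for sd in self.proposal_sd):
            raise ValueError("proposal_sd entries must be positive")


@dataclass(frozen=True)
class ParameterChain:
    """Retained MCMC draws (rows) for named parameters (columns)."""

    draws: np.ndarray
    acceptance_rate: float
    param_names: tuple[str, ...]
    notes: tuple[str, ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return self.draws.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.draws[:, self.param_names.index(name)]


@dataclass(frozen=True)
class PosteriorSummary:
    """(2.5%, 50%, 97.5%) posterior quantiles for P (= T_piv), S, and TRT."""

    P: tuple[float, float, float]
    S: tuple[float, float, float]
    TRT: tuple[float, float, float]
    l: float = 0.05


@dataclass(frozen=True)
class DiagnosticReport:
    acceptance_rate: float
    lag1_autocorr: tuple[float, ...]
    split_rhat: tuple[float, ...]
    flagged: bool


def _bounds_matrix(prior: PriorSpec, model: str) -> tuple[np.ndarray, tuple[str, ...]]:
    if model == "logistic":
        names: tuple[str, ...] = ("P", "S")
        rows = [prior.P_bounds, prior.S_bounds]
    elif model == "flexit":
        if prior.K_bounds is None:
            raise ValueError("flexit sampling requires PriorSpec.K_bounds")
        names = ("P", "S_slope", "K1", "K2")
        rows = [prior.P_bounds, prior.S_bounds, prior.K_bounds, prior.K_bounds]
    else:
        raise ValueError(f"unknown model {model!r}")
    return np.asarray(rows, dtype=float), names


def _make_loglik(
    data: BinomialDataset | None, model: str
) -> Callable[[np.ndarray], float]:
    if data is None:
        return lambda x: 0.0
    if model == "logistic":
        T = data.temperatures
        m = data.males
        f = data.totals - data.males

        def loglik(x: np.ndarray) -> float:
            z = np.clip((x[0] - T) / x[1], -500.0, 500.0)
            sr = np.clip(1.0 / (1.0 + np.exp(z)), 1e-12, 1.0 - 1e-12)
            return float(m @ np.log(sr) + f @ np.log1p(-sr))

        return loglik

    def loglik_flexit(x: np.ndarray) -> float:
        return log_likelihood(FlexitNorm(x[0], x[1], x[2], x[3]), data)

    return loglik_flexit


def _initial_point(
    data: BinomialDataset | None,
    model: str,
    prior: PriorSpec,
    bounds: np.ndarray,
) -> np.ndarray:
    mid = bounds.mean(axis=1)
    if data is None:
        return mid
    fit = fit_mle(data, model=model, direction=prior.direction)
    if model == "logistic":
        x0 = np.asarray([fit.params.P, fit.params.S])
    else:
        p = fit.params
        x0 = np.asarray([p.P, p.S_slope, p.K1, p.K2])
    # Clip the start strictly inside the prior box.
    pad = 0.01 * (bounds[:, 1] - bounds[:, 0])
    return np.clip(x0, bounds[:, 0] + pad, bounds[:, 1] - pad)


def run_mcmc(
    data: BinomialDataset | None,
    model: str,
    prior: PriorSpec,
    config: McmcConfig,
    init: np.ndarray | None = None,
) -> ParameterChain:
    """Sample reaction-norm parameters by component-wise random-walk MH.

    The log-target is the binomial log-likelihood plus the prior log
    density (-inf outside the bounds; inside, 0 for uniform components and
    the half-normal term for S when ``prior.S_scale`` is set).  Passing
    ``data=None`` samples the prior alone, which is useful for sampler
    validation.
    The chain starts at the MLE (clipped inside the prior box), or at the
    box centre when there is no data.
    """
    bounds, names = _bounds_matrix(prior, model)
    npar = len(names)
    sds = list(config.proposal_sd)
    if len(sds) < npar:  # extend for flexit shape parameters
        sds = sds + [0.25] * (npar - len(sds))
    sds_arr = np.asarray(sds[:npar], dtype=float)

    loglik = _make_loglik(data, model)
    if model == "logistic" and prior.S_scale is not None:
        half_inv_var = 1.0 / (2.0 * prior.S_scale**2)
        base_loglik = loglik

        def target(x: np.ndarray) -> float:
            return base_loglik(x) - x[1] * x[1] * half_inv_var

    else:
        target = loglik
    lo, hi = bounds[:, 0], bounds[:, 1]
    x = np.array(
        _initial_point(data, model, prior, bounds) if init is None else init,
        dtype=float,
    )
    if np.any(x <= lo) or np.any(x >= hi):
        raise ValueError("initial point must lie strictly inside the prior bounds")

    rng = np.random.default_rng(config.seed)
    lp = target(x)
    n_keep = (config.n_iterations - config.burn_in) // config.thin
    draws = np.empty((n_keep, npar))
    accepted = 0
    proposed = 0
    kept = 0
    # Pre-generate the innovations and uniforms for speed.
    steps = rng.normal(0.0, 1.0, size=(config.n_iterations, npar)) * sds_arr
    logu = np.log(rng.uniform(size=(config.n_iterations, npar)))
    for it in range(config.n_iterations):
        for j in range(npar):
            proposed += 1
            xj_new = x[j] + steps[it, j]
            if xj_new <= lo[j] or xj_new >= hi[j]:
                continue  # flat prior: out-of-bounds proposal rejected outright
            old = x[j]
            x[j] = xj_new
            lp_new = target(x)
            if logu[it, j] < lp_new - lp:
                lp = lp_new
                accepted += 1
            else:
                x[j] = old
        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            draws[kept] = x
            kept += 1
    notes: tuple[str, ...] = ()
    if accepted == 0:
        notes = ("convergence failure: zero proposals accepted over the whole run",)
    return ParameterChain(
        draws=draws[:kept],
        acceptance_rate=accepted / proposed,
        param_names=names,
        notes=notes,
    )


def _trt_per_draw(chain: ParameterChain, l: float) -> np.ndarray:
    from .reaction_norms import trt  # local import avoids cycle at module load

    if "S" in chain.param_names:  # logistic chain: closed form, vectorised
        return 2.0 * np.abs(chain.column("S")) * math.log((1.0 - l) / l)
    return np.asarray(
        [
            trt(FlexitNorm(p, s, k1, k2), l)
            for p, s, k1, k2 in chain.draws
        ]
    )


def summarize_posterior(chain: ParameterChain, l: float = 0.05) -> PosteriorSummary:
    """Empirical (2.5, 50, 97.5)% quantiles of T_piv, S, and per-draw TRT.

    TRT is transformed draw by draw and then summarised; summarising S first
    and transforming its quantiles would not guarantee ordered TRT quantiles.
    """
    if len(chain) == 0:
        raise ValueError("cannot summarise an empty chain")
    if not 0.0 < l < 0.5:
        raise ValueError(f"TRT threshold l must be in (0, 0.5), got {l!r}")
    p_q = np.quantile(chain.column("P"), _QUANTS)
    s_name = "S" if "S" in chain.param_names else "S_slope"
    s_q = np.quantile(chain.column(s_name), _QUANTS)
    trt_q = np.quantile(_trt_per_draw(chain, l), _QUANTS)
    return PosteriorSummary(P=tuple(p_q), S=tuple(s_q), TRT=tuple(trt_q), l=l)


def effective_diagnostics(chain: ParameterChain) -> DiagnosticReport:
    """Acceptance rate, lag-1 autocorrelation, and split-half R-hat per parameter.

    The retained chain is split into halves and the classic potential scale
    reduction factor computed on them; a factor above 1.05 (or a degenerate,
    constant parameter) flags the run.
    """
    if len(chain) < 100:
        raise ValueError("diagnostics require at least 100 retained draws")
    lag1 = []
    rhats = []
    flagged = bool(chain.notes)
    for j in range(chain.draws.shape[1]):
        x = chain.draws[:, j]
        if np.var(x) == 0.0:
            lag1.append(1.0)
            rhats.append(math.inf)
            flagged = True
            continue
        lag1.append(float(np.corrcoef(x[:-1], x[1:])[0, 1]))
        half = len(x) // 2
        halves = np.stack([x[:half], x[half : 2 * half]])
        n = half
        means = halves.mean(axis=1)
        w = halves.var(axis=1, ddof=1).mean()
        b = n * means.var(ddof=1)
        var_hat = (n - 1) / n * w + b / n
        rhat = math.sqrt(var_hat / w)
        rhats.append(float(rhat))
        if rhat > 1.05:
            flagged = True
    return DiagnosticReport(
        acceptance_rate=chain.acceptance_rate,
        lag1_autocorr=tuple(lag1),
        split_rhat=tuple(rhats),
        flagged=flagged,
    )


def write_chain(chain: ParameterChain, path: str | Path) -> None:
    """Export the retained draws as tab-separated text, one row per draw."""
    header = "\t".join(chain.param_names)
    np.savetxt(path, chain.draws, delimiter="\t", header=header, comments="")
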