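"""Synthetic sex-count generator and pipeline parameter-recovery harness.

The generator draws hatchling sex counts with exactly the statistical
structure the analysis assumes: at each constant incubation temperature T,
the number of males among sexed hatchlings is Binomial(n, m(T)), where the
joint FMF male-proportion curve is the product of the two limb logistics,

    m(T) = logistic(P_fm, S_fm)(T) * logistic(P_mf, S_mf)(T),

with S_fm > 0 (female-to-male limb) and S_mf < 0 (male-to-female limb).
The product form is ~0 at both temperature extremes, peaks between the two
pivots strictly below 1, and coincides with each limb's logistic away from
the opposite pivot.  An unidentified-sex dropout is applied independently
of sex.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .fmf_pipeline import analyze_population
from .posterior_mcmc import McmcConfig
from .reaction_norms import LogisticNorm, logistic_sr
from .sexcount_io import SexCountRecord, SexCountTable

__all__ = [
    "FmfTruth",
    "SimDesign",
    "RecoveryReport",
    "simulate_counts",
    "recovery_experiment",
]

_TRT_FACTOR = 2.0 * math.log(19.0)  # logistic TRT per unit |S| at l = 0.05


@dataclass(frozen=True)
class FmfTruth:
    """True dual-transition reaction norm used to generate data."""

    P_fm: float
    S_fm: float
    P_mf: float
    S_mf: float

    def __post_init__(self) -> None:
        if self.S_fm <= 0:
            raise ValueError("S_fm must be > 0 (FM limb increases with T)")
        if self.S_mf >= 0:
            raise ValueError("S_mf must be < 0 (MF limb decreases with T)")
        if not self.P_fm < self.P_mf:
            raise ValueError("require P_fm < P_mf for an FMF pattern")

    def male_proportion(self, T: float | np.ndarray) -> float | np.ndarray:
        fm = logistic_sr(LogisticNorm(self.P_fm, self.S_fm), T)
        mf = logistic_sr(LogisticNorm(self.P_mf, self.S_mf), T)
        return fm * mf

    @property
    def trt_fm(self) -> float:
        return _TRT_FACTOR * abs(self.S_fm)

    @property
    def trt_mf(self) -> float:
        return _TRT_FACTOR * abs(self.S_mf)

    def joint_pivots(self) -> tuple[float, float]:
        """The joint curve's actual 1:1 crossings (FM side, MF side).

        When the two transitions overlap, each limb's 50% crossing of the
        *product* curve sits slightly toward the opposite limb relative to
        the limb parameter P, so these -- not ``P_fm``/``P_mf`` -- are the
        pivotal temperatures a sexed-hatchling experiment actually probes.
        Raises ``ValueError`` if the male proportion never exceeds 1/2.
        """
        from scipy.optimize import brentq, minimize_scalar

        lo = self.P_fm - 20.0 * abs(self.S_fm)
        hi = self.P_mf + 20.0 * abs(self.S_mf)
        peak = minimize_scalar(
            lambda T: -self.male_proportion(T), bounds=(lo, hi), method="bounded"
        ).x
        if self.male_proportion(peak) <= 0.5:
            raise ValueError("joint curve never reaches a male majority")

        def f(T: float) -> float:
            return self.male_proportion(T) - 0.5

        return (
            float(brentq(f, lo, peak, xtol=1e-10)),
            float(brentq(f, peak, hi, xtol=1e-10)),
        )


@dataclass(frozen=True)
class SimDesign:
    """Incubation design for the generator.

    Defaults mirror the gecko experiment's design: five constant
    temperatures spanning 24-32 degC, with clutch sizes per temperature on
    the order of the study's 50-90 sexed hatchlings, and a small
    sex-independent chance that a hatchling's sex cannot be identified.
    """

    temperatures: tuple[float, ...] = (24.0, 26.0, 28.0, 30.0, 32.0)
    eggs_per_temperature: int = 60
    unidentified_prob: float = 0.02
    seed: int = 0
    populations: int = 1

    def __post_init__(self) -> None:
        if len(self.temperatures) < 2:
            raise ValueError("need at least two incubation temperatures")
        if self.eggs_per_temperature < 1:
            raise ValueError("eggs_per_temperature must be >= 1")
        if not 0.0 <= self.unidentified_prob < 1.0:
            raise ValueError("unidentified_prob must be in [0, 1)")
        if self.populations < 1:
            raise ValueError("populations must be >= 1")


def simulate_counts(truth: FmfTruth, design: SimDesign) -> SexCountTable:
    """Draw a sex-count table from the FMF truth under the design.

    Per temperature: ``n_sexed ~ Binomial(eggs, 1 - unidentified_prob)``,
    then ``males ~ Binomial(n_sexed, m(T))``; females are the remainder and
    the dropout count is ``eggs - n_sexed``.  Reproducible under the seed.
    """
    rng = np.random.default_rng(design.seed)
    records = []
    for p in range(design.populations):
        label = f"sim{p + 1}"
        for T in design.temperatures:
            eggs = design.eggs_per_temperature
            n_sexed = int(rng.binomial(eggs, 1.0 - design.unidentified_prob))
            males = int(rng.binomial(n_sexed, truth.male_proportion(T))) if n_sexed else 0
            records.append(
                SexCountRecord(
                    population=label,
                    temperature=T,
                    n_female=n_sexed - males,
                    n_male=males,
                    n_unidentified=eggs - n_sexed,
                )
            )
    return SexCountTable(tuple(records))


@dataclass(frozen=True)
class RecoveryReport:
    """Bias, RMSE, and credible-interval coverage against a known truth.

    Keys of the per-quantity dictionaries: ``P_fm``, ``P_mf``, ``TRT_fm``,
    ``TRT_mf``.  Coverage is the fraction of replicates whose central 95%
    credible interval contains the true value.
    """

    truth: FmfTruth
    replicates: int
    n_success: int
    bias: dict[str, float]
    rmse: dict[str, float]
    coverage: dict[str, float]
    medians: dict[str, tuple[float, ...]]
    failures: tuple[str, ...] = field(default_factory=tuple)


def recovery_experiment(
    truth: FmfTruth,
    design: SimDesign,
    replicates: int,
    config: McmcConfig,
    rule: str = "crossing",
    candidates: Sequence[str] = ("logistic",),
) -> RecoveryReport:
    """Repeatedly simulate and re-analyse; score posterior medians against truth.

    Pivotal temperatures are scored against the joint curve's actual 1:1
    crossings (:meth:`FmfTruth.joint_pivots`); TRTs against the limb values
    ``2 ln(19) |S|``.

    Each replicate simulates a fresh table (seed ``design.seed + r``), runs
    the full per-population pipeline with MCMC seed ``config.seed + 10 * r``,
    and records the posterior medians and 95% intervals for both pivotal
    temperatures and both TRTs.  Per-replicate failures are collected, not
    fatal.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    pivot_fm, pivot_mf = truth.joint_pivots()
    true_values = {
        "P_fm": pivot_fm,
        "P_mf": pivot_mf,
        "TRT_fm": truth.trt_fm,
        "TRT_mf": truth.trt_mf,
    }
    medians: dict[str, list[float]] = {k: [] for k in true_values}
    covered: dict[str, list[bool]] = {k: [] for k in true_values}
    failures: list[str] = []
    for r in range(replicates):
        rep_design = dataclasses.replace(design, seed=design.seed + r, populations=1)
        rep_config = dataclasses.replace(config, seed=config.seed + 10 * r)
        try:
            table = simulate_counts(truth, rep_design)
            result = analyze_population(
                table, "sim1", rep_config, rule=rule, candidates=candidates
            )
        except Exception as exc:  # aggregate, don't abort the experiment
            failures.append(f"replicate {r}: {type(exc).__name__}: {exc}")
            continue
        for key, limb in (("fm", result.fm), ("mf", result.mf)):
            p_lo, p_med, p_hi = limb.posterior.P
            t_lo, t_med, t_hi = limb.posterior.TRT
            medians[f"P_{key}"].append(p_med)
            covered[f"P_{key}"].append(p_lo <= true_values[f"P_{key}"] <= p_hi)
            medians[f"TRT_{key}"].append(t_med)
            covered[f"TRT_{key}"].append(t_lo <= true_values[f"TRT_{key}"] <= t_hi)
    n_success = len(medians["P_fm"])
    bias = {}
    rmse = {}
    coverage = {}
    for k, tv in true_values.items():
        vals = np.asarray(medians[k])
        if vals.size:
            bias[k] = float(np.mean(vals - tv))
            rmse[k] = float(np.sqrt(np.mean((vals - tv) ** 2)))
            coverage[k] = float(np.mean(covered[k]))
        else:
            bias[k] = rmse[k] = coverage[k] = math.nan
    return RecoveryReport(
        truth=truth,
        replicates=replicates,
        n_success=n_success,
        bias=bias,
        rmse=rmse,
        coverage=coverage,
        medians={k: tuple(v) for k, v in medians.items()},
        failures=tuple(failures),
    )
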