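"""Per-population FMF analysis: limb splitting, fitting, MCMC, classification.

An FMF (female-male-female) pattern of temperature-dependent sex
determination has two monotone transitions: a female-to-male (FM) limb at
low temperatures and a male-to-female (MF) limb at high temperatures.  Each
limb is analysed independently -- AICc model selection between the logistic
and flexit curves, then Metropolis-Hastings posteriors for the pivotal
temperature and TRT under the selected model.

The split between limbs is not observable directly.  Three rules are
provided:

* ``crossing`` (default): each limb runs from its female-biased extreme
  through the sex-ratio reversal -- the FM limb covers temperatures up to
  and including the *first* with an observed male majority, the MF limb
  temperatures from the *last* male-majority temperature upward.  Interior
  plateau temperatures between the two crossings belong to neither limb.
* ``middle``: split at the median-ranked incubation temperature (28 degC
  for five temperatures 24-32 degC), shared by both limbs.
* ``peak``: split at the temperature with the highest observed male
  proportion, shared by both limbs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .ml_fitting import BinomialDataset, ModelSelection, select_model
from .posterior_mcmc import (
    McmcConfig,
    ParameterChain,
    PosteriorSummary,
    PriorSpec,
    default_prior,
    run_mcmc,
    summarize_posterior,
)
from .sexcount_io import SexCountTable
from .sexratio_tests import DEFAULT_ALPHA, DepartureRow, departure_table, _rows_frame

__all__ = [
    "LimbSplit",
    "LimbAnalysis",
    "PopulationResult",
    "LimbSplitError",
    "split_limbs",
    "analyze_population",
    "analyze_table",
    "classify_pattern",
    "write_results",
]

SPLIT_RULES = ("crossing", "middle", "peak")


class LimbSplitError(ValueError):
    """The population has too few temperatures to define two limbs."""


@dataclass(frozen=True)
class LimbSplit:
    """Assignment of a population's temperatures to the two limbs.

    ``split_temperature`` is the temperature shared by both limbs under the
    ``middle``/``peak`` rules; under ``crossing`` it is the FM limb's upper
    boundary (the limbs need not share a temperature).
    """

    fm_temperatures: tuple[float, ...]
    mf_temperatures: tuple[float, ...]
    rule: str
    split_temperature: float


@dataclass(frozen=True)
class LimbAnalysis:
    """Everything computed for one transition limb."""

    direction: str
    data: BinomialDataset
    selection: ModelSelection
    prior: PriorSpec
    chain: ParameterChain
    posterior: PosteriorSummary


@dataclass(frozen=True)
class PopulationResult:
    population: str
    split: LimbSplit
    fm: LimbAnalysis
    mf: LimbAnalysis
    departure_rows: tuple[DepartureRow, ...]
    pattern: str


def _limb_dataset(table: SexCountTable, temps: Sequence[float]) -> BinomialDataset:
    recs = {r.temperature: r for r in table}
    chosen = [recs[t] for t in temps]
    return BinomialDataset(
        temperatures=np.asarray([r.temperature for r in chosen], dtype=float),
        males=np.asarray([r.n_male for r in chosen], dtype=float),
        totals=np.asarray([r.n_sexed for r in chosen], dtype=float),
    )


def split_limbs(
    table: SexCountTable, population: str, rule: str = "crossing"
) -> tuple[LimbSplit, BinomialDataset, BinomialDataset]:
    """Split one population's treatments into FM and MF limb datasets.

    ``crossing`` bounds the FM limb at the first temperature with an
    observed male majority and starts the MF limb at the last such
    temperature (falling back to the male-proportion peak if no treatment
    has a majority, in which case the peak is shared).  ``middle`` takes
    the median-ranked temperature and ``peak`` the male-proportion maximum
    (ties toward the lower temperature); both share the split temperature
    between the limbs.  Every limb is padded to at least two temperatures.
    """
    if rule not in SPLIT_RULES:
        raise ValueError(f"rule must be one of {SPLIT_RULES}, got {rule!r}")
    sub = table.for_population(population)
    temps = sorted({r.temperature for r in sub})
    if len(temps) < 3:
        raise LimbSplitError(
            f"population {population!r} has {len(temps)} temperatures; need >= 3"
        )
    by_temp = {r.temperature: r for r in sub}
    if rule == "middle":
        t_fm = t_mf = temps[(len(temps) - 1) // 2]
    elif rule == "peak":
        t_fm = t_mf = max(temps, key=lambda t: (by_temp[t].male_proportion, -t))
    else:
        majority = [t for t in temps if by_temp[t].male_proportion > 0.5]
        if majority:
            t_fm, t_mf = majority[0], majority[-1]
        else:
            t_fm = t_mf = max(temps, key=lambda t: (by_temp[t].male_proportion, -t))
    # Guarantee two design points per limb even for edge-located crossings.
    t_fm = max(t_fm, temps[1])
    t_mf = min(t_mf, temps[-2])
    fm_temps = tuple(t for t in temps if t <= t_fm)
    mf_temps = tuple(t for t in temps if t >= t_mf)
    if len(fm_temps) < 2 or len(mf_temps) < 2:
        raise LimbSplitError(
            f"split at {t_fm}/{t_mf} degC leaves a limb with fewer than 2 temperatures"
        )
    split = LimbSplit(fm_temps, mf_temps, rule, t_fm)
    return split, _limb_dataset(sub, fm_temps), _limb_dataset(sub, mf_temps)


def classify_pattern(
    rows: Sequence[DepartureRow], alpha: float = DEFAULT_ALPHA
) -> str:
    """Classify a population's pattern from its per-temperature departure tests.

    ``FMF``: significantly female-biased at both the lowest and highest
    temperatures, with a male majority at some interior temperature.
    ``FM`` / ``MF``: significant female bias at one extreme and significant
    male bias at the other, with no interior reversal (the FMF check runs
    first, so a detected reversal takes precedence).  Anything else: ``none``.
    """
    rows = sorted(rows, key=lambda r: r.temperature)
    if len(rows) < 2:
        return "none"
    low, high = rows[0], rows[-1]
    interior = rows[1:-1]
    if (
        low.female_biased
        and high.female_biased
        and any(r.male_proportion > 0.5 for r in interior)
    ):
        return "FMF"
    if low.female_biased and high.male_biased:
        return "FM"
    if low.male_biased and high.female_biased:
        return "MF"
    return "none"


def _analyze_limb(
    data: BinomialDataset,
    direction: str,
    config: McmcConfig,
    prior_template: PriorSpec | None,
    candidates: Sequence[str],
    l: float,
) -> LimbAnalysis:
    selection = select_model(data, direction=direction, candidates=candidates)
    model = selection.best
    if prior_template is None:
        prior = default_prior(direction, model=model)
    else:
        # Re-orient the template's S bounds to the limb direction.
        lo, hi = prior_template.S_bounds
        s_max = max(abs(lo), abs(hi))
        s_bounds = (0.0, s_max) if direction == "FM" else (-s_max, 0.0)
        k_bounds = prior_template.K_bounds
        if model == "flexit" and k_bounds is None:
            k_bounds = (0.1, 10.0)
        prior = PriorSpec(
            prior_template.P_bounds, s_bounds, k_bounds, prior_template.S_scale
        )
    chain = run_mcmc(data, model, prior, config)
    posterior = summarize_posterior(chain, l=l)
    return LimbAnalysis(direction, data, selection, prior, chain, posterior)


def analyze_population(
    table: SexCountTable,
    population: str,
    config: McmcConfig,
    prior_template: PriorSpec | None = None,
    rule: str = "crossing",
    candidates: Sequence[str] = ("logistic", "flexit"),
    l: float = 0.05,
    alpha: float = DEFAULT_ALPHA,
) -> PopulationResult:
    """Full single-population analysis.

    Splits the limbs, runs AICc model selection and MCMC per limb (the MF
    limb's chain is seeded with ``config.seed + 1`` so the two chains are
    independent but jointly reproducible), attaches the per-temperature
    departure tests, and classifies the pattern.
    """
    try:
        split, fm_data, mf_data = split_limbs(table, population, rule=rule)
        fm = _analyze_limb(fm_data, "FM", config, prior_template, candidates, l)
        mf_config = dataclasses.replace(config, seed=config.seed + 1)
        mf = _analyze_limb(mf_data, "MF", mf_config, prior_template, candidates, l)
        rows = tuple(departure_table(table.for_population(population), alpha=alpha))
    except ValueError as exc:
        raise type(exc)(f"population {population!r}: {exc}") from exc
    return PopulationResult(
        population=population,
        split=split,
        fm=fm,
        mf=mf,
        departure_rows=rows,
        pattern=classify_pattern(rows, alpha=alpha),
    )


def analyze_table(
    table: SexCountTable,
    config: McmcConfig,
    prior_template: PriorSpec | None = None,
    rule: str = "crossing",
    candidates: Sequence[str] = ("logistic", "flexit"),
    l: float = 0.05,
    alpha: float = DEFAULT_ALPHA,
) -> list[PopulationResult]:
    """Analyse every population in the table with per-population seed offsets."""
    results = []
    for i, population in enumerate(table.populations):
        pop_config = dataclasses.replace(config, seed=config.seed + 1000 * i)
        results.append(
            analyze_population(
                table,
                population,
                pop_config,
                prior_template=prior_template,
                rule=rule,
                candidates=candidates,
                l=l,
                alpha=alpha,
            )
        )
    return results


def _quantile_frame(results: Sequence[PopulationResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        for direction, limb in (("FM", res.fm), ("MF", res.mf)):
            for name, quants in (("T_piv", limb.posterior.P), ("TRT", limb.posterior.TRT)):
                q025, q50, q975 = quants
                rows.append(
                    {
                        "population": res.population,
                        "transition": direction,
                        "parameter": name,
                        "q2.5": round(q025, 2),
                        "q50": round(q50, 2),
                        "q97.5": round(q975, 2),
                    }
                )
    return pd.DataFrame(rows)


def write_results(
    results: Sequence[PopulationResult],
    outdir: str | Path,
    config: McmcConfig | None = None,
) -> dict[str, Path]:
    """Write the quantile table, departure table, and run metadata.

    Emits ``tpiv_trt.tsv`` (population x transition x {T_piv, TRT}
    quantiles), ``departure.tsv`` (per-treatment 1:1 tests), and
    ``run_meta.json`` (seeds, priors, sampler settings, selected models,
    acceptance rates, patterns) under ``outdir``.
    """
    if not results:
        raise ValueError("results must be non-empty")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "tpiv_trt": outdir / "tpiv_trt.tsv",
        "departure": outdir / "departure.tsv",
        "meta": outdir / "run_meta.json",
    }
    _quantile_frame(results).to_csv(paths["tpiv_trt"], sep="\t", index=False)
    all_rows = [row for res in results for row in res.departure_rows]
    _rows_frame(all_rows).to_csv(paths["departure"], sep="\t", index=False)
    meta: dict = {
        "trt_threshold_l": results[0].fm.posterior.l,
        "populations": {},
    }
    if config is not None:
        meta["mcmc"] = {
            "seed": config.seed,
            "n_iterations": config.n_iterations,
            "burn_in": config.burn_in,
            "thin": config.thin,
            "proposal_sd": list(config.proposal_sd),
        }
    for res in results:
        meta["populations"][res.population] = {
            "pattern": res.pattern,
            "split_rule": res.split.rule,
            "split_temperature": res.split.split_temperature,
            "limbs": {
                direction: {
                    "model": limb.selection.best,
                    "akaike_weight": round(
                        limb.selection.akaike_weight[limb.selection.best], 4
                    ),
                    "prior_P_bounds": list(limb.prior.P_bounds),
                    "prior_S_bounds": list(limb.prior.S_bounds),
                    "acceptance_rate": round(limb.chain.acceptance_rate, 4),
                }
                for direction, limb in (("FM", res.fm), ("MF", res.mf))
            },
        }
    paths["meta"].write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return paths
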