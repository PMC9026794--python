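"""Chi-square goodness-of-fit tests for departure of sex ratios from 1:1.

For one treatment with F females and M males identified, the expected count
under a balanced sex ratio is (F + M)/2 per sex, giving the 1-df statistic

    chi2 = (F - M)^2 / (F + M).

No continuity correction is applied, and unidentified hatchlings are
excluded before the test.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
from scipy.stats import chi2 as _chi2_dist

from .sexcount_io import SexCountTable

__all__ = [
    "ChiSquareResult",
    "DepartureRow",
    "EmptyTreatmentError",
    "chisq_departure",
    "departure_table",
    "write_departure_table",
]

DEFAULT_ALPHA = 0.05


class EmptyTreatmentError(ValueError):
    """No sexed hatchlings in a treatment; the departure test is undefined."""


@dataclass(frozen=True)
class ChiSquareResult:
    chi2: float
    df: int
    p: float
    n_used: int


@dataclass(frozen=True)
class DepartureRow:
    """One treatment's departure test with the bias flags used downstream."""

    population: str
    temperature: float
    n_female: int
    n_male: int
    result: ChiSquareResult
    alpha: float = DEFAULT_ALPHA

    @property
    def significant(self) -> bool:
        return self.result.p < self.alpha

    @property
    def female_biased(self) -> bool:
        return self.n_female > self.n_male and self.significant

    @property
    def male_biased(self) -> bool:
        return self.n_male > self.n_female and self.significant

    @property
    def male_proportion(self) -> float:
        return self.n_male / (self.n_female + self.n_male)


def chisq_departure(n_female: int, n_male: int) -> ChiSquareResult:
    """Test F:M counts against an expected 1:1 split (df = 1, uncorrected)."""
    if n_female < 0 or n_male < 0:
        raise ValueError("counts must be non-negative")
    total = n_female + n_male
    if total == 0:
        raise EmptyTreatmentError("no sexed hatchlings in this treatment")
    stat = (n_female - n_male) ** 2 / total
    return ChiSquareResult(
        chi2=float(stat), df=1, p=float(_chi2_dist.sf(stat, 1)), n_used=total
    )


def departure_table(
    table: SexCountTable, alpha: float = DEFAULT_ALPHA
) -> list[DepartureRow]:
    """Run the departure test on every record of a table, order preserved."""
    rows = []
    for rec in table:
        try:
            result = chisq_departure(rec.n_female, rec.n_male)
        except EmptyTreatmentError as exc:
            raise EmptyTreatmentError(
                f"{rec.population} at {rec.temperature} degC: {exc}"
            ) from exc
        rows.append(
            DepartureRow(
                population=rec.population,
                temperature=rec.temperature,
                n_female=rec.n_female,
                n_male=rec.n_male,
                result=result,
                alpha=alpha,
            )
        )
    return rows


def _rows_frame(rows: Sequence[DepartureRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "population": [r.population for r in rows],
            "temperature_C": [r.temperature for r in rows],
            "n_female": [r.n_female for r in rows],
            "n_male": [r.n_male for r in rows],
            "chi2": [round(r.result.chi2, 3) for r in rows],
            "df": [r.result.df for r in rows],
            "p": [round(r.result.p, 4) for r in rows],
            "significant": [r.significant for r in rows],
            "bias": [
                "female" if r.female_biased else "male" if r.male_biased else "none"
                for r in rows
            ],
        }
    )


def write_departure_table(rows: Sequence[DepartureRow], path: str | Path) -> None:
    """Write the per-treatment test table as tab-separated text."""
    _rows_frame(rows).to_csv(path, sep="\t", index=False)
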