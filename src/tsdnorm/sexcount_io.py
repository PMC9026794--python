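"""Hatchling sex-count data model, CSV readers/writers, and egg-geometry helpers.

The observational unit throughout the package is one incubation treatment:
a (population, constant incubation temperature) pair with counts of female,
male, and unidentified hatchlings.  Unidentified hatchlings are carried in
the data model but excluded from every downstream statistic.

The packaged dataset covers three *Gekko japonicus* populations sampled
along a latitudinal cline in eastern China (Yancheng, northern; Chuzhou,
central; Wenzhou, southern), each incubated at 24, 26, 28, 30 and 32 degC.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

__all__ = [
    "COLUMNS",
    "SexCountRecord",
    "SexCountTable",
    "EggDimensions",
    "MissingColumnError",
    "InvalidCountError",
    "DuplicateTreatmentError",
    "read_sex_counts",
    "write_sex_counts",
    "load_gekko_fixture",
    "egg_volume",
    "apportion_clutch_mass",
]

#: CSV dialect: comma-separated, UTF-8, header mandatory, these five columns.
COLUMNS = ("population", "temperature_C", "n_female", "n_male", "n_unidentified")

_FIXTURE_NAME = "gekko_japonicus_sexcounts.csv"


class MissingColumnError(ValueError):
    """A required column is absent from the input header."""


class InvalidCountError(ValueError):
    """A count field is negative, non-integer, or otherwise unusable."""


class DuplicateTreatmentError(ValueError):
    """The same (population, temperature) pair appears more than once."""


@dataclass(frozen=True)
class SexCountRecord:
    """Sexed-hatchling counts for one incubation treatment."""

    population: str
    temperature: float
    n_female: int
    n_male: int
    n_unidentified: int = 0

    def __post_init__(self) -> None:
        if not math.isfinite(self.temperature) or not 0.0 < self.temperature < 50.0:
            raise ValueError(
                f"temperature must be finite and in (0, 50) degC, got {self.temperature!r}"
            )
        for name in ("n_female", "n_male", "n_unidentified"):
            value = getattr(self, name)
            if isinstance(value, bool) or value != int(value):
                raise InvalidCountError(f"{name} must be integer-valued, got {value!r}")
            if value < 0:
                raise InvalidCountError(f"{name} must be >= 0, got {value!r}")
            object.__setattr__(self, name, int(value))
        object.__setattr__(self, "temperature", float(self.temperature))

    @property
    def n_sexed(self) -> int:
        """Hatchlings with an identified sex (females + males)."""
        return self.n_female + self.n_male

    @property
    def male_proportion(self) -> float:
        """Observed male proportion among sexed hatchlings (NaN if none sexed)."""
        return self.n_male / self.n_sexed if self.n_sexed else math.nan


@dataclass(frozen=True)
class SexCountTable:
    """An ordered collection of sex-count records with unique treatments."""

    records: tuple[SexCountRecord, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        records = tuple(self.records)
        if not records:
            raise ValueError("a SexCountTable requires at least one record")
        seen: set[tuple[str, float]] = set()
        for rec in records:
            key = (rec.population, rec.temperature)
            if key in seen:
                raise DuplicateTreatmentError(
                    f"duplicate treatment {rec.population!r} at {rec.temperature} degC"
                )
            seen.add(key)
        object.__setattr__(self, "records", records)

    def __iter__(self) -> Iterator[SexCountRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def populations(self) -> tuple[str, ...]:
        """Population labels in first-appearance order."""
        out: list[str] = []
        for rec in self.records:
            if rec.population not in out:
                out.append(rec.population)
        return tuple(out)

    def for_population(self, population: str) -> "SexCountTable":
        """Sub-table for one population, sorted by temperature."""
        subset = sorted(
            (r for r in self.records if r.population == population),
            key=lambda r: r.temperature,
        )
        if not subset:
            raise KeyError(f"no records for population {population!r}")
        return SexCountTable(tuple(subset))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.population, r.temperature, r.n_female, r.n_male, r.n_unidentified)
                for r in self.records
            ],
            columns=list(COLUMNS),
        )


def _records_from_frame(frame: pd.DataFrame) -> SexCountTable:
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise MissingColumnError(f"missing required column(s): {', '.join(missing)}")
    records = []
    for row in frame.itertuples(index=False):
        counts = {}
        for name in ("n_female", "n_male", "n_unidentified"):
            raw = getattr(row, name)
            try:
                value = float(raw)
            except (TypeError, ValueError) as exc:
                raise InvalidCountError(f"{name}={raw!r} is not a number") from exc
            counts[name] = value
        records.append(
            SexCountRecord(
                population=str(row.population),
                temperature=float(row.temperature_C),
                n_female=counts["n_female"],
                n_male=counts["n_male"],
                n_unidentified=counts["n_unidentified"],
            )
        )
    return SexCountTable(tuple(records))


def read_sex_counts(path: str | Path) -> SexCountTable:
    """Read a sex-count table from a headered CSV file.

    Raises
    ------
    MissingColumnError, InvalidCountError, DuplicateTreatmentError
        For a malformed header, bad counts, or repeated treatments.
    """
    frame = pd.read_csv(path)
    if frame.empty and not set(COLUMNS) <= set(frame.columns):
        raise MissingColumnError(f"empty or headerless file: {path}")
    return _records_from_frame(frame)


def write_sex_counts(table: SexCountTable, path: str | Path) -> None:
    """Write a table in the same CSV dialect that :func:`read_sex_counts` reads."""
    table.to_frame().to_csv(path, index=False)


def load_gekko_fixture() -> SexCountTable:
    """The packaged *Gekko japonicus* incubation dataset.

    15 treatments: populations {Yancheng, Chuzhou, Wenzhou} x constant
    incubation temperatures {24, 26, 28, 30, 32} degC.
    """
    source = resources.files("tsdnorm").joinpath("data", _FIXTURE_NAME)
    with resources.as_file(source) as path:
        return read_sex_counts(path)


@dataclass(frozen=True)
class EggDimensions:
    """Length and width of one egg, in millimetres."""

    length: float
    width: float

    def __post_init__(self) -> None:
        if not (self.length > 0 and self.width > 0):
            raise ValueError("egg dimensions must be positive")
        if self.length < self.width:
            warnings.warn(
                f"egg length ({self.length}) < width ({self.width}); "
                "dimensions may be swapped",
                stacklevel=3,
            )


def egg_volume(dims: EggDimensions) -> float:
    """Ellipsoid egg volume in mm^3: V = 4/3 pi (length/2) (width/2)^2."""
    return (4.0 / 3.0) * math.pi * (dims.length / 2.0) * (dims.width / 2.0) ** 2


def apportion_clutch_mass(total_mass: float, volumes: Iterable[float]) -> list[float]:
    """Split a jointly-weighed clutch mass across eggs proportionally to volume.

    Rigid-shelled gecko eggs in a clutch usually adhere and are weighed
    together; each egg's mass is the clutch mass times its share of the
    summed egg volume.  The output conserves ``total_mass`` exactly up to
    floating-point rounding.
    """
    vols = [float(v) for v in volumes]
    if not vols:
        raise ValueError("volumes must be non-empty")
    if any(v <= 0 for v in vols):
        raise ValueError("all volumes must be positive")
    if not total_mass > 0:
        raise ValueError("total_mass must be positive")
    total_volume = sum(vols)
    return [total_mass * v / total_volume for v in vols]
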