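"""Built-in Jilin Province health-resource dataset, plan targets, and CSV I/O.

The built-in fixture holds the six annual indicator series (2015-2022) from
the Jilin Statistical Yearbook that the package's worked example analyses:
medical institutions, medical beds, health technicians, licensed (assistant)
physicians, registered nurses and pharmacists.  The 14th 5-Year-Plan targets
for 2025 and the projected 2025 permanent population ship as a small YAML
config next to the code.

User data enters through :func:`read_series_csv` (columns ``year,value``);
result tables leave through :func:`write_table_csv`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError

__all__ = [
    "AnnualSeries",
    "PlanTargets",
    "INDICATORS",
    "load_builtin_dataset",
    "load_plan_targets",
    "read_series_csv",
    "write_series_csv",
    "write_table_csv",
]

#: Canonical indicator names, in the order the yearbook tables list them.
INDICATORS = (
    "Medical institutions",
    "Medical beds",
    "Health technicians",
    "Licensed (assistant) physicians",
    "Registered nurses",
    "Pharmacists",
)

# Annual counts 2015-2022, one row per year, one column per indicator
# (same order as INDICATORS).  Physical resources are institutions and
# beds; the remaining four are headcounts of health human resources.
_YEARS = tuple(range(2015, 2023))
_VALUES = (
    (20619, 144695, 159103, 67279, 60742, 7903),
    (20828, 151155, 166527, 69613, 65736, 7931),
    (20827, 153625, 168080, 70564, 67142, 7900),
    (22648, 166743, 183327, 76910, 76140, 8139),
    (22178, 170582, 188257, 78741, 78870, 8078),
    (25626, 173143, 212140, 85123, 95392, 8717),
    (25345, 176306, 217215, 87315, 97803, 8894),
    (25031, 176993, 217979, 86661, 98639, 8731),
)


@dataclass(frozen=True)
class AnnualSeries:
    """An annual count series: the raw sequence X(0) a grey model is fit to.

    Parameters
    ----------
    name
        Indicator label, e.g. ``"Registered nurses"``.
    years
        Strictly consecutive integer years, one per observation.
    values
        Positive counts, same length as ``years``.  At least four
        observations are required: fewer leave no room for residual
        diagnostics on top of the two fitted parameters.
    """

    name: str
    years: tuple[int, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        years = tuple(int(y) for y in self.years)
        values = tuple(float(v) for v in self.values)
        if len(years) != len(values):
            raise ValidationError(
                f"{self.name!r}: {len(years)} years but {len(values)} values"
            )
        if len(values) < 4:
            raise ValidationError(
                f"{self.name!r}: need at least 4 observations, got {len(values)}"
            )
        for i, (prev, nxt) in enumerate(zip(years, years[1:])):
            if nxt != prev + 1:
                raise ValidationError(
                    f"{self.name!r}: years must be consecutive; "
                    f"gap between {prev} and {nxt} (row {i + 2})"
                )
        for i, v in enumerate(values):
            if not v > 0 or not np.isfinite(v):
                raise ValidationError(
                    f"{self.name!r}: value must be a positive finite number; "
                    f"got {v!r} for year {years[i]} (row {i + 1})"
                )
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.values)

    def to_array(self) -> np.ndarray:
        """Values as a float ndarray."""
        return np.asarray(self.values, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, "value": self.values})


@dataclass(frozen=True)
class PlanTargets:
    """2025 development targets of the 14th 5-Year Plan plus the projected
    2025 permanent population used to turn count forecasts into rates."""

    population_2025: float
    targets: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.population_2025 > 0:
            raise ValidationError("population_2025 must be positive")
        for key, val in self.targets.items():
            if not float(val) > 0:
                raise ValidationError(f"plan target {key!r} must be positive, got {val}")


def load_builtin_dataset() -> dict[str, AnnualSeries]:
    """Return the six built-in 2015-2022 indicator series keyed by name."""
    out: dict[str, AnnualSeries] = {}
    for j, name in enumerate(INDICATORS):
        out[name] = AnnualSeries(
            name=name,
            years=_YEARS,
            values=tuple(row[j] for row in _VALUES),
        )
    return out


def load_plan_targets(path: str | Path | None = None) -> PlanTargets:
    """Load plan targets from YAML; defaults to the packaged config.

    The file has two keys: ``population_2025`` (persons) and ``targets``,
    a mapping from indicator/ratio key to planned 2025 value.
    """
    if path is None:
        ref = resources.files("greycast").joinpath("data/plan_targets.yaml")
        raw = yaml.safe_load(ref.read_text(encoding="utf-8"))
    else:
        path = Path(path)
        if not path.exists():
            raise ValidationError(f"plan-targets file not found: {path}")
        raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    try:
        return PlanTargets(
            population_2025=float(raw["population_2025"]),
            targets={str(k): float(v) for k, v in raw["targets"].items()},
        )
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"malformed plan-targets config: {exc}") from exc


def read_series_csv(path: str | Path, name: str | None = None) -> AnnualSeries:
    """Parse an annual series from a ``year,value`` CSV file.

    The file must be UTF-8 with a header row; values use ``.`` as the
    decimal separator and no thousands separators.  Violations of the
    series invariants (non-positive values, year gaps, fewer than four
    rows) raise :class:`~greycast.errors.ValidationError` naming the
    offending row.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"input file not found: {path}")
    years: list[int] = []
    values: list[float] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [f.strip().lower() for f in reader.fieldnames[:2]] != ["year", "value"]:
            raise ValidationError(
                f"{path}: expected header 'year,value', got {reader.fieldnames}"
            )
        for i, row in enumerate(reader, start=2):
            try:
                years.append(int(row["year"]))
                values.append(float(row["value"]))
            except (TypeError, KeyError, ValueError) as exc:
                raise ValidationError(f"{path}: unparsable row {i}: {row}") from exc
    return AnnualSeries(name=name or path.stem, years=tuple(years), values=tuple(values))


def write_series_csv(series: AnnualSeries, path: str | Path) -> None:
    """Write a series as a ``year,value`` CSV (inverse of :func:`read_series_csv`)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["year", "value"])
        for year, value in zip(series.years, series.values):
            writer.writerow([year, _format_number(value)])


def write_table_csv(table, path: str | Path) -> None:
    """Write a result table (anything exposing ``to_frame()``) as byte-stable CSV.

    Column order and numeric formatting are fixed by the table's
    ``to_frame`` method, so repeated runs produce identical bytes.
    """
    frame = table.to_frame() if hasattr(table, "to_frame") else pd.DataFrame(table)
    path = Path(path)
    frame.to_csv(path, index=False, lineterminator="\n", float_format="%.6f")


def _format_number(value: float) -> str:
    """Integers without a decimal point, everything else via repr."""
    if float(value).is_integer():
        return str(int(value))
    return repr(float(value))
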