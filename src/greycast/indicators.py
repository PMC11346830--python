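"""Plan-gap indicators: turn 2025 forecasts into per-capita rates and
met/unmet comparisons against the 14th 5-Year-Plan targets.

Count forecasts become per-thousand-population rates via the projected
2025 permanent population; the doctor-nurse ratio is expressed in the
conventional ``1 : r`` form (nurses per physician).  Comparisons use
unrounded values throughout; 2-dp rounding (half away from zero) is a
display convention only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .dataset import PlanTargets
from .errors import ValidationError
from .gm11 import round_half_away

__all__ = [
    "PlanRow",
    "PlanComparison",
    "per_thousand",
    "doctor_nurse_ratio",
    "compare_to_plan",
]


def per_thousand(count: float, population: float) -> float:
    """Rate per 1000 population: ``1000 * count / population``."""
    if not population > 0:
        raise ValidationError(f"population must be positive, got {population}")
    return 1000.0 * count / population


def doctor_nurse_ratio(physicians: float, nurses: float) -> float:
    """Nurses per physician, the ``r`` of a doctor-nurse ratio ``1 : r``."""
    if not physicians > 0:
        raise ValidationError(f"physician count must be positive, got {physicians}")
    return nurses / physicians


@dataclass(frozen=True)
class PlanRow:
    """One plan-comparison row; ``met`` uses >= on unrounded values."""

    indicator: str
    target_2025: float
    projected_2025: float

    @property
    def met(self) -> bool:
        return self.projected_2025 >= self.target_2025


@dataclass(frozen=True)
class PlanComparison:
    """Plan-target comparison table (one row per plan indicator)."""

    rows: tuple[PlanRow, ...]
    population_2025: float

    @property
    def unmet(self) -> tuple[PlanRow, ...]:
        return tuple(row for row in self.rows if not row.met)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "indicator": [r.indicator for r in self.rows],
                "target_2025": [_display(r.target_2025) for r in self.rows],
                "projected_2025": [_display(r.projected_2025) for r in self.rows],
                "met": [("yes" if r.met else "no") for r in self.rows],
            }
        )


def _display(value: float) -> str:
    """Counts as integers, rates/ratios at 2 dp (half away from zero)."""
    if value >= 1000:
        return str(int(round_half_away(value)))
    return f"{round_half_away(value * 100) / 100:.2f}"


# (row label, target key, builder) in plan-table order.  Builders map the
# six 2025 count forecasts + population to the row's projected value.
_PLAN_ROWS = (
    (
        "Number of medical beds per thousand population",
        "beds_per_thousand",
        lambda f, pop: per_thousand(f["Medical beds"], pop),
    ),
    (
        "Total number of licensed (assistant) physicians",
        "physicians_total",
        lambda f, pop: f["Licensed (assistant) physicians"],
    ),
    (
        "Number of licensed (assistant) physicians per thousand population",
        "physicians_per_thousand",
        lambda f, pop: per_thousand(f["Licensed (assistant) physicians"], pop),
    ),
    (
        "Total number of registered nurses",
        "nurses_total",
        lambda f, pop: f["Registered nurses"],
    ),
    (
        "Number of registered nurses per thousand population",
        "nurses_per_thousand",
        lambda f, pop: per_thousand(f["Registered nurses"], pop),
    ),
    (
        "Doctor-nurse ratio",
        "doctor_nurse_ratio",
        lambda f, pop: doctor_nurse_ratio(
            f["Licensed (assistant) physicians"], f["Registered nurses"]
        ),
    ),
    (
        "Total number of pharmacists",
        "pharmacists_total",
        lambda f, pop: f["Pharmacists"],
    ),
    (
        "Number of pharmacists per thousand population",
        "pharmacists_per_thousand",
        lambda f, pop: per_thousand(f["Pharmacists"], pop),
    ),
)


def compare_to_plan(forecasts: Mapping[str, float], targets: PlanTargets) -> PlanComparison:
    """Compare 2025 forecasts (keyed by canonical indicator name) to the plan.

    ``forecasts`` must contain every indicator a plan row needs; a missing
    indicator or target raises :class:`~greycast.errors.ValidationError`.
    """
    rows = []
    for label, key, build in _PLAN_ROWS:
        if key not in targets.targets:
            raise ValidationError(f"plan target {key!r} missing from targets config")
        try:
            projected = build(forecasts, targets.population_2025)
        except KeyError as exc:
            raise ValidationError(
                f"forecast for indicator {exc.args[0]!r} required by plan row {label!r}"
            ) from exc
        rows.append(PlanRow(indicator=label, target_2025=float(targets.targets[key]), projected_2025=float(projected)))
    return PlanComparison(rows=tuple(rows), population_2025=targets.population_2025)
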