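"""Model-adequacy diagnostics for GM(1,1) fits.

Two classical grey-theory statistics grade a fitted model:

* the posterior error ratio ``C`` — the variance of the residuals divided
  by the variance of the actual series (smaller is better; a model that
  explains the series leaves residual variance far below the raw
  variance), and
* the small-error probability ``P`` — the fraction of residuals lying
  within ``0.6745 * S1`` of the mean residual, where ``S1`` is the
  standard deviation of the actual series (0.6745 is the quartile point
  of the normal distribution, so an adequate model should put nearly all
  residuals inside that band).

Both statistics use population (divide-by-n) variance and include every
fitted point, including the anchor year whose residual is zero by
construction.  ``(P, C)`` map to a four-level accuracy grade; the overall
grade is the worse of the two component levels.

Two applicability flags accompany the grade: ``a`` in (-2, 2) is required
for the exponential form to be meaningful at all, and ``-a <= 0.3`` is the
conventional bound under which GM(1,1) is considered suitable for
medium-term extrapolation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import AnnualSeries
from .errors import DegenerateModelError, ValidationError
from .gm11 import GM11Params, fit, predict

__all__ = [
    "Grade",
    "ApplicabilityFlags",
    "FitReport",
    "relative_errors",
    "posterior_error_ratio",
    "small_error_probability",
    "grade",
    "applicability",
    "diagnose",
]

#: Quartile point of the standard normal: half the probability mass lies
#: within 0.6745 standard deviations of the mean.
SMALL_ERROR_COEF = 0.6745


class Grade(enum.IntEnum):
    """Four-level prediction-accuracy grade; lower is better."""

    EXCELLENT = 1
    QUALIFIED = 2
    BARELY_QUALIFIED = 3
    UNQUALIFIED = 4

    @property
    def label(self) -> str:
        return _GRADE_LABELS[self]


_GRADE_LABELS = {
    Grade.EXCELLENT: "Level 1 (Excellent)",
    Grade.QUALIFIED: "Level 2 (Qualified)",
    Grade.BARELY_QUALIFIED: "Level 3 (Barely qualified)",
    Grade.UNQUALIFIED: "Level 4 (Unqualified)",
}

# Grade thresholds: P passes level i if P >= _P_CUTS[i]; C passes level i
# if C <= _C_CUTS[i].  Boundary inclusivity follows the standard table
# (P >= 0.95 and C <= 0.35 are both Level 1).
_P_CUTS = {Grade.EXCELLENT: 0.95, Grade.QUALIFIED: 0.80, Grade.BARELY_QUALIFIED: 0.70}
_C_CUTS = {Grade.EXCELLENT: 0.35, Grade.QUALIFIED: 0.50, Grade.BARELY_QUALIFIED: 0.65}


def _aligned(actual, fitted) -> tuple[np.ndarray, np.ndarray]:
    actual = np.asarray(actual, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    if actual.shape != fitted.shape:
        raise ValidationError(
            f"actual and fitted lengths differ: {actual.shape} vs {fitted.shape}"
        )
    if actual.size < 2:
        raise ValidationError("need at least 2 points for diagnostics")
    return actual, fitted


def relative_errors(actual, fitted) -> np.ndarray:
    """Percent relative error ``100 * |actual - fitted| / actual`` per point."""
    actual = np.asarray(actual, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    if actual.shape != fitted.shape:
        raise ValidationError(
            f"actual and fitted lengths differ: {actual.shape} vs {fitted.shape}"
        )
    return 100.0 * np.abs(actual - fitted) / actual


def posterior_error_ratio(actual, fitted) -> float:
    """Posterior error ratio ``C = Var(residuals) / Var(actuals)``.

    Population variance on both sides (the divisor cancels).  Zero iff
    the residuals are constant; a constant actual series has zero
    variance and is rejected as degenerate.
    """
    actual, fitted = _aligned(actual, fitted)
    var_actual = np.var(actual)
    if var_actual == 0.0:
        raise DegenerateModelError("constant actual series: S1 = 0, C undefined")
    residuals = actual - fitted
    return float(np.var(residuals) / var_actual)


def small_error_probability(actual, fitted) -> float:
    """Fraction of residuals within ``0.6745 * S1`` of the mean residual."""
    actual, fitted = _aligned(actual, fitted)
    s1 = np.std(actual)
    if s1 == 0.0:
        raise DegenerateModelError("constant actual series: S1 = 0, P undefined")
    residuals = actual - fitted
    inside = np.abs(residuals - residuals.mean()) < SMALL_ERROR_COEF * s1
    return float(inside.mean())


def _level_from_p(p: float) -> Grade:
    for level in (Grade.EXCELLENT, Grade.QUALIFIED, Grade.BARELY_QUALIFIED):
        if p >= _P_CUTS[level]:
            return level
    return Grade.UNQUALIFIED


def _level_from_c(c: float) -> Grade:
    for level in (Grade.EXCELLENT, Grade.QUALIFIED, Grade.BARELY_QUALIFIED):
        if c <= _C_CUTS[level]:
            return level
    return Grade.UNQUALIFIED


def grade(c: float, p: float) -> Grade:
    """Overall accuracy grade: the worse of the P-level and the C-level."""
    if c < 0:
        raise ValidationError(f"C must be >= 0, got {c}")
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"P must be in [0, 1], got {p}")
    return max(_level_from_p(p), _level_from_c(c))


@dataclass(frozen=True)
class ApplicabilityFlags:
    """Development-coefficient range checks.

    ``meaningful``: a in (-2, 2), outside which the discretised model has
    no sensible continuous counterpart.  ``applicable``: a >= -0.3, the
    conventional bound for trustworthy medium-term extrapolation.  Both
    are advisory — reported, never enforced.
    """

    meaningful: bool
    applicable: bool


def applicability(a: float) -> ApplicabilityFlags:
    """Range checks on the development coefficient ``a``."""
    if not np.isfinite(a):
        raise ValidationError(f"development coefficient must be finite, got {a}")
    return ApplicabilityFlags(meaningful=(-2.0 < a < 2.0), applicable=(a >= -0.3))


@dataclass(frozen=True)
class FitReport:
    """Full adequacy report for one fitted series."""

    indicator: str
    params: GM11Params
    residuals: np.ndarray
    relative_errors_pct: np.ndarray
    c: float
    p: float
    grade: Grade
    flags: ApplicabilityFlags
    max_relative_error_threshold_pct: float = 10.0

    @property
    def max_relative_error_pct(self) -> float:
        return float(np.max(self.relative_errors_pct))

    @property
    def relative_errors_acceptable(self) -> bool:
        """Advisory flag: worst in-sample relative error under the threshold."""
        return self.max_relative_error_pct <= self.max_relative_error_threshold_pct

    def to_frame(self) -> pd.DataFrame:
        """One table row: indicator, a, b, C, P, level (4/4/4/3 dp display)."""
        return pd.DataFrame(
            {
                "indicator": [self.indicator],
                "a": [f"{self.params.a:.4f}"],
                "b": [f"{self.params.b:.4f}"],
                "C": [f"{self.c:.4f}"],
                "P": [f"{self.p:.3f}"],
                "level": [int(self.grade)],
            }
        )


def diagnose(
    series: AnnualSeries,
    params: GM11Params | None = None,
    max_relative_error_threshold_pct: float = 10.0,
) -> FitReport:
    """Fit (unless ``params`` is given) and compute the full adequacy report."""
    if params is None:
        params = fit(series)
    actual = series.to_array()
    fitted = predict(params, horizon=0)
    c = posterior_error_ratio(actual, fitted)
    p = small_error_probability(actual, fitted)
    return FitReport(
        indicator=series.name,
        params=params,
        residuals=actual - fitted,
        relative_errors_pct=relative_errors(actual, fitted),
        c=c,
        p=p,
        grade=grade(c, p),
        flags=applicability(params.a),
        max_relative_error_threshold_pct=max_relative_error_threshold_pct,
    )
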