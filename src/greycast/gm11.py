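"""The GM(1,1) grey forecasting model.

GM(1,1) — grey model, first order, one variable — forecasts a short,
strictly positive series ``x0 = [x0(1), ..., x0(n)]`` by smoothing it with
a cumulative sum (the accumulated generating operation, AGO), fitting the
grey difference equation

    x0(k) + a * z1(k) = b,    k = 2..n,

by ordinary least squares, where ``z1`` is the equal-weight mean of
consecutive accumulated values, and then evaluating the whitening
equation's time response

    xhat1(k+1) = (x0(1) - b/a) * exp(-a*k) + b/a

whose first differences (inverse AGO) restore fitted and forecast values
on the original scale.  The parameter ``a`` is the development coefficient
(negative for a growing series); ``b`` is the grey input.

The model is designed for very short series (n of 5-12): with only two
parameters it extracts the dominant exponential trend and nothing else.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import AnnualSeries
from .errors import DegenerateModelError, ValidationError

__all__ = [
    "GM11Params",
    "SequenceTriple",
    "ForecastTable",
    "ago",
    "iago",
    "mean_sequence",
    "sequences",
    "fit",
    "time_response",
    "predict",
    "forecast_table",
    "round_half_away",
]

#: Development coefficients smaller than this (in absolute value) are treated
#: as a flat series: the restored value b/a is then numerically meaningless.
_FLAT_TOL = 1e-12


def ago(x0) -> np.ndarray:
    """Accumulated generating operation: the running sum of ``x0``.

    For positive input the result is strictly increasing, which is what
    makes the accumulated series amenable to an exponential fit.
    """
    x0 = np.asarray(x0, dtype=float)
    if x0.size == 0:
        raise ValidationError("ago: input sequence is empty")
    return np.cumsum(x0)


def iago(x1) -> np.ndarray:
    """Inverse AGO: first differences, keeping the first element.

    ``iago(ago(x))`` recovers ``x`` for any finite input (exactly in exact
    arithmetic; to within a unit of floating-point rounding per element
    otherwise).
    """
    x1 = np.asarray(x1, dtype=float)
    if x1.size == 0:
        raise ValidationError("iago: input sequence is empty")
    return np.concatenate([x1[:1], np.diff(x1)])


def mean_sequence(x1_ago) -> np.ndarray:
    """Equal-weight mean of consecutive accumulated values.

    ``z1(k) = 0.5 * (x1(k-1) + x1(k))`` for k = 2..n; length n-1.  This is
    the regressor of the grey difference equation.
    """
    x1_ago = np.asarray(x1_ago, dtype=float)
    if x1_ago.size < 2:
        raise ValidationError("mean_sequence: need at least 2 accumulated values")
    return 0.5 * (x1_ago[:-1] + x1_ago[1:])


@dataclass(frozen=True)
class SequenceTriple:
    """Original series, its accumulation X(1), and the mean sequence Z(1)."""

    x0: np.ndarray
    x1_ago: np.ndarray
    z1: np.ndarray


def sequences(x0) -> SequenceTriple:
    """Compute the AGO and mean sequences used in fitting."""
    x0 = np.asarray(x0, dtype=float)
    x1 = ago(x0)
    return SequenceTriple(x0=x0, x1_ago=x1, z1=mean_sequence(x1))


@dataclass(frozen=True)
class GM11Params:
    """Fitted GM(1,1) state.

    Attributes
    ----------
    a
        Development coefficient (dimensionless exponential rate; negative
        for a growing series).  Never zero: flat series are rejected.
    b
        Grey input, in the units of the series.
    x1
        First observation x0(1), the anchor of the time response.
    n
        Number of observations the model was fitted to.
    """

    a: float
    b: float
    x1: float
    n: int

    def __post_init__(self) -> None:
        if abs(self.a) < _FLAT_TOL:
            raise DegenerateModelError(
                "development coefficient a is (numerically) zero: the series is "
                "flat and the GM(1,1) restored value b/a is undefined"
            )
        if self.n < 4:
            raise ValidationError(f"need n >= 4 fitted observations, got {self.n}")


def fit(series: AnnualSeries | np.ndarray) -> GM11Params:
    """Estimate (a, b) by least squares on the grey difference equation.

    Builds ``B`` with rows ``(-z1(k), 1)`` and ``Y = [x0(2), ..., x0(n)]``
    and solves the 2x2 normal equations ``(B'B) theta = B'Y`` in closed
    form.  The closed form is exact for this two-parameter problem and is
    cross-checked against an orthogonal-factorisation solver in the test
    suite; if the normal equations are singular, or the estimated ``a`` is
    numerically zero (flat series), a
    :class:`~greycast.errors.DegenerateModelError` is raised.
    """
    x0 = series.to_array() if isinstance(series, AnnualSeries) else np.asarray(series, dtype=float)
    if x0.size < 4:
        raise ValidationError(f"need at least 4 observations to fit, got {x0.size}")
    if np.any(x0 <= 0) or not np.all(np.isfinite(x0)):
        raise ValidationError("all values must be positive and finite")

    seq = sequences(x0)
    z, y = seq.z1, x0[1:]
    m = z.size
    s_z, s_zz = z.sum(), (z * z).sum()
    s_y, s_zy = y.sum(), (z * y).sum()
    det = m * s_zz - s_z * s_z
    # det is (m * variance of z) scaled; zero only if all z1 coincide.
    if abs(det) <= 1e-14 * max(m * s_zz, s_z * s_z, 1.0):
        raise DegenerateModelError("singular normal equations: mean sequence is constant")
    a = (s_z * s_y - m * s_zy) / det
    b = (s_zz * s_y - s_z * s_zy) / det
    return GM11Params(a=a, b=b, x1=float(x0[0]), n=int(x0.size))


def time_response(params: GM11Params, k) -> np.ndarray | float:
    """Accumulated prediction ``xhat1(k+1)`` of the whitening equation.

    ``k`` may be a scalar or array of non-negative integers; ``k = 0``
    returns ``x0(1)`` exactly.
    """
    k_arr = np.asarray(k, dtype=float)
    drift = params.b / params.a
    out = (params.x1 - drift) * np.exp(-params.a * k_arr) + drift
    return out if k_arr.ndim else float(out)


def predict(params: GM11Params, horizon: int = 0) -> np.ndarray:
    """Fitted values for the training window plus ``horizon`` forecasts.

    Returns ``n + horizon`` values on the original scale, obtained by
    first-differencing the time response (inverse AGO).  The first value
    equals ``x0(1)`` exactly — the model reproduces its anchor point with
    zero residual by construction.
    """
    if horizon < 0:
        raise ValidationError(f"horizon must be >= 0, got {horizon}")
    k = np.arange(params.n + horizon)
    xhat1 = time_response(params, k)
    return iago(xhat1)


@dataclass(frozen=True)
class ForecastTable:
    """Actual, fitted and forecast values for one indicator.

    ``years`` covers the training window plus the forecast horizon;
    ``actual`` and ``relative_error_pct`` carry NaN on forecast years.
    Display rounding (counts to nearest integer, errors to 3 dp) happens
    only in ``to_frame``; the stored arrays keep full precision.
    """

    indicator: str
    years: tuple[int, ...]
    actual: np.ndarray
    predicted: np.ndarray
    relative_error_pct: np.ndarray
    params: GM11Params

    @property
    def horizon(self) -> int:
        return len(self.years) - self.params.n

    def forecast(self, year: int) -> float:
        """Unrounded predicted value for ``year``."""
        try:
            return float(self.predicted[self.years.index(year)])
        except ValueError as exc:
            raise ValidationError(f"year {year} outside table range {self.years[0]}-{self.years[-1]}") from exc

    def to_frame(self) -> pd.DataFrame:
        actual = [("" if np.isnan(v) else int(v)) for v in self.actual]
        pred = [int(round_half_away(v)) for v in self.predicted]
        err = [("" if np.isnan(v) else f"{v:.3f}") for v in self.relative_error_pct]
        return pd.DataFrame(
            {
                "year": self.years,
                "actual": actual,
                "predicted": pred,
                "relative_error_pct": err,
            }
        )


def forecast_table(series: AnnualSeries, horizon: int = 3, params: GM11Params | None = None) -> ForecastTable:
    """Fit (unless ``params`` is given) and tabulate fitted + forecast values."""
    from .diagnostics import relative_errors  # local import: avoid cycle

    if params is None:
        params = fit(series)
    x0 = series.to_array()
    pred = predict(params, horizon=horizon)
    years = tuple(range(series.years[0], series.years[0] + len(pred)))
    actual = np.full(len(pred), np.nan)
    actual[: len(x0)] = x0
    rel = np.full(len(pred), np.nan)
    rel[: len(x0)] = relative_errors(x0, pred[: len(x0)])
    return ForecastTable(
        indicator=series.name,
        years=years,
        actual=actual,
        predicted=pred,
        relative_error_pct=rel,
        params=params,
    )


def round_half_away(x):
    """Round half away from zero (2.5 -> 3, -2.5 -> -3), elementwise.

    Used for display of count forecasts; ``numpy.round`` rounds half to
    even, which disagrees on exact .5 boundaries.
    """
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.floor(np.abs(x) + 0.5)
    return float(out) if out.ndim == 0 else out
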