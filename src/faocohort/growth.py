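"""Fetal growth-chart evaluation, inversion, and estimated fetal weight.

A growth chart is a monotone table of gestational age (days since last
menstrual period, LMP) against the median value of one fetal biometry
measurement — biparietal diameter (BPD), abdominal circumference (AC) or
femur length (FL), all in mm.  Forward evaluation interpolates the median
at an arbitrary gestational age with a shape-preserving monotone cubic
(PCHIP), exact at the knots.  Inversion converts a measured length back to
the "ultrasound gestational age" (GA-BPD, GA-AC, GA-FL) by bisection on
the monotone forward curve, to a tolerance of 1e-3 day — far below
clinical resolution.

Charts are pluggable CSV tables (``ga_days,median_mm``).  The module ships
*synthetic* default curves (smooth monotone polynomials with realistic
magnitudes) so the pipeline and its tests never depend on any published
chart's coefficients; real charts drop in via :func:`load_growth_chart`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

__all__ = [
    "MeasurementKind",
    "GrowthChartTable",
    "BiometrySnapshot",
    "EfwResult",
    "ChartError",
    "UnconvertibleMeasurement",
    "load_growth_chart",
    "default_chart",
    "expected_biometry",
    "estimate_ga",
    "estimate_fetal_weight",
]

DAYS_PER_WEEK = 7.0


class MeasurementKind(str, Enum):
    BPD = "bpd"
    AC = "ac"
    FL = "fl"


class ChartError(ValueError):
    """Raised for malformed growth-chart tables."""


class UnconvertibleMeasurement(ValueError):
    """Measurement outside the chart's value range; the record should be
    flagged, not silently dropped."""


@dataclass(frozen=True)
class GrowthChartTable:
    """Monotone GA -> median-biometry reference for one measurement kind."""

    measurement_kind: MeasurementKind
    ga_days: np.ndarray        # strictly increasing knots, days since LMP
    median_mm: np.ndarray      # strictly increasing medians, mm
    _interp: PchipInterpolator = field(repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        ga = np.asarray(self.ga_days, dtype=float)
        mm = np.asarray(self.median_mm, dtype=float)
        if ga.ndim != 1 or ga.size < 2 or ga.size != mm.size:
            raise ChartError("chart needs at least two (ga_days, median_mm) rows")
        if np.any(np.diff(ga) <= 0):
            raise ChartError("ga_days must be strictly increasing (no duplicates)")
        if np.any(np.diff(mm) <= 0):
            raise ChartError("median_mm must be strictly increasing")
        object.__setattr__(self, "ga_days", ga)
        object.__setattr__(self, "median_mm", mm)
        object.__setattr__(self, "_interp", PchipInterpolator(ga, mm))

    @property
    def valid_range(self) -> tuple[float, float]:
        return float(self.ga_days[0]), float(self.ga_days[-1])

    @property
    def value_range(self) -> tuple[float, float]:
        return float(self.median_mm[0]), float(self.median_mm[-1])

    def value(self, ga_days):
        """Median biometry (mm) at ``ga_days``; exact at knots."""
        ga = np.asarray(ga_days, dtype=float)
        lo, hi = self.valid_range
        if np.any(ga < lo) or np.any(ga > hi):
            raise ChartError(
                f"ga_days outside chart valid range [{lo:g}, {hi:g}] days"
            )
        out = self._interp(ga)
        return float(out) if np.isscalar(ga_days) else out

    def invert(self, measurement_mm, tol_days: float = 1e-3):
        """Gestational age (days) whose median equals ``measurement_mm``.

        Bisection on the monotone forward curve.  Raises
        :class:`UnconvertibleMeasurement` for values outside the chart's
        value range.
        """
        mm = np.asarray(measurement_mm, dtype=float)
        vlo, vhi = self.value_range
        if np.any(mm < vlo) or np.any(mm > vhi):
            raise UnconvertibleMeasurement(
                f"measurement outside chart value range [{vlo:g}, {vhi:g}] mm"
            )
        lo = np.full(mm.shape, self.ga_days[0], dtype=float)
        hi = np.full(mm.shape, self.ga_days[-1], dtype=float)
        # log2(span/tol) iterations; span <= ~300 days
        n_iter = int(np.ceil(np.log2((hi.flat[0] - lo.flat[0]) / tol_days))) + 1
        for _ in range(n_iter):
            mid = 0.5 * (lo + hi)
            below = self._interp(mid) < mm
            lo = np.where(below, mid, lo)
            hi = np.where(below, hi, mid)
        out = 0.5 * (lo + hi)
        return float(out) if np.isscalar(measurement_mm) else out


@dataclass(frozen=True)
class BiometrySnapshot:
    """One ultrasound visit: mean-of-three BPD/AC/FL plus the LMP-based GA."""

    ga_lmp_days: float
    bpd_mm: float
    ac_mm: float
    fl_mm: float
    scan_context: str = "mid_gestation"   # or "near_term"

    def __post_init__(self) -> None:
        for name in ("bpd_mm", "ac_mm", "fl_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class EfwResult:
    efw_g: float


def load_growth_chart(path: str | Path, measurement_kind: MeasurementKind | str) -> GrowthChartTable:
    """Read a two-column CSV (``ga_days,median_mm``, header required) and
    validate monotonicity."""
    df = pd.read_csv(path)
    missing = {"ga_days", "median_mm"} - set(df.columns)
    if missing:
        raise ChartError(f"growth chart CSV missing columns: {sorted(missing)}")
    if df["ga_days"].duplicated().any():
        raise ChartError("duplicate ga_days rows in growth chart")
    df = df.sort_values("ga_days")
    return GrowthChartTable(
        MeasurementKind(measurement_kind),
        df["ga_days"].to_numpy(float),
        df["median_mm"].to_numpy(float),
    )


# Synthetic default median curves (mm as a function of gestational weeks).
# Smooth, strictly increasing over 14-43 wk, with magnitudes typical of
# second/third-trimester biometry; NOT any published chart.
_DEFAULT_CURVES = {
    MeasurementKind.BPD: lambda w: -0.0406 * w**2 + 4.72 * w - 30.8,
    MeasurementKind.AC: lambda w: 0.02 * w**2 + 9.6 * w - 57.3,
    MeasurementKind.FL: lambda w: -0.0316 * w**2 + 4.07 * w - 36.6,
}


def default_chart(measurement_kind: MeasurementKind | str,
                  week_min: int = 14, week_max: int = 43) -> GrowthChartTable:
    """Synthetic weekly-knot default chart for one measurement kind."""
    kind = MeasurementKind(measurement_kind)
    weeks = np.arange(week_min, week_max + 1, dtype=float)
    mm = _DEFAULT_CURVES[kind](weeks)
    return GrowthChartTable(kind, weeks * DAYS_PER_WEEK, mm)


def expected_biometry(chart: GrowthChartTable, ga_days) -> float:
    """Forward evaluation: interpolated median (mm) at ``ga_days``."""
    return chart.value(ga_days)


def estimate_ga(chart: GrowthChartTable, measurement_mm, tol_days: float = 1e-3):
    """Invert the chart: the unique GA (days) whose median equals the
    measurement, by bisection."""
    return chart.invert(measurement_mm, tol_days=tol_days)


def estimate_fetal_weight(bpd_cm: float, ac_cm: float, fl_cm: float,
                          coef_bpd3: float = 1.07,
                          coef_ac2fl: float = 0.30) -> EfwResult:
    """Estimated fetal weight (g) from BPD, AC, FL in cm.

    Default coefficients follow the standard Japanese ultrasound
    (Shinozuka-type) polynomial EFW = 1.07*BPD^3 + 0.30*AC^2*FL; both
    coefficients are configurable.
    """
    if bpd_cm < 0 or ac_cm < 0 or fl_cm < 0:
        raise ValueError("biometry inputs must be non-negative")
    return EfwResult(coef_bpd3 * bpd_cm**3 + coef_ac2fl * ac_cm**2 * fl_cm)
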