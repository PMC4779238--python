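"""qPCR assay qualification from dilution-series calibration curves.

A calibration curve is an ordinary least-squares fit of quantification
cycle (Cq) against log10 of template input (ng). The derived performance
parameters are:

- amplification efficiency  E = (10^(−1/slope) − 1)·100  [percent];
  a slope of −1/log10(2) ≈ −3.32 corresponds to 100% (perfect doubling),
- the coefficient of determination R² of the fit,
- the theoretical 1 ng detection: the expected Cq at 1 ng input, which is
  exactly the fitted intercept (log10(1) = 0).

Default qualification thresholds (efficiency 90–110%, R² >= 0.99) reflect
common MIQE-style practice and are explicit, overridable configuration —
they are a package default, not a published constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CalibrationPoint",
    "CalibrationFit",
    "QualificationCriteria",
    "DEFAULT_CRITERIA",
    "FOURFOLD_DILUTION_NG",
    "fit_calibration",
    "efficiency_from_slope",
    "slope_from_efficiency",
    "theoretical_1ng",
    "qualify_assay",
    "simulate_dilution_series",
    "evaluate_assay_table",
]

# Standard four-point, fourfold dilution series (ng per reaction).
FOURFOLD_DILUTION_NG: tuple[float, ...] = (10.0, 2.5, 0.625, 0.156)


@dataclass(frozen=True)
class CalibrationPoint:
    input_amount: float  # ng per reaction
    cq: float

    def __post_init__(self) -> None:
        if self.input_amount <= 0:
            raise ValueError("input amount must be positive (ng)")


@dataclass(frozen=True)
class CalibrationFit:
    """OLS calibration fit of Cq on log10(input ng), with derived parameters."""

    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency_percent(self) -> float:
        return efficiency_from_slope(self.slope)

    @property
    def theoretical_1ng_ct(self) -> float:
        return self.intercept


@dataclass(frozen=True)
class QualificationCriteria:
    efficiency_range: tuple[float, float] = (90.0, 110.0)
    min_r_squared: float = 0.99
    max_theoretical_1ng_ct: Optional[float] = None

    def __post_init__(self) -> None:
        lo, hi = self.efficiency_range
        if lo >= hi:
            raise ValueError("efficiency range must have lo < hi")


DEFAULT_CRITERIA = QualificationCriteria()


def fit_calibration(points: Sequence[CalibrationPoint]) -> CalibrationFit:
    """Least-squares calibration fit of Cq against log10(input ng)."""
    if len(points) < 2:
        raise ValueError("calibration needs at least 2 points")
    x = np.log10([p.input_amount for p in points])
    y = np.array([p.cq for p in points])
    if np.allclose(x, x[0]):
        raise ValueError("calibration needs at least 2 distinct input amounts")
    result = stats.linregress(x, y)
    return CalibrationFit(
        slope=float(result.slope),
        intercept=float(result.intercept),
        r_squared=float(result.rvalue) ** 2,
    )


def efficiency_from_slope(slope: float) -> float:
    """Amplification efficiency in percent: E = (10^(−1/slope) − 1)·100."""
    if slope >= 0:
        raise ValueError(
            f"slope must be negative for an amplifying assay, got {slope}"
        )
    return (10.0 ** (-1.0 / slope) - 1.0) * 100.0


def slope_from_efficiency(efficiency_percent: float) -> float:
    """Inverse of :func:`efficiency_from_slope` on the valid domain."""
    if efficiency_percent <= 0:
        raise ValueError("efficiency must be positive")
    return -1.0 / math.log10(1.0 + efficiency_percent / 100.0)


def theoretical_1ng(fit: CalibrationFit) -> float:
    """Expected Cq at 1 ng input: the calibration line's intercept."""
    return fit.intercept


def qualify_assay(
    fit: CalibrationFit,
    criteria: QualificationCriteria = DEFAULT_CRITERIA,
) -> tuple[bool, list[str]]:
    """Check a fit against qualification criteria; returns (pass, reasons)."""
    reasons: list[str] = []
    lo, hi = criteria.efficiency_range
    if not lo <= fit.efficiency_percent <= hi:
        reasons.append("efficiency")
    if fit.r_squared < criteria.min_r_squared:
        reasons.append("r_squared")
    if (criteria.max_theoretical_1ng_ct is not None
            and fit.theoretical_1ng_ct > criteria.max_theoretical_1ng_ct):
        reasons.append("theoretical_1ng_ct")
    return (not reasons, reasons)


def simulate_dilution_series(
    efficiency_percent: float,
    ct_1ng: float,
    amounts: Sequence[float] = FOURFOLD_DILUTION_NG,
    cq_noise_sd: float = 0.0,
    seed: int = 0,
) -> list[CalibrationPoint]:
    """Simulate Cq values for a dilution series of a given true efficiency.

    Cq = ct_1ng − log10(amount)/log10(1 + E/100) + N(0, cq_noise_sd);
    deterministic for a given seed.
    """
    if efficiency_percent <= 0:
        raise ValueError("efficiency must be positive")
    if any(a <= 0 for a in amounts):
        raise ValueError("amounts must be positive")
    rng = np.random.default_rng(seed)
    denom = math.log10(1.0 + efficiency_percent / 100.0)
    points = []
    for amount in amounts:
        cq = ct_1ng - math.log10(amount) / denom
        if cq_noise_sd > 0:
            cq += rng.normal(0.0, cq_noise_sd)
        points.append(CalibrationPoint(amount, float(cq)))
    return points


def evaluate_assay_table(
    table: pd.DataFrame,
    criteria: QualificationCriteria = DEFAULT_CRITERIA,
) -> pd.DataFrame:
    """Fit and qualify every assay in a long table.

    ``table`` needs columns assay_id, input_ng, cq (one row per calibration
    point). Returns one row per assay with slope, intercept, r_squared,
    efficiency_percent, theoretical_1ng_ct, qualified, and reasons.
    """
    required = {"assay_id", "input_ng", "cq"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"assay table missing columns {sorted(missing)}")
    rows = []
    for assay_id, group in table.groupby("assay_id", sort=True):
        points = [
            CalibrationPoint(float(r.input_ng), float(r.cq))
            for r in group.itertuples()
        ]
        try:
            fit = fit_calibration(points)
            passed, reasons = qualify_assay(fit, criteria)
            rows.append({
                "assay_id": assay_id,
                "n_points": len(points),
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r_squared": fit.r_squared,
                "efficiency_percent": fit.efficiency_percent,
                "theoretical_1ng_ct": fit.theoretical_1ng_ct,
                "qualified": passed,
                "reasons": ";".join(reasons),
            })
        except ValueError as exc:
            rows.append({
                "assay_id": assay_id, "n_points": len(points),
                "slope": float("nan"), "intercept": float("nan"),
                "r_squared": float("nan"),
                "efficiency_percent": float("nan"),
                "theoretical_1ng_ct": float("nan"),
                "qualified": False, "reasons": f"fit_error:{exc}",
            })
    return pd.DataFrame(rows)
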