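"""Transformations between gradient retention, chromatographic
hydrophobicity indices and plasma-protein-binding scales.

Fast-gradient biomimetic chromatography reports affinity on calibrated
index scales: a linear calibration maps gradient retention time to the
index scale (CHI or log k) using a set of reference standards run on
the same system.  Albumin binding is reported both as a log affinity
(LogK_HSA) and as percent bound (%HSA); the two are linked by the
logistic form

    LogK_HSA = log10( %HSA / (101 - %HSA) )

a reverse-engineered relation: the 101 denominator is the only
affine-log form consistent with the packaged index table at its printed
2-decimal precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "fit_calibration",
    "index_from_retention",
    "logk_from_percent_hsa",
    "percent_hsa_from_logk",
    "round_half_up",
]


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round with ties away from zero, matching printed-table precision."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CalibrationCurve:
    """Least-squares line mapping gradient retention time to an index scale."""

    standard_names: list[str]
    retention_times: np.ndarray
    reference_values: np.ndarray
    slope: float
    intercept: float
    r2_fit: float


def fit_calibration(
    times, refs, standard_names: list[str] | None = None
) -> CalibrationCurve:
    """Fit the calibration line index = slope * t_r + intercept.

    Parameters
    ----------
    times : array-like
        Gradient retention times of the reference standards, minutes.
    refs : array-like
        Their reference index values (CHI or log k scale).
    standard_names : list of str, optional
        Names of the standards, bookkeeping only.
    """
    t = np.asarray(times, dtype=float)
    r = np.asarray(refs, dtype=float)
    if t.shape != r.shape:
        raise ValueError(f"length mismatch: {t.size} times vs {r.size} reference values")
    if t.size < 2:
        raise ValueError("calibration needs at least 2 standards")
    if np.ptp(t) == 0:
        raise ValueError("degenerate calibration: all retention times identical")
    if np.ptp(r) == 0:
        # flat reference line: scipy's r-value is 0/0 here, define fit as exact
        slope, intercept, r2 = 0.0, float(r[0]), 1.0
    else:
        res = stats.linregress(t, r)
        slope, intercept, r2 = float(res.slope), float(res.intercept), float(res.rvalue**2)
    return CalibrationCurve(
        standard_names=list(standard_names) if standard_names else [],
        retention_times=t,
        reference_values=r,
        slope=slope,
        intercept=intercept,
        r2_fit=r2,
    )


def index_from_retention(t_r, curve: CalibrationCurve):
    """Convert retention time(s) to the calibrated index scale."""
    if curve is None or not np.isfinite(curve.slope):
        raise ValueError("calibration curve is not fitted")
    t = np.asarray(t_r, dtype=float)
    out = curve.slope * t + curve.intercept
    return float(out) if np.isscalar(t_r) else out


def logk_from_percent_hsa(pct):
    """Percent albumin binding -> log affinity, log10(pct / (101 - pct)).

    Valid for 0 < pct < 101; vectorised.
    """
    p = np.asarray(pct, dtype=float)
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p >= 101):
        raise ValueError("percent bound must lie strictly between 0 and 101")
    out = np.log10(p / (101.0 - p))
    return float(out) if np.isscalar(pct) else out


def percent_hsa_from_logk(logk):
    """Log affinity -> percent albumin binding, 101*10^k / (1 + 10^k).

    Strictly increasing, bounded in (0, 101); exact inverse of
    :func:`logk_from_percent_hsa`.
    """
    k = np.asarray(logk, dtype=float)
    if np.any(~np.isfinite(k)):
        raise ValueError("logk must be finite")
    tenk = np.power(10.0, k)
    out = 101.0 * tenk / (1.0 + tenk)
    return float(out) if np.isscalar(logk) else out
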