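"""Optical-to-destructive calibration statistics.

Links the non-destructive optical readouts (per-channel average
fluorescence lifetimes) to destructive reference values (biochemical
content, mechanical moduli) through simple linear least-squares
calibrations, and validates predicted against measured values with Lin's
concordance correlation coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LinkedSample",
    "CalibrationModel",
    "Prediction",
    "fit_linear",
    "predict_from_calibration",
    "lin_ccc",
    "calibrate_pairs",
]


@dataclass
class LinkedSample:
    """Paired non-destructive and destructive measurements for one sample.

    Optional fields left as NaN are treated as missing and removed by
    pairwise-complete deletion when a calibration is fitted.
    """

    sample_id: str
    timepoint: int
    ch2_lt: float = np.nan  # ns
    ch3_lt: float = np.nan  # ns
    gag_ww: float = np.nan  # % wet weight
    collagen_ww: float = np.nan  # % wet weight
    compressive_modulus: float = np.nan  # kPa
    tensile_modulus: float = np.nan  # kPa
    group: str = ""

    def __post_init__(self) -> None:
        for name in (
            "ch2_lt",
            "ch3_lt",
            "gag_ww",
            "collagen_ww",
            "compressive_modulus",
            "tensile_modulus",
        ):
            v = getattr(self, name)
            if np.isfinite(v) and v <= 0:
                raise ValueError(f"{name} must be positive when present, got {v}")


@dataclass(frozen=True)
class CalibrationModel:
    """An ordinary-least-squares calibration y = slope*x + intercept."""

    predictor: str
    response: str
    slope: float
    intercept: float
    r_squared: float
    n: int
    p_value: float = np.nan
    stderr_slope: float = np.nan
    x_range: tuple[float, float] = (np.nan, np.nan)
    group: str = "pooled"

    def __post_init__(self) -> None:
        if not -1e-12 <= self.r_squared <= 1 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")
        if self.n < 3:
            raise ValueError("n must be >= 3")


@dataclass(frozen=True)
class Prediction:
    value: float
    extrapolated: bool


def _pairwise_complete(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def fit_linear(
    x, y, predictor: str = "x", response: str = "y", group: str = "pooled"
) -> CalibrationModel:
    """Simple linear least-squares calibration of y on x.

    Missing values are removed pairwise; at least 3 complete pairs are
    required and x must not be constant.  R² is the squared Pearson
    correlation (identical to the OLS coefficient of determination for a
    single predictor).
    """
    xv, yv = _pairwise_complete(x, y)
    if xv.size < 3:
        raise ValueError(f"need >= 3 complete pairs, got {xv.size}")
    if np.ptp(xv) == 0:
        raise ValueError("x is constant: degenerate fit")
    res = stats.linregress(xv, yv)
    return CalibrationModel(
        predictor=predictor,
        response=response,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=int(xv.size),
        p_value=float(res.pvalue),
        stderr_slope=float(res.stderr),
        x_range=(float(xv.min()), float(xv.max())),
        group=group,
    )


def predict_from_calibration(x: float, model: CalibrationModel) -> Prediction:
    """Evaluate a calibration at ``x``; flags extrapolation outside the
    training range."""
    lo, hi = model.x_range
    extrapolated = bool(np.isfinite(lo) and (x < lo or x > hi))
    return Prediction(value=model.slope * x + model.intercept, extrapolated=extrapolated)


def lin_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient.

    rho_c = 2 cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))^2)

    with population (divide-by-n) moments, matching Lin's original
    formulation; the n vs n-1 choice cancels except in the mean-shift
    term.  Penalizes both poor correlation and systematic bias, so
    rho_c = 1 only for exact agreement y = x.
    """
    xv, yv = _pairwise_complete(x, y)
    if xv.size < 3:
        raise ValueError(f"need >= 3 complete pairs, got {xv.size}")
    mx, my = xv.mean(), yv.mean()
    vx, vy = xv.var(), yv.var()  # population moments
    cov = float(np.mean((xv - mx) * (yv - my)))
    denom = vx + vy + (mx - my) ** 2
    if denom == 0:
        raise ValueError("zero total variance with equal means: rho_c undefined")
    return 2.0 * cov / denom


def calibrate_pairs(
    table: pd.DataFrame,
    pairs: list[tuple[str, str]],
    group_col: str | None = "group",
) -> pd.DataFrame:
    """Fit predictor→response calibrations over a linked-sample table.

    Correlations are fitted separately per treatment group when
    ``group_col`` is present (mirroring per-treatment modeling in matched
    designs) and a pooled fit is always emitted.  No multiple-testing
    correction is applied to the calibration p-values; rows report raw
    values.

    Returns a tidy DataFrame with one row per (pair, group).
    """
    rows = []
    groups: list[tuple[str, pd.DataFrame]] = [("pooled", table)]
    if group_col and group_col in table.columns:
        groups += [(str(g), sub) for g, sub in table.groupby(group_col)]
    for xcol, ycol in pairs:
        for gname, sub in groups:
            try:
                m = fit_linear(sub[xcol], sub[ycol], xcol, ycol, group=gname)
            except ValueError:
                continue  # too few complete pairs in this stratum
            rows.append(
                {
                    "predictor": m.predictor,
                    "response": m.response,
                    "group": m.group,
                    "slope": m.slope,
                    "intercept": m.intercept,
                    "r2": m.r_squared,
                    "n": m.n,
                    "p": m.p_value,
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["multiple_testing"] = "none (raw p-values)"
    return out
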