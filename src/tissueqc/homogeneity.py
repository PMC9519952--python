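"""Imaging-based homogeneity index.

Combines structural homogeneity from ultrasound void volumetry (HS) with
biochemical homogeneity from the FLIm channel-2 and channel-3 lifetime
distributions (HF2, HF3) into a single homogeneity index

    HI = 1/2 (HS + 1/2 [HF2 + HF3])

so that a perfectly homogeneous construct scores 100%.  HS is
100 - void volume (%).  HF is the area under the probability density
function of the lifetime values within ±10% of the mean lifetime,
expressed as a percentage (the area under the entire PDF is 100%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "HomogeneityResult",
    "InsufficientDataError",
    "structural_homogeneity",
    "flim_homogeneity",
    "homogeneity_index",
]


class InsufficientDataError(ValueError):
    """Too few lifetime values to estimate a distribution."""


@dataclass(frozen=True)
class HomogeneityResult:
    """HS, HF2, HF3 and HI percentages for one sample at one time point."""

    hs: float
    hf2: float
    hf3: float
    hi: float
    sample_id: str = ""
    timepoint: int | None = None

    def __post_init__(self) -> None:
        for name in ("hs", "hf2", "hf3", "hi"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name}={v} outside [0, 100]")
        expected = 0.5 * (self.hs + 0.5 * (self.hf2 + self.hf3))
        if abs(self.hi - expected) > 1e-9:
            raise ValueError("hi must equal 0.5*(hs + 0.5*(hf2 + hf3))")

    @classmethod
    def from_components(
        cls,
        hs: float,
        hf2: float,
        hf3: float,
        sample_id: str = "",
        timepoint: int | None = None,
    ) -> "HomogeneityResult":
        return cls(
            hs=hs,
            hf2=hf2,
            hf3=hf3,
            hi=homogeneity_index(hs, hf2, hf3),
            sample_id=sample_id,
            timepoint=timepoint,
        )


def structural_homogeneity(void_percent: float) -> float:
    """HS = 100 - void volume (%)."""
    if not 0.0 <= void_percent <= 100.0:
        raise ValueError(f"void_percent {void_percent} outside [0, 100]")
    return 100.0 - void_percent


def flim_homogeneity(
    lt_values: np.ndarray,
    window_fraction: float = 0.1,
    method: str = "empirical",
) -> float:
    """Percent of the lifetime PDF within ±``window_fraction`` of the mean.

    With the default empirical estimator the area under the PDF over
    [µ(1-f), µ(1+f)] is exactly the fraction of values inside that closed
    interval, so a window wide enough to contain every observed value
    returns exactly 100.  A Gaussian KDE (Silverman bandwidth) is
    available behind ``method='kde'`` for sensitivity checks; it
    integrates the smoothed density over the same interval.

    Parameters
    ----------
    lt_values : array-like
        Valid lifetime values (ns); NaNs are ignored.  At least 10 valid
        values are required.
    window_fraction : float
        Half-width of the window as a fraction of the mean (default 0.1).

    Returns
    -------
    float
        HF in percent, in [0, 100].
    """
    vals = np.asarray(lt_values, dtype=float).ravel()
    vals = vals[np.isfinite(vals)]
    if vals.size < 10:
        raise InsufficientDataError(f"need >= 10 valid lifetimes, got {vals.size}")
    if window_fraction <= 0:
        raise ValueError("window_fraction must be positive")
    mu = vals.mean()
    lo, hi = mu * (1.0 - window_fraction), mu * (1.0 + window_fraction)
    if method == "empirical":
        frac = np.count_nonzero((vals >= lo) & (vals <= hi)) / vals.size
        return 100.0 * frac
    if method == "kde":
        from scipy.stats import gaussian_kde

        if np.ptp(vals) == 0:  # point mass: KDE degenerate, window contains it
            return 100.0
        kde = gaussian_kde(vals)  # Silverman-like (scott) default bandwidth
        area = kde.integrate_box_1d(lo, hi)
        return float(np.clip(100.0 * area, 0.0, 100.0))
    raise ValueError(f"unknown method {method!r}")


def homogeneity_index(hs: float, hf2: float, hf3: float) -> float:
    """HI = 1/2 (HS + 1/2 [HF2 + HF3]), all in percent."""
    for name, v in (("hs", hs), ("hf2", hf2), ("hf3", hf3)):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"{name}={v} outside [0, 100]")
    return 0.5 * (hs + 0.5 * (hf2 + hf3))
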