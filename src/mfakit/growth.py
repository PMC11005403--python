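"""Doubling-time estimation from cell-count growth kinetics.

The doubling time tau is obtained by least-squares regression of
ln(density) on time within the exponential window: tau = ln(2)/slope,
reported in minutes with a delta-method standard error.  Ratios between
strains (e.g. a knockdown vs its reference) propagate SEs to first order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import stats

LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class GrowthCurve:
    """Cell-count kinetics for one culture (times in hours, cells/mL)."""

    times: np.ndarray
    densities: np.ndarray
    replicate: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        d = np.asarray(self.densities, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "densities", d)
        if t.size != d.size:
            raise ValueError("times and densities must have equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(d <= 0) or not np.all(np.isfinite(d)):
            raise ValueError("densities must be positive and finite")


@dataclass(frozen=True)
class DoublingTime:
    """tau in minutes with fit standard error and the window used (hours)."""

    tau: float
    se: float
    window: Tuple[float, float]
    r_squared: float
    n_points: int = 0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"doubling time must be positive, got {self.tau}")


def fit_doubling_time(curve: GrowthCurve,
                      window: Optional[Tuple[float, float]] = None) -> DoublingTime:
    """Fit ln(density) vs time and convert the slope to a doubling time.

    ``window=(t0, t1)`` restricts the fit to points with t0 <= t <= t1;
    ``window=None`` auto-selects the contiguous span of >= 4 points that
    maximizes R^2 (the exponential phase).  At least 3 points and a positive
    slope (net growth) are required.
    """
    if window is None:
        window = auto_window(curve)
    t0, t1 = window
    mask = (curve.times >= t0) & (curve.times <= t1)
    t = curve.times[mask]
    d = curve.densities[mask]
    if t.size < 3:
        raise ValueError(f"window {window} contains {t.size} points; need >= 3")
    fit = stats.linregress(t, np.log(d))
    slope = float(fit.slope)  # per hour
    if slope <= 0:
        raise ValueError("non-positive growth slope: no exponential growth "
                         "in the window")
    tau_min = 60.0 * LN2 / slope
    se_min = 60.0 * LN2 * float(fit.stderr) / slope ** 2
    return DoublingTime(tau=tau_min, se=se_min, window=(float(t0), float(t1)),
                        r_squared=float(fit.rvalue) ** 2, n_points=int(t.size))


def auto_window(curve: GrowthCurve, min_points: int = 4) -> Tuple[float, float]:
    """Contiguous span of >= ``min_points`` samples maximizing the R^2 of the
    ln-linear fit (ties favour more points, then the earlier span).

    On a lag/log/stationary piecewise curve this lands inside the
    exponential phase, where log-density is closest to linear.
    """
    t, d = curve.times, curve.densities
    if t.size < min_points:
        raise ValueError(f"need at least {min_points} points for auto window")
    logd = np.log(d)
    best = None
    for i in range(t.size - min_points + 1):
        for j in range(i + min_points, t.size + 1):
            fit = stats.linregress(t[i:j], logd[i:j])
            if fit.slope <= 0:
                continue
            r2 = float(fit.rvalue) ** 2
            key = (round(r2, 12), j - i, -i)
            if best is None or key > best[0]:
                best = (key, (float(t[i]), float(t[j - 1])))
    if best is None:
        raise ValueError("no growing window found")
    return best[1]


def doubling_ratio(a: DoublingTime, b: DoublingTime) -> Tuple[float, float]:
    """Ratio a.tau / b.tau with first-order SE propagation:
    SE = ratio * sqrt((se_a/tau_a)^2 + (se_b/tau_b)^2)."""
    ratio = a.tau / b.tau
    se = abs(ratio) * np.sqrt((a.se / a.tau) ** 2 + (b.se / b.tau) ** 2)
    return float(ratio), float(se)


def simulate_growth_curve(tau_min: float, times_h, n0: float = 1e6,
                          noise_sd_log: float = 0.0,
                          rng: Optional[np.random.Generator] = None,
                          replicate: str = "sim") -> GrowthCurve:
    """Exponential growth at a known doubling time with multiplicative
    lognormal counting noise (SD on the natural-log scale)."""
    if tau_min <= 0:
        raise ValueError("tau_min must be positive")
    t = np.asarray(times_h, dtype=float)
    dens = n0 * np.exp2(60.0 * t / tau_min)
    if noise_sd_log > 0:
        rng = np.random.default_rng() if rng is None else rng
        dens = dens * np.exp(rng.normal(0.0, noise_sd_log, t.size))
    return GrowthCurve(times=t, densities=dens, replicate=replicate)
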