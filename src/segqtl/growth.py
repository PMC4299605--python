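"""Growth-parameter extraction from optical-density time series.

Micro-fermentation platforms record light scattering (LS) every few minutes;
a linear LS-to-OD calibration converts the series to OD units.  From each
curve five parameters are derived and served as QTL traits:

* efficiency — the OD gain from inoculation to the end of the experiment;
* AUC — area under the baseline-subtracted curve (OD x hours);
* mu_max — maximum specific growth rate: the maximal slope of ln(OD),
  estimated from the first derivative of a smoothing-spline fit (or a
  sliding-window OLS slope);
* lag time — where the tangent at the point of maximal growth rate crosses
  the inoculation OD level;
* doubling time — ln(2)/mu_max, exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from scipy.stats import linregress

__all__ = ["GrowthCurve", "GrowthParams", "calibrate_ls_to_od", "growth_params"]


@dataclass
class GrowthCurve:
    """An OD time series for one strain/replicate (time in hours)."""

    time: np.ndarray
    od: np.ndarray
    strain_id: str = ""
    replicate_id: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.time.shape != self.od.shape:
            raise ValueError("time and OD must have the same length")
        if (np.diff(self.time) <= 0).any():
            raise ValueError("time points must be strictly increasing")


@dataclass
class GrowthParams:
    """Derived growth parameters; all NaN when no growth is detectable."""

    efficiency: float  # delta OD
    auc: float  # OD * hours above baseline
    mu_max: float  # 1/hour
    lag_time: float  # hours
    doubling_time: float  # hours, ln(2)/mu_max

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "efficiency": self.efficiency,
                "auc": self.auc,
                "mu_max": self.mu_max,
                "lag_time": self.lag_time,
                "doubling_time": self.doubling_time,
            }
        )


def calibrate_ls_to_od(
    ls_series: np.ndarray, ls_anchor: np.ndarray, od_anchor: np.ndarray
) -> np.ndarray:
    """Map light-scattering values to OD via OLS on anchor pairs."""
    ls_anchor = np.asarray(ls_anchor, dtype=float)
    od_anchor = np.asarray(od_anchor, dtype=float)
    if len(ls_anchor) < 2:
        raise ValueError("need at least two anchor pairs")
    fit = linregress(ls_anchor, od_anchor)
    return fit.intercept + fit.slope * np.asarray(ls_series, dtype=float)


def _mu_max_spline(t: np.ndarray, log_od: np.ndarray):
    """Max of the first derivative of a GCV smoothing spline of ln(OD)."""
    spl = make_smoothing_spline(t, log_od)
    grid = np.linspace(t[0], t[-1], max(200, 4 * len(t)))
    deriv = spl.derivative()(grid)
    k = int(np.argmax(deriv))
    return float(deriv[k]), float(grid[k]), float(spl(grid[k]))


def _mu_max_window(t: np.ndarray, log_od: np.ndarray, window: int = 7):
    """Max sliding-window OLS slope of ln(OD)."""
    window = min(window, len(t))
    best = (-np.inf, t[0], log_od[0])
    for i in range(len(t) - window + 1):
        ts, ys = t[i: i + window], log_od[i: i + window]
        slope = linregress(ts, ys).slope
        if slope > best[0]:
            mid = i + window // 2
            best = (slope, t[mid], log_od[mid])
    return float(best[0]), float(best[1]), float(best[2])


def growth_params(curve: GrowthCurve, smoothing: str = "spline") -> GrowthParams:
    """Extract the growth parameters of one curve.

    ``smoothing`` selects the mu_max estimator: ``"spline"`` (first
    derivative of a smoothing spline of ln OD) or ``"window"`` (maximum
    sliding-window OLS slope).  The lag time is the tangent-intercept
    construction: the tangent to ln(OD) at the point of maximal growth rate
    is traced back to the initial OD level.  Curves without positive growth
    (mu_max <= 0) report NaN for the rate-derived parameters.
    """
    t, od = curve.time, curve.od
    if len(t) < 10:
        raise ValueError("need at least 10 time points")
    if (od <= 0).any():
        raise ValueError("OD must be positive for log operations")

    efficiency = float(od[-1] - od[0])
    baseline = od[0]
    auc = float(np.trapezoid(np.clip(od - baseline, 0, None), t))

    log_od = np.log(od)
    if smoothing == "spline":
        mu, t_star, y_star = _mu_max_spline(t, log_od)
    elif smoothing == "window":
        mu, t_star, y_star = _mu_max_window(t, log_od)
    else:
        raise ValueError(f"unknown smoothing {smoothing!r}")

    if mu <= 1e-9 or not np.isfinite(mu):  # flat within numerical noise
        nan = float("nan")
        return GrowthParams(efficiency, auc, nan, nan, nan)

    # tangent through (t*, ln OD(t*)) with slope mu intersects ln OD(0)
    lag = t_star - (y_star - log_od[0]) / mu
    return GrowthParams(efficiency, auc, mu, float(lag), float(np.log(2) / mu))
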