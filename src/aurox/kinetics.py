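"""Au(III) oxidation kinetics from soil-microcosm time series.

Microcosms are slurries spiked with metallic gold particles; dissolved
Au(III) is assayed colorimetrically with TMB (absorbance at 654 nm) against
an AuCl3 standard curve, alongside slurry pH.  This module covers:

* calibration: ordinary least squares standard curve and its inversion,
* phase-wise linear oxidation-rate estimation over user-chosen time
  windows (with an optional two-segment breakpoint search),
* the Pearson correlation between Au(III) and pH over a window, and
* the peak Au(III) concentration as a percentage of total spiked gold.

Replicates are summarised as mean +/- sd per time point before fitting;
fitting on raw replicates is available via ``use_replicates``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class KineticsError(ValueError):
    pass


@dataclass
class StandardCurve:
    """Linear TMB calibration: absorbance = slope * concentration + intercept."""

    concentrations: np.ndarray  # uM
    absorbances: np.ndarray     # AU at 654 nm
    slope: float                # AU/uM
    intercept: float            # AU
    r2: float

    def predict(self, conc):
        return self.slope * np.asarray(conc, dtype=float) + self.intercept


@dataclass
class MicrocosmSeries:
    """Replicate-summarised Au(III)/pH trajectory of one microcosm condition."""

    condition: str
    times: np.ndarray          # h, strictly increasing
    au3: np.ndarray            # uM, mean over replicates
    au3_sd: np.ndarray         # uM
    ph: np.ndarray             # mean pH
    replicates: int
    total_au: float            # uM of spiked metallic gold

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.au3 = np.asarray(self.au3, dtype=float)
        self.au3_sd = np.asarray(self.au3_sd, dtype=float)
        self.ph = np.asarray(self.ph, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise KineticsError("sampling times must be strictly increasing")
        if self.replicates < 1:
            raise KineticsError("need at least one replicate")
        if self.total_au <= 0:
            raise KineticsError("total spiked gold must be positive")

    @classmethod
    def from_tidy(
        cls,
        frame: pd.DataFrame,
        condition: str,
        total_au: float,
        curve: "StandardCurve | None" = None,
    ) -> "MicrocosmSeries":
        """Build from tidy rows (condition, replicate, time_h, au3_uM or
        absorbance, ph).  If ``curve`` is given, absorbances are inverted."""
        sub = frame[frame["condition"] == condition]
        if sub.empty:
            raise KineticsError(f"no rows for condition {condition!r}")
        sub = sub.copy()
        if "au3_uM" not in sub.columns:
            if curve is None:
                raise KineticsError("absorbance input needs a standard curve")
            sub["au3_uM"] = absorbance_to_au3(curve, sub["absorbance"].to_numpy())
        g = sub.groupby("time_h")
        agg = g.agg(au3=("au3_uM", "mean"), sd=("au3_uM", "std"),
                    ph=("ph", "mean"), n=("au3_uM", "size")).reset_index()
        return cls(
            condition=condition,
            times=agg["time_h"].to_numpy(),
            au3=agg["au3"].to_numpy(),
            au3_sd=np.nan_to_num(agg["sd"].to_numpy()),
            ph=agg["ph"].to_numpy(),
            replicates=int(agg["n"].max()),
            total_au=total_au,
        )


@dataclass
class PhaseFit:
    """OLS line over one phase window: au3 = rate * t + intercept."""

    window: tuple[float, float]  # h
    rate: float                  # uM/h
    intercept: float             # uM
    r2: float
    n_points: int


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def fit_standard_curve(concs, abs_values) -> StandardCurve:
    """Ordinary least squares calibration line through the standards."""
    c = np.asarray(concs, dtype=float)
    a = np.asarray(abs_values, dtype=float)
    if c.shape != a.shape or c.size < 2:
        raise KineticsError("need >= 2 matched (concentration, absorbance) points")
    if np.ptp(c) == 0:
        raise KineticsError("all standard concentrations are identical")
    res = stats.linregress(c, a)
    return StandardCurve(c, a, res.slope, res.intercept, res.rvalue**2)


def absorbance_to_au3(curve: StandardCurve, A, clip: bool = True):
    """Invert the calibration: concentration = (A - intercept)/slope.

    Negative inferred concentrations are clipped to 0 (``clip=True``); the
    returned array's companion count of clipped values is available via
    :func:`count_clipped`.
    """
    if curve.slope == 0:
        raise KineticsError("calibration slope is zero; cannot invert")
    conc = (np.asarray(A, dtype=float) - curve.intercept) / curve.slope
    if clip:
        conc = np.clip(conc, 0.0, None)
    return conc


def count_clipped(curve: StandardCurve, A) -> int:
    """Number of absorbances that map below zero concentration."""
    conc = (np.asarray(A, dtype=float) - curve.intercept) / curve.slope
    return int(np.sum(conc < 0))


# ---------------------------------------------------------------------------
# rates, correlation, inventory
# ---------------------------------------------------------------------------

def _window_mask(times: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    t0, t1 = window
    return (times >= t0) & (times <= t1)


def fit_phase_rate(series: MicrocosmSeries, window: tuple[float, float]) -> PhaseFit:
    """OLS slope of Au(III) vs time inside ``window`` (inclusive), in uM/h."""
    m = _window_mask(series.times, window)
    if m.sum() < 2:
        raise KineticsError(f"fewer than 2 observations in window {window}")
    t = series.times[m]
    y = series.au3[m]
    if np.ptp(y) == 0:
        return PhaseFit(window, 0.0, float(y[0]), 1.0, int(m.sum()))
    res = stats.linregress(t, y)
    return PhaseFit(window, res.slope, res.intercept, res.rvalue**2, int(m.sum()))


def breakpoint_search(
    series: MicrocosmSeries, min_points: int = 2
) -> tuple[float, PhaseFit, PhaseFit]:
    """Two-segment split over observed times minimising total SSE.

    Exploratory helper: scans every observed time as a candidate breakpoint
    (each segment keeping >= ``min_points`` observations) and returns the
    breakpoint and the two phase fits.  Phase windows for reported rates
    should normally be chosen by inspection instead.
    """
    t = series.times
    best = None
    for k in range(min_points - 1, len(t) - min_points):
        w1 = (t[0], t[k])
        w2 = (t[k], t[-1])
        f1 = fit_phase_rate(series, w1)
        f2 = fit_phase_rate(series, w2)
        sse = 0.0
        for w, f in ((w1, f1), (w2, f2)):
            m = _window_mask(t, w)
            resid = series.au3[m] - (f.rate * t[m] + f.intercept)
            sse += float(resid @ resid)
        if best is None or sse < best[0]:
            best = (sse, t[k], f1, f2)
    if best is None:
        raise KineticsError("series too short for a two-segment split")
    return best[1], best[2], best[3]


def correlate_au3_ph(
    series: MicrocosmSeries, window: tuple[float, float], tails: int = 2
) -> tuple[float, float]:
    """Pearson r between Au(III) and pH in ``window`` and its t-test p-value.

    ``tails=1`` gives the one-tailed p in the direction of the observed r;
    ``tails=2`` the usual two-tailed p (n-2 degrees of freedom).
    """
    if tails not in (1, 2):
        raise KineticsError("tails must be 1 or 2")
    m = _window_mask(series.times, window)
    if m.sum() < 3:
        raise KineticsError("need >= 3 points for a correlation")
    x = series.au3[m]
    y = series.ph[m]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise KineticsError("zero variance in Au(III) or pH over the window")
    r, p_two = stats.pearsonr(x, y)
    p = p_two / 2 if tails == 1 else p_two
    return float(r), float(p)


def percent_oxidized(series: MicrocosmSeries) -> tuple[float, float]:
    """Time of maximum Au(III) and the maximum as % of total spiked gold."""
    if series.au3.size == 0:
        raise KineticsError("empty series")
    i = int(np.argmax(series.au3))
    pct = 100.0 * float(series.au3[i]) / series.total_au
    return float(series.times[i]), pct
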