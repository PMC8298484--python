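"""Single-component cosinor rhythmometry.

The model is Y(t) = M + A*cos(2*pi*t/tau + phi) + e(t): M is the mesor
(rhythm-adjusted mean), A the amplitude (half the peak-to-trough extent of
the fitted curve), phi the acrophase angle and tau the period.  For fixed
tau the model linearizes to Y = M + beta*cos(wt) + gamma*sin(wt) with
beta = A*cos(phi), gamma = -A*sin(phi), and is fit by ordinary least
squares; the best-fitting period is then profiled out by a one-dimensional
search (coarse grid plus golden-section refinement), which reaches the same
optimum as joint nonlinear fitting without its convergence fragility.

The acrophase angle is recovered from (beta, gamma) by a full four-quadrant
sign-case resolution, so peak clock times are correct in every quadrant;
observed (as opposed to model-based) peak and nadir times are located
directly on smoothed data, cycle by cycle, and summarized by a 24-h
circular mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from ._utils import circular_mean_hours, hours_to_hhmm
from .preprocessing import SmoothedSeries, TemperatureSeries

__all__ = [
    "CosinorFit",
    "ObservedTiming",
    "CosinorRegressor",
    "fit_fixed_period",
    "estimate_period",
    "corrected_acrophase",
    "acrophase_to_degrees_delay",
    "extrema_clock_times",
    "observed_extrema",
]

TWO_PI = 2.0 * math.pi
#: clock time (hours) of the first sample of a harmonized window
WINDOW_T0_CLOCK = 12.0


@dataclass
class CosinorFit:
    """Per-subject cosinor parameters and derived clock-time extrema."""

    mesor: float
    amplitude: float
    acrophase: float  # phi, radians in (-pi, pi]
    period: float  # tau, hours
    beta: float
    gamma: float
    rss: float
    acrophase_clock: str = ""
    bathyphase_clock: str = ""
    subject_id: str = ""

    def curve(self, t_hours: np.ndarray) -> np.ndarray:
        return self.mesor + self.amplitude * np.cos(
            TWO_PI * np.asarray(t_hours) / self.period + self.acrophase
        )

    @property
    def peak_time_h(self) -> float:
        """First model peak, hours after window start."""
        return (-self.acrophase * self.period / TWO_PI) % self.period


@dataclass
class ObservedTiming:
    """Peak/nadir clock times read off smoothed data, cycle by cycle."""

    acrophase_clock: str
    bathyphase_clock: str
    per_cycle_acro: list[float]
    per_cycle_bathy: list[float]


def corrected_acrophase(beta: float, gamma: float) -> float:
    """Acrophase angle phi from the linearized coefficients.

    Resolves phi over all four quadrants from the signs of (beta, gamma)
    so that beta = A*cos(phi) and gamma = -A*sin(phi); the sign-case table
    is equivalent to a full-range two-argument arctangent.  phi lies in
    (-pi, pi].
    """
    if beta == 0.0 and gamma == 0.0:
        raise ValueError("acrophase undefined for a zero-amplitude signal")
    theta = math.atan(abs(gamma / beta)) if beta != 0.0 else math.pi / 2.0
    if beta >= 0 and gamma >= 0:
        phi = -theta
    elif beta < 0 and gamma >= 0:
        phi = theta - math.pi
    elif beta < 0 and gamma < 0:
        phi = math.pi - theta
    else:  # beta >= 0, gamma < 0
        phi = theta
    if phi <= -math.pi:
        phi += TWO_PI
    return phi


def acrophase_to_degrees_delay(phi: float) -> float:
    """Acrophase expressed as a non-negative delay in degrees, in [0, 360)."""
    return (-math.degrees(phi)) % 360.0


def _design_fit(t: np.ndarray, y: np.ndarray, tau: float):
    w = TWO_PI / tau
    c, s = np.cos(w * t), np.sin(w * t)
    X = np.column_stack([np.ones_like(t), c, s])
    xtx = X.T @ X
    # collinearity guard: tau far beyond the window makes cos/sin ~ constant
    if np.linalg.cond(xtx) > 1e10:
        raise ValueError(f"singular cosinor design at period {tau} h")
    coef = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ coef
    return coef, float(resid @ resid)


class CosinorRegressor(RegressorMixin, BaseEstimator):
    """Least-squares cosinor fit with optional period search.

    Parameters
    ----------
    period : float or None
        Fixed period in hours; ``None`` profiles the period over
        ``period_bounds`` by residual sum of squares.
    period_bounds : (float, float)
        Search range in hours (default [20, 30], bracketing the circadian
        range reported for free-living adolescents).
    coarse_step_h : float
        Grid step of the coarse period sweep (default 0.1 h = 6 min).
    resolution_h : float
        Golden-section refinement tolerance (default 1 minute).

    Attributes (after ``fit``)
    --------------------------
    mesor_, amplitude_, acrophase_, period_, beta_, gamma_, rss_ : float
    fit_ : CosinorFit
    """

    def __init__(
        self,
        period: float | None = None,
        period_bounds: tuple[float, float] = (20.0, 30.0),
        coarse_step_h: float = 0.1,
        resolution_h: float = 1.0 / 60.0,
    ):
        self.period = period
        self.period_bounds = period_bounds
        self.coarse_step_h = coarse_step_h
        self.resolution_h = resolution_h

    # -- internals ---------------------------------------------------------
    def _rss(self, t, y, tau):
        return _design_fit(t, y, tau)[1]

    def _golden(self, t, y, lo, hi):
        invphi = (math.sqrt(5.0) - 1.0) / 2.0
        a, b = lo, hi
        c, d = b - invphi * (b - a), a + invphi * (b - a)
        fc, fd = self._rss(t, y, c), self._rss(t, y, d)
        while (b - a) > self.resolution_h:
            if fc < fd:
                b, d, fd = d, c, fc
                c = b - invphi * (b - a)
                fc = self._rss(t, y, c)
            else:
                a, c, fc = c, d, fd
                d = a + invphi * (b - a)
                fd = self._rss(t, y, d)
        return (a + b) / 2.0

    # -- API ---------------------------------------------------------------
    def fit(self, t, y):
        t = np.asarray(t, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        ok = np.isfinite(y) & np.isfinite(t)
        t, y = t[ok], y[ok]
        if len(y) < 3:
            raise ValueError("cosinor fit needs at least 3 observations")

        if self.period is not None:
            if self.period <= 0:
                raise ValueError("period must be positive")
            tau = float(self.period)
        else:
            lo, hi = self.period_bounds
            if not 0 < lo < hi:
                raise ValueError(f"invalid period bounds {self.period_bounds}")
            if self.resolution_h < 1.0 / 3600.0:
                raise ValueError("period resolution finer than 1 s is not supported")
            taus = np.arange(lo, hi + 1e-9, self.coarse_step_h)
            rsss = np.array([self._rss(t, y, tv) for tv in taus])
            if np.ptp(rsss) < 1e-12 * max(rsss.max(), 1.0):
                # flat profile: constant series, period unidentifiable
                coef, rss = _design_fit(t, y, 24.0)
                self._finalize(coef, math.nan, rss)
                return self
            i = int(np.argmin(rsss))
            tau = self._golden(t, y, taus[max(i - 1, 0)], taus[min(i + 1, len(taus) - 1)])
        coef, rss = _design_fit(t, y, tau)
        self._finalize(coef, tau, rss)
        return self

    def _finalize(self, coef, tau, rss):
        m, beta, gamma = map(float, coef)
        amplitude = math.hypot(beta, gamma)
        phi = corrected_acrophase(beta, gamma) if amplitude > 1e-12 else math.nan
        if amplitude <= 1e-12:
            amplitude = 0.0
        self.mesor_, self.amplitude_, self.acrophase_ = m, amplitude, phi
        self.period_, self.beta_, self.gamma_, self.rss_ = tau, beta, gamma, rss
        acro, bathy = ("", "")
        if amplitude > 0 and math.isfinite(tau):
            fit = CosinorFit(m, amplitude, phi, tau, beta, gamma, rss)
            acro, bathy = extrema_clock_times(fit)
        self.fit_ = CosinorFit(m, amplitude, phi, tau, beta, gamma, rss, acro, bathy)

    def predict(self, t):
        return self.fit_.curve(np.asarray(t, dtype=float))


def _series_arrays(series) -> tuple[np.ndarray, np.ndarray, str]:
    if isinstance(series, (TemperatureSeries, SmoothedSeries)):
        return series.t_hours, series.values, series.subject_id
    y = np.asarray(series, dtype=float)
    return np.arange(len(y)) / 60.0, y, ""


def fit_fixed_period(series, tau: float) -> CosinorFit:
    """Least-squares cosinor fit at a fixed period ``tau`` (hours)."""
    t, y, sid = _series_arrays(series)
    reg = CosinorRegressor(period=tau).fit(t, y)
    reg.fit_.subject_id = sid
    return reg.fit_


def estimate_period(
    series,
    tau_range: tuple[float, float] = (20.0, 30.0),
    resolution_h: float = 1.0 / 60.0,
) -> CosinorFit:
    """Cosinor fit with the period profiled over ``tau_range`` by RSS."""
    t, y, sid = _series_arrays(series)
    reg = CosinorRegressor(period=None, period_bounds=tau_range, resolution_h=resolution_h)
    reg.fit(t, y)
    reg.fit_.subject_id = sid
    return reg.fit_


def extrema_clock_times(fit: CosinorFit, t0_clock: float = WINDOW_T0_CLOCK) -> tuple[str, str]:
    """Clock times (hh:mm) of the first model peak and trough after window start."""
    if fit.amplitude <= 0 or not math.isfinite(fit.period):
        raise ValueError("extrema undefined for a zero-amplitude fit")
    peak = fit.peak_time_h
    trough = (peak + fit.period / 2.0) % fit.period
    return (
        hours_to_hhmm(t0_clock + peak),
        hours_to_hhmm(t0_clock + trough),
    )


def observed_extrema(
    smoothed: SmoothedSeries, t0_clock: float = WINDOW_T0_CLOCK
) -> ObservedTiming:
    """Per-cycle peak/nadir clock times on smoothed data, plus circular means.

    The window is split into consecutive 24-h cycles from its start; each
    cycle contributes its argmax/argmin as a clock time, and the summary is
    the circular mean over cycles on a 24-h dial (so peaks at 23:30 and
    00:30 average to 00:00, not 12:00).  Constant cycles are skipped.
    """
    values = np.asarray(smoothed.values, dtype=float)
    n_cycles = len(values) // (24 * 60)
    if n_cycles < 2:
        raise ValueError("observed extrema need at least two full 24-h cycles")
    acro, bathy = [], []
    for c in range(n_cycles):
        cycle = values[c * 1440 : (c + 1) * 1440]
        if np.ptp(cycle) < 1e-12:
            continue
        acro.append((t0_clock + int(np.argmax(cycle)) / 60.0) % 24.0)
        bathy.append((t0_clock + int(np.argmin(cycle)) / 60.0) % 24.0)
    if not acro:
        raise ValueError("all cycles constant: observed extrema undefined")
    return ObservedTiming(
        acrophase_clock=hours_to_hhmm(circular_mean_hours(np.array(acro))),
        bathyphase_clock=hours_to_hhmm(circular_mean_hours(np.array(bathy))),
        per_cycle_acro=acro,
        per_cycle_bathy=bathy,
    )
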