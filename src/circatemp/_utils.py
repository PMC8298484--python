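"""Small shared helpers: clock-time formatting and circular statistics."""

from __future__ import annotations

import numpy as np

TWO_PI = 2.0 * np.pi


def hours_to_hhmm(hours: float) -> str:
    """Format decimal clock hours as ``hh:mm`` (rounded to the minute)."""
    if not np.isfinite(hours):
        return "--:--"
    total_min = int(round((hours % 24.0) * 60.0)) % (24 * 60)
    return f"{total_min // 60:02d}:{total_min % 60:02d}"


def hhmm_to_hours(s: str) -> float:
    h, m = s.split(":")
    return int(h) + int(m) / 60.0


def circular_mean_hours(hours: np.ndarray, period: float = 24.0) -> float:
    """Circular mean of clock times on a ``period``-hour dial.

    Returns a value in ``[0, period)``; NaN if the resultant vector is
    (numerically) zero, i.e. the times are perfectly dispersed.
    """
    hours = np.asarray(hours, dtype=float)
    hours = hours[np.isfinite(hours)]
    if hours.size == 0:
        return float("nan")
    ang = TWO_PI * hours / period
    c, s = np.cos(ang).mean(), np.sin(ang).mean()
    if np.hypot(c, s) < 1e-12:
        return float("nan")
    return float((np.arctan2(s, c) * period / TWO_PI) % period)


def anchored_hours(clock_hours: np.ndarray | float, anchor: float = 18.0) -> np.ndarray | float:
    """Clock time re-expressed as hours since ``anchor`` (default 18:00).

    Linearizes night-time clock arithmetic: onsets of 23:30 and 00:30 map to
    5.5 and 6.5, so means and SDs behave.
    """
    return (np.asarray(clock_hours, dtype=float) - anchor) % 24.0


def unanchored_hours(anchored: np.ndarray | float, anchor: float = 18.0) -> np.ndarray | float:
    return (np.asarray(anchored, dtype=float) + anchor) % 24.0


def check_seed(seed) -> int:
    """Validate a user-supplied RNG seed."""
    if seed is None or isinstance(seed, bool) or not isinstance(seed, (int, np.integer)):
        raise ValueError(f"seed must be a non-negative integer, got {seed!r}")
    if seed < 0:
        raise ValueError(f"seed must be non-negative, got {seed}")
    return int(seed)
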