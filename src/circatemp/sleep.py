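"""Actigraphy-style sleep summaries, DSP classification and MEQ scoring.

Per-night sleep episodes (bedtime, onset, offset, WASO) are aggregated into
duration, quality, timing and regularity measures.  Clock-time moments are
taken on an 18:00-anchored linear scale — onsets in this adolescent
population never cluster near 18:00, so means and SDs of times straddling
midnight are safe (23:30 and 00:30 average to 00:00, with an SD of about
42 min rather than 12 h).

Delayed sleep phase (DSP) is a rule-based label: sleep onset strictly after
01:00 on at least three nights per week, normalized by the number of
observed nights.  The morningness score is the plain sum of the six
short-form MEQ items; higher means more morning-oriented.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import anchored_hours, hours_to_hhmm, unanchored_hours
from .simulate import MEQ_ITEM_RANGES

__all__ = ["SleepSummary", "summarize_sleep", "classify_dsp", "score_meq"]

ANCHOR = 18.0  # clock hour anchoring the linear night scale


@dataclass
class SleepSummary:
    subject_id: str
    assumed_sleep_h: float
    waso_min: float
    sol_min: float
    onset_mean_clock: float
    midpoint_mean_clock: float
    offset_mean_clock: float
    sd_onset_min: float
    sd_midpoint_min: float
    n_nights: int
    dsp: bool | None = None
    meq_sum: int | None = None
    insufficient: bool = False

    def row(self) -> dict:
        """Flat dict with clock times both as hh:mm and decimal hours."""
        return {
            "subject_id": self.subject_id,
            "assumed_sleep": hours_to_hhmm(self.assumed_sleep_h),
            "assumed_sleep_h": round(self.assumed_sleep_h, 4),
            "waso": hours_to_hhmm(self.waso_min / 60.0),
            "waso_min": round(self.waso_min, 2),
            "sol": hours_to_hhmm(self.sol_min / 60.0),
            "sol_min": round(self.sol_min, 2),
            "onset_mean": hours_to_hhmm(self.onset_mean_clock),
            "onset_mean_h": round(self.onset_mean_clock, 4),
            "midpoint_mean": hours_to_hhmm(self.midpoint_mean_clock),
            "midpoint_mean_h": round(self.midpoint_mean_clock, 4),
            "offset_mean": hours_to_hhmm(self.offset_mean_clock),
            "offset_mean_h": round(self.offset_mean_clock, 4),
            "sd_onset_min": round(self.sd_onset_min, 2),
            "sd_midpoint_min": round(self.sd_midpoint_min, 2),
            "n_nights": self.n_nights,
            "dsp": self.dsp,
            "meq_sum": self.meq_sum,
            "insufficient": self.insufficient,
        }


def _clock_hours(ts: pd.Series) -> np.ndarray:
    ts = pd.to_datetime(ts)
    return (ts.dt.hour + ts.dt.minute / 60.0 + ts.dt.second / 3600.0).to_numpy()


def _validate_episodes(episodes: pd.DataFrame) -> pd.DataFrame:
    ep = episodes.copy()
    for col in ("bedtime", "onset", "offset"):
        ep[col] = pd.to_datetime(ep[col])
    bad = (ep["bedtime"] > ep["onset"]) | (ep["onset"] >= ep["offset"])
    bad |= (ep["offset"] - ep["onset"]) > pd.Timedelta(hours=16)
    bad |= ep["waso_min"] < 0
    return ep[~bad]


def summarize_sleep(episodes: pd.DataFrame, min_nights: int = 3) -> SleepSummary:
    """Aggregate one subject's nightly episodes into a sleep summary.

    Means of onset/midpoint/offset are taken on the 18:00-anchored scale and
    mapped back to clock time; regularity is the night-to-night SD of onset
    and midpoint in minutes.  Fewer than ``min_nights`` valid nights flags
    the summary insufficient instead of raising.
    """
    sid = str(episodes["subject_id"].iloc[0]) if len(episodes) else ""
    ep = _validate_episodes(episodes)
    n = len(ep)
    if n < min_nights:
        return SleepSummary(sid, *[np.nan] * 8, n_nights=n, insufficient=True)

    duration_h = (ep["offset"] - ep["onset"]).dt.total_seconds().to_numpy() / 3600.0
    sol_min = (ep["onset"] - ep["bedtime"]).dt.total_seconds().to_numpy() / 60.0
    onset_a = anchored_hours(_clock_hours(ep["onset"]), ANCHOR)
    offset_a = anchored_hours(_clock_hours(ep["offset"]), ANCHOR)
    midpoint_a = onset_a + duration_h / 2.0

    return SleepSummary(
        subject_id=sid,
        assumed_sleep_h=float(duration_h.mean()),
        waso_min=float(ep["waso_min"].mean()),
        sol_min=float(sol_min.mean()),
        onset_mean_clock=float(unanchored_hours(onset_a.mean(), ANCHOR)),
        midpoint_mean_clock=float(unanchored_hours(midpoint_a.mean(), ANCHOR)),
        offset_mean_clock=float(unanchored_hours(offset_a.mean(), ANCHOR)),
        sd_onset_min=float(onset_a.std(ddof=1) * 60.0),
        sd_midpoint_min=float(midpoint_a.std(ddof=1) * 60.0),
        n_nights=n,
    )


def classify_dsp(
    episodes: pd.DataFrame,
    late_threshold_clock: float = 1.0,
    per_week: float = 3.0,
    use_bedtime: bool = False,
    min_nights: int = 3,
) -> bool:
    """Delayed-sleep-phase rule: onset strictly after 01:00 >= 3 times/week.

    The count of late nights is normalized by the observed nights,
    ``(late / n) * 7 >= per_week``, because measurement windows vary in
    length.  Nights with a missing onset are excluded from numerator and
    denominator.  ``use_bedtime`` applies the rule to bedtime instead.
    """
    col = "bedtime" if use_bedtime else "onset"
    ep = episodes.dropna(subset=[col])
    n = len(ep)
    if n < min_nights:
        raise ValueError(f"DSP rule needs at least {min_nights} nights, got {n}")
    clock_a = anchored_hours(_clock_hours(ep[col]), ANCHOR)
    late = clock_a > anchored_hours(late_threshold_clock, ANCHOR)
    return bool((late.sum() / n) * 7.0 >= per_week)


def score_meq(items: dict[str, int] | pd.Series,
              item_ranges: dict[str, tuple[int, int]] = MEQ_ITEM_RANGES) -> int:
    """Sum score of the six short-form morningness items.

    All items must be present and within their legal response ranges; no
    prorating of missing items.
    """
    total = 0
    for name, (lo, hi) in item_ranges.items():
        if name not in items or pd.isna(items[name]):
            raise ValueError(f"missing MEQ item {name}: score undefined")
        v = int(items[name])
        if not lo <= v <= hi:
            raise ValueError(f"MEQ {name}={v} outside legal range [{lo}, {hi}]")
        total += v
    return total
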