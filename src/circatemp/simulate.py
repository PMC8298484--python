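"""Synthetic free-living wrist-temperature cohorts.

Each subject's recording is a single-component cosinor signal

    Y(t) = M + A * cos(2*pi*(t - t_peak)/tau)

sampled once per minute for three days, plus AR(1) sensor noise, an additive
warm-up transient after the logger is strapped on, sensor quantization, and
contiguous missing runs where the logger was detached.  Recording start times
are jittered between 15:00 and 22:00, as in ambulatory protocols where
devices are handed out during the afternoon or evening.

A cohort bundle adds per-subject sleep episodes (8 nights with bedtime,
onset, offset, wake-after-sleep-onset), the six morningness-questionnaire
items, demographics, and the generating truth labels, so every downstream
stage of the pipeline can be exercised without real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from ._utils import anchored_hours, check_seed
from .specs import ArchetypeSpec, NoiseSpec, default_archetypes, default_noise

__all__ = [
    "RawRecording",
    "CohortBundle",
    "generate_series",
    "generate_cohort",
    "MEQ_ITEM_RANGES",
]

#: Response range (min, max) of each short-form morningness item.
MEQ_ITEM_RANGES: dict[str, tuple[int, int]] = {
    "item4": (1, 4),
    "item7": (1, 4),
    "item9": (1, 4),
    "item15": (1, 4),
    "item17": (1, 5),
    "item19": (1, 4),
}

_BASE_DATE = pd.Timestamp("2017-01-09")
_MINUTES = 72 * 60  # three-day recording


@dataclass
class RawRecording:
    """One subject's raw minute-resolution recording.

    ``values`` holds NaN where the sample is missing; ``truth`` records the
    generating archetype label and the realized per-subject parameters.
    """

    subject_id: str
    start_time: pd.Timestamp
    values: np.ndarray
    truth: dict = field(default_factory=dict)

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_time, periods=len(self.values), freq="min")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"subject_id": self.subject_id, "timestamp": self.timestamps, "temp_c": self.values}
        )


@dataclass
class CohortBundle:
    """All inputs of one simulated cohort."""

    recordings: list[RawRecording]
    sleep: pd.DataFrame
    meq: pd.DataFrame
    demographics: pd.DataFrame
    truth: pd.DataFrame

    @property
    def n_subjects(self) -> int:
        return len(self.recordings)

    def temperature_frame(self) -> pd.DataFrame:
        return pd.concat([r.to_frame() for r in self.recordings], ignore_index=True)

    def write_csvs(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, frame in [
            ("temperature", self.temperature_frame()),
            ("sleep", self.sleep),
            ("meq", self.meq),
            ("demographics", self.demographics),
            ("truth", self.truth),
        ]:
            paths[name] = outdir / f"{name}.csv"
            frame.to_csv(paths[name], index=False)
        return paths


def _cosinor_curve(t_hours: np.ndarray, mesor: float, amplitude: float,
                   period: float, peak_hours: float) -> np.ndarray:
    return mesor + amplitude * np.cos(2.0 * np.pi * (t_hours - peak_hours) / period)


#: between-subject SDs of the realized cosinor parameters
#: (mesor degC, amplitude degC, period h)
PARAM_SDS = (0.15, 0.15, 0.4)


def _draw_subject_params(
    archetype: ArchetypeSpec,
    rng: np.random.Generator,
    param_sds: tuple[float, float, float] = PARAM_SDS,
) -> dict:
    mesor_sd, amp_sd, period_sd = param_sds
    mesor = rng.normal(archetype.mesor, mesor_sd)
    amplitude = rng.normal(archetype.amplitude, amp_sd)
    while amplitude <= 0.2:  # truncation keeps the rhythm detectable
        amplitude = rng.normal(archetype.amplitude, amp_sd)
    period = rng.normal(archetype.period, period_sd)
    return {
        "mesor": float(mesor),
        "amplitude": float(amplitude),
        "period": float(period),
        "acrophase_clock": float(archetype.acrophase_clock),
    }


def _ar1_noise(n: int, sigma: float, phi: float, rng: np.random.Generator) -> np.ndarray:
    if sigma == 0.0:
        return np.zeros(n)
    innovations = rng.normal(0.0, sigma, size=n)
    # stationary start so the marginal SD is constant over the record
    innovations[0] = rng.normal(0.0, sigma / np.sqrt(1.0 - phi**2))
    return lfilter([1.0], [1.0, -phi], innovations)


def _missing_mask(n: int, fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Contiguous missing runs (re-attachment gaps) covering ~``fraction`` of samples."""
    mask = np.zeros(n, dtype=bool)
    target = int(round(fraction * n))
    attempts = 0
    while mask.sum() < target and attempts < 10 * n:
        run = int(rng.integers(5, 91))
        start = int(rng.integers(0, n - run))
        mask[start : start + run] = True
        attempts += 1
    return mask


def generate_series(
    archetype: ArchetypeSpec,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    n_minutes: int = _MINUTES,
    param_sds: tuple[float, float, float] = PARAM_SDS,
) -> RawRecording:
    """Simulate one subject's three-day minute-resolution recording.

    The start time is drawn uniformly between 15:00 and 22:00; realized
    cosinor parameters are jittered around the archetype values
    (mesor/amplitude SD 0.15 °C, amplitude truncated > 0.2 °C, period SD
    0.4 h).  The first ``noise.transient_duration`` minutes carry an
    additive warm-up ramp (the logger starts below skin temperature).
    """
    seed = check_seed(seed)
    if n_minutes <= 0:
        raise ValueError(f"n_minutes must be positive, got {n_minutes}")
    noise = noise if noise is not None else default_noise()
    rng = np.random.default_rng(seed)

    start_minute = int(rng.integers(15 * 60, 22 * 60 + 1))
    start_time = _BASE_DATE + pd.Timedelta(minutes=start_minute)

    params = _draw_subject_params(archetype, rng, param_sds)
    # time axis in clock hours since midnight of the start day
    t_hours = start_minute / 60.0 + np.arange(n_minutes) / 60.0
    values = _cosinor_curve(
        t_hours, params["mesor"], params["amplitude"], params["period"],
        params["acrophase_clock"],
    )
    values = values + _ar1_noise(n_minutes, noise.sigma, noise.ar_coefficient, rng)

    if noise.transient_magnitude > 0 and noise.transient_duration > 0:
        dur = min(noise.transient_duration, n_minutes)
        ramp = np.arange(dur) / float(noise.transient_duration)
        values[:dur] -= noise.transient_magnitude * (1.0 - ramp)

    if noise.quantization_step > 0:
        values = np.round(values / noise.quantization_step) * noise.quantization_step

    if noise.missing_fraction > 0:
        values = values.copy()
        values[_missing_mask(n_minutes, noise.missing_fraction, rng)] = np.nan

    truth = dict(params, label=archetype.label)
    return RawRecording(
        subject_id=f"S{seed:06d}", start_time=start_time, values=values, truth=truth
    )


def _sleep_onsets(
    archetype: ArchetypeSpec, dsp: bool, n_nights: int, rng: np.random.Generator
) -> np.ndarray:
    """Nightly onsets on the 18:00-anchored scale, consistent with the DSP label.

    A DSP subject gets at least 4 of 8 onsets after 01:00 (anchored > 7 h);
    a non-DSP subject at most 2 — so the rule-based classifier recovers the
    label exactly at zero noise.
    """
    mean = anchored_hours(archetype.sleep_onset_mean)
    onsets = rng.normal(mean, archetype.sleep_onset_sd / 60.0, size=n_nights)
    late_cut = anchored_hours(1.0)  # 01:00 -> 7 h after 18:00
    late = onsets > late_cut
    need_late = max(4, int(np.ceil(n_nights / 2))) if dsp else 0
    max_late = n_nights if dsp else 2
    if late.sum() < need_late:
        order = np.argsort(-onsets)  # latest first: shift the closest candidates
        for idx in order:
            if late.sum() >= need_late:
                break
            if not late[idx]:
                onsets[idx] = late_cut + abs(rng.normal(0.75, 0.5))
                late = onsets > late_cut
    elif late.sum() > max_late:
        order = np.argsort(onsets)  # earliest of the late ones moved back first
        for idx in order:
            if late.sum() <= max_late:
                break
            if late[idx]:
                onsets[idx] = late_cut - abs(rng.normal(0.75, 0.5))
                late = onsets > late_cut
    return onsets


def _meq_items(archetype: ArchetypeSpec, rng: np.random.Generator) -> dict[str, int]:
    lo = sum(r[0] for r in MEQ_ITEM_RANGES.values())
    hi = sum(r[1] for r in MEQ_ITEM_RANGES.values())
    total = int(round(np.clip(rng.normal(archetype.meq_mean, archetype.meq_sd), lo, hi)))
    items = {k: r[0] for k, r in MEQ_ITEM_RANGES.items()}
    remaining = total - lo
    keys = list(MEQ_ITEM_RANGES)
    while remaining > 0:
        open_keys = [k for k in keys if items[k] < MEQ_ITEM_RANGES[k][1]]
        k = open_keys[rng.integers(len(open_keys))]
        items[k] += 1
        remaining -= 1
    return items


def generate_cohort(
    archetypes: list[ArchetypeSpec] | None = None,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    n_nights: int = 8,
    age_mean: float = 16.9,
    age_sd: float = 0.12,
    bmi_mean: float = 21.7,
    bmi_sd: float = 3.0,
    male_prob: float = 0.30,
) -> CohortBundle:
    """Simulate a full cohort: recordings, sleep diaries, MEQ items, demographics.

    Subjects are generated archetype by archetype with independent child
    seeds, so a fixed ``seed`` reproduces the bundle bit-for-bit.
    """
    seed = check_seed(seed)
    archetypes = archetypes if archetypes is not None else default_archetypes()
    if not archetypes:
        raise ValueError("at least one archetype is required")
    noise = noise if noise is not None else default_noise()

    rec_seed_seq, behaviour_seq = np.random.SeedSequence(seed).spawn(2)
    rec_seeds = rec_seed_seq.generate_state(sum(a.n_subjects for a in archetypes))
    rng = np.random.default_rng(behaviour_seq)

    recordings: list[RawRecording] = []
    sleep_rows, meq_rows, demo_rows, truth_rows = [], [], [], []
    sid = 0
    for arch in archetypes:
        for _ in range(arch.n_subjects):
            rec = generate_series(arch, noise, seed=int(rec_seeds[sid] % 2**31))
            subject_id = f"S{sid:04d}"
            rec.subject_id = subject_id
            recordings.append(rec)

            dsp = bool(rng.random() < arch.dsp_prob)
            onsets_anchored = _sleep_onsets(arch, dsp, n_nights, rng)
            for night, onset_a in enumerate(onsets_anchored):
                duration = rng.normal(8.0, 40.0 / 60.0)
                sol = max(rng.normal(20.0, 8.0), 0.0) / 60.0
                waso = max(rng.normal(55.0, 15.0), 0.0)
                # night 0 onset falls on the evening/night after day 0
                onset = _BASE_DATE + pd.Timedelta(hours=18.0 + onset_a + 24.0 * night)
                sleep_rows.append(
                    {
                        "subject_id": subject_id,
                        "night": night,
                        "bedtime": onset - pd.Timedelta(hours=sol),
                        "onset": onset,
                        "offset": onset + pd.Timedelta(hours=duration),
                        "waso_min": round(waso, 1),
                    }
                )
            meq_rows.append({"subject_id": subject_id, **_meq_items(arch, rng)})
            demo_rows.append(
                {
                    "subject_id": subject_id,
                    "sex": "male" if rng.random() < male_prob else "female",
                    "age": round(rng.normal(age_mean, age_sd), 2),
                    "bmi": round(rng.normal(bmi_mean, bmi_sd), 2),
                }
            )
            truth_rows.append(
                {"subject_id": subject_id, "label": arch.label, "dsp": dsp, **rec.truth}
            )
            sid += 1

    return CohortBundle(
        recordings=recordings,
        sleep=pd.DataFrame(sleep_rows),
        meq=pd.DataFrame(meq_rows),
        demographics=pd.DataFrame(demo_rows),
        truth=pd.DataFrame(truth_rows),
    )
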