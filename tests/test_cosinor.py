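"""Cosinor fitting, period search, acrophase quadrants, observed extrema."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import circatemp as ct
from circatemp._utils import hhmm_to_hours
from circatemp.cosinor import CosinorFit
from circatemp.preprocessing import SmoothedSeries


def _curve(t, mesor, amp, tau, phi):
    return mesor + amp * np.cos(2 * np.pi * t / tau + phi)


class TestFixedPeriodFit:
    def test_exact_recovery(self, minute_grid_48h):
        y = _curve(minute_grid_48h, 34.0, 2.0, 24.0, 0.0)
        f = ct.fit_fixed_period(y, 24.0)
        assert f.mesor == pytest.approx(34.0, abs=1e-9)
        assert f.amplitude == pytest.approx(2.0, abs=1e-9)
        assert f.acrophase == pytest.approx(0.0, abs=1e-9)

    def test_constant_series(self):
        f = ct.fit_fixed_period(np.full(2880, 33.0), 24.0)
        assert f.mesor == pytest.approx(33.0)
        assert f.amplitude == 0.0
        assert f.rss == pytest.approx(0.0, abs=1e-18)

    def test_matches_brute_force_grid_oracle(self, minute_grid_48h):
        rng = np.random.default_rng(8)
        y = _curve(minute_grid_48h, 34.0, 1.5, 24.0, 1.0) + rng.normal(0, 0.4, 2880)
        f = ct.fit_fixed_period(y, 24.0)
        # independent oracle: dense grid search over (M, A, phi)
        best, best_rss = None, np.inf
        for m in np.linspace(33.8, 34.2, 21):
            for a in np.linspace(1.2, 1.8, 31):
                for p in np.linspace(0.8, 1.2, 41):
                    rss = np.sum((y - _curve(minute_grid_48h, m, a, 24.0, p)) ** 2)
                    if rss < best_rss:
                        best, best_rss = (m, a, p), rss
        assert f.mesor == pytest.approx(best[0], abs=0.02)
        assert f.amplitude == pytest.approx(best[1], abs=0.02)
        assert f.acrophase == pytest.approx(best[2], abs=0.02)

    def test_singular_design_rejected(self, minute_grid_48h):
        with pytest.raises(ValueError):
            ct.fit_fixed_period(np.ones(2880), 1e6)

    def test_roundtrip_refit_identical(self, minute_grid_48h):
        y = _curve(minute_grid_48h, 33.5, 1.2, 25.3, -2.1)
        f1 = ct.fit_fixed_period(y, 25.3)
        f2 = ct.fit_fixed_period(f1.curve(minute_grid_48h), 25.3)
        for attr in ("mesor", "amplitude", "acrophase"):
            assert getattr(f1, attr) == pytest.approx(getattr(f2, attr), abs=1e-9)


class TestPeriodSearch:
    def test_noiseless_recovery(self, minute_grid_48h):
        y = _curve(minute_grid_48h, 34.0, 1.5, 25.0, 0.7)
        f = ct.estimate_period(y)
        assert f.period == pytest.approx(25.0, abs=1 / 60.0)

    def test_24h_not_pushed_to_boundary(self, minute_grid_48h):
        y = _curve(minute_grid_48h, 34.0, 1.5, 24.0, 0.0)
        f = ct.estimate_period(y, tau_range=(20.0, 30.0))
        assert f.period == pytest.approx(24.0, abs=1 / 60.0)
        assert 20.5 < f.period < 29.5

    def test_constant_series_period_undefined(self):
        f = ct.estimate_period(np.full(2880, 33.0))
        assert math.isnan(f.period)
        assert f.amplitude == 0.0

    def test_search_beats_fixed_24h_rss(self, minute_grid_48h):
        rng = np.random.default_rng(9)
        y = _curve(minute_grid_48h, 34.0, 1.5, 25.75, 0.3) + rng.normal(0, 0.3, 2880)
        assert ct.estimate_period(y).rss <= ct.fit_fixed_period(y, 24.0).rss + 1e-9

    def test_mean_period_recovery_under_noise(self):
        """Period estimates at tau=25.75 are unbiased within 0.15 h."""
        noise = ct.NoiseSpec.from_marginal_sd(0.4, transient_magnitude=0.0,
                                              missing_fraction=0.0)
        arch = ct.default_archetypes()[0]
        taus = []
        for s in range(100):
            rec = ct.generate_series(arch, noise, seed=500 + s,
                                     param_sds=(0.15, 0.15, 0.0))
            taus.append(ct.estimate_period(ct.harmonize_start(rec)).period)
        assert np.mean(taus) == pytest.approx(arch.period, abs=0.15)

    def test_too_fine_resolution_rejected(self):
        with pytest.raises(ValueError):
            ct.estimate_period(np.ones(100), resolution_h=1e-6)


class TestCorrectedAcrophase:
    @pytest.mark.parametrize(
        "beta,gamma,phi,peak_frac",
        [
            (1.0, 0.0, 0.0, 0.0),       # peak at t=0
            (0.0, 1.0, -np.pi / 2, 0.25),  # peak at tau/4
            (-1.0, 0.0, np.pi, 0.5),
            (0.0, -1.0, np.pi / 2, 0.75),
        ],
    )
    def test_quadrant_cases(self, beta, gamma, phi, peak_frac):
        got = ct.corrected_acrophase(beta, gamma)
        assert got == pytest.approx(phi, abs=1e-12)
        tau = 24.0
        peak = (-got * tau / (2 * np.pi)) % tau
        assert peak == pytest.approx(peak_frac * tau, abs=1e-9)

    def test_zero_amplitude_rejected(self):
        with pytest.raises(ValueError):
            ct.corrected_acrophase(0.0, 0.0)

    def test_peak_matches_argmax_oracle(self):
        """1000 random (beta, gamma): phi-derived peak = brute-force argmax
        of the reconstructed curve on a 1-second grid, within 2 s."""
        rng = np.random.default_rng(10)
        tau = 24.0
        t = np.arange(0, tau, 1.0 / 3600.0)
        for _ in range(1000):
            beta, gamma = rng.normal(size=2)
            if math.hypot(beta, gamma) < 1e-3:
                continue
            phi = ct.corrected_acrophase(beta, gamma)
            peak = (-phi * tau / (2 * np.pi)) % tau
            curve = beta * np.cos(2 * np.pi * t / tau) + gamma * np.sin(2 * np.pi * t / tau)
            brute = t[np.argmax(curve)]
            diff = min(abs(peak - brute), tau - abs(peak - brute))
            assert diff <= 2.0 / 3600.0

    @settings(max_examples=200, derandomize=True)
    @given(st.floats(-10, 10), st.floats(-10, 10))
    def test_identity_beta_gamma(self, beta, gamma):
        """beta = A cos(phi) and gamma = -A sin(phi) hold in every quadrant."""
        if math.hypot(beta, gamma) < 1e-6:
            return
        phi = ct.corrected_acrophase(beta, gamma)
        a = math.hypot(beta, gamma)
        assert beta == pytest.approx(a * math.cos(phi), abs=1e-9)
        assert gamma == pytest.approx(-a * math.sin(phi), abs=1e-9)
        assert -math.pi < phi <= math.pi


class TestClockTimes:
    def test_24h_phase_zero(self):
        f = CosinorFit(34.0, 1.0, 0.0, 24.0, 1.0, 0.0, 0.0)
        acro, bathy = ct.extrema_clock_times(f, t0_clock=12.0)
        assert (acro, bathy) == ("12:00", "00:00")

    def test_half_cycle_shift(self):
        f = CosinorFit(34.0, 1.0, math.pi, 24.0, -1.0, 0.0, 0.0)
        acro, _ = ct.extrema_clock_times(f, t0_clock=12.0)
        assert acro == "00:00"

    def test_random_fits_match_argmax_oracle(self):
        """Reported clock time = first interior local maximum of the curve."""
        rng = np.random.default_rng(12)
        for _ in range(50):
            tau = rng.uniform(20, 30)
            phi = rng.uniform(-np.pi, np.pi)
            f = CosinorFit(34.0, 1.0, phi, tau,
                           math.cos(phi), -math.sin(phi), 0.0)
            acro, _ = ct.extrema_clock_times(f, t0_clock=12.0)
            # oracle: scan two periods and take the first strict local max
            t = np.arange(0, 2 * tau, 1.0 / 60.0)
            c = f.curve(t)
            interior = np.flatnonzero((c[1:-1] > c[:-2]) & (c[1:-1] >= c[2:])) + 1
            brute_peak = (12.0 + t[interior[0]]) % 24.0
            got = hhmm_to_hours(acro)
            diff = min(abs(got - brute_peak), 24.0 - abs(got - brute_peak))
            assert diff <= 1.5 / 60.0

    def test_zero_amplitude_undefined(self):
        f = CosinorFit(34.0, 0.0, math.nan, 24.0, 0.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            ct.extrema_clock_times(f)


class TestObservedExtrema:
    @staticmethod
    def _smoothed(values):
        return SmoothedSeries("x", values, "loess", 0.3)

    def test_pure_24h_cosine_peaking_0230(self, minute_grid_48h):
        # peak at 02:30 clock = 14.5 h after window start (noon)
        y = 34 + np.cos(2 * np.pi * (minute_grid_48h - 14.5) / 24.0)
        obs = ct.observed_extrema(self._smoothed(y))
        assert obs.acrophase_clock == "02:30"

    def test_circular_mean_of_two_cycles(self):
        # cycle peaks at 02:00 then 03:00 -> circular mean 02:30
        n = 2880
        y = np.zeros(n)
        y[int(14.0 * 60)] = 1.0   # 02:00 in cycle 1
        y[1440 + int(15.0 * 60)] = 1.0  # 03:00 in cycle 2
        y[10] = -1.0
        y[1440 + 10] = -1.0
        obs = ct.observed_extrema(self._smoothed(y))
        assert obs.acrophase_clock == "02:30"

    def test_wraparound_mean(self):
        # peaks 23:30 and 00:30 -> 00:00, not 12:00
        y = np.zeros(2880)
        y[int(11.5 * 60)] = 1.0   # 23:30 in cycle 1
        y[1440 + int(12.5 * 60)] = 1.0  # 00:30 in cycle 2
        y[5], y[1445] = -1.0, -1.0
        obs = ct.observed_extrema(self._smoothed(y))
        assert obs.acrophase_clock == "00:00"

    def test_all_constant_rejected(self):
        with pytest.raises(ValueError):
            ct.observed_extrema(self._smoothed(np.ones(2880)))

    def test_model_and_observed_agree_on_noiseless_input(self, minute_grid_48h):
        y = _curve(minute_grid_48h, 34.0, 1.5, 24.0, -2.0)
        f = ct.estimate_period(y)
        obs = ct.observed_extrema(self._smoothed(y))
        model_acro = hhmm_to_hours(f.acrophase_clock)
        observed = hhmm_to_hours(obs.acrophase_clock)
        diff = min(abs(model_acro - observed), 24 - abs(model_acro - observed))
        assert diff <= 2.0 / 60.0
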