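"""Raw-recording preprocessing: start harmonization, imputation, smoothing.

Recordings start at jittered evening times and carry a warm-up transient in
the first hours, so every record is re-anchored to the first noon after its
start ("12 p.m." read as noon) and cut to a canonical 48-h window of 2880
minute samples.  Missing cells are then filled by a regularized iterative
principal-components scheme operating across subjects, and each series is
smoothed with degree-2 loess (tricube weights) or, for the sensitivity
analysis, a generalized-cross-validated cubic smoothing spline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import LSQUnivariateSpline, make_smoothing_spline
from sklearn.base import BaseEstimator, TransformerMixin

from .simulate import RawRecording

__all__ = [
    "TemperatureSeries",
    "SmoothedSeries",
    "UnusableRecordingError",
    "harmonize_start",
    "IterativePCAImputer",
    "impute_missing",
    "LoessSmoother",
    "loess_smooth",
    "SplineSmoother",
    "spline_smooth",
    "sensitivity_filter",
]

WINDOW_MINUTES = 48 * 60  # canonical harmonized length
PHYSIO_BOUNDS = (20.0, 42.0)


class UnusableRecordingError(ValueError):
    """Raised when a recording cannot cover the canonical 48-h window."""


@dataclass
class TemperatureSeries:
    """A harmonized 48-h, minute-resolution temperature series.

    ``t0`` is the clock time of the first sample (noon after harmonization);
    ``values`` holds NaN at missing samples until imputation, after which
    ``missing_mask`` still records which cells were filled.
    """

    subject_id: str
    t0: pd.Timestamp
    values: np.ndarray
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.values)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)

    @property
    def t_hours(self) -> np.ndarray:
        """Hours since window start (noon)."""
        return np.arange(len(self.values)) / 60.0


@dataclass
class SmoothedSeries:
    subject_id: str
    values: np.ndarray
    method: str
    span_or_penalty: float

    @property
    def t_hours(self) -> np.ndarray:
        return np.arange(len(self.values)) / 60.0


def harmonize_start(raw: RawRecording, window_minutes: int = WINDOW_MINUTES) -> TemperatureSeries:
    """Re-anchor a recording to the first noon at/after its start and cut 48 h.

    Samples before noon are dropped (a start at exactly noon keeps its first
    sample); samples beyond the 48-h window are discarded; minutes the
    recording does not cover are flagged missing.  A recording too short to
    reach the end of the window raises :class:`UnusableRecordingError`.
    """
    start = raw.start_time
    noon = start.normalize() + pd.Timedelta(hours=12)
    if start > noon:
        noon += pd.Timedelta(days=1)
    offset = int((noon - start).total_seconds() // 60)
    end_needed = offset + window_minutes
    if end_needed > len(raw.values):
        raise UnusableRecordingError(
            f"{raw.subject_id}: recording covers only "
            f"{len(raw.values) - offset} of {window_minutes} minutes after noon"
        )
    values = np.asarray(raw.values, dtype=float)[offset:end_needed].copy()
    return TemperatureSeries(subject_id=raw.subject_id, t0=noon, values=values)


# ---------------------------------------------------------------------------
# imputation


class IterativePCAImputer(TransformerMixin, BaseEstimator):
    """Regularized iterative principal-components imputation.

    Missing cells of the subjects x timepoints matrix are initialized at
    column means, then the matrix is repeatedly column-centered, approximated
    at rank ``n_components`` with singular values shrunk by the mean residual
    variance (a soft, regularized truncation that avoids overfitting the
    missing cells), and only the missing cells are refilled — until the
    largest change falls below ``tol``.  Observed cells are never altered.

    Attributes
    ----------
    n_iter_ : int
        Iterations run.
    converged_ : bool
        False if the loop hit ``max_iter`` (a warning is issued).
    """

    def __init__(self, n_components: int = 2, tol: float = 1e-6, max_iter: int = 1000):
        self.n_components = n_components
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None):
        self.fit_transform(X)
        return self

    def fit_transform(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        mask = np.isnan(X)
        if not mask.any():
            self.n_iter_, self.converged_ = 0, True
            return X.copy()
        if mask.all(axis=0).any():
            raise ValueError("every column must have at least one observed value")

        filled = X.copy()
        col_means = np.nanmean(X, axis=0)
        filled[mask] = np.take(col_means, np.nonzero(mask)[1])

        ncp = min(self.n_components, min(filled.shape) - 1)
        self.converged_ = False
        for it in range(1, self.max_iter + 1):
            mu = filled.mean(axis=0)
            centered = filled - mu
            u, s, vt = np.linalg.svd(centered, full_matrices=False)
            tail = s[ncp:]
            sigma2 = float(np.mean(tail**2)) if tail.size else 0.0
            s_shrunk = np.maximum(s[:ncp] - sigma2 / np.where(s[:ncp] > 0, s[:ncp], 1.0), 0.0)
            approx = (u[:, :ncp] * s_shrunk) @ vt[:ncp] + mu
            delta = np.max(np.abs(approx[mask] - filled[mask]))
            filled[mask] = approx[mask]
            if delta < self.tol:
                self.converged_ = True
                break
        self.n_iter_ = it
        if not self.converged_:
            warnings.warn("iterative PCA imputation did not converge", RuntimeWarning)
        return filled

    def transform(self, X):
        # stateless by design: each matrix is completed on its own
        return self.fit_transform(X)


def impute_missing(matrix: np.ndarray, ncp: int = 2, tol: float = 1e-6,
                   max_iter: int = 1000) -> np.ndarray:
    """Functional wrapper over :class:`IterativePCAImputer`."""
    return IterativePCAImputer(n_components=ncp, tol=tol, max_iter=max_iter).fit_transform(matrix)


# ---------------------------------------------------------------------------
# loess smoothing


def _loess_kernel_matrix(n: int, span: float, degree: int) -> np.ndarray:
    """Equivalent-kernel rows of a uniform-grid loess smoother.

    On a uniform grid the fitted value at each point is a fixed linear
    functional of the q nearest observations, so the whole smoother is an
    n x q kernel matrix: one shared row for interior points and individual
    rows near the boundaries.
    """
    if not 0.0 < span <= 1.0:
        raise ValueError(f"span must lie in (0, 1], got {span}")
    q = max(int(np.ceil(span * n)), degree + 2)
    q = min(q, n)
    half = (q - 1) // 2

    def kernel_row(center: int, start: int) -> np.ndarray:
        dx = np.arange(start, start + q, dtype=float) - center
        dmax = np.abs(dx).max()
        w = (1.0 - (np.abs(dx) / dmax) ** 3) ** 3
        w = np.maximum(w, 0.0)
        X = np.vander(dx, degree + 1, increasing=True)
        XtW = X.T * w
        try:
            beta_map = np.linalg.solve(XtW @ X, XtW)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"loess span {span} gives a singular local design") from exc
        return beta_map[0]  # intercept row = fitted value at the center

    kernels = np.empty((n, q))
    starts = np.clip(np.arange(n) - half, 0, n - q)
    interior = kernel_row(half, 0)  # shared by all un-clipped windows
    for i in range(n):
        if starts[i] == i - half:
            kernels[i] = interior
        else:
            kernels[i] = kernel_row(i, starts[i])
    return kernels


_KERNEL_CACHE: dict[tuple[int, float, int], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}


def _loess_apply(values: np.ndarray, span: float, degree: int) -> np.ndarray:
    n = len(values)
    key = (n, span, degree)
    if key not in _KERNEL_CACHE:
        kernels = _loess_kernel_matrix(n, span, degree)
        q = kernels.shape[1]
        starts = np.clip(np.arange(n) - (q - 1) // 2, 0, n - q)
        interior = starts == np.arange(n) - (q - 1) // 2
        _KERNEL_CACHE[key] = (kernels, starts, interior)
    kernels, starts, interior = _KERNEL_CACHE[key]
    q = kernels.shape[1]
    out = np.empty(n)
    first = int(np.argmax(interior))
    # interior points share one equivalent kernel -> a single convolution
    conv = np.convolve(values, kernels[first][::-1], mode="valid")
    out[interior] = conv[starts[interior]]
    for i in np.flatnonzero(~interior):
        out[i] = kernels[i] @ values[starts[i] : starts[i] + q]
    return out


class LoessSmoother(TransformerMixin, BaseEstimator):
    """Degree-2 loess with tricube weights on a uniform minute grid.

    ``transform`` accepts a (n_subjects, n_timepoints) matrix and smooths
    each row; ``span`` is the fraction of points in each local window.
    """

    def __init__(self, span: float = 0.3, degree: int = 2):
        self.span = span
        self.degree = degree

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if np.isnan(X).any():
            raise ValueError("smoothing requires an imputed (NaN-free) matrix")
        return np.vstack([_loess_apply(row, self.span, self.degree) for row in X])


def loess_smooth(series: TemperatureSeries, span: float = 0.3) -> SmoothedSeries:
    smoothed = LoessSmoother(span=span).transform(series.values[None, :])[0]
    return SmoothedSeries(series.subject_id, smoothed, method="loess", span_or_penalty=span)


# ---------------------------------------------------------------------------
# spline smoothing


class SplineSmoother(TransformerMixin, BaseEstimator):
    """Penalized cubic smoothing spline, penalty chosen by GCV.

    ``gcv_stride`` thins the minute grid before the GCV solve (the spline is
    still evaluated at every minute); on these heavily oversampled series
    this cuts the cost several-fold at a sub-resolution change in the fit.
    If GCV degenerates to a near-interpolating fit (noiseless input), the
    smoother falls back to a least-squares regression spline with
    ``fallback_df`` effective degrees of freedom and warns.
    """

    def __init__(self, fallback_df: int = 30, gcv_stride: int = 4):
        self.fallback_df = fallback_df
        self.gcv_stride = gcv_stride

    def fit(self, X, y=None):
        return self

    def _smooth_one(self, values: np.ndarray) -> np.ndarray:
        n = len(values)
        x = np.arange(n) / 60.0
        s = max(int(self.gcv_stride), 1)
        try:
            spl = make_smoothing_spline(x[::s], values[::s])
            out = spl(x)
            resid_var = float(np.var(values - out))
            if resid_var > 1e-12 * max(float(np.var(values)), 1.0):
                return out
            raise RuntimeError("GCV chose an interpolating fit")
        except (RuntimeError, np.linalg.LinAlgError):
            warnings.warn(
                "GCV degenerate; falling back to a fixed-df regression spline",
                RuntimeWarning,
            )
            n_knots = max(self.fallback_df - 4, 1)
            knots = np.linspace(x[0], x[-1], n_knots + 2)[1:-1]
            return LSQUnivariateSpline(x, values, knots, k=3)(x)

    def transform(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if np.isnan(X).any():
            raise ValueError("smoothing requires an imputed (NaN-free) matrix")
        return np.vstack([self._smooth_one(row) for row in X])


def spline_smooth(series: TemperatureSeries) -> SmoothedSeries:
    smoothed = SplineSmoother().transform(series.values[None, :])[0]
    return SmoothedSeries(series.subject_id, smoothed, method="spline", span_or_penalty=np.nan)


# ---------------------------------------------------------------------------
# smoother-sensitivity exclusion


def sensitivity_filter(
    fits_loess: dict[str, "CosinorFit"],
    fits_spline: dict[str, "CosinorFit"],
    period_threshold_h: float = 2.0,
    amplitude_rel_threshold: float = 0.25,
) -> tuple[list[str], pd.DataFrame]:
    """Exclude subjects whose cosinor fit depends strongly on the smoother.

    A subject is excluded when the loess- and spline-based fits disagree by
    more than ``period_threshold_h`` hours in period, or by more than
    ``amplitude_rel_threshold`` relative amplitude.  Returns the kept
    subject ids and a frame of exclusions with reasons.
    """
    if set(fits_loess) != set(fits_spline):
        raise ValueError("loess and spline fit lists must cover the same subjects")
    kept, rows = [], []
    for sid in fits_loess:
        fl, fs = fits_loess[sid], fits_spline[sid]
        reasons = []
        if abs(fl.period - fs.period) > period_threshold_h:
            reasons.append("period")
        amax = max(fl.amplitude, fs.amplitude)
        if amax > 0 and abs(fl.amplitude - fs.amplitude) / amax > amplitude_rel_threshold:
            reasons.append("amplitude")
        if reasons:
            rows.append({"subject_id": sid, "reason": "+".join(reasons)})
        else:
            kept.append(sid)
    return kept, pd.DataFrame(rows, columns=["subject_id", "reason"])
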