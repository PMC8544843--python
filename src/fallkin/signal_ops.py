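"""Signal-processing primitives for marker trajectories.

All operations work on :class:`Series` — a uniformly sampled real sequence
with a sample rate and start time.  The processing chain used on the video
side is: calibrate (pixels to metres) -> dual-pass low-pass filter at the
native 30 Hz rate -> upsample to 600 Hz by cubic spline -> synchronize to
the ground truth by cross-correlation -> differentiate by central
differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as _sig
from scipy.interpolate import CubicSpline


@dataclass(frozen=True)
class Series:
    """A uniformly sampled scalar time series."""

    values: np.ndarray
    sample_rate: float  # Hz
    start_time: float = 0.0  # s

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1:
            raise ValueError("Series values must be 1-D")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self.values)) * self.dt

    @property
    def duration(self) -> float:
        return (len(self.values) - 1) * self.dt


@dataclass(frozen=True)
class FilterSpec:
    """Dual-pass Butterworth low-pass filter parameters.

    ``order`` is the per-pass order (default 4); the forward-backward
    application doubles the effective magnitude order and cancels phase.
    No cutoff pre-warping is applied: the stated cutoff is the per-pass
    -3 dB point, so the dual-pass gain there is 0.5 (power), i.e. the
    amplitude ratio is 1/2 for each squared pass — standard biomechanics
    practice.
    """

    cutoff: float  # Hz
    order: int = 4
    passes: str = "dual"

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.passes != "dual":
            raise ValueError("only dual-pass filtering is supported")


class FlatSignalError(ValueError):
    """Cross-correlation is undefined for a zero-variance signal."""


def lowpass_dualpass(s: Series, spec: FilterSpec) -> Series:
    """Zero-phase low-pass filter (forward-backward Butterworth).

    Edge transients are suppressed by reflective (even) padding of three
    filter lengths on each end, discarded after filtering; DC gain is
    exactly 1, so a constant series is returned unchanged.
    """
    nyq = s.sample_rate / 2.0
    if spec.cutoff >= nyq:
        raise ValueError(f"cutoff {spec.cutoff} Hz >= Nyquist {nyq} Hz")
    padlen = 3 * (spec.order + 1)
    if len(s) <= padlen:
        raise ValueError(
            f"series of length {len(s)} too short for order-{spec.order} dual-pass "
            f"filtering (needs > {padlen} samples)"
        )
    b, a = _sig.butter(spec.order, spec.cutoff / nyq, btype="low")
    out = _sig.filtfilt(b, a, s.values, padtype="even", padlen=padlen)
    return replace(s, values=out)


def resample_to(s: Series, target_rate: float, kind: str = "cubic") -> Series:
    """Resample to ``target_rate`` preserving total duration.

    Cubic-spline interpolation on positions by default (so differentiated
    velocities are continuous); ``kind="linear"`` is available.  When the
    target rate is an integer multiple of the source rate the original
    sample instants are reproduced exactly.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if target_rate == s.sample_rate:
        return s
    n_new = int(round(s.duration * target_rate)) + 1
    t_new = s.start_time + np.arange(n_new) / target_rate
    if kind == "cubic":
        interp = CubicSpline(s.times, s.values)
    elif kind == "linear":
        def interp(t):  # noqa: E731-style closure keeps the two branches symmetric
            return np.interp(t, s.times, s.values)
    else:
        raise ValueError(f"unknown interpolation kind {kind!r}")
    return Series(interp(t_new), sample_rate=target_rate, start_time=s.start_time)


def sync_lag(reference: Series, test: Series, max_lag: float = 2.0) -> float:
    """Lag (s) of ``test`` relative to ``reference`` by cross-correlation.

    Both series must share a sample rate (resample first).  Returns the lag
    maximizing the normalized cross-correlation over integer sample shifts
    within ``±max_lag`` seconds; shifting ``test`` by ``-lag`` aligns it
    with the reference.  Ties break toward the smaller ``|lag|``.
    """
    if reference.sample_rate != test.sample_rate:
        raise ValueError("reference and test must share a sample rate")
    a = reference.values - reference.values.mean()
    b = test.values - test.values.mean()
    if not (np.any(a) and np.any(b)):
        raise FlatSignalError("cross-correlation undefined for flat signal")
    rate = reference.sample_rate
    max_shift = int(round(max_lag * rate))
    a = reference.values
    b = test.values
    n, m = len(a), len(b)
    cc = _sig.correlate(a, b, mode="full")
    lags = np.arange(-(m - 1), n)
    keep = np.abs(lags) <= max_shift
    cc, lags = cc[keep], lags[keep]
    min_overlap = 0.5 * min(n, m)
    # Pearson correlation per overlap window (zero-normalized): exactly 1
    # for identical content, immune to window-mean and overlap-length bias
    csum_a = np.concatenate([[0.0], np.cumsum(a)])
    csum_a2 = np.concatenate([[0.0], np.cumsum(a**2)])
    csum_b = np.concatenate([[0.0], np.cumsum(b)])
    csum_b2 = np.concatenate([[0.0], np.cumsum(b**2)])
    lo_a = np.maximum(0, lags)
    hi_a = np.minimum(n, m + lags)
    overlap = hi_a - lo_a
    valid = overlap >= min_overlap
    if not np.any(valid):
        raise ValueError("no lag satisfies the 50% overlap requirement")
    sa = csum_a[hi_a] - csum_a[lo_a]
    saa = csum_a2[hi_a] - csum_a2[lo_a]
    sb = csum_b[hi_a - lags] - csum_b[lo_a - lags]
    sbb = csum_b2[hi_a - lags] - csum_b2[lo_a - lags]
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = cc - sa * sb / overlap
        var = (saa - sa**2 / overlap) * (sbb - sb**2 / overlap)
        ncc = np.where(valid & (var > 0), cov / np.sqrt(var), -np.inf)
    best = ncc.max()
    candidates = lags[ncc >= best - 1e-9]
    lag_samples = candidates[np.argmin(np.abs(candidates))]
    # reference leads: test delayed by -lag_samples relative to reference
    return float(-lag_samples / rate)


def shift_series(s: Series, lag_seconds: float) -> Series:
    """Shift a series in time by an integer number of samples (nearest)."""
    k = int(round(lag_seconds * s.sample_rate))
    v = s.values
    if k > 0:
        out = np.concatenate([np.full(k, v[0]), v[:-k]]) if k < len(v) else np.full_like(v, v[0])
    elif k < 0:
        k = -k
        out = np.concatenate([v[k:], np.full(k, v[-1])]) if k < len(v) else np.full_like(v, v[-1])
    else:
        out = v.copy()
    return replace(s, values=out)


def central_difference(s: Series) -> Series:
    """First-order central-difference derivative.

    Interior samples use ``(x[i+1] - x[i-1]) / (2 dt)``; endpoints use
    one-sided differences, so the output length equals the input length.
    """
    if len(s) < 3:
        raise ValueError("central difference needs at least 3 samples")
    return replace(s, values=np.gradient(s.values, s.dt))


def energy_fraction_above(s: Series, f: float) -> float:
    """Fraction of spectral energy (DC excluded) at frequencies above ``f``.

    Energy is the squared magnitude of the discrete Fourier transform of
    the raw sequence.  ``f`` at or above Nyquist returns 0 by convention,
    with a warning.
    """
    if len(s) < 8:
        raise ValueError("need at least 8 samples for a spectral estimate")
    nyq = s.sample_rate / 2.0
    if f >= nyq:
        warnings.warn(
            f"threshold {f} Hz at or above Nyquist {nyq} Hz; returning 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    spec = np.fft.rfft(s.values)
    freqs = np.fft.rfftfreq(len(s), s.dt)
    power = np.abs(spec[1:]) ** 2  # exclude DC
    total = power.sum()
    if total == 0:
        return 0.0
    return float(power[freqs[1:] > f].sum() / total)
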