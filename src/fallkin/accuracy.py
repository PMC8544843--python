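"""Accuracy measures comparing a test signal set to ground truth.

Conventions (applied uniformly and worth stating once):

* RMSE is computed between fall onset and fall end.
* NRMSE is RMSE as a percent of the *reference* signal's peak-to-peak
  amplitude over that interval — "amplitude" here means the range of the
  ground-truth signal, since it is the stable side of the comparison.
* Peak differences are signed test − reference (video − motion capture),
  so an overestimate is positive; the percent form divides by the
  magnitude of the reference peak.
* Percent measures are computed per fall, then averaged across falls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as _stats

OUTCOMES = ("pos_v", "pos_h", "pos_ang", "vel_v", "vel_h", "vel_ang")


@dataclass(frozen=True)
class AccuracyRecord:
    """One fall x body part (or segment) x outcome comparison."""

    trial_id: str
    body_part: str
    outcome: str  # one of OUTCOMES
    rmse: float
    nrmse: float  # %
    peak_diff_raw: float = math.nan  # signed; velocities only
    peak_diff_pct: float = math.nan  # signed %; velocities only

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.rmse < 0 or self.nrmse < 0:
            raise ValueError("rmse and nrmse must be non-negative")


@dataclass(frozen=True)
class AgreementFit:
    """OLS agreement between test and reference peak values."""

    slope: float
    intercept: float
    r_squared: float
    mean_signed_error: float  # %, mean of per-pair signed percent error

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared outside [0, 1]")


def _slice(values: np.ndarray, interval: Tuple[int, int] | None) -> np.ndarray:
    if interval is None:
        return np.asarray(values, dtype=float)
    i0, i1 = interval
    return np.asarray(values, dtype=float)[i0:i1]


def rmse(test: Sequence[float], ref: Sequence[float],
         interval: Tuple[int, int] | None = None) -> float:
    """Root-mean-square difference over the (half-open) frame interval."""
    a = _slice(test, interval)
    b = _slice(ref, interval)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch after alignment: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("empty comparison interval")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def nrmse(test: Sequence[float], ref: Sequence[float],
          interval: Tuple[int, int] | None = None) -> float:
    """RMSE as a percent of the reference peak-to-peak amplitude."""
    b = _slice(ref, interval)
    amp = float(b.max() - b.min()) if b.size else 0.0
    if amp <= 0:
        raise ValueError("reference amplitude is zero; NRMSE undefined")
    return 100.0 * rmse(test, ref, interval) / amp


def peak_difference(test_peak: float, ref_peak: float) -> Tuple[float, float]:
    """Signed raw and percent difference between peak values.

    Raw = test − reference; percent = 100 · raw / |reference|.  Positive
    values mean the test instrument overestimated the peak.
    """
    if ref_peak == 0:
        raise ValueError("reference peak is zero; percent difference undefined")
    raw = test_peak - ref_peak
    return raw, 100.0 * raw / abs(ref_peak)


def linear_agreement(test_peaks: Sequence[float],
                     ref_peaks: Sequence[float]) -> AgreementFit:
    """OLS fit of test on reference peaks, with R^2 and mean signed % error."""
    x = np.asarray(ref_peaks, dtype=float)
    y = np.asarray(test_peaks, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least 3 matched peak pairs")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in reference peaks")
    fit = _stats.linregress(x, y)
    if np.any(x == 0):
        raise ValueError("zero reference peak; percent error undefined")
    mse = float(np.mean(100.0 * (y - x) / np.abs(x)))
    return AgreementFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        mean_signed_error=mse,
    )


def records_frame(records: Iterable[AccuracyRecord]) -> pd.DataFrame:
    """Tidy DataFrame, one row per AccuracyRecord."""
    rows = [asdict(r) for r in records]
    if not rows:
        raise ValueError("no records")
    return pd.DataFrame(rows)


def aggregate(records: Iterable[AccuracyRecord] | pd.DataFrame,
              group_by: List[str] | None = None) -> pd.DataFrame:
    """Mean ± SE summary per group.

    SE = SD/sqrt(n) (sample SD); a single-record group reports SE 0 with
    n = 1.  Percent measures enter as per-fall values, so the group mean is
    the across-fall average the experimental tables report.
    """
    df = records if isinstance(records, pd.DataFrame) else records_frame(records)
    if df.empty:
        raise ValueError("no records to aggregate")
    group_by = group_by or ["outcome"]
    metrics = ["rmse", "nrmse", "peak_diff_raw", "peak_diff_pct"]
    out = []
    for keys, grp in df.groupby(group_by, dropna=False):
        if not isinstance(keys, tuple):
            keys = (keys,)
        row = dict(zip(group_by, keys))
        row["n"] = len(grp)
        for m in metrics:
            vals = grp[m].dropna().to_numpy()
            if vals.size == 0:
                row[f"{m}_mean"] = math.nan
                row[f"{m}_se"] = math.nan
            else:
                row[f"{m}_mean"] = float(vals.mean())
                row[f"{m}_se"] = (
                    float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
                )
        out.append(row)
    return pd.DataFrame(out)
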