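"""Agreement and drift statistics for joint-angle time series.

The core quantities mirror standard practice for validating wearable-sensor
kinematics against a reference: per-minute RMS differences, Pearson
correlations, a per-subject linear fit of per-minute RMS against time whose
slope (deg/min) quantifies drift, cross-correlation time synchronization,
and median/IQR summaries with 1.5*IQR outlier flagging.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, NamedTuple

import numpy as np
from scipy import signal, stats

__all__ = [
    "DriftFit",
    "SyncResult",
    "Summary",
    "wrap_degrees",
    "rms_per_window",
    "drift_fit",
    "pearson",
    "synchronize",
    "summary",
    "compare_report",
]


class DriftFit(NamedTuple):
    slope: float  # deg/min
    intercept: float  # deg
    r_squared: float


class SyncResult(NamedTuple):
    lag_s: float
    lag_samples: int
    at_boundary: bool


class Summary(NamedTuple):
    median: float
    q1: float
    q3: float
    iqr: float
    outliers: np.ndarray


def wrap_degrees(d):
    """Wrap angle differences to (-180, 180] degrees."""
    d = np.asarray(d, float)
    out = (d + 180.0) % 360.0 - 180.0
    return np.where(out == -180.0, 180.0, out)


def _check_aligned(t_a, t_b):
    t_a = np.asarray(t_a, float)
    t_b = np.asarray(t_b, float)
    if len(t_a) != len(t_b) or not np.allclose(t_a, t_b, atol=1e-9):
        raise ValueError("angle series are not time-aligned")
    return t_a


def rms_per_window(t, a, b, window_s: float = 60.0) -> np.ndarray:
    """Per-window RMS of the wrapped difference ``a - b`` (degrees); one
    value per complete window, trailing partial window dropped."""
    t = np.asarray(t, float)
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) != len(t) or len(b) != len(t):
        raise ValueError("length mismatch between time and values")
    d = wrap_degrees(a - b)
    dt = np.median(np.diff(t)) if len(t) > 1 else 1.0
    per = max(int(round(window_s / dt)), 1)
    n_win = len(d) // per
    if n_win < 1:
        raise ValueError("series shorter than one window")
    w = d[: n_win * per].reshape(n_win, per)
    return np.sqrt(np.mean(w**2, axis=1))


def drift_fit(per_minute_rms, minutes=None) -> DriftFit:
    """Ordinary least squares of per-minute RMS against minute index;
    slope is the drift rate in deg/min."""
    y = np.asarray(per_minute_rms, float)
    if len(y) < 2:
        raise ValueError("drift fit needs at least 2 per-minute values")
    x = np.arange(len(y), dtype=float) if minutes is None else np.asarray(minutes, float)
    res = stats.linregress(x, y)
    return DriftFit(float(res.slope), float(res.intercept), float(res.rvalue**2))


def pearson(a, b) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        raise ValueError("Pearson correlation undefined for a constant series")
    return float(stats.pearsonr(a, b).statistic)


def synchronize(t, a, b, max_lag_s: float) -> SyncResult:
    """Lag (b relative to a) maximizing the normalized cross-correlation of
    the mean-removed series; positive lag means ``b`` is ``a`` delayed.

    Ties are broken toward the smallest |lag|.  A maximum on the search
    boundary is reported with ``at_boundary=True`` (low confidence).
    """
    t = np.asarray(t, float)
    a = np.asarray(a, float) - np.mean(a)
    b = np.asarray(b, float) - np.mean(b)
    if np.all(a == 0.0) or np.all(b == 0.0):
        raise ValueError("cannot synchronize flat signals")
    dt = np.median(np.diff(t))
    max_lag = int(round(max_lag_s / dt))
    cc = signal.correlate(b, a, mode="full")
    lags = signal.correlation_lags(len(b), len(a), mode="full")
    m = np.abs(lags) <= max_lag
    cc, lags = cc[m], lags[m]
    order = np.lexsort((np.abs(lags), -cc))  # max cc, then smallest |lag|
    best = lags[order[0]]
    return SyncResult(float(best * dt), int(best), abs(best) == max_lag)


def summary(values) -> Summary:
    """Median, quartiles (linear interpolation) and 1.5*IQR outliers."""
    v = np.asarray(values, float)
    if v.size < 1:
        raise ValueError("summary needs at least one value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    out = v[(v < q1 - 1.5 * iqr) | (v > q3 + 1.5 * iqr)]
    return Summary(float(med), float(q1), float(q3), float(iqr), out)


def _base_coord(name: str) -> str:
    for suffix in ("_r", "_l"):
        if name.endswith(suffix):
            return name[: -len(suffix)]
    return name


def compare_report(
    t,
    estimated: Mapping[str, np.ndarray],
    reference: Mapping[str, np.ndarray],
    window_s: float = 60.0,
    pool_bilateral: bool = True,
) -> dict:
    """Full per-coordinate agreement report (all angles in degrees).

    For each coordinate present in both inputs: per-window RMS, median/IQR
    with outlier count over windows, Pearson r, drift fit of per-window RMS,
    and the first-to-last-window change in correlation.  When
    ``pool_bilateral`` is set, right/left coordinates are additionally pooled
    under their base name (pooling the per-window RMS values and averaging r).
    """
    t = np.asarray(t, float)
    coords = [c for c in estimated if c in reference]
    if not coords:
        raise ValueError("no common coordinates between estimate and reference")
    dt = np.median(np.diff(t))
    per = max(int(round(window_s / dt)), 1)
    report = {"window_s": window_s, "coordinates": {}, "pooled": {}}
    for c in coords:
        a, b = np.asarray(estimated[c], float), np.asarray(reference[c], float)
        rms = rms_per_window(t, a, b, window_s)
        fit = drift_fit(rms)
        s = summary(rms)
        entry = {
            "per_window_rms_deg": rms.tolist(),
            "median_rms_deg": s.median,
            "iqr_deg": s.iqr,
            "n_outlier_windows": int(len(s.outliers)),
            "drift_slope_deg_per_min": fit.slope * (60.0 / window_s),
            "drift_intercept_deg": fit.intercept,
            "drift_r_squared": fit.r_squared,
        }
        try:
            entry["pearson_r"] = pearson(a, b)
            n_win = len(rms)
            first = slice(0, per)
            last = slice((n_win - 1) * per, n_win * per)
            entry["delta_r_first_last"] = pearson(a[last], b[last]) - pearson(
                a[first], b[first]
            )
        except ValueError:
            entry["pearson_r"] = math.nan
            entry["delta_r_first_last"] = math.nan
        report["coordinates"][c] = entry
    if pool_bilateral:
        groups: dict = {}
        for c in coords:
            groups.setdefault(_base_coord(c), []).append(c)
        for base, members in groups.items():
            pooled_rms = np.concatenate(
                [report["coordinates"][c]["per_window_rms_deg"] for c in members]
            )
            s = summary(pooled_rms)
            rs = [
                r
                for c in members
                if not math.isnan(r := report["coordinates"][c]["pearson_r"])
            ]
            report["pooled"][base] = {
                "median_rms_deg": s.median,
                "iqr_deg": s.iqr,
                "n_outliers": int(len(s.outliers)),
                "mean_pearson_r": float(np.mean(rs)) if rs else math.nan,
                "mean_drift_slope_deg_per_min": float(
                    np.mean(
                        [
                            report["coordinates"][c]["drift_slope_deg_per_min"]
                            for c in members
                        ]
                    )
                ),
            }
    return report
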