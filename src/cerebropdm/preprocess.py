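"""Conversion of raw beat-to-beat / breath-to-breath series into
analysis-ready uniform 1 Hz records.

The chain is: cubic-spline resampling to a uniform grid, iterative Grubbs
artifact removal (spike replacement by interpolation), zero-phase 5th-order
Butterworth high-pass at 0.005 Hz to remove baseline drift, and a 5-sample
trim at each end.  The order of operations is fixed and recorded in the QC
metadata of every preprocessed recording.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal, stats
from scipy.interpolate import CubicSpline

from .series import EventSeries, SubjectRecording, UniformSeries

__all__ = [
    "resample_to_uniform",
    "remove_artifacts_grubbs",
    "highpass_baseline",
    "trim_edges",
    "preprocess_series",
    "preprocess_recording",
]


def resample_to_uniform(es: EventSeries, fs: float = 1.0) -> UniformSeries:
    """Natural cubic spline through the events, sampled uniformly at fs
    over [first event, last event]."""
    if len(es) < 4:
        raise ValueError("cubic spline needs at least 4 events")
    span = es.times[-1] - es.times[0]
    if span < 10.0:
        raise ValueError("record span must be at least 10 s")
    spline = CubicSpline(es.times, es.values, bc_type="natural")
    n = int(np.floor(span * fs)) + 1
    grid = es.times[0] + np.arange(n) / fs
    return UniformSeries(spline(grid), fs=fs, label=es.label, units=es.units)


def _grubbs_critical(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value at significance level alpha."""
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), df=n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t ** 2 / (n - 2 + t ** 2))


def remove_artifacts_grubbs(x: UniformSeries, significance: float = 0.95):
    """Iterative one-at-a-time Grubbs outlier test with spline replacement.

    Each iteration tests the sample farthest from the mean against the
    t-based critical value at the stated significance; a rejected sample is
    replaced by cubic-spline interpolation over the unflagged neighbors
    (preserving the uniform grid) and the test repeats until no rejection.
    Returns ``(cleaned UniformSeries, sorted flagged indices)``.
    """
    n = len(x)
    if n < 7:
        raise ValueError("Grubbs test needs at least 7 samples")
    if not 0 < significance < 1:
        raise ValueError("significance must lie in (0, 1)")
    alpha = 1.0 - significance
    v = x.values.copy()
    t = np.arange(n)
    flagged: set[int] = set()
    # already-replaced samples are not re-tested (otherwise a replacement
    # that is still the farthest-from-mean sample would loop forever)
    candidates = np.ones(n, dtype=bool)
    while candidates.any():
        mean, sd = v.mean(), v.std(ddof=1)
        if sd == 0.0:
            break  # constant series: test undefined, nothing to flag
        dev = np.abs(v - mean)
        dev[~candidates] = -1.0
        i = int(np.argmax(dev))
        G = dev[i] / sd
        if G <= _grubbs_critical(n, alpha):
            break
        flagged.add(i)
        candidates[i] = False
        keep = np.setdiff1d(t, list(flagged))
        spline = CubicSpline(keep, x.values[keep], bc_type="natural")
        idx = np.array(sorted(flagged))
        v[idx] = spline(idx)
    if len(flagged) > 0.1 * n:
        warnings.warn(
            f"Grubbs flagged {len(flagged)}/{n} samples (> 10%): "
            "pathological input?", UserWarning, stacklevel=2)
    return x.with_values(v), sorted(flagged)


def highpass_baseline(x: UniformSeries, order: int = 5,
                      fc: float = 0.005) -> UniformSeries:
    """Zero-phase (forward-backward) Butterworth high-pass detrending.

    The effective attenuation is the squared one-pass magnitude response.
    """
    if len(x) <= 6 * order:
        raise ValueError(f"series too short for order-{order} filtfilt")
    if fc >= x.fs / 2:
        raise ValueError("cut-off must be below the Nyquist frequency")
    sos = signal.butter(order, fc, btype="highpass", fs=x.fs, output="sos")
    return x.with_values(signal.sosfiltfilt(sos, x.values))


def trim_edges(x: UniformSeries, n_trim: int = 5) -> UniformSeries:
    """Drop n_trim samples from each end (filter-transient guard)."""
    if n_trim < 0:
        raise ValueError("n_trim must be >= 0")
    if n_trim == 0:
        return x
    if len(x) <= 2 * n_trim:
        raise ValueError("series too short to trim")
    return x.with_values(x.values[n_trim:-n_trim])


def preprocess_series(x, fs: float = 1.0, significance: float = 0.95,
                      filter_order: int = 5, fc: float = 0.005,
                      n_trim: int = 5):
    """Full chain on one channel: resample -> Grubbs -> high-pass -> trim.

    ``x`` may be an :class:`EventSeries` (resampled first) or an already
    uniform series.  Returns ``(UniformSeries, qc dict)``.
    """
    if isinstance(x, EventSeries):
        u = resample_to_uniform(x, fs=fs)
    else:
        u = x
    pre_var = float(np.var(u.values))
    u, flagged = remove_artifacts_grubbs(u, significance=significance)
    u = highpass_baseline(u, order=filter_order, fc=fc)
    u = trim_edges(u, n_trim=n_trim)
    qc = {
        "label": u.label,
        "n_flagged": len(flagged),
        "flagged_indices": list(flagged),
        "pre_variance": pre_var,
        "post_variance": float(np.var(u.values)),
        "order_of_operations": "resample,grubbs,highpass,trim",
        "grubbs_significance": significance,
        "filter_order": filter_order,
        "cutoff_hz": fc,
        "n_trim": n_trim,
    }
    return u, qc


def preprocess_recording(rec: SubjectRecording, **kwargs) -> SubjectRecording:
    """Apply the preprocessing chain to all three channels of a recording.

    QC records for each channel are stored under ``meta['qc']``.
    """
    bp, qc_bp = preprocess_series(rec.bp, **kwargs)
    co2, qc_co2 = preprocess_series(rec.co2, **kwargs)
    flow, qc_flow = preprocess_series(rec.flow, **kwargs)
    meta = dict(rec.meta)
    meta["qc"] = {"bp": qc_bp, "co2": qc_co2, "flow": qc_flow}
    return SubjectRecording(subject_id=rec.subject_id, group=rec.group,
                            condition=rec.condition, bp=bp, co2=co2,
                            flow=flow, meta=meta)
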