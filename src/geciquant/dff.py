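"""ΔF/F normalization, spontaneous-event detection and transient kinetics.

The quantification protocol implemented here: baseline F0 is the bottom
8th percentile of the background-subtracted fluorescence distribution;
events are excursions above median + 3 SD of the ΔF/F trace; peak
amplitudes are 3-point averages around the maximum; decay kinetics come
from a single-exponential fit over a 1.1-s window after the peak.
"""
from __future__ import annotations

import warnings
from typing import NamedTuple

import numpy as np
from scipy.optimize import curve_fit

from .core import (AnalysisConfig, CalciumEvent, DffTrace, FluorescenceTrace,
                   NonPositiveBaselineError)

__all__ = [
    "compute_dff",
    "detect_events",
    "peak_amplitude",
    "fit_decay",
    "DecayFit",
    "activity_summary",
]


def compute_dff(trace: FluorescenceTrace,
                config: AnalysisConfig = AnalysisConfig()) -> DffTrace:
    """Normalize a fluorescence trace to ΔF/F = (F − F0)/F0.

    F0 is the ``config.baseline_percentile`` (default 8th) percentile of
    the whole trace's value distribution, computed with the
    linear-interpolation percentile definition.
    """
    f = trace.values
    f0 = float(np.percentile(f, config.baseline_percentile))
    if f0 <= 0:
        raise NonPositiveBaselineError(
            f"baseline F0 = {f0:.4g} is not positive for ROI "
            f"{trace.roi_id}; check background subtraction")
    return DffTrace(values=(f - f0) / f0, f0=f0,
                    frame_rate=trace.frame_rate, roi_id=trace.roi_id)


def _trace_sd(values: np.ndarray, robust: bool) -> float:
    if robust:
        med = np.median(values)
        return float(1.4826 * np.median(np.abs(values - med)))
    return float(np.std(values, ddof=1)) if values.size > 1 else 0.0


def peak_amplitude(dff: DffTrace, peak_frame: int,
                   config: AnalysisConfig = AnalysisConfig()) -> float:
    """Peak amplitude as the mean of ``peak_avg_points`` samples centred
    on ``peak_frame``, truncated at the trace edges."""
    n = dff.n_frames
    if not 0 <= peak_frame < n:
        raise IndexError(f"peak_frame {peak_frame} outside trace of {n} frames")
    half = config.peak_avg_points // 2
    lo = max(0, peak_frame - half)
    hi = min(n, peak_frame + config.peak_avg_points - half)
    return float(np.mean(dff.values[lo:hi]))


class DecayFit(NamedTuple):
    """Result of the exponential decay fit; ``tau`` is NaN when undefined."""

    tau: float
    r2: float

    @property
    def defined(self) -> bool:
        return bool(np.isfinite(self.tau))


def _loglinear_fit(t: np.ndarray, y: np.ndarray) -> tuple[float, float] | None:
    """Closed-form fit of log y = log A − t/τ on strictly positive samples."""
    mask = y > 0
    if mask.sum() < 2:
        return None
    slope, intercept = np.polyfit(t[mask], np.log(y[mask]), 1)
    if slope >= 0:
        return None
    return float(np.exp(intercept)), float(-1.0 / slope)


def fit_decay(dff: DffTrace, peak_frame: int,
              config: AnalysisConfig = AnalysisConfig()) -> DecayFit:
    """Fit ``y(t) = A·exp(-t/τ)`` to the decay after ``peak_frame``.

    The fit window runs from the peak over ``decay_fit_window_s``
    (default 1.1 s).  When fewer than 4 frames remain in the window, or
    the segment is degenerate (constant or non-positive), τ is undefined
    and returned as NaN rather than raising.

    With ``config.decay_offset`` the model gains an additive constant.
    """
    n_win = int(round(config.decay_fit_window_s * dff.frame_rate))
    y = dff.values[peak_frame:peak_frame + n_win + 1]
    if y.size < 4:
        return DecayFit(float("nan"), float("nan"))
    t = np.arange(y.size) / dff.frame_rate
    if np.ptp(y) == 0 or np.max(y) <= 0:
        return DecayFit(float("nan"), float("nan"))

    init = _loglinear_fit(t, y)
    if init is None:
        init = (max(float(y[0]), 1e-6), config.decay_fit_window_s / 3)

    try:
        if config.decay_offset:
            def model(t, a, tau, c):
                return a * np.exp(-t / tau) + c
            p0 = (*init, float(np.min(y)))
            bounds = ([0.0, 1e-6, -np.inf], [np.inf, np.inf, np.inf])
        else:
            def model(t, a, tau):
                return a * np.exp(-t / tau)
            p0 = init
            bounds = ([0.0, 1e-6], [np.inf, np.inf])
        popt, _ = curve_fit(model, t, y, p0=p0, bounds=bounds, maxfev=10000)
    except RuntimeError:
        return DecayFit(float("nan"), float("nan"))

    resid = y - model(t, *popt)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else float("nan")
    return DecayFit(float(popt[1]), r2)


def detect_events(dff: DffTrace,
                  config: AnalysisConfig = AnalysisConfig()) -> list[CalciumEvent]:
    """Detect spontaneous calcium transients.

    The detection threshold is median + ``event_threshold_sd`` × SD of the
    full ΔF/F trace (events included; set ``config.robust_sd`` for a
    MAD-based SD).  Each maximal contiguous supra-threshold run is one
    event; runs separated by less than one decay-fit window are merged so
    a single transient is not double-counted.
    """
    v = dff.values
    sd = _trace_sd(v, config.robust_sd)
    if sd == 0:
        warnings.warn("zero-variance ΔF/F trace: no events detectable",
                      stacklevel=2)
        return []
    threshold = float(np.median(v)) + config.event_threshold_sd * sd

    above = v > threshold
    if not np.any(above):
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
    starts, stops = edges[::2], edges[1::2]  # stop exclusive

    merge_gap = int(round(config.decay_fit_window_s * dff.frame_rate))
    merged: list[list[int]] = [[int(starts[0]), int(stops[0])]]
    for s, e in zip(starts[1:], stops[1:]):
        if s - merged[-1][1] < merge_gap:
            merged[-1][1] = int(e)
        else:
            merged.append([int(s), int(e)])

    events = []
    for s, e in merged:
        peak = int(s + np.argmax(v[s:e]))
        amp = peak_amplitude(dff, peak, config)
        if amp <= 0:
            # extreme negative flanks can drag the 3-point average below
            # zero; the raw peak sample sits above the positive threshold
            amp = float(v[peak])
        fit = fit_decay(dff, peak, config)
        events.append(CalciumEvent(onset_frame=s, peak_frame=peak,
                                   peak_amplitude=amp,
                                   decay_tau=fit.tau, fit_r2=fit.r2))
    return events


def activity_summary(events: list[CalciumEvent], dff: DffTrace,
                     config: AnalysisConfig = AnalysisConfig()
                     ) -> tuple[float, bool]:
    """Event rate in events/min and whether the ROI counts as active.

    A neuron is active when at least one supra-threshold event was
    detected in its trace.
    """
    minutes = dff.duration / 60.0
    if minutes <= 0:
        raise ValueError("recording duration must be positive")
    return len(events) / minutes, len(events) >= 1
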