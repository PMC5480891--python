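"""Shared containers and analysis constants.

All times are seconds, all frame indices 0-based, and ΔF/F is stored as a
dimensionless fraction (0.087 = 8.7%).  Reports render percentages.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AnalysisConfig",
    "SpikeTrain",
    "FluorescenceTrace",
    "DffTrace",
    "CalciumEvent",
    "NonPositiveBaselineError",
]


class NonPositiveBaselineError(ValueError):
    """Raised when the estimated baseline fluorescence F0 is not positive."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Constants of the quantification protocol.

    Parameters
    ----------
    baseline_percentile
        Percentile of the background-subtracted fluorescence distribution
        used as the baseline F0 (bottom 8th percentile).
    event_threshold_sd
        A spontaneous event must exceed the trace median by this many
        standard deviations of the ΔF/F trace.
    peak_avg_points
        Number of samples averaged around the maximum to estimate a peak
        amplitude (3-point average).
    decay_fit_window_s
        Length of the window after the peak over which a single exponential
        is fitted to obtain the decay time constant τ.
    burst_window_s
        Maximum interval between consecutive APs for them to count as one
        burst driving a single calcium transient (300 ms).
    baseline_snr_window_s
        Length of the pre-spike baseline window whose ΔF/F standard
        deviation is the SNR denominator (1 s).
    fpr
        Target false-positive rate when calibrating the SNR detection
        threshold on noise-only baselines.
    robust_sd
        Use a median-absolute-deviation based SD for the event threshold
        instead of the plain standard deviation of the full trace.
    decay_offset
        Fit ``A·exp(-t/τ) + C`` instead of the default offset-free model.
    threshold_method
        ``"gaussian"``: threshold from a Gaussian fit of the null SNRs;
        ``"percentile"``: empirical (1-fpr) percentile of the null SNRs.
    """

    baseline_percentile: float = 8.0
    event_threshold_sd: float = 3.0
    peak_avg_points: int = 3
    decay_fit_window_s: float = 1.1
    burst_window_s: float = 0.3
    baseline_snr_window_s: float = 1.0
    fpr: float = 0.05
    robust_sd: bool = False
    decay_offset: bool = False
    threshold_method: str = "gaussian"

    def __post_init__(self) -> None:
        if not 0.0 < self.baseline_percentile < 50.0:
            raise ValueError("baseline_percentile must lie in (0, 50)")
        for name in ("event_threshold_sd", "peak_avg_points",
                     "decay_fit_window_s", "burst_window_s",
                     "baseline_snr_window_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.fpr < 1.0:
            raise ValueError("fpr must lie in (0, 1)")
        if self.threshold_method not in ("gaussian", "percentile"):
            raise ValueError("threshold_method must be 'gaussian' or 'percentile'")


@dataclass(frozen=True)
class SpikeTrain:
    """Action-potential times from electrophysiology.

    ``times`` are seconds, strictly increasing, within ``[0, duration]``.
    """

    times: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if t.ndim != 1:
            raise ValueError("spike times must be one-dimensional")
        if t.size and (np.any(np.diff(t) <= 0)):
            raise ValueError("spike times must be strictly increasing")
        if t.size and (t[0] < 0 or t[-1] > self.duration):
            raise ValueError("spike times must lie within [0, duration]")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass
class FluorescenceTrace:
    """Per-ROI raw (background-subtracted) fluorescence time series."""

    values: np.ndarray
    frame_rate: float
    roi_id: int | str = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("trace must be a non-empty 1-D array")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if np.all(self.values < 0):
            warnings.warn(
                f"trace for ROI {self.roi_id} is entirely negative; "
                "check the background estimate", stacklevel=2)

    @property
    def n_frames(self) -> int:
        return int(self.values.size)

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate


@dataclass
class DffTrace:
    """Normalized ΔF/F = (F − F0)/F0 time series with its baseline F0."""

    values: np.ndarray
    f0: float
    frame_rate: float
    roi_id: int | str = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("ΔF/F trace must be a non-empty 1-D array")
        if self.f0 <= 0:
            raise NonPositiveBaselineError(
                f"F0 must be positive (ROI {self.roi_id})")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ΔF/F values must be finite")

    @property
    def n_frames(self) -> int:
        return int(self.values.size)

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate


@dataclass(frozen=True)
class CalciumEvent:
    """One detected calcium transient.

    ``decay_tau`` is NaN when the decay fit is undefined (window truncated
    or degenerate segment); ``fit_r2`` is NaN in the same cases.
    """

    onset_frame: int
    peak_frame: int
    peak_amplitude: float
    decay_tau: float = float("nan")
    fit_r2: float = float("nan")

    def __post_init__(self) -> None:
        if self.onset_frame > self.peak_frame:
            raise ValueError("onset_frame must not exceed peak_frame")
        if self.peak_amplitude <= 0:
            raise ValueError("peak_amplitude must be positive")
        if np.isfinite(self.decay_tau) and self.decay_tau <= 0:
            raise ValueError("decay_tau must be positive when defined")

    @property
    def has_tau(self) -> bool:
        return bool(np.isfinite(self.decay_tau))
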