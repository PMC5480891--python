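"""AP-detection-efficiency estimation.

The detection question: given the SNR of a spike-evoked transient (peak
ΔF/F over the SD of the 1-s pre-spike baseline), which transients would
an observer accept at a fixed false-positive rate?  The null SNR
distribution is built from spike-free baseline segments, a Gaussian is
fitted to it, and the threshold is placed at the (1 − fpr) quantile of
the fit; detection efficiency per AP count is the fraction of transients
whose SNR clears the threshold.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core import AnalysisConfig, DffTrace, SpikeTrain
from .evoked import EvokedTransient

__all__ = [
    "DetectionThreshold",
    "DetectionResult",
    "baseline_snr_null",
    "calibrate_threshold",
    "detection_efficiency",
]


@dataclass(frozen=True)
class DetectionThreshold:
    """SNR cutoff calibrated to a target false-positive rate."""

    mu_null: float
    sigma_null: float
    threshold: float
    fpr: float
    method: str = "gaussian"


@dataclass(frozen=True)
class DetectionResult:
    """Detected / total counts and fractions per AP count."""

    table: pd.DataFrame   # columns: n_aps, detected, total, fraction

    @classmethod
    def from_counts(cls, counts: dict[int, tuple[int, int]]
                    ) -> "DetectionResult":
        """Build a result from (detected, total) pairs keyed by AP count."""
        rows = []
        for n_aps in sorted(counts):
            det, tot = counts[n_aps]
            if not 0 <= det <= tot:
                raise ValueError(f"need 0 ≤ detected ≤ total for n={n_aps}")
            rows.append({"n_aps": n_aps, "detected": det, "total": tot,
                         "fraction": det / tot if tot else np.nan})
        return cls(table=pd.DataFrame(
            rows, columns=["n_aps", "detected", "total", "fraction"]))

    def fraction_pct(self, n_aps: int) -> int:
        """Detection efficiency for one AP count, rounded to integer %."""
        row = self.table[self.table["n_aps"] == n_aps]
        if row.empty:
            raise KeyError(f"no transients with {n_aps} APs")
        return int(round(100 * float(row["fraction"].iloc[0])))


def _spike_free_spans(trace: DffTrace, spikes: SpikeTrain,
                      config: AnalysisConfig) -> list[tuple[float, float]]:
    """Spans untouched by any AP's baseline or response footprint."""
    guard_pre = config.baseline_snr_window_s
    guard_post = 3.0 * config.decay_fit_window_s
    spans = []
    t0 = 0.0
    for ap in spikes.times:
        if ap - guard_pre > t0:
            spans.append((t0, ap - guard_pre))
        t0 = max(t0, ap + guard_post)
    if trace.duration > t0:
        spans.append((t0, trace.duration))
    return spans


def _segment_snr(seg: np.ndarray, config: AnalysisConfig) -> float:
    """Split-half null SNR of one baseline segment.

    The first half provides the SD (the noise estimate), the second half
    the peak (3-point average around its maximum), so numerator and
    denominator are independent.  Returns NaN for a zero-SD half.
    """
    half = seg.size // 2
    sd = float(np.std(seg[:half], ddof=1))
    if sd == 0:
        return float("nan")
    second = seg[half:]
    i = int(np.argmax(second))
    lo = max(0, i - config.peak_avg_points // 2)
    hi = min(second.size, lo + config.peak_avg_points)
    return float(np.mean(second[lo:hi])) / sd


def baseline_snr_null(dff_traces: list[DffTrace],
                      spike_trains: list[SpikeTrain] | None = None,
                      config: AnalysisConfig = AnalysisConfig()) -> np.ndarray:
    """Null SNR values from spike-free baseline segments.

    Spike-free spans of each trace are tiled into non-overlapping
    segments of ``baseline_snr_window_s`` (1 s), each yielding one
    split-half SNR.  Traces without any usable segment raise; zero-SD
    (noiseless) segments are flagged with a warning and skipped.
    """
    if spike_trains is None:
        spike_trains = [SpikeTrain(np.empty(0), tr.duration)
                        for tr in dff_traces]
    if len(spike_trains) != len(dff_traces):
        raise ValueError("need one spike train per trace")

    values: list[float] = []
    empty_traces: list[int | str] = []
    n_degenerate = 0
    for tr, st in zip(dff_traces, spike_trains):
        seg_frames = int(round(config.baseline_snr_window_s * tr.frame_rate))
        got = False
        for lo_s, hi_s in _spike_free_spans(tr, st, config):
            lo = int(np.ceil(lo_s * tr.frame_rate))
            hi = int(np.floor(hi_s * tr.frame_rate))
            for start in range(lo, hi - seg_frames + 1, seg_frames):
                snr = _segment_snr(tr.values[start:start + seg_frames], config)
                got = True
                if np.isnan(snr):
                    n_degenerate += 1
                else:
                    values.append(snr)
        if not got:
            empty_traces.append(tr.roi_id)
    if empty_traces:
        raise ValueError(
            f"no spike-free baseline segment in traces {empty_traces}")
    if n_degenerate:
        warnings.warn(f"{n_degenerate} zero-SD baseline segments skipped "
                      "(noiseless or constant data)", stacklevel=2)
    return np.asarray(values)


def calibrate_threshold(null_snrs: np.ndarray, fpr: float = 0.05,
                        method: str = "gaussian") -> DetectionThreshold:
    """Set the SNR detection threshold from the null distribution.

    ``method="gaussian"`` (default) fits a Gaussian (sample mean and SD)
    to the null SNRs and places the threshold at its (1 − fpr) quantile,
    ``mu + z(1−fpr)·sigma``.  ``method="percentile"`` uses the empirical
    (1 − fpr) percentile instead.
    """
    null_snrs = np.asarray(null_snrs, dtype=float)
    null_snrs = null_snrs[np.isfinite(null_snrs)]
    if null_snrs.size < 20:
        raise ValueError(
            f"need at least 20 null SNR values for a stable fit, "
            f"got {null_snrs.size}")
    mu = float(np.mean(null_snrs))
    sigma = float(np.std(null_snrs, ddof=1))
    if sigma == 0:
        warnings.warn("null SNRs have zero spread; threshold equals mean",
                      stacklevel=2)
        return DetectionThreshold(mu, 0.0, mu, fpr, method)
    if method == "gaussian":
        thr = mu + float(norm.ppf(1.0 - fpr)) * sigma
    elif method == "percentile":
        thr = float(np.percentile(null_snrs, 100 * (1.0 - fpr)))
    else:
        raise ValueError("method must be 'gaussian' or 'percentile'")
    return DetectionThreshold(mu, sigma, thr, fpr, method)


def detection_efficiency(transients: list[EvokedTransient],
                         threshold: DetectionThreshold) -> DetectionResult:
    """Fraction of evoked transients whose SNR clears the threshold,
    per AP count, with exact counts retained."""
    for t in transients:
        if not np.isfinite(t.snr):
            raise ValueError("every transient must have a finite SNR")
    counts: dict[int, tuple[int, int]] = {}
    for t in transients:
        det, tot = counts.get(t.burst.n_aps, (0, 0))
        counts[t.burst.n_aps] = (det + (t.snr > threshold.threshold), tot + 1)
    return DetectionResult.from_counts(counts)
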