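"""Spike-triggered transient analysis.

Groups simultaneously recorded APs into 300-ms bursts, measures the
evoked ΔF/F transient of each burst (peak amplitude, decay constant and
SNR against the 1-s pre-spike baseline), builds the amplitude-vs-AP-count
relation and the average single-AP waveform, and probes the saturating
ceiling ΔF/F_max from a driven plateau.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AnalysisConfig, DffTrace, SpikeTrain
from .dff import fit_decay, peak_amplitude

__all__ = [
    "Burst",
    "EvokedTransient",
    "ExcludedBurst",
    "group_aps",
    "extract_evoked",
    "analyze_evoked",
    "amplitude_vs_ap_count",
    "single_ap_waveform",
    "estimate_dff_max",
]


@dataclass(frozen=True)
class Burst:
    """A group of APs treated as the driver of one calcium transient."""

    ap_times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.ap_times, dtype=float)
        object.__setattr__(self, "ap_times", t)
        if t.size < 1:
            raise ValueError("a burst holds at least one AP")

    @property
    def n_aps(self) -> int:
        return int(self.ap_times.size)

    @property
    def first_ap_time(self) -> float:
        return float(self.ap_times[0])


@dataclass(frozen=True)
class EvokedTransient:
    """The ΔF/F transient evoked by one AP burst."""

    burst: Burst
    peak_frame: int
    peak_amplitude: float
    decay_tau: float
    fit_r2: float
    baseline_sd: float
    snr: float


@dataclass(frozen=True)
class ExcludedBurst:
    """A burst dropped from the evoked analysis, with the logged reason."""

    burst: Burst
    reason: str


def group_aps(spikes: SpikeTrain,
              config: AnalysisConfig = AnalysisConfig(), *,
              rule: str = "chain") -> list[Burst]:
    """Partition a spike train into bursts.

    ``rule="chain"`` (default): consecutive APs join one burst whenever
    their interval is at most ``burst_window_s``; ``rule="window"``: a
    burst holds all APs within ``burst_window_s`` of its first AP.  The
    two coincide for the short bursts typical in vivo.
    """
    t = spikes.times
    if t.size == 0:
        return []
    if rule == "chain":
        breaks = np.flatnonzero(np.diff(t) > config.burst_window_s)
        groups = np.split(t, breaks + 1)
    elif rule == "window":
        groups = []
        start = 0
        for i in range(1, t.size + 1):
            if i == t.size or t[i] - t[start] > config.burst_window_s:
                groups.append(t[start:i])
                start = i
    else:
        raise ValueError("rule must be 'chain' or 'window'")
    return [Burst(ap_times=g) for g in groups]


def extract_evoked(dff: DffTrace, burst: Burst,
                   config: AnalysisConfig = AnalysisConfig()
                   ) -> EvokedTransient | ExcludedBurst:
    """Measure the transient evoked by one burst.

    The peak is the 3-point-average maximum within the window
    ``(first AP, first AP + decay_fit_window_s]``; the SNR denominator is
    the SD of the unfiltered ΔF/F over the 1-s window before the first
    AP.  Bursts lacking a full pre- or post-window are excluded with a
    reason rather than raising.
    """
    fr = dff.frame_rate
    t1 = burst.first_ap_time
    pre_frames = int(round(config.baseline_snr_window_s * fr))
    i_first = int(np.floor(t1 * fr))

    base_lo = i_first - pre_frames
    if base_lo < 0:
        return ExcludedBurst(burst, "insufficient pre-AP baseline window")
    post_mask = (dff.times > t1) & (dff.times <= t1 + config.decay_fit_window_s)
    n_post = int(post_mask.sum())
    if n_post < 4 or (t1 + config.decay_fit_window_s) > dff.duration:
        return ExcludedBurst(burst, "insufficient post-AP response window")

    baseline = dff.values[base_lo:i_first]
    baseline_sd = float(np.std(baseline, ddof=1))

    post_idx = np.flatnonzero(post_mask)
    peak = int(post_idx[np.argmax(dff.values[post_idx])])
    amp = peak_amplitude(dff, peak, config)
    fit = fit_decay(dff, peak, config)
    snr = amp / baseline_sd if baseline_sd > 0 else float("inf")
    return EvokedTransient(burst=burst, peak_frame=peak, peak_amplitude=amp,
                           decay_tau=fit.tau, fit_r2=fit.r2,
                           baseline_sd=baseline_sd, snr=snr)


def analyze_evoked(dff: DffTrace, spikes: SpikeTrain,
                   config: AnalysisConfig = AnalysisConfig()
                   ) -> tuple[list[EvokedTransient], list[ExcludedBurst]]:
    """Group APs into bursts and measure every analyzable transient.

    Beyond the window checks of :func:`extract_evoked`, a burst whose
    baseline window overlaps the response window of the previous burst is
    excluded (contaminated baseline).  Analyzed plus excluded bursts
    always account for every burst.
    """
    bursts = group_aps(spikes, config)
    analyzed: list[EvokedTransient] = []
    excluded: list[ExcludedBurst] = []
    prev_response_end = -np.inf
    for b in bursts:
        if b.first_ap_time - config.baseline_snr_window_s < prev_response_end:
            excluded.append(ExcludedBurst(
                b, "baseline overlaps previous response window"))
        else:
            res = extract_evoked(dff, b, config)
            (analyzed if isinstance(res, EvokedTransient)
             else excluded).append(res)
        prev_response_end = (b.ap_times[-1] + config.decay_fit_window_s)
    return analyzed, excluded


def amplitude_vs_ap_count(transients: list[EvokedTransient]) -> pd.DataFrame:
    """Mean ± SEM of peak ΔF/F grouped by the number of APs per burst.

    Rows only exist for AP counts that occurred (no NaN rows).
    """
    if not transients:
        raise ValueError("need at least one transient")
    df = pd.DataFrame({"n_aps": [t.burst.n_aps for t in transients],
                       "amplitude": [t.peak_amplitude for t in transients]})
    g = df.groupby("n_aps")["amplitude"]
    out = pd.DataFrame({
        "mean_amplitude": g.mean(),
        "sem": g.apply(lambda s: s.std(ddof=1) / np.sqrt(len(s))
                       if len(s) > 1 else np.nan),
        "count": g.size(),
    })
    return out.reset_index()


def single_ap_waveform(dff: DffTrace, transients: list[EvokedTransient],
                       config: AnalysisConfig = AnalysisConfig(), *,
                       pre_s: float = 0.5, post_s: float = 1.5
                       ) -> pd.DataFrame:
    """Time-aligned mean ± SEM ΔF/F waveform of single-AP transients.

    Snippets are aligned on the frame of each single-AP burst's first AP;
    snippets truncated by the trace edges are dropped.
    """
    fr = dff.frame_rate
    n_pre, n_post = int(round(pre_s * fr)), int(round(post_s * fr))
    snippets = []
    for tr in transients:
        if tr.burst.n_aps != 1:
            continue
        i0 = int(np.floor(tr.burst.first_ap_time * fr))
        if i0 - n_pre < 0 or i0 + n_post + 1 > dff.n_frames:
            continue
        snippets.append(dff.values[i0 - n_pre:i0 + n_post + 1])
    if not snippets:
        raise ValueError("no complete single-AP snippets available")
    arr = np.asarray(snippets)
    t = (np.arange(-n_pre, n_post + 1)) / fr
    sem = (arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0])
           if arr.shape[0] > 1 else np.full(arr.shape[1], np.nan))
    return pd.DataFrame({"t_s": t, "mean_dff": arr.mean(axis=0), "sem": sem,
                         "n": arr.shape[0]})


def estimate_dff_max(dff: DffTrace,
                     drive_window: tuple[float, float] | None = None) -> float:
    """Estimate the saturating ceiling ΔF/F_max from a driven plateau.

    ``drive_window`` marks the seconds during which the cell was driven
    to saturation (e.g. by strong current injection).  Returns the 99th
    percentile of ΔF/F within that segment — a robust plateau estimate
    that, like any ΔF/F-based probe, remains a lower bound on the true
    ceiling (resting-calcium and baseline effects bias it downward).
    """
    if drive_window is None:
        raise ValueError("no driven segment marked; pass drive_window=(t0, t1)")
    t0, t1 = drive_window
    mask = (dff.times >= t0) & (dff.times <= t1)
    if not mask.any():
        raise ValueError(f"drive_window {drive_window} contains no frames")
    return float(np.percentile(dff.values[mask], 99))
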