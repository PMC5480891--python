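"""Spike-to-fluorescence forward model and synthetic movie rendering.

This module generates ground-truth data emulating 12-Hz two-photon
recordings of cortical neurons expressing a red genetically encoded
calcium indicator: Poisson spike trains with short bursts, a saturating
indicator response with single-AP ΔF/F transients of a few percent and
sub-second exponential decay, and rendered single- or two-channel movies
containing calcium-insensitive autofluorescent puncta.

The forward model per trace is

    F(t) = F0 · (1 + s(L(t))) + noise,

where ``L(t)`` sums a unit-peak difference-of-exponentials kernel scaled
by the single-AP amplitude over all APs, and ``s`` is a hyperbolic
(Hill coefficient 1) saturating transform with ceiling ``dff_max``,
calibrated at construction so the single-AP response stays quasi-linear.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .core import AnalysisConfig, FluorescenceTrace, SpikeTrain

__all__ = [
    "IndicatorModel",
    "SimulationConfig",
    "GroundTruth",
    "generate_spike_train",
    "simulate_trace",
    "grid_layout",
    "render_movie",
    "write_ground_truth",
    "read_ground_truth",
]


class InvalidModelError(ValueError):
    """Raised for physically impossible indicator parameters."""


@dataclass(frozen=True)
class IndicatorModel:
    """Parameters of the saturating calcium-indicator response.

    Defaults are the transgenic-expression characterization values:
    single-AP ΔF/F amplitude 8.7%, decay time constant 0.35 s and
    saturating ceiling ΔF/F_max = 373%.  ``half_saturation`` is the
    linear-sum level at which the response reaches half the ceiling; when
    left ``None`` it is calibrated numerically so that the single-AP
    response equals the nominal amplitude.

    ``noise_sd`` is the per-frame additive noise in ΔF/F units.  Its
    default (0.03) puts the single-AP SNR near 2.5–3, the regime in which
    roughly half of single APs are detectable — the operating point of
    in vivo somatic imaging at 12 Hz.
    """

    single_ap_amplitude: float = 0.087
    decay_tau: float = 0.35
    rise_tau: float = 0.03
    dff_max: float = 3.73
    half_saturation: float | None = None
    baseline_f0: float = 100.0
    noise_sd: float = 0.03

    def __post_init__(self) -> None:
        if self.decay_tau <= 0 or self.rise_tau <= 0:
            raise InvalidModelError("time constants must be positive")
        if not 0 < self.single_ap_amplitude < self.dff_max:
            raise InvalidModelError(
                "need 0 < single_ap_amplitude < dff_max "
                f"(got {self.single_ap_amplitude} vs {self.dff_max})")
        if self.baseline_f0 <= 0:
            raise InvalidModelError("baseline_f0 must be positive")
        if self.noise_sd < 0:
            raise InvalidModelError("noise_sd must be non-negative")
        if self.half_saturation is None:
            object.__setattr__(self, "half_saturation", self._calibrate())
        elif self.half_saturation <= 0:
            raise InvalidModelError("half_saturation must be positive")

    def _calibrate(self) -> float:
        """Solve for the half-saturation K with s(a) = a, a the single-AP
        amplitude; root-found numerically (the root is dff_max − a)."""
        a, m = self.single_ap_amplitude, self.dff_max

        def gap(k: float) -> float:
            return m * a / (a + k) - a

        return float(brentq(gap, a * 1e-6 + 1e-12, 1e6 * m))

    def saturate(self, linear_sum: np.ndarray | float) -> np.ndarray | float:
        """Hyperbolic saturation s(x) = dff_max·x/(x + K), s(0) = 0."""
        x = np.asarray(linear_sum, dtype=float)
        return self.dff_max * x / (x + self.half_saturation)

    def kernel(self, t: np.ndarray) -> np.ndarray:
        """Unit-peak single-AP ΔF/F kernel (zero for t < 0)."""
        t = np.asarray(t, dtype=float)
        r, d = self.rise_tau, self.decay_tau
        raw = np.where(t >= 0, (1.0 - np.exp(-np.maximum(t, 0) / r))
                       * np.exp(-np.maximum(t, 0) / d), 0.0)
        t_peak = r * np.log1p(d / r)
        peak = (1.0 - np.exp(-t_peak / r)) * np.exp(-t_peak / d)
        return raw / peak


@dataclass(frozen=True)
class SimulationConfig:
    """Spike-train and sampling parameters.

    The defaults emulate spontaneous activity of layer-2/3 neurons imaged
    at a 12-Hz frame rate: an overall AP rate of 0.05 Hz (about three
    events per minute, transients arriving mostly as singles with
    occasional short bursts).  ``burst_prob`` is the probability that an
    AP is followed within 300 ms by another AP of the same burst.
    """

    frame_rate: float = 12.0
    duration: float = 180.0
    firing_rate: float = 0.05
    burst_prob: float = 0.3
    max_burst_size: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.firing_rate < 0:
            raise ValueError("firing_rate must be non-negative")
        if not 0 <= self.burst_prob < 1:
            raise ValueError("burst_prob must lie in [0, 1)")
        if self.max_burst_size < 1:
            raise ValueError("max_burst_size must be at least 1")


@dataclass
class GroundTruth:
    """Everything the generator knows that an analysis must recover."""

    spike_times: np.ndarray
    burst_amplitudes: np.ndarray   # true peak ΔF/F per burst, fine-grid
    burst_sizes: np.ndarray        # APs per burst, chaining rule
    roi_masks: dict[int, np.ndarray] | None = None   # roi_id -> (N, 2) pixels
    puncta_pixels: np.ndarray | None = None          # (N, 2) static pixels
    mixing_matrix: np.ndarray | None = None
    frame_shape: tuple[int, int] | None = None


def _burst_sizes(rng: np.random.Generator, n: int, p: float,
                 max_size: int) -> np.ndarray:
    """Truncated geometric burst sizes: P(k) ∝ (1−p)·p^(k−1), k ≤ max."""
    if p == 0:
        return np.ones(n, dtype=int)
    return np.minimum(rng.geometric(1.0 - p, size=n), max_size)


def _mean_burst_size(p: float, max_size: int) -> float:
    if p == 0:
        return 1.0
    k = np.arange(1, max_size + 1)
    w = (1.0 - p) * p ** (k - 1)
    w[-1] += p ** max_size  # truncation mass collapses onto max_size
    return float(np.sum(k * w))


def generate_spike_train(config: SimulationConfig) -> SpikeTrain:
    """Sample a spike train of bursty APs.

    Burst onsets follow a Poisson process whose rate is chosen so that
    the overall AP rate equals ``config.firing_rate``; burst sizes are
    truncated-geometric and intra-burst inter-spike intervals are drawn
    uniformly from 5–100 ms, well inside the 300-ms burst window.
    """
    rng = np.random.default_rng(config.seed)
    if config.firing_rate == 0:
        return SpikeTrain(times=np.empty(0), duration=config.duration)

    start_rate = config.firing_rate / _mean_burst_size(
        config.burst_prob, config.max_burst_size)
    # over-sample arrivals, then truncate at the duration
    n_guess = max(16, int(3 * start_rate * config.duration + 20))
    starts = np.cumsum(rng.exponential(1.0 / start_rate, size=n_guess))
    starts = starts[starts < config.duration]
    sizes = _burst_sizes(rng, starts.size, config.burst_prob,
                         config.max_burst_size)

    times: list[float] = []
    for t0, k in zip(starts, sizes):
        isis = rng.uniform(0.005, 0.100, size=k - 1)
        burst = t0 + np.concatenate(([0.0], np.cumsum(isis)))
        times.extend(burst[burst <= config.duration])
    t = np.unique(np.asarray(times))
    return SpikeTrain(times=t, duration=config.duration)


def _linear_sum(t: np.ndarray, spikes: SpikeTrain,
                model: IndicatorModel) -> np.ndarray:
    L = np.zeros_like(t)
    for ts in spikes.times:
        L += model.single_ap_amplitude * model.kernel(t - ts)
    return L


def simulate_trace(spikes: SpikeTrain, model: IndicatorModel,
                   config: SimulationConfig, *, shot_noise: bool = False,
                   rng: np.random.Generator | None = None
                   ) -> tuple[FluorescenceTrace, GroundTruth]:
    """Render a noisy fluorescence trace from a spike train.

    Returns the frame-sampled trace together with the ground truth: the
    true peak ΔF/F of every burst, evaluated on a 1-ms grid so frame
    sampling does not bias the reference values.

    With ``shot_noise`` the additive Gaussian noise is replaced by a
    Poisson draw with the clean trace as its mean (photon-counting-like
    noise); by default noise is Gaussian with SD ``model.noise_sd`` in
    ΔF/F units.
    """
    if spikes.times.size and (spikes.times[0] < 0
                              or spikes.times[-1] > config.duration):
        raise ValueError("spikes must lie within [0, duration]")
    rng = np.random.default_rng(config.seed) if rng is None else rng

    n = int(round(config.duration * config.frame_rate))
    t = np.arange(n) / config.frame_rate
    dff = np.asarray(model.saturate(_linear_sum(t, spikes, model)))

    clean = model.baseline_f0 * (1.0 + dff)
    if shot_noise:
        f = rng.poisson(np.maximum(clean, 0)).astype(float)
    elif model.noise_sd > 0:
        f = clean + model.baseline_f0 * model.noise_sd * rng.standard_normal(n)
    else:
        f = clean
    f = np.maximum(f, 0.0)

    truth = GroundTruth(spike_times=spikes.times.copy(),
                        **_burst_truth(spikes, model, config))
    return (FluorescenceTrace(values=f, frame_rate=config.frame_rate),
            truth)


def _burst_truth(spikes: SpikeTrain, model: IndicatorModel,
                 config: SimulationConfig) -> dict:
    """True per-burst peak ΔF/F on a fine time grid (chaining-rule bursts)."""
    cfg = AnalysisConfig()
    if spikes.times.size == 0:
        return dict(burst_amplitudes=np.empty(0), burst_sizes=np.empty(0, int))
    dt = 1e-3
    t_fine = np.arange(0.0, config.duration + cfg.decay_fit_window_s, dt)
    dff_fine = np.asarray(model.saturate(_linear_sum(t_fine, spikes, model)))

    # chaining rule: consecutive APs within the burst window share a burst
    breaks = np.flatnonzero(np.diff(spikes.times) > cfg.burst_window_s)
    groups = np.split(spikes.times, breaks + 1)
    amps, sizes = [], []
    for g in groups:
        mask = (t_fine > g[0]) & (t_fine <= g[0] + cfg.decay_fit_window_s)
        amps.append(float(dff_fine[mask].max()))
        sizes.append(len(g))
    return dict(burst_amplitudes=np.asarray(amps),
                burst_sizes=np.asarray(sizes, dtype=int))


# ---------------------------------------------------------------------------
# movie rendering


def grid_layout(n_rois: int, shape: tuple[int, int] = (64, 64),
                roi_size: int = 5, margin: int = 3, n_puncta: int = 0,
                seed: int = 0) -> GroundTruth:
    """Lay out square ROIs on a grid plus optional random puncta pixels.

    Puncta are placed outside every ROI; they stand in for the static,
    calcium-insensitive autofluorescent structures seen in cortex.
    """
    rng = np.random.default_rng(seed)
    rows, cols = shape
    step = roi_size + margin
    positions = [(r, c) for r in range(margin, rows - roi_size, step)
                 for c in range(margin, cols - roi_size, step)]
    if len(positions) < n_rois:
        raise ValueError(f"cannot place {n_rois} ROIs on a {shape} grid")
    masks: dict[int, np.ndarray] = {}
    occupied = np.zeros(shape, dtype=bool)
    for i, (r, c) in enumerate(positions[:n_rois]):
        rr, cc = np.meshgrid(np.arange(r, r + roi_size),
                             np.arange(c, c + roi_size), indexing="ij")
        masks[i] = np.column_stack([rr.ravel(), cc.ravel()])
        occupied[rr, cc] = True

    puncta = None
    if n_puncta > 0:
        free = np.column_stack(np.nonzero(~occupied))
        idx = rng.choice(free.shape[0], size=n_puncta, replace=False)
        puncta = free[idx]
    return GroundTruth(spike_times=np.empty(0),
                       burst_amplitudes=np.empty(0),
                       burst_sizes=np.empty(0, int),
                       roi_masks=masks, puncta_pixels=puncta,
                       frame_shape=shape)


def render_movie(traces: list[FluorescenceTrace], layout: GroundTruth,
                 two_channel: np.ndarray | None = None, seed: int = 0, *,
                 background: float = 10.0, pixel_noise_sd: float = 0.0,
                 puncta_brightness: float = 200.0):
    """Render per-ROI traces into an image time series.

    Pixels of ROI ``i`` carry ``background + traces[i]``; everything else
    sits at the background level.  Puncta pixels from the layout add a
    static calcium-insensitive source.  With ``two_channel`` (a 2×2
    mixing matrix, rows = observed channels, columns = [indicator,
    puncta] sources), the output gains a trailing channel axis; the
    matrix must be nonsingular.  Gaussian pixel noise is added last.
    """
    from .movie_io import Movie  # local import avoids a module cycle

    if layout.roi_masks is None or len(layout.roi_masks) != len(traces):
        raise ValueError("layout must provide one ROI mask per trace")
    n_frames = traces[0].n_frames
    frame_rate = traces[0].frame_rate
    for tr in traces:
        if tr.n_frames != n_frames:
            raise ValueError("all traces must have equal frame counts")

    shape = _layout_shape(layout)
    flat_seen = np.zeros(shape, dtype=bool)
    for pix in layout.roi_masks.values():
        if flat_seen[pix[:, 0], pix[:, 1]].any():
            raise ValueError("ROI masks overlap")
        flat_seen[pix[:, 0], pix[:, 1]] = True

    rng = np.random.default_rng(seed)
    indicator = np.full((n_frames,) + shape, background, dtype=float)
    for i, tr in zip(layout.roi_masks, traces):
        pix = layout.roi_masks[i]
        indicator[:, pix[:, 0], pix[:, 1]] = background + tr.values[:, None]

    puncta = np.zeros(shape, dtype=float)
    if layout.puncta_pixels is not None:
        puncta[layout.puncta_pixels[:, 0], layout.puncta_pixels[:, 1]] = \
            puncta_brightness

    if two_channel is None:
        data = indicator + puncta[None, :, :]
        if pixel_noise_sd > 0:
            data = data + rng.normal(0.0, pixel_noise_sd, size=data.shape)
        return Movie(data=np.maximum(data, 0.0), frame_rate=frame_rate)

    m = np.asarray(two_channel, dtype=float)
    if m.shape != (2, 2):
        raise ValueError("mixing matrix must be 2×2")
    if abs(np.linalg.det(m)) < 1e-12:
        raise ValueError("mixing matrix is singular")
    sources = np.stack([indicator,
                        np.broadcast_to(puncta, indicator.shape)], axis=-1)
    data = sources @ m.T     # observed channels, last axis
    if pixel_noise_sd > 0:
        data = data + rng.normal(0.0, pixel_noise_sd, size=data.shape)
    return Movie(data=np.maximum(data, 0.0), frame_rate=frame_rate,
                 channel_names=("red", "green"))


def _layout_shape(layout: GroundTruth) -> tuple[int, int]:
    if layout.frame_shape is not None:
        return tuple(layout.frame_shape)
    pix = np.vstack([p for p in layout.roi_masks.values()]
                    + ([layout.puncta_pixels]
                       if layout.puncta_pixels is not None else []))
    return int(pix[:, 0].max()) + 2, int(pix[:, 1].max()) + 2


# ---------------------------------------------------------------------------
# ground-truth sidecar (plain JSON; pixel lists run-length encoded per row)


def _rle_encode(pixels: np.ndarray) -> list[list[int]]:
    """Encode an (N, 2) pixel set as rows of [row, col_start, run_length]."""
    runs = []
    order = np.lexsort((pixels[:, 1], pixels[:, 0]))
    px = pixels[order]
    start = px[0]
    length = 1
    for prev, cur in zip(px[:-1], px[1:]):
        if cur[0] == prev[0] and cur[1] == prev[1] + 1:
            length += 1
        else:
            runs.append([int(start[0]), int(start[1]), length])
            start, length = cur, 1
    runs.append([int(start[0]), int(start[1]), length])
    return runs


def _rle_decode(runs: list[list[int]]) -> np.ndarray:
    pix = [(r, c0 + k) for r, c0, n in runs for k in range(n)]
    return np.asarray(pix, dtype=int)


def write_ground_truth(truth: GroundTruth, path) -> None:
    doc = {
        "spike_times_s": [float(t) for t in truth.spike_times],
        "burst_amplitudes": [float(a) for a in truth.burst_amplitudes],
        "burst_sizes": [int(s) for s in truth.burst_sizes],
        "roi_masks_rle": ({str(k): _rle_encode(v)
                           for k, v in truth.roi_masks.items()}
                          if truth.roi_masks else None),
        "puncta_pixels_rle": (_rle_encode(truth.puncta_pixels)
                              if truth.puncta_pixels is not None
                              and len(truth.puncta_pixels) else None),
        "mixing_matrix": (np.asarray(truth.mixing_matrix).tolist()
                          if truth.mixing_matrix is not None else None),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_ground_truth(path) -> GroundTruth:
    with open(path) as fh:
        doc = json.load(fh)
    return GroundTruth(
        spike_times=np.asarray(doc["spike_times_s"], dtype=float),
        burst_amplitudes=np.asarray(doc["burst_amplitudes"], dtype=float),
        burst_sizes=np.asarray(doc["burst_sizes"], dtype=int),
        roi_masks=({int(k): _rle_decode(v)
                    for k, v in doc["roi_masks_rle"].items()}
                   if doc.get("roi_masks_rle") else None),
        puncta_pixels=(_rle_decode(doc["puncta_pixels_rle"])
                       if doc.get("puncta_pixels_rle") else None),
        mixing_matrix=(np.asarray(doc["mixing_matrix"], dtype=float)
                       if doc.get("mixing_matrix") else None),
    )
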