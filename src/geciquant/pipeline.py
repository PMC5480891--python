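"""End-to-end orchestration of the characterization stages.

One YAML config drives five modes: ``simulate`` (write a synthetic
ground-truth dataset), ``spontaneous`` (event detection and activity
summaries), ``evoked`` (spike-triggered transients, amplitude-vs-AP
curves and detection efficiency), ``stability`` (longitudinal pooling
and ANOVA), and ``unmix`` (two-channel spectral separation).  Outputs
are CSV/JSON files with fixed names under the configured output
directory, plus a run log echoing every parameter used.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import AnalysisConfig, SpikeTrain
from .detection import baseline_snr_null, calibrate_threshold, \
    detection_efficiency
from .dff import activity_summary, compute_dff, detect_events
from .evoked import amplitude_vs_ap_count, analyze_evoked, single_ap_waveform
from .movie_io import extract_trace, read_movie, read_rois, read_spikes, \
    read_traces, write_movie, write_traces
from .stability import SessionRecord, nested_anova, session_summary
from .synthetic import IndicatorModel, SimulationConfig, generate_spike_train, \
    grid_layout, render_movie, simulate_trace, write_ground_truth
from .unmixing import MixingMatrix, classify_puncta, unmix

__all__ = ["PipelineConfig", "run"]

_MODES = ("simulate", "spontaneous", "evoked", "stability", "unmix")
_FLOAT_FMT = "%.6f"


@dataclass
class PipelineConfig:
    """Parsed pipeline configuration (see :func:`PipelineConfig.from_yaml`)."""

    mode: str
    out_dir: Path
    seed: int = 0
    frame_rate: float = 12.0
    paths: dict = field(default_factory=dict)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    simulate: dict = field(default_factory=dict)
    unmix: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")
        self.out_dir = Path(self.out_dir)
        needed = {"spontaneous": ["traces"], "evoked": ["traces", "spikes"],
                  "stability": ["sessions"], "unmix": ["movie", "rois"],
                  "simulate": []}[self.mode]
        for key in needed:
            p = self.paths.get(key)
            if p is None:
                raise FileNotFoundError(
                    f"mode '{self.mode}' requires paths.{key}")
            if not Path(p).exists():
                raise FileNotFoundError(
                    f"paths.{key} = {p} does not exist")

    @classmethod
    def from_yaml(cls, path, seed: int | None = None) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        analysis = AnalysisConfig(**doc.get("analysis", {}))
        cfg = cls(mode=doc["mode"], out_dir=doc.get("out_dir", "out"),
                  seed=int(doc.get("seed", 0)),
                  frame_rate=float(doc.get("frame_rate", 12.0)),
                  paths=doc.get("paths", {}) or {}, analysis=analysis,
                  simulate=doc.get("simulate", {}) or {},
                  unmix=doc.get("unmix", {}) or {})
        if seed is not None:
            cfg.seed = int(seed)
        return cfg


def run(config: PipelineConfig) -> dict:
    """Execute the configured mode; returns {output name: path}.

    Deterministic for a fixed seed.  Any stage failure propagates as an
    exception naming the stage; no partial outputs are interpreted as
    success.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    stage = config.mode
    try:
        outputs = _DISPATCH[stage](config)
    except Exception as exc:
        raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
    _write_log(config, outputs)
    outputs["run_log"] = str(out / "run_log.json")
    return outputs


def _write_log(config: PipelineConfig, outputs: dict) -> None:
    log = {
        "version": __version__,
        "mode": config.mode,
        "seed": config.seed,
        "frame_rate": config.frame_rate,
        "analysis": dataclasses.asdict(config.analysis),
        "paths": {k: str(v) for k, v in config.paths.items()},
        "outputs": {k: str(v) for k, v in outputs.items()},
        "exclusions": outputs.pop("_exclusions", []),
    }
    with open(config.out_dir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=1)


# ---------------------------------------------------------------------------
# stages


def _simulate(config: PipelineConfig) -> dict:
    sim_doc = dict(config.simulate)
    n_rois = int(sim_doc.pop("n_rois", 4))
    two_channel = sim_doc.pop("two_channel", False)
    n_puncta = int(sim_doc.pop("n_puncta", 6 if two_channel else 0))
    model = IndicatorModel(**sim_doc.pop("indicator", {}))
    sim = SimulationConfig(seed=config.seed,
                           frame_rate=config.frame_rate, **sim_doc)

    traces, truths = [], []
    for i in range(n_rois):
        sub = dataclasses.replace(sim, seed=sim.seed + 1 + i)
        spikes = generate_spike_train(sub)
        tr, truth = simulate_trace(spikes, model, sub)
        tr.roi_id = i
        traces.append(tr)
        truths.append(truth)

    layout = grid_layout(n_rois, n_puncta=n_puncta, seed=sim.seed)
    layout.spike_times = truths[0].spike_times
    layout.burst_amplitudes = truths[0].burst_amplitudes
    layout.burst_sizes = truths[0].burst_sizes
    mixing = np.array([[0.9, 0.2], [0.1, 0.8]]) if two_channel else None
    layout.mixing_matrix = mixing
    movie = render_movie(traces, layout, two_channel=mixing,
                         seed=sim.seed + 1000, pixel_noise_sd=1.0)

    out = config.out_dir
    write_movie(movie, out / "movie.tif")
    write_traces(traces, out / "traces.csv")
    write_ground_truth(layout, out / "ground_truth.json")
    per_roi = {f"roi_{i}": {"spike_times_s": truths[i].spike_times.tolist(),
                            "burst_amplitudes":
                                truths[i].burst_amplitudes.tolist(),
                            "burst_sizes": truths[i].burst_sizes.tolist()}
               for i in range(n_rois)}
    with open(out / "spike_truth.json", "w") as fh:
        json.dump(per_roi, fh, indent=1)
    return {"movie": str(out / "movie.tif"),
            "traces": str(out / "traces.csv"),
            "ground_truth": str(out / "ground_truth.json"),
            "spike_truth": str(out / "spike_truth.json")}


def _load_traces(config: PipelineConfig):
    return read_traces(config.paths["traces"], config.frame_rate)


def _spontaneous(config: PipelineConfig) -> dict:
    rows, summary_rows = [], []
    for tr in _load_traces(config):
        dff = compute_dff(tr, config.analysis)
        events = detect_events(dff, config.analysis)
        rate, active = activity_summary(events, dff, config.analysis)
        summary_rows.append({"roi_id": tr.roi_id, "n_events": len(events),
                             "event_rate_per_min": rate, "is_active": active,
                             "f0": dff.f0})
        for ev in events:
            rows.append({"roi_id": tr.roi_id,
                         "onset_s": ev.onset_frame / dff.frame_rate,
                         "peak_s": ev.peak_frame / dff.frame_rate,
                         "amplitude_pct": 100 * ev.peak_amplitude,
                         "tau_s": ev.decay_tau, "r2": ev.fit_r2})
    out = config.out_dir
    pd.DataFrame(rows, columns=["roi_id", "onset_s", "peak_s",
                                "amplitude_pct", "tau_s", "r2"]
                 ).to_csv(out / "events.csv", index=False,
                          float_format=_FLOAT_FMT)
    pd.DataFrame(summary_rows).to_csv(out / "activity.csv", index=False,
                                      float_format=_FLOAT_FMT)
    return {"events": str(out / "events.csv"),
            "activity": str(out / "activity.csv")}


def _evoked(config: PipelineConfig) -> dict:
    traces = _load_traces(config)
    exclusions = []
    all_transients = []
    dffs, spike_trains = [], []
    rows = []
    for tr in traces:
        dff = compute_dff(tr, config.analysis)
        spikes = read_spikes(config.paths["spikes"], duration=dff.duration)
        transients, excluded = analyze_evoked(dff, spikes, config.analysis)
        dffs.append(dff)
        spike_trains.append(spikes)
        all_transients.extend(transients)
        for i, t in enumerate(transients):
            rows.append({"roi_id": tr.roi_id, "burst_id": i,
                         "n_aps": t.burst.n_aps,
                         "first_ap_s": t.burst.first_ap_time,
                         "amplitude_pct": 100 * t.peak_amplitude,
                         "tau_s": t.decay_tau, "snr": t.snr})
        exclusions.extend(
            {"roi_id": tr.roi_id, "first_ap_s": e.burst.first_ap_time,
             "reason": e.reason} for e in excluded)

    if not all_transients:
        raise ValueError("no analyzable evoked transients")
    out = config.out_dir
    pd.DataFrame(rows).to_csv(out / "evoked.csv", index=False,
                              float_format=_FLOAT_FMT)
    amplitude_vs_ap_count(all_transients).to_csv(
        out / "amplitude_vs_ap.csv", index=False, float_format=_FLOAT_FMT)
    try:
        wf = single_ap_waveform(dffs[0], [t for t in all_transients],
                                config.analysis)
        wf.assign(mean_dff_pct=100 * wf["mean_dff"],
                  sem_pct=100 * wf["sem"]).to_csv(
            out / "single_ap_waveform.csv", index=False,
            float_format=_FLOAT_FMT)
    except ValueError:
        pass  # no single-AP transients in this dataset

    nulls = baseline_snr_null(dffs, spike_trains, config.analysis)
    thr = calibrate_threshold(nulls, config.analysis.fpr,
                              config.analysis.threshold_method)
    eff = detection_efficiency(all_transients, thr)
    table = eff.table.assign(
        fraction_pct=(100 * eff.table["fraction"]).round().astype(int))
    table.to_csv(out / "detection.csv", index=False, float_format=_FLOAT_FMT)
    with open(out / "threshold.json", "w") as fh:
        json.dump({"mu": thr.mu_null, "sigma": thr.sigma_null,
                   "threshold": thr.threshold, "fpr": thr.fpr,
                   "method": thr.method}, fh, indent=1)
    return {"evoked": str(out / "evoked.csv"),
            "amplitude_vs_ap": str(out / "amplitude_vs_ap.csv"),
            "detection": str(out / "detection.csv"),
            "threshold": str(out / "threshold.json"),
            "_exclusions": exclusions}


def _stability(config: PipelineConfig) -> dict:
    sessions = pd.read_csv(config.paths["sessions"])
    for col in ("mouse_id", "session_id", "dpi", "traces_csv"):
        if col not in sessions.columns:
            raise ValueError(f"sessions CSV needs a '{col}' column")
    base = Path(config.paths["sessions"]).parent
    records, amp_rows = [], []
    for _, row in sessions.iterrows():
        traces = read_traces(base / row["traces_csv"], config.frame_rate)
        events = {}
        duration = None
        for tr in traces:
            dff = compute_dff(tr, config.analysis)
            events[tr.roi_id] = detect_events(dff, config.analysis)
            duration = dff.duration
        rec = SessionRecord(mouse_id=str(row["mouse_id"]),
                            session_id=str(row["session_id"]),
                            dpi=int(row["dpi"]), events=events,
                            duration_s=duration, n_rois_total=len(traces))
        records.append(rec)
        for ev_list in events.values():
            amp_rows.extend({"mouse": rec.mouse_id, "dpi": rec.dpi,
                             "amplitude": e.peak_amplitude}
                            for e in ev_list)

    out = config.out_dir
    session_summary(records).to_csv(out / "stability.csv", index=False,
                                    float_format=_FLOAT_FMT)
    anova_doc = {}
    df = pd.DataFrame(amp_rows)
    if not df.empty and df["mouse"].nunique() >= 2 and df["dpi"].nunique() >= 2:
        for res in nested_anova(df["amplitude"], df["mouse"], df["dpi"]):
            anova_doc[res.factor] = {"F": res.F, "df_num": res.df_num,
                                     "df_den": res.df_den, "p": res.p,
                                     "degenerate": res.degenerate}
    with open(out / "anova.json", "w") as fh:
        json.dump(anova_doc, fh, indent=1)
    return {"stability": str(out / "stability.csv"),
            "anova": str(out / "anova.json")}


def _unmix(config: PipelineConfig) -> dict:
    movie = read_movie(config.paths["movie"], config.frame_rate)
    if movie.n_channels != 2:
        raise ValueError("unmix mode requires a two-channel movie")
    rois = read_rois(config.paths["rois"], movie.frame_shape)
    doc = config.unmix
    if "matrix" in doc:
        matrix = MixingMatrix(np.asarray(doc["matrix"], dtype=float))
    else:
        from .unmixing import estimate_mixing
        matrix = estimate_mixing(movie.data,
                                 rois.rois[int(doc["indicator_ref"])],
                                 rois.rois[int(doc["puncta_ref"])])
    res = unmix(movie.data, matrix)

    out = config.out_dir
    from .movie_io import Movie
    for k, name in enumerate(("indicator", "puncta")):
        write_movie(Movie(data=res.sources[..., k],
                          frame_rate=config.frame_rate),
                    out / f"unmixed_{name}.tif")

    source_movie = Movie(data=res.sources[..., 0],
                         frame_rate=config.frame_rate)
    dffs, events = {}, {}
    for rid in rois.rois:
        tr = extract_trace(source_movie, rois, rid)
        dff = compute_dff(tr, config.analysis)
        dffs[rid] = dff
        events[rid] = detect_events(dff, config.analysis)
    classify_puncta(dffs, events).to_csv(out / "classification.csv",
                                         index=False, float_format=_FLOAT_FMT)
    with open(out / "mixing.json", "w") as fh:
        json.dump({"matrix": matrix.m.tolist(), "cond": matrix.cond,
                   "n_clipped": res.n_clipped}, fh, indent=1)
    return {"unmixed_indicator": str(out / "unmixed_indicator.tif"),
            "unmixed_puncta": str(out / "unmixed_puncta.tif"),
            "classification": str(out / "classification.csv"),
            "mixing": str(out / "mixing.json")}


_DISPATCH = {"simulate": _simulate, "spontaneous": _spontaneous,
             "evoked": _evoked, "stability": _stability, "unmix": _unmix}
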