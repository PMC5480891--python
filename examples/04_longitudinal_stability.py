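"""Longitudinal stability statistics across pseudo-sessions.

Four imaging sessions (22/45/65/100 days post-induction) are simulated
from one stationary generator for two mice; pooled amplitudes are then
tested for mouse and session effects with the fixed-effects ANOVA, and
matched-cell amplitude distributions compared with the rank-sum test.
"""
import dataclasses

import numpy as np

from geciquant import (AnalysisConfig, IndicatorModel, SessionRecord,
                       SimulationConfig, amplitude_distributions, compute_dff,
                       detect_events, generate_spike_train, nested_anova,
                       ranksum, session_summary, simulate_trace)

model = IndicatorModel(single_ap_amplitude=0.15)  # well-detectable events
analysis = AnalysisConfig(decay_offset=True)      # see example 01
records = []
for m, mouse in enumerate(("m1", "m2")):
    for s, dpi in enumerate((22, 45, 65, 100)):
        cfg = SimulationConfig(duration=300.0, firing_rate=0.1,
                               seed=1000 * m + 10 * s + 1)
        events = {}
        for roi in range(8):
            sub = dataclasses.replace(cfg, seed=cfg.seed + 100 * roi)
            tr, _ = simulate_trace(generate_spike_train(sub), model, sub)
            events[roi] = detect_events(compute_dff(tr, analysis), analysis)
        records.append(SessionRecord(mouse_id=mouse, session_id=f"{mouse}-{dpi}",
                                     dpi=dpi, events=events,
                                     duration_s=300.0, n_rois_total=8))

table = session_summary(records)
print(table[["dpi", "active_fraction", "event_rate_mean",
             "amplitude_mean", "tau_median"]].round(3).to_string(index=False))

amps, mice, dpis = [], [], []
for rec in records:
    for ev_list in rec.events.values():
        for ev in ev_list:
            amps.append(ev.peak_amplitude)
            mice.append(rec.mouse_id)
            dpis.append(rec.dpi)
res_mouse, res_session = nested_anova(amps, mice, dpis)
for r in (res_mouse, res_session):
    print(f"{r.factor}: F({r.df_num},{r.df_den}) = {r.F:.2f}, p = {r.p:.2f}")
print("-> the generator is stationary, so session effects only reach "
      "significance at chance level; amplitudes are stable over months")

dists = amplitude_distributions(records, roi_ids=set(range(8)))
w, p = ranksum(dists[65], dists[100])
print(f"matched cells, 65 vs 100 DPI amplitudes: rank-sum p = {p:.2f}")
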