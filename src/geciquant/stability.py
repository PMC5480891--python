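"""Longitudinal multi-session statistics.

Pools calcium-transient features (amplitude, decay constant, event rate)
across imaging sessions at different days post-induction (DPI) and asks
whether they drift: a two-factor fixed-effects ANOVA with mouse and
session factors sharing a common residual, a Wilcoxon rank-sum test for
matched-cell amplitude distributions, and per-session summary tables.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from scipy.stats import norm, rankdata

from .core import CalciumEvent

__all__ = [
    "SessionRecord",
    "AnovaResult",
    "nested_anova",
    "ranksum",
    "session_summary",
    "amplitude_distributions",
]


@dataclass
class SessionRecord:
    """Events of one imaging session, keyed for longitudinal pooling."""

    mouse_id: str
    session_id: str
    dpi: int
    events: dict[int | str, list[CalciumEvent]]  # roi_id -> events
    duration_s: float
    n_rois_total: int

    def __post_init__(self) -> None:
        if self.dpi < 0:
            raise ValueError("days post-induction must be non-negative")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.n_rois_active > self.n_rois_total:
            raise ValueError("more active ROIs than ROIs in total")

    @property
    def n_rois_active(self) -> int:
        return sum(1 for ev in self.events.values() if len(ev) >= 1)


@dataclass(frozen=True)
class AnovaResult:
    """F-test for one factor of the fixed-effects decomposition."""

    factor: str
    F: float
    df_num: int
    df_den: int
    p: float
    ss: float
    degenerate: bool = False


def _factor_ss(values: np.ndarray, *label_sets: np.ndarray) -> float:
    """Model sum of squares of an additive fixed-effects fit (via OLS on
    dummy codes), measured about the grand mean."""
    n = values.size
    cols = [np.ones(n)]
    for labels in label_sets:
        levels = np.unique(labels)
        for lev in levels[1:]:
            cols.append((labels == lev).astype(float))
    X = np.column_stack(cols)
    fitted = X @ np.linalg.lstsq(X, values, rcond=None)[0]
    return float(np.sum((fitted - values.mean()) ** 2))


def nested_anova(values, mouse_labels, session_labels
                 ) -> tuple[AnovaResult, AnovaResult]:
    """Two-factor fixed-effects ANOVA with a common residual term.

    Sequential (Type-I) sums of squares in the order mouse, then
    session; degrees of freedom are (m−1), (s−1) and
    N−1−(m−1)−(s−1) for the residual, so with 2 mice and 4 sessions the
    F ratios carry the familiar F(1, N−5) / F(3, N−5) pattern.  On
    balanced data the decomposition is exact:
    SS_total = SS_mouse + SS_session + SS_residual.

    Designs with empty (mouse, session) cells are analyzed as-is with an
    unbalanced-design warning; Type-I SS then depend on the factor order.
    """
    y = np.asarray(values, dtype=float)
    mouse = np.asarray(mouse_labels)
    session = np.asarray(session_labels)
    if not (y.size == mouse.size == session.size):
        raise ValueError("values and label arrays must have equal length")
    m_levels, s_levels = np.unique(mouse), np.unique(session)
    m, s = m_levels.size, s_levels.size
    if m < 2 or s < 2:
        raise ValueError("need at least 2 mice and 2 sessions")

    cells = {(a, b) for a, b in zip(mouse, session)}
    if len(cells) < m * s:
        warnings.warn("unbalanced design with empty cells; Type-I SS in "
                      "fixed label order (mouse, then session)", stacklevel=2)

    n = y.size
    ss_total = float(np.sum((y - y.mean()) ** 2))
    df_mouse, df_session = m - 1, s - 1
    df_res = n - 1 - df_mouse - df_session
    if df_res < 1:
        raise ValueError("not enough observations for a residual term")

    if ss_total == 0:
        res = [AnovaResult(f, 0.0, d, df_res, float("nan"), 0.0,
                           degenerate=True)
               for f, d in (("mouse", df_mouse), ("session", df_session))]
        return res[0], res[1]

    ss_mouse = _factor_ss(y, mouse)
    ss_both = _factor_ss(y, mouse, session)
    ss_session = max(ss_both - ss_mouse, 0.0)
    ss_res = max(ss_total - ss_both, 0.0)
    ms_res = ss_res / df_res

    def result(name: str, ss: float, df: int) -> AnovaResult:
        if ms_res == 0:
            return AnovaResult(name, float("inf") if ss > 0 else 0.0,
                               df, df_res, 0.0 if ss > 0 else float("nan"),
                               ss, degenerate=True)
        F = (ss / df) / ms_res
        return AnovaResult(name, F, df, df_res,
                           float(f_dist.sf(F, df, df_res)), ss)

    return result("mouse", ss_mouse, df_mouse), \
        result("session", ss_session, df_session)


def ranksum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns the rank sum W of the first sample and the two-sided p-value:
    exact by enumeration of all rank assignments when the combined sample
    has at most 20 observations (ties handled through midranks), and the
    normal approximation with tie correction and continuity correction
    otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = x.size, y.size
    n = nx + ny
    ranks = rankdata(np.concatenate([x, y]))
    w = float(ranks[:nx].sum())
    e_w = nx * (n + 1) / 2.0

    if n <= 20:
        dev = abs(w - e_w)
        hits = total = 0
        for idx in combinations(range(n), nx):
            total += 1
            if abs(ranks[list(idx)].sum() - e_w) >= dev - 1e-9:
                hits += 1
        return w, hits / total

    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts))
    var_w = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1.0)))
    if var_w == 0:
        return w, 1.0
    z = (abs(w - e_w) - 0.5) / np.sqrt(var_w)
    return w, float(min(1.0, 2.0 * norm.sf(max(z, 0.0))))


def session_summary(records: list[SessionRecord]) -> pd.DataFrame:
    """Per-DPI pooled statistics.

    Event rates (events/min) are computed per active ROI — neurons with
    at least one detected transient — matching how spontaneous-activity
    frequencies are conventionally reported; amplitude statistics pool
    all events of the session.  τ is summarized by median and IQR over
    events whose decay fit reached r² ≥ 0.5: overlapping transients
    inside the fit window produce occasional unbounded τ estimates, so
    the pooled summary must be robust.  The output is sorted by DPI and
    is invariant to the order of the input records.
    """
    if not records:
        raise ValueError("need at least one session record")
    rows = []
    for dpi in sorted({r.dpi for r in records}):
        recs = [r for r in records if r.dpi == dpi]
        rates, amps, taus = [], [], []
        n_total = n_active = 0
        for r in recs:
            n_total += r.n_rois_total
            n_active += r.n_rois_active
            for ev in r.events.values():
                if ev:
                    rates.append(len(ev) / (r.duration_s / 60.0))
                amps.extend(e.peak_amplitude for e in ev)
                taus.extend(e.decay_tau for e in ev
                            if e.has_tau and e.fit_r2 >= 0.5)
        rows.append({
            "dpi": dpi,
            "n_rois_total": n_total,
            "n_rois_active": n_active,
            "active_fraction": n_active / n_total if n_total else np.nan,
            "event_rate_mean": float(np.mean(rates)) if rates else 0.0,
            "event_rate_sd": (float(np.std(rates, ddof=1))
                              if len(rates) > 1 else np.nan),
            "amplitude_mean": float(np.mean(amps)) if amps else np.nan,
            "amplitude_sd": (float(np.std(amps, ddof=1))
                             if len(amps) > 1 else np.nan),
            "tau_median": float(np.median(taus)) if taus else np.nan,
            "tau_iqr": (float(np.subtract(*np.percentile(taus, [75, 25])))
                        if len(taus) > 1 else np.nan),
        })
    return pd.DataFrame(rows)


def amplitude_distributions(records: list[SessionRecord],
                            roi_ids: set | None = None
                            ) -> dict[int, np.ndarray]:
    """Sorted event-amplitude samples per DPI, optionally restricted to
    matched ROI identities (cells followed across sessions), ready for
    cumulative-distribution comparison with :func:`ranksum`."""
    out: dict[int, list[float]] = {}
    for r in records:
        bucket = out.setdefault(r.dpi, [])
        for rid, ev in r.events.items():
            if roi_ids is not None and rid not in roi_ids:
                continue
            bucket.extend(e.peak_amplitude for e in ev)
    return {dpi: np.sort(np.asarray(v)) for dpi, v in out.items()}
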