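"""Longitudinal statistics: fixed-effects ANOVA, rank-sum, summaries."""
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu, rankdata

from geciquant import (CalciumEvent, SessionRecord, amplitude_distributions,
                       nested_anova, ranksum, session_summary)


def brute_force_anova(values, mouse, session):
    """Independent sums-of-squares oracle via explicit group means."""
    y = np.asarray(values, float)
    mouse = np.asarray(mouse)
    session = np.asarray(session)
    gm = y.mean()
    ss_total = np.sum((y - gm) ** 2)
    ss_mouse = sum(np.sum(mouse == m) * (y[mouse == m].mean() - gm) ** 2
                   for m in np.unique(mouse))
    # balanced designs: session SS about the grand mean
    ss_session = sum(np.sum(session == s) * (y[session == s].mean() - gm) ** 2
                     for s in np.unique(session))
    ss_res = ss_total - ss_mouse - ss_session
    return ss_total, ss_mouse, ss_session, ss_res


class TestNestedAnova:
    def _balanced(self, seed=0, reps=2, effect=0.0):
        rng = np.random.default_rng(seed)
        rows = []
        for m in ("m1", "m2"):
            for s in range(4):
                for _ in range(reps):
                    rows.append((rng.normal(effect * (m == "m2"), 1.0), m, s))
        y, mouse, session = map(np.asarray, zip(*rows))
        return y.astype(float), mouse, session

    def test_matches_brute_force_on_balanced_data(self):
        y, mouse, session = self._balanced(seed=1)
        res_m, res_s = nested_anova(y, mouse, session)
        ss_total, ss_m, ss_s, ss_res = brute_force_anova(y, mouse, session)
        m, s, n = 2, 4, y.size
        df_res = n - 1 - (m - 1) - (s - 1)
        assert res_m.ss == pytest.approx(ss_m, abs=1e-10)
        assert res_s.ss == pytest.approx(ss_s, abs=1e-10)
        assert res_m.F == pytest.approx(
            (ss_m / (m - 1)) / (ss_res / df_res), abs=1e-10)
        assert res_s.df_num == 3 and res_s.df_den == df_res

    def test_matches_statsmodels_type1(self):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols
        y, mouse, session = self._balanced(seed=2, reps=3, effect=0.7)
        df = pd.DataFrame({"y": y, "mouse": mouse,
                           "session": session.astype(str)})
        fit = ols("y ~ C(mouse) + C(session)", data=df).fit()
        table = sm.stats.anova_lm(fit, typ=1)
        res_m, res_s = nested_anova(y, mouse, session)
        assert res_m.F == pytest.approx(table.loc["C(mouse)", "F"], rel=1e-8)
        assert res_s.F == pytest.approx(table.loc["C(session)", "F"],
                                        rel=1e-8)
        assert res_m.p == pytest.approx(table.loc["C(mouse)", "PR(>F)"],
                                        rel=1e-8)

    def test_ss_identity_on_balanced_data(self):
        y, mouse, session = self._balanced(seed=3, reps=5, effect=0.4)
        res_m, res_s = nested_anova(y, mouse, session)
        ss_total = float(np.sum((y - y.mean()) ** 2))
        ss_res = ss_total - res_m.ss - res_s.ss
        ms_res = ss_res / res_m.df_den
        assert res_m.F * ms_res * res_m.df_num == pytest.approx(
            res_m.ss, rel=1e-9)
        # identity SS_total = SS_mouse + SS_session + SS_residual
        bt, bm, bs, br = brute_force_anova(y, mouse, session)
        assert bm + bs + br == pytest.approx(bt, rel=1e-9)
        assert res_m.ss + res_s.ss + ss_res == pytest.approx(ss_total,
                                                             rel=1e-9)

    def test_identical_values_degenerate(self):
        y = np.full(16, 2.5)
        mouse = np.repeat(["a", "b"], 8)
        session = np.tile(np.repeat([0, 1], 4), 2)
        res_m, res_s = nested_anova(y, mouse, session)
        assert res_m.degenerate and res_m.F == 0.0

    def test_type_one_error_rate_calibrated(self):
        # under the null (no mouse, no session effect) the session F-test
        # rejects at alpha=0.05 in 5% +/- 1.5% of replicates
        rng = np.random.default_rng(42)
        mouse = np.repeat(["m1", "m2"], 40)
        session = np.tile(np.repeat([0, 1, 2, 3], 10), 2)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            y = rng.standard_normal(80)
            _, res_s = nested_anova(y, mouse, session)
            rejections += res_s.p < 0.05
        assert rejections / n_rep == pytest.approx(0.05, abs=0.015)

    def test_unbalanced_design_warns(self):
        y = np.arange(10.0)
        mouse = np.array(["a"] * 5 + ["b"] * 5)
        session = np.array([0, 0, 0, 1, 1, 0, 0, 0, 0, 0])  # b never in s=1
        with pytest.warns(UserWarning, match="unbalanced"):
            nested_anova(y, mouse, session)

    def test_single_factor_level_rejected(self):
        with pytest.raises(ValueError):
            nested_anova(np.arange(6.0), ["a"] * 6, [0, 1, 0, 1, 0, 1])


class TestRanksum:
    def test_exact_small_sample(self):
        # x=[1,2] vs y=[3,4]: 2 of the 6 rank assignments are as extreme
        _, p = ranksum([1, 2], [3, 4])
        assert p == pytest.approx(1 / 3)

    def test_identical_samples_p_one(self):
        _, p = ranksum([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_exact_matches_permutation_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            x = rng.normal(0, 1, rng.integers(2, 5))
            y = rng.normal(0.5, 1, rng.integers(2, 5))
            w, p = ranksum(x, y)
            # full-permutation oracle
            pooled = np.concatenate([x, y])
            ranks = rankdata(pooled)
            nx, n = x.size, pooled.size
            e_w = nx * (n + 1) / 2
            dev = abs(ranks[:nx].sum() - e_w)
            hits = total = 0
            for idx in combinations(range(n), nx):
                total += 1
                hits += abs(ranks[list(idx)].sum() - e_w) >= dev - 1e-9
            assert p == pytest.approx(hits / total, abs=1e-12)

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 6)
        y = rng.normal(1, 1, 7)
        _, p = ranksum(x, y)
        ref = mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert p == pytest.approx(ref.pvalue, abs=1e-9)

    @settings(derandomize=True, max_examples=40)
    @given(seed=st.integers(0, 10**6))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 5)
        y = rng.normal(1, 1, 6)
        _, p1 = ranksum(x, y)
        _, p2 = ranksum(np.exp(x), np.exp(y))
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_large_sample_normal_approximation(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 30)
        y = rng.normal(0.8, 1, 35)
        _, p = ranksum(x, y)
        ref = mannwhitneyu(x, y, alternative="two-sided")
        assert p == pytest.approx(ref.pvalue, rel=0.05)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ranksum([], [1.0])


def _event(amp=0.1, tau=0.3):
    return CalciumEvent(onset_frame=0, peak_frame=1, peak_amplitude=amp,
                        decay_tau=tau, fit_r2=0.9)


def _record(mouse="m1", session="s1", dpi=22, n_active=2, n_total=4,
            events_per_roi=3, duration_s=180.0, amp=0.1):
    events = {}
    for i in range(n_total):
        events[i] = [_event(amp)] * events_per_roi if i < n_active else []
    return SessionRecord(mouse_id=mouse, session_id=session, dpi=dpi,
                         events=events, duration_s=duration_s,
                         n_rois_total=n_total)


class TestSessionSummary:
    def test_rates_and_active_fraction(self):
        rec = _record(n_active=5, n_total=20, events_per_roi=6,
                      duration_s=180.0)
        table = session_summary([rec])
        row = table.iloc[0]
        assert row["active_fraction"] == pytest.approx(0.25)
        assert row["event_rate_mean"] == pytest.approx(2.0)  # 6 events/3 min

    def test_mean_of_rates(self):
        rec = _record(n_active=3, n_total=3, duration_s=60.0)
        rec.events = {0: [_event()] * 1, 1: [_event()] * 2, 2: [_event()] * 3}
        table = session_summary([rec])
        assert table.iloc[0]["event_rate_mean"] == pytest.approx(2.0)

    def test_permutation_invariance(self):
        recs = [_record(dpi=d, amp=0.05 * (i + 1))
                for i, d in enumerate((22, 45, 65, 100))]
        a = session_summary(recs)
        b = session_summary(recs[::-1])
        pd.testing.assert_frame_equal(a, b)

    def test_amplitude_distributions_matched_rois(self):
        recs = [_record(dpi=65), _record(dpi=100, amp=0.2)]
        dists = amplitude_distributions(recs, roi_ids={0, 1})
        assert set(dists) == {65, 100}
        assert np.all(dists[100] == 0.2)

    def test_active_roi_invariant(self):
        with pytest.raises(ValueError):
            SessionRecord(mouse_id="m", session_id="s", dpi=10,
                          events={0: [_event()]}, duration_s=60.0,
                          n_rois_total=0)

    def test_stable_generator_sessions_yield_uniform_anova_p(self):
        # pseudo-sessions from one stationary generator: the session
        # factor should be null -- p-values spread over (0, 1), mean ~0.5
        rng = np.random.default_rng(9)
        ps = []
        for _ in range(200)[:200]:
            y = rng.standard_normal(48)
            mouse = np.repeat(["a", "b"], 24)
            session = np.tile(np.repeat([22, 45, 65, 100], 6), 2)
            _, res_s = nested_anova(y, mouse, session)
            ps.append(res_s.p)
        ps = np.asarray(ps)
        assert 0.4 < ps.mean() < 0.6
        assert (ps < 0.05).mean() < 0.11
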