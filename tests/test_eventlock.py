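"""Event-locked windows, activation, channel tests, time-course profiling."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from narrafnirs.datatypes import HemoSeries, InputError, PTSD, TEC
from narrafnirs.eventlock import (characterize_timecourse, extract_windows,
                                  grand_average, group_channel_test,
                                  subject_activation)

FS = 11.0
SEGS = {"rest": (0.0, 300.0), "digits1": (300.0, 330.0),
        "narration": (330.0, 510.0), "digits2": (510.0, 540.0)}


def make_hemo(hbo, subject_id="S"):
    hbo = np.atleast_2d(hbo)
    return HemoSeries(fs_hz=FS, hbo=hbo, hbr=-0.3 * hbo, segments=SEGS,
                      zscored=True, subject_id=subject_id)


class TestExtractWindows:
    def test_shape_contract(self):
        hemo = make_hemo(np.zeros(5940))
        ws = extract_windows(hemo, [335.0, 350.0, 400.0], 0)
        assert ws.windows.shape == (3, 110)

    def test_onset_too_near_end_dropped(self):
        hemo = make_hemo(np.zeros(5940))
        ws = extract_windows(hemo, [400.0, 536.0], 0)  # 536 + 10 > 540
        assert ws.n_events == 1

    def test_constant_series_gives_constant_windows(self):
        hemo = make_hemo(np.full(5940, 2.5))
        ws = extract_windows(hemo, [340.0, 360.0], 0)
        assert np.ptp(ws.windows) == 0.0

    def test_unzscored_input_rejected(self):
        hemo = make_hemo(np.zeros(5940))
        hemo.zscored = False
        with pytest.raises(InputError):
            extract_windows(hemo, [340.0], 0)


class TestSubjectActivation:
    def test_arithmetic(self):
        hbo = np.zeros(5940)
        hemo = make_hemo(hbo)
        hemo.hbo[0, hemo.segment_slice("digits1")] = 0.2
        hemo.hbo[0, hemo.segment_slice("digits2")] = 0.2
        ws = extract_windows(hemo, [340.0], 0)
        ws.windows[:] = 0.5
        assert subject_activation(ws, hemo) == pytest.approx(0.3)

    def test_identical_signal_everywhere_gives_zero(self):
        hemo = make_hemo(np.full(5940, 1.7))
        ws = extract_windows(hemo, [340.0, 400.0], 0)
        assert subject_activation(ws, hemo) == pytest.approx(0.0)

    def test_matches_flat_loop_recomputation(self):
        rng = np.random.default_rng(6)
        hemo = make_hemo(rng.normal(size=5940))
        onsets = [333.0, 341.5, 402.2, 490.0]
        ws = extract_windows(hemo, onsets, 0)
        got = subject_activation(ws, hemo)
        # brute force: loop sample by sample
        acc = []
        for onset in onsets:
            s = int(round(onset * FS))
            acc.extend(hemo.hbo[0, s:s + 110])
        digits = list(hemo.hbo[0, 3300:3630]) + list(hemo.hbo[0, 5610:5940])
        expected = np.mean(acc) - np.mean(digits)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_empty_windows_rejected(self):
        hemo = make_hemo(np.zeros(5940))
        ws = extract_windows(hemo, [539.0], 0)
        with pytest.raises(InputError):
            subject_activation(ws, hemo)


def mw_exact_p(x, y):
    """Exact two-sided Mann-Whitney p by full enumeration (oracle)."""
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    u_obs = sum(1 for xi in x for yi in y if xi > yi) \
        + 0.5 * sum(1 for xi in x for yi in y if xi == yi)
    stats = []
    for comb in itertools.combinations(range(n + m), n):
        xs = pooled[list(comb)]
        ys = np.delete(pooled, list(comb))
        u = sum(1 for xi in xs for yi in ys if xi > yi) \
            + 0.5 * sum(1 for xi in xs for yi in ys if xi == yi)
        stats.append(u)
    stats = np.asarray(stats)
    mu = n * m / 2
    return np.mean(np.abs(stats - mu) >= abs(u_obs - mu) - 1e-12)


def bh_definitional(p):
    """Benjamini-Hochberg adjusted p-values straight from the definition."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


def activation_frame(x, y):
    rows = [{"subject_id": f"P{i}", "group": PTSD, "channel": 0,
             "activation": v} for i, v in enumerate(x)]
    rows += [{"subject_id": f"T{i}", "group": TEC, "channel": 0,
              "activation": v} for i, v in enumerate(y)]
    return pd.DataFrame(rows)


class TestGroupChannelTest:
    def test_separated_triples_exact_p(self):
        res = group_channel_test(activation_frame([1, 2, 3], [4, 5, 6]))[0]
        assert res.u_stat == 0.0
        assert res.p_value == pytest.approx(0.1)

    def test_identical_groups_zero_delta_p_one(self):
        res = group_channel_test(activation_frame([2, 2, 2], [2, 2, 2]))[0]
        assert res.cliffs_delta == 0.0
        assert res.p_value == 1.0

    def test_small_groups_match_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            x = rng.normal(size=7)
            y = rng.normal(0.8, 1.0, size=6)
            res = group_channel_test(activation_frame(x, y))[0]
            assert res.p_value == pytest.approx(mw_exact_p(x, y), abs=1e-12)
            # the tie-corrected normal approximation stays close to exact
            asym = sps.mannwhitneyu(x, y, alternative="two-sided",
                                    method="asymptotic").pvalue
            assert abs(asym - mw_exact_p(x, y)) < 0.02

    def test_bh_hand_example(self):
        np.testing.assert_allclose(
            bh_definitional([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_q_values_match_definitional_bh(self):
        rng = np.random.default_rng(2)
        rows = []
        for ch in range(20):
            for i, v in enumerate(rng.normal(size=6)):
                rows.append({"subject_id": f"P{i}", "group": PTSD,
                             "channel": ch, "activation": v})
            for i, v in enumerate(rng.normal(0.4, 1, size=6)):
                rows.append({"subject_id": f"T{i}", "group": TEC,
                             "channel": ch, "activation": v})
        results = group_channel_test(pd.DataFrame(rows))
        q = np.array([r.q_value for r in results])
        p = np.array([r.p_value for r in results])
        np.testing.assert_allclose(q, bh_definitional(p), atol=1e-12)
        assert (q >= p - 1e-12).all() and ((0 <= q) & (q <= 1)).all()

    def test_too_few_subjects_rejected(self):
        with pytest.raises(InputError):
            group_channel_test(activation_frame([1.0], [2, 3]))


class TestGrandAverage:
    def test_single_subject_single_window(self):
        hemo = make_hemo(np.sin(np.arange(5940) / 50))
        ws = extract_windows(hemo, [340.0], 0)
        np.testing.assert_array_equal(grand_average([ws]), ws.windows[0])

    def test_two_constant_subjects(self):
        a = extract_windows(make_hemo(np.zeros(5940)), [340.0], 0)
        b = extract_windows(make_hemo(np.ones(5940)), [340.0, 400.0], 0)
        np.testing.assert_allclose(grand_average([a, b]), 0.5)

    def test_event_order_invariance(self):
        rng = np.random.default_rng(3)
        hemo = make_hemo(rng.normal(size=5940))
        ws = extract_windows(hemo, [340.0, 360.0, 380.0], 0)
        shuffled = extract_windows(hemo, [380.0, 340.0, 360.0], 0)
        np.testing.assert_allclose(grand_average([ws]),
                                   grand_average([shuffled]))

    def test_empty_group_rejected(self):
        with pytest.raises(InputError):
            grand_average([])


class TestCharacterizeTimecourse:
    def test_monotone_ramp_has_perfect_rank_correlation(self):
        prof = characterize_timecourse(np.linspace(0, 1, 110), FS)
        assert prof.spearman_r == pytest.approx(1.0)

    def test_flat_zero_series(self):
        prof = characterize_timecourse(np.zeros(110), FS)
        assert prof.no_latency
        assert prof.difference == 0.0

    def test_trapezoid_latency_recovered_within_one_sample(self):
        t = np.arange(110) / FS
        series = np.interp(t, [0, 3.82, 7.55, 10.0], [0, 0, 1.0, 0.4])
        # small baseline wiggle so the 2 SD threshold is meaningful
        series[:22] += 1e-3 * np.sin(np.arange(22))
        prof = characterize_timecourse(series, FS)
        assert prof.latency_s is not None
        assert abs(prof.latency_s - 3.82) <= 1.0 / FS + 1e-9
        assert prof.peak_time_s == pytest.approx(7.55, abs=1.0 / FS)
        assert prof.difference == pytest.approx(series.max() - series.min())

    def test_slope_consistency_on_noiseless_profile(self):
        # slope(per sample) x rise length(samples) ~ peak - baseline
        t = np.arange(110) / FS
        series = np.interp(t, [0, 3.82, 7.55, 10.0], [0, 0, 1.0, 0.4])
        series[:22] += 1e-4 * np.sin(np.arange(22))
        prof = characterize_timecourse(series, FS)
        rise_samples = (prof.peak_time_s - prof.latency_s) * FS
        assert prof.slope_per_sample * rise_samples == \
            pytest.approx(prof.peak_value, rel=0.05)

    def test_early_plateau_flags_no_latency(self):
        series = np.ones(110)
        series[0] = 0.99  # tiny baseline variance
        prof = characterize_timecourse(series, FS)
        assert prof.no_latency and prof.latency_s is None
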