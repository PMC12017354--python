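"""Event-locked Oxy-Hb analysis around negative-word onsets.

Z-scored Oxy-Hb is windowed for 10 s after each negative-word onset;
per-subject activation is the pooled window mean minus the mean over the
two digit-repetition control blocks; group differences are tested per
channel with Mann-Whitney U and Benjamini-Hochberg FDR; the group-average
window is characterised by latency, slope, peak and a rank correlation
with time.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .datatypes import (ChannelTestResult, EventWindowSet, HemoSeries,
                        InputError, TimecourseProfile, PTSD, TEC)
from .stats import cliffs_delta

log = logging.getLogger(__name__)

WINDOW_S = 10.0


def extract_windows(hemo: HemoSeries, onsets_s: Sequence[float], channel: int,
                    window_s: float = WINDOW_S) -> EventWindowSet:
    """Slice 10 s Oxy-Hb windows after each onset (absolute recording time).

    Onsets with fewer than ``window_s`` seconds of recording remaining are
    dropped (and logged).  Overlapping windows are permitted.
    """
    if not hemo.zscored:
        raise InputError("extract_windows expects z-scored input")
    onsets = np.asarray(sorted(onsets_s), float)
    n_win = int(round(window_s * hemo.fs_hz))
    starts = np.round(onsets * hemo.fs_hz).astype(int)
    keep = starts + n_win <= hemo.n_samples
    if (~keep).any():
        log.info("extract_windows: dropped %d onsets too close to the end",
                 int((~keep).sum()))
    starts = starts[keep]
    windows = np.stack([hemo.hbo[channel, s:s + n_win] for s in starts]) \
        if starts.size else np.empty((0, n_win))
    return EventWindowSet(subject_id=hemo.subject_id or "", channel=channel,
                          onsets_s=onsets[keep], windows=windows,
                          fs_hz=hemo.fs_hz)


def subject_activation(windows: EventWindowSet, hemo: HemoSeries) -> float:
    """Pooled window mean minus the pooled digit-task baseline mean."""
    if windows.n_events == 0:
        raise InputError("no usable event windows for this subject")
    for seg in ("digits1", "digits2"):
        if seg not in hemo.segments:
            raise InputError(f"missing digit segment {seg!r}")
    ch = windows.channel
    digit = np.concatenate([hemo.hbo[ch, hemo.segment_slice("digits1")],
                            hemo.hbo[ch, hemo.segment_slice("digits2")]])
    return float(windows.windows.mean() - digit.mean())


def group_channel_test(table: pd.DataFrame) -> list[ChannelTestResult]:
    """Channelwise two-sided Mann-Whitney U with BH-FDR across channels.

    ``table`` columns: subject_id, group, channel, activation.  Exact U
    enumeration when both groups have <= 8 subjects and no ties; the
    tie-corrected normal approximation otherwise.  Cliff's delta
    (PTSD vs TEC) is reported as the effect size.
    """
    results: list[ChannelTestResult] = []
    raw_p: list[float] = []
    for channel, sub in table.groupby("channel"):
        x = sub.loc[sub["group"] == PTSD, "activation"].to_numpy(float)
        y = sub.loc[sub["group"] == TEC, "activation"].to_numpy(float)
        if x.size < 2 or y.size < 2:
            raise InputError(f"channel {channel}: need >= 2 subjects per group")
        both = np.concatenate([x, y])
        if np.ptp(both) == 0:
            u, p = x.size * y.size / 2.0, 1.0
        else:
            no_ties = np.unique(both).size == both.size
            method = "exact" if (x.size <= 8 and y.size <= 8 and no_ties) \
                else "asymptotic"
            res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
            u, p = float(res.statistic), float(res.pvalue)
        results.append(ChannelTestResult(
            channel=int(channel), u_stat=u, p_value=p, q_value=np.nan,
            cliffs_delta=cliffs_delta(x, y),
            median_ptsd=float(np.median(x)), median_tec=float(np.median(y)),
            n_ptsd=x.size, n_tec=y.size))
        raw_p.append(p)
    _, q, _, _ = multipletests(raw_p, method="fdr_bh")
    for r, qi in zip(results, q):
        r.q_value = float(qi)
    return results


def grand_average(windowsets: Iterable[EventWindowSet]) -> np.ndarray:
    """Within-subject mean over events, then unweighted mean over subjects."""
    per_subject = [ws.windows.mean(axis=0) for ws in windowsets
                   if ws.n_events > 0]
    if not per_subject:
        raise InputError("no subjects with usable windows")
    return np.mean(per_subject, axis=0)


def characterize_timecourse(series: np.ndarray, fs_hz: float,
                            baseline_window_s: float = 2.0,
                            theta: float = 2.0, m_s: float = 1.0,
                            difference_ref: str = "minimum"
                            ) -> TimecourseProfile:
    """Landmark profile of one event-locked group-average curve.

    Baseline is the mean/SD of the first ``baseline_window_s`` seconds.
    Latency is the first time the curve stays above baseline mean +
    ``theta`` x SD for at least ``m_s`` continuous seconds; meeting the
    criterion at t = 0, or never, sets the no-latency flag.  Slope is the
    least-squares slope between latency and peak (per sample, and x fs
    per second).  ``difference`` is peak minus the window minimum (or
    minus the baseline mean with ``difference_ref='baseline'``).
    Spearman's rank correlation of the curve against time is computed
    over the full window.
    """
    series = np.asarray(series, float)
    n = series.size
    if n < 2:
        raise InputError("series too short")
    nb = max(1, int(round(baseline_window_s * fs_hz)))
    base_mu = series[:nb].mean()
    base_sd = series[:nb].std(ddof=0)
    if base_sd == 0:
        log.warning("characterize_timecourse: zero baseline SD; threshold "
                    "degenerates to the baseline mean")
    thr = base_mu + theta * base_sd
    m = max(1, int(round(m_s * fs_hz)))

    above = series > thr
    latency_idx = None
    run = 0
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= m:
            latency_idx = i - m + 1
            break
    no_latency = latency_idx is None or latency_idx == 0
    latency_s = None if no_latency else latency_idx / fs_hz

    peak_idx = int(np.argmax(series))
    peak_value = float(series[peak_idx])
    peak_time_s = peak_idx / fs_hz

    slope_ps = slope_sec = None
    if not no_latency and peak_idx > latency_idx:
        seg = series[latency_idx:peak_idx + 1]
        slope_ps = float(np.polyfit(np.arange(seg.size), seg, 1)[0])
        slope_sec = slope_ps * fs_hz

    if difference_ref == "baseline":
        difference = peak_value - base_mu
    else:
        difference = peak_value - float(series.min())

    if np.ptp(series) == 0:
        r, p = 0.0, 1.0  # constant curve carries no time trend
    else:
        r, p = sps.spearmanr(np.arange(n), series)
    return TimecourseProfile(latency_s=latency_s, slope_per_sample=slope_ps,
                             slope_per_second=slope_sec,
                             peak_value=peak_value, peak_time_s=peak_time_s,
                             difference=float(difference),
                             spearman_r=float(r), spearman_p=float(p),
                             no_latency=bool(no_latency))
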