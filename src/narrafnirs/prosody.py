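"""Prosodic features from frame-level f0 tracks.

Three scalar features per narration: voiced-frame mean pitch, semitone
change across the narration (declination), and pause count.  Definitions
are explicit because extraction toolchains differ:

* mean pitch — arithmetic mean of f0 over voiced frames only;
* semitone change — ``12 * log2(median f0 of the last voiced decile /
  median f0 of the first voiced decile)``; negative values mean the pitch
  declined;
* pause count — number of maximal unvoiced runs at least ``min_pause_s``
  long (closed threshold: a run of exactly ``min_pause_s`` counts).
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np

from .datatypes import InputError, ProsodyTrack

log = logging.getLogger(__name__)

DEFAULT_MIN_PAUSE_S = 0.06


def mean_pitch(track: ProsodyTrack) -> Optional[float]:
    f0 = track.f0_hz[track.voiced]
    if f0.size == 0:
        log.warning("mean_pitch: no voiced frames")
        return None
    return float(f0.mean())


def semitone_change(track: ProsodyTrack, method: str = "decile") -> Optional[float]:
    """Pitch declination in semitones over the narration.

    ``method='decile'`` (default) compares the median f0 of the last and
    first voiced deciles.  ``method='slope'`` fits a least-squares line to
    semitones vs voiced-frame index and reports slope x (n-1), i.e. the
    fitted start-to-end change.
    """
    f0 = track.f0_hz[track.voiced]
    if f0.size < 2:
        log.warning("semitone_change: fewer than 2 voiced frames")
        return None
    if method == "slope":
        st = 12.0 * np.log2(f0)
        idx = np.arange(f0.size)
        slope = np.polyfit(idx, st, 1)[0]
        return float(slope * (f0.size - 1))
    k = max(1, f0.size // 10)
    first = np.median(f0[:k])
    last = np.median(f0[-k:])
    if first <= 0 or last <= 0:
        return None
    return float(12.0 * np.log2(last / first))


def count_pauses(track: ProsodyTrack,
                 min_pause_s: float = DEFAULT_MIN_PAUSE_S) -> int:
    """Number of maximal unvoiced runs with duration >= min_pause_s."""
    if min_pause_s <= 1.0 / track.frame_hz:
        raise InputError("min_pause_s must exceed the frame spacing")
    unvoiced = ~track.voiced
    if not unvoiced.any():
        return 0
    # run-length encode the unvoiced mask
    edges = np.diff(unvoiced.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if unvoiced[0]:
        starts = np.r_[0, starts]
    if unvoiced[-1]:
        ends = np.r_[ends, unvoiced.size]
    min_frames = int(np.ceil(min_pause_s * track.frame_hz))
    return int(np.sum((ends - starts) >= min_frames))


def prosody_features(track: ProsodyTrack,
                     min_pause_s: float = DEFAULT_MIN_PAUSE_S) -> dict:
    mp = mean_pitch(track)
    st = semitone_change(track)
    return {
        "mean_pitch_hz": float("nan") if mp is None else mp,
        "semitone_change": float("nan") if st is None else st,
        "pause_count": count_pauses(track, min_pause_s),
    }
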