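"""Lexical richness and emotional/factual vocabulary rates.

Operates on timed transcripts; onset markers are carried through tagging
untouched so downstream event-locking can use them.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import InputError, TimedTranscript
from .lexicon import Lexicon

log = logging.getLogger(__name__)


def honore_r(tokens: Sequence[str]) -> Optional[float]:
    """Honore's lexical-richness statistic R = 100 ln(N) / (1 - V1/V).

    N is the token count, V the number of distinct types and V1 the number
    of hapax legomena (types occurring exactly once).  Natural log.  When
    every type is a hapax (V1 == V) the statistic diverges; ``None`` is
    returned and a warning logged.
    """
    tokens = list(tokens)
    n = len(tokens)
    if n < 2:
        raise InputError("honore_r needs at least 2 tokens")
    counts = Counter(tokens)
    v = len(counts)
    v1 = sum(1 for c in counts.values() if c == 1)
    if v1 == v:
        log.warning("honore_r undefined: all %d types are hapax legomena", v)
        return None
    return 100.0 * math.log(n) / (1.0 - v1 / v)


def tag_tokens_lexicon(transcript: TimedTranscript, lexicon: Lexicon
                       ) -> TimedTranscript:
    """Label every token by lexicon lookup (neutral when absent).

    Onset/offset markers are preserved unchanged; any pre-existing
    category column is replaced.
    """
    if len(transcript) == 0:
        raise InputError("empty transcript")
    df = transcript.tokens.copy()
    df["category"] = [lexicon.category(t) for t in df["token"]]
    return TimedTranscript(tokens=df, narration_bounds=transcript.narration_bounds)


def emotion_rates(transcript: TimedTranscript) -> dict[str, float]:
    """Percent of tokens per category from a labelled transcript."""
    if len(transcript) == 0:
        raise InputError("empty transcript")
    if "category" not in transcript.tokens.columns:
        raise InputError("transcript is not labelled; run tag_tokens_lexicon")
    cats = transcript.tokens["category"]
    n = len(cats)
    return {
        "neg_pct": 100.0 * (cats == "negative").sum() / n,
        "pos_pct": 100.0 * (cats == "positive").sum() / n,
        "factual_pct": 100.0 * (cats == "factual").sum() / n,
        "neutral_pct": 100.0 * (cats == "neutral").sum() / n,
    }


def language_features(transcript: TimedTranscript, lexicon: Lexicon
                      ) -> dict[str, float]:
    """One subject's lexical feature row: rates plus Honore's R."""
    tagged = tag_tokens_lexicon(transcript, lexicon)
    feats = emotion_rates(tagged)
    r = honore_r(tagged.tokens["token"].tolist())
    feats["honore_r"] = float("nan") if r is None else r
    feats["n_tokens"] = float(len(tagged))
    return feats


def language_feature_table(transcripts: dict[str, TimedTranscript],
                           lexicon: Lexicon) -> pd.DataFrame:
    rows = []
    for sid, tr in transcripts.items():
        row = {"subject_id": sid}
        row.update(language_features(tr, lexicon))
        rows.append(row)
    return pd.DataFrame(rows)
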