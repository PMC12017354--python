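"""Synthetic word-category lexicon.

A toy LIWC-style lexicon mapping surface forms to one of four disjoint
categories (negative, positive, factual, neutral).  Word forms are
synthetic (``neg012``, ``nw0451`` ...) and generated deterministically, so
the lexicon a cohort was generated from can always be rebuilt bit-for-bit
and every synthetic token is guaranteed to be covered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .datatypes import ConfigurationError

# vocabulary sizes of the packaged lexicon
N_NEGATIVE = 80
N_POSITIVE = 80
N_FACTUAL = 120
N_NEUTRAL_COMMON = 20
N_NEUTRAL_RARE = 4000


def negative_words(n: int = N_NEGATIVE) -> list[str]:
    return [f"neg{i:03d}" for i in range(n)]


def positive_words(n: int = N_POSITIVE) -> list[str]:
    return [f"pos{i:03d}" for i in range(n)]


def factual_words(n: int = N_FACTUAL) -> list[str]:
    return [f"fact{i:03d}" for i in range(n)]


def neutral_common_words(n: int = N_NEUTRAL_COMMON) -> list[str]:
    return [f"cw{i:02d}" for i in range(n)]


def neutral_rare_words(n: int = N_NEUTRAL_RARE) -> list[str]:
    return [f"nw{i:04d}" for i in range(n)]


@dataclass
class Lexicon:
    """Surface form -> category map with a neutral default for OOV forms."""

    entries: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for word, cat in self.entries.items():
            if cat not in ("negative", "positive", "neutral", "factual"):
                raise ConfigurationError(f"unknown category {cat!r} for {word!r}")

    def category(self, token: str) -> str:
        return self.entries.get(token, "neutral")

    def __contains__(self, token: str) -> bool:
        return token in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def words(self, category: str) -> list[str]:
        return [w for w, c in self.entries.items() if c == category]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf8") as fh:
            fh.write("word\tcategory\n")
            for word, cat in self.entries.items():
                fh.write(f"{word}\t{cat}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Lexicon":
        entries: dict[str, str] = {}
        with open(path, encoding="utf8") as fh:
            header = fh.readline()
            if not header.startswith("word"):
                raise ConfigurationError(f"{path}: missing lexicon header")
            for line in fh:
                word, cat = line.rstrip("\n").split("\t")
                entries[word] = cat
        return cls(entries)


def build_default_lexicon() -> Lexicon:
    """The packaged synthetic lexicon (deterministic, covers the generator)."""
    entries: dict[str, str] = {}
    for w in negative_words():
        entries[w] = "negative"
    for w in positive_words():
        entries[w] = "positive"
    for w in factual_words():
        entries[w] = "factual"
    for w in neutral_common_words() + neutral_rare_words():
        entries[w] = "neutral"
    return Lexicon(entries)
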