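"""Keyword binning, seed-sample construction, and the supplemental key-phrase
sweep.

The seed labeled set for a rare outcome cannot come from a simple random
sample (at ~0.5% prevalence a 200-narrative sample would contain ~1 case).
Instead the corpus is screened with a handful of keywords likely to co-occur
with the outcome ("drive", "license", "vision", "DMV"), narratives are binned
by the exact keyword subset they match, and the annotation sample is drawn
stratified over bins.  After classification, a more specific key-phrase sweep
over low-probability narratives recovers cases the classifier missed.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

logger = logging.getLogger("dcas")

__all__ = [
    "DEFAULT_KEYWORDS",
    "KeywordBinning",
    "SeedSamplePlan",
    "KeyPhraseList",
    "match_keywords",
    "bin_corpus",
    "draw_seed_sample",
    "keyphrase_sweep",
    "default_keyphrases",
]

DEFAULT_KEYWORDS: tuple[str, ...] = ("drive", "license", "vision", "DMV")


def match_keywords(
    text: str, keywords: Sequence[str] = DEFAULT_KEYWORDS
) -> frozenset[str]:
    """Exact subset of keywords present in raw text.

    Case-insensitive substring semantics: "driver" and "driveway" match
    "drive".  This maximizes seed recall at the cost of irrelevant hits,
    which the binning step is designed to absorb.
    """
    if not keywords:
        raise ValueError("keywords must be non-empty")
    low = text.lower()
    return frozenset(k for k in keywords if k.lower() in low)


@dataclass
class KeywordBinning:
    """Partition of a corpus by matched keyword subset.

    ``bins`` maps each exact matched subset (including the empty subset) to
    the narrative ids in it; every id lands in exactly one bin.
    """

    keywords: tuple[str, ...]
    bins: dict[frozenset[str], list[str]]

    @property
    def n_documents(self) -> int:
        return sum(len(v) for v in self.bins.values())


def bin_corpus(
    texts: Mapping[str, str], keywords: Sequence[str] = DEFAULT_KEYWORDS
) -> KeywordBinning:
    """Assign each narrative to the bin keyed by its matched keyword subset."""
    if not texts:
        raise ValueError("corpus must be non-empty")
    bins: dict[frozenset[str], list[str]] = {}
    for doc_id, text in texts.items():
        key = match_keywords(text, keywords)
        bins.setdefault(key, []).append(doc_id)
    return KeywordBinning(keywords=tuple(keywords), bins=bins)


@dataclass
class SeedSamplePlan:
    """Stratified draw over keyword bins for the first annotation round.

    Single-keyword bins larger than ``exhaustive_max_bin_size`` are "large":
    ``large_bin_total`` narratives are drawn from their union, allocated
    proportionally to bin size with largest-remainder rounding
    (``large_bin_mode="total"``), or ``large_bin_total`` from each
    (``large_bin_mode="each"``).  All other bins with at least one keyword
    are reviewed exhaustively; ``no_match_count`` narratives are drawn from
    the no-keyword bin to reflect the base rate.
    """

    large_bin_total: int = 60
    exhaustive_max_bin_size: int = 10
    no_match_count: int = 34
    large_bin_mode: str = "total"  # "total" | "each"

    def __post_init__(self) -> None:
        if self.large_bin_total < 0 or self.no_match_count < 0:
            raise ValueError("sample counts must be >= 0")
        if self.exhaustive_max_bin_size < 0:
            raise ValueError("exhaustive_max_bin_size must be >= 0")
        if self.large_bin_mode not in ("total", "each"):
            raise ValueError("large_bin_mode must be 'total' or 'each'")


def _largest_remainder(total: int, sizes: Sequence[int]) -> list[int]:
    """Proportional integer allocation of `total` across strata of `sizes`."""
    sizes_arr = np.asarray(sizes, dtype=float)
    if sizes_arr.sum() == 0:
        return [0] * len(sizes)
    quota = total * sizes_arr / sizes_arr.sum()
    alloc = np.floor(quota).astype(int)
    remainder = quota - alloc
    for i in np.argsort(-remainder)[: total - int(alloc.sum())]:
        alloc[i] += 1
    return alloc.tolist()


def _capped_draw(
    ids: Sequence[str], k: int, rng: np.random.Generator, bin_label: str
) -> list[str]:
    if k >= len(ids):
        if k > len(ids):
            logger.warning(
                "requested %d from bin %s holding %d; taking all", k, bin_label, len(ids)
            )
        return list(ids)
    picked = rng.choice(len(ids), size=k, replace=False)
    return [ids[i] for i in sorted(picked)]


def draw_seed_sample(
    binning: KeywordBinning,
    plan: SeedSamplePlan | None = None,
    rng: np.random.Generator | int | None = None,
) -> list[tuple[str, frozenset[str]]]:
    """Draw the seed annotation worklist: (narrative id, bin key) pairs.

    Without-replacement within each stratum; over-requests are capped at the
    bin size with a logged warning; reproducible given the rng seed.
    """
    plan = plan or SeedSamplePlan()
    rng = np.random.default_rng(rng)
    out: list[tuple[str, frozenset[str]]] = []

    keyed = sorted(
        (key for key in binning.bins if key), key=lambda k: sorted(k)
    )
    large = [
        k
        for k in keyed
        if len(k) == 1 and len(binning.bins[k]) > plan.exhaustive_max_bin_size
    ]
    small = [k for k in keyed if k not in large]

    if plan.large_bin_mode == "total":
        allocs = _largest_remainder(
            plan.large_bin_total, [len(binning.bins[k]) for k in large]
        )
    else:
        allocs = [plan.large_bin_total] * len(large)
    for key, want in zip(large, allocs):
        ids = sorted(binning.bins[key])
        out.extend((i, key) for i in _capped_draw(ids, want, rng, str(set(key))))

    for key in small:
        out.extend((i, key) for i in sorted(binning.bins[key]))

    empty = frozenset()
    if empty in binning.bins and plan.no_match_count:
        ids = sorted(binning.bins[empty])
        out.extend(
            (i, empty) for i in _capped_draw(ids, plan.no_match_count, rng, "{}")
        )
    return out


@dataclass
class KeyPhraseList:
    """Ordered literal phrases / word-gap patterns for the supplemental sweep.

    ``*`` in a phrase matches a gap of one or two words.  Matching is
    case-insensitive on raw (unstemmed) narrative text.
    """

    phrases: tuple[str, ...]
    provenance: str = "user-supplied"
    _patterns: list[re.Pattern] = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.phrases or any(not p.strip() for p in self.phrases):
            raise ValueError("key-phrase list must contain non-empty phrases")
        self.phrases = tuple(self.phrases)
        self._patterns = [self._compile(p) for p in self.phrases]

    @staticmethod
    def _compile(phrase: str) -> re.Pattern:
        parts = [
            r"\w+(?:\s+\w+)?" if tok == "*" else re.escape(tok)
            for tok in phrase.split()
        ]
        return re.compile(r"\s+".join(parts), re.IGNORECASE)

    def first_match(self, text: str) -> str | None:
        for phrase, pat in zip(self.phrases, self._patterns):
            if pat.search(text):
                return phrase
        return None


def default_keyphrases() -> KeyPhraseList:
    """The shipped key-phrase list (a documented reconstruction, not the
    original study's supplementary list — override for real analyses)."""
    raw = yaml.safe_load(
        resources.files("dcas.data").joinpath("keyphrases_default.yaml").read_text("utf-8")
    )
    return KeyPhraseList(tuple(raw["phrases"]), provenance=raw["provenance"])


def keyphrase_sweep(
    texts: Mapping[str, str], phrases: KeyPhraseList
) -> list[tuple[str, str]]:
    """Ids (with their first matching phrase) whose raw text matches >= 1
    phrase.  An empty phrase list is an error: "no sweep configured" must not
    be confusable with "sweep found nothing"."""
    if not isinstance(phrases, KeyPhraseList):
        phrases = KeyPhraseList(tuple(phrases))
    out = []
    for doc_id, text in texts.items():
        hit = phrases.first_match(text)
        if hit is not None:
            out.append((doc_id, hit))
    return out
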