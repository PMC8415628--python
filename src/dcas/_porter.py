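"""Classic Porter (1980) suffix-stripping stemmer.

Single-pass implementation of the original algorithm (steps 1a-5b), used to
collapse inflectional variants ("walking", "walked", "walks" -> "walk") before
n-gram construction.  Outputs are memoised: narrative corpora reuse a small
vocabulary, so stemming is effectively a dictionary lookup after warm-up.
"""

from __future__ import annotations

from functools import lru_cache

__all__ = ["stem"]


def _is_consonant(word: str, i: int) -> bool:
    c = word[i]
    if c in "aeiou":
        return False
    if c == "y":
        return i == 0 or not _is_consonant(word, i - 1)
    return True


def _measure(stem_: str) -> int:
    """Number of VC sequences in the [C](VC)^m[V] decomposition."""
    n = 0
    i = 0
    length = len(stem_)
    while i < length and _is_consonant(stem_, i):
        i += 1
    while i < length:
        while i < length and not _is_consonant(stem_, i):
            i += 1
        if i >= length:
            break
        n += 1
        while i < length and _is_consonant(stem_, i):
            i += 1
    return n


def _contains_vowel(stem_: str) -> bool:
    return any(not _is_consonant(stem_, i) for i in range(len(stem_)))


def _ends_double_consonant(word: str) -> bool:
    return (
        len(word) >= 2
        and word[-1] == word[-2]
        and _is_consonant(word, len(word) - 1)
    )


def _ends_cvc(word: str) -> bool:
    if len(word) < 3:
        return False
    if (
        _is_consonant(word, len(word) - 3)
        and not _is_consonant(word, len(word) - 2)
        and _is_consonant(word, len(word) - 1)
    ):
        return word[-1] not in "wxy"
    return False


_STEP2 = (
    ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
    ("izer", "ize"), ("abli", "able"), ("alli", "al"), ("entli", "ent"),
    ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
    ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
    ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
)

_STEP3 = (
    ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
    ("ical", "ic"), ("ful", ""), ("ness", ""),
)

_STEP4 = (
    "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
    "ment", "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
)


def _step1a(word: str) -> str:
    if word.endswith("sses"):
        return word[:-2]
    if word.endswith("ies"):
        return word[:-2]
    if word.endswith("ss"):
        return word
    if word.endswith("s"):
        return word[:-1]
    return word


def _step1b(word: str) -> str:
    if word.endswith("eed"):
        if _measure(word[:-3]) > 0:
            return word[:-1]
        return word
    flag = False
    if word.endswith("ed") and _contains_vowel(word[:-2]):
        word = word[:-2]
        flag = True
    elif word.endswith("ing") and _contains_vowel(word[:-3]):
        word = word[:-3]
        flag = True
    if flag:
        if word.endswith(("at", "bl", "iz")):
            return word + "e"
        if _ends_double_consonant(word) and word[-1] not in "lsz":
            return word[:-1]
        if _measure(word) == 1 and _ends_cvc(word):
            return word + "e"
    return word


def _step1c(word: str) -> str:
    if word.endswith("y") and _contains_vowel(word[:-1]):
        return word[:-1] + "i"
    return word


def _step2(word: str) -> str:
    for suffix, repl in _STEP2:
        if word.endswith(suffix):
            stem_ = word[: -len(suffix)]
            if _measure(stem_) > 0:
                return stem_ + repl
            return word
    return word


def _step3(word: str) -> str:
    for suffix, repl in _STEP3:
        if word.endswith(suffix):
            stem_ = word[: -len(suffix)]
            if _measure(stem_) > 0:
                return stem_ + repl
            return word
    return word


def _step4(word: str) -> str:
    for suffix in _STEP4:
        if word.endswith(suffix):
            stem_ = word[: -len(suffix)]
            if _measure(stem_) > 1:
                if suffix == "ion" and (not stem_ or stem_[-1] not in "st"):
                    return word
                return stem_
            return word
    return word


def _step5a(word: str) -> str:
    if word.endswith("e"):
        stem_ = word[:-1]
        m = _measure(stem_)
        if m > 1 or (m == 1 and not _ends_cvc(stem_)):
            return stem_
    return word


def _step5b(word: str) -> str:
    if _measure(word) > 1 and word.endswith("ll"):
        return word[:-1]
    return word


@lru_cache(maxsize=65536)
def stem(word: str) -> str:
    """Stem a single lowercase word.

    Words of length <= 2 are returned unchanged, per the original algorithm.
    """
    if len(word) <= 2:
        return word
    word = _step1a(word)
    word = _step1b(word)
    word = _step1c(word)
    word = _step2(word)
    word = _step3(word)
    word = _step4(word)
    word = _step5a(word)
    word = _step5b(word)
    return word
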