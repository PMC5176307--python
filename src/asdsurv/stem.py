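"""Porter stemmer for English clinical text.

Implements the 1980 Porter suffix-stripping algorithm with the standard
revised step 1c (terminal ``y`` becomes ``i`` only when preceded by a
non-initial consonant, so ``happy -> happi`` but ``play -> play``).
Stemming here only has to be deterministic and train/predict-consistent;
the exact stem spellings are irrelevant downstream as long as inflected
variants collapse to a common token.
"""

from __future__ import annotations

_VOWELS = frozenset("aeiou")


def _is_consonant(word: str, i: int) -> bool:
    c = word[i]
    if c in _VOWELS:
        return False
    if c == "y":
        # y is a vowel when it follows a consonant
        return i == 0 or not _is_consonant(word, i - 1)
    return True


def _measure(stem: str) -> int:
    """Number of vowel->consonant transitions, the m of [C](VC)^m[V]."""
    m = 0
    prev_vowel = False
    for i in range(len(stem)):
        if _is_consonant(stem, i):
            if prev_vowel:
                m += 1
            prev_vowel = False
        else:
            prev_vowel = True
    return m


def _has_vowel(stem: str) -> bool:
    return any(not _is_consonant(stem, i) for i in range(len(stem)))


def _ends_double_consonant(word: str) -> bool:
    return (
        len(word) >= 2
        and word[-1] == word[-2]
        and _is_consonant(word, len(word) - 1)
    )


def _ends_cvc(word: str) -> bool:
    """*o condition: stem ends consonant-vowel-consonant, final not w/x/y."""
    if len(word) < 3:
        return False
    return (
        _is_consonant(word, len(word) - 3)
        and not _is_consonant(word, len(word) - 2)
        and _is_consonant(word, len(word) - 1)
        and word[-1] not in "wxy"
    )


def _step1a(w: str) -> str:
    if w.endswith("sses"):
        return w[:-2]
    if w.endswith("ies"):
        return w[:-2]
    if w.endswith("ss"):
        return w
    if w.endswith("s"):
        return w[:-1]
    return w


def _step1b(w: str) -> str:
    if w.endswith("eed"):
        if _measure(w[:-3]) > 0:
            return w[:-1]
        return w
    removed = False
    if w.endswith("ed") and _has_vowel(w[:-2]):
        w, removed = w[:-2], True
    elif w.endswith("ing") and _has_vowel(w[:-3]):
        w, removed = w[:-3], True
    if removed:
        if w.endswith(("at", "bl", "iz")):
            return w + "e"
        if _ends_double_consonant(w) and w[-1] not in "lsz":
            return w[:-1]
        if _measure(w) == 1 and _ends_cvc(w):
            return w + "e"
    return w


def _step1c(w: str) -> str:
    # revised rule: y -> i after a consonant that is not the first letter
    if w.endswith("y") and len(w) > 2 and _is_consonant(w, len(w) - 2):
        return w[:-1] + "i"
    return w


# (suffix, replacement) pairs; within a step the longest matching suffix is
# the one whose condition is evaluated, per the original description.
_STEP2 = [
    ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
    ("izer", "ize"), ("abli", "able"), ("alli", "al"), ("entli", "ent"),
    ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
    ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
    ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
]
_STEP3 = [
    ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
    ("ical", "ic"), ("ful", ""), ("ness", ""),
]
_STEP4 = [
    "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
    "ment", "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
]


def _longest_rule(w: str, rules: list[tuple[str, str]], min_m: int) -> str:
    best = None
    for suf, rep in rules:
        if w.endswith(suf) and (best is None or len(suf) > len(best[0])):
            best = (suf, rep)
    if best is not None:
        stem = w[: len(w) - len(best[0])]
        if _measure(stem) > min_m:
            return stem + best[1]
    return w


def _step4(w: str) -> str:
    best = None
    for suf in _STEP4:
        if w.endswith(suf) and (best is None or len(suf) > len(best)):
            best = suf
    if best is not None:
        stem = w[: len(w) - len(best)]
        if _measure(stem) > 1:
            if best == "ion" and not stem.endswith(("s", "t")):
                return w
            return stem
    return w


def _step5a(w: str) -> str:
    if w.endswith("e"):
        stem = w[:-1]
        m = _measure(stem)
        if m > 1 or (m == 1 and not _ends_cvc(stem)):
            return stem
    return w


def _step5b(w: str) -> str:
    if w.endswith("ll") and _measure(w) > 1:
        return w[:-1]
    return w


def porter_stem(word: str) -> str:
    """Return the Porter stem of a single lower-case word.

    Words of length <= 2 are returned unchanged, as in the reference
    algorithm.
    """
    if len(word) <= 2:
        return word
    w = _step1a(word)
    w = _step1b(w)
    w = _step1c(w)
    w = _longest_rule(w, _STEP2, 0)
    w = _longest_rule(w, _STEP3, 0)
    w = _step4(w)
    w = _step5a(w)
    w = _step5b(w)
    return w


#: registry of available stemmers; ``stemmer_id`` in VocabularySpec keys this
STEMMERS = {
    "porter": porter_stem,
    "identity": lambda w: w,
}


def get_stemmer(stemmer_id: str):
    try:
        return STEMMERS[stemmer_id]
    except KeyError:
        raise ValueError(
            f"unknown stemmer_id {stemmer_id!r}; available: {sorted(STEMMERS)}"
        ) from None
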