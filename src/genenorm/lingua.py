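"""Lightweight linguistic preprocessing: Porter stemming and rule-based POS.

Both are deterministic, dependency-free stand-ins for the heavier NLP
toolchains a production deployment might swap in; the tagger model records
which stemmer/tagger produced its features so models are never mixed across
incompatible preprocessing.
"""

from __future__ import annotations

import re

STEMMER_NAME = "porter-v1"
POS_TAGGER_NAME = "rulepos-v1"

_VOWELS = "aeiou"


def _is_cons(word: str, i: int) -> bool:
    ch = word[i]
    if ch in _VOWELS:
        return False
    if ch == "y":
        return i == 0 or not _is_cons(word, i - 1)
    return True


def _measure(stem: str) -> int:
    """Number of VC sequences (the Porter measure m)."""
    forms = ""
    for i in range(len(stem)):
        forms += "c" if _is_cons(stem, i) else "v"
    return len(re.findall("vc", forms))


def _has_vowel(stem: str) -> bool:
    return any(not _is_cons(stem, i) for i in range(len(stem)))


def _ends_double_cons(word: str) -> bool:
    return (len(word) >= 2 and word[-1] == word[-2]
            and _is_cons(word, len(word) - 1))


def _cvc(word: str) -> bool:
    if len(word) < 3:
        return False
    return (_is_cons(word, len(word) - 3)
            and not _is_cons(word, len(word) - 2)
            and _is_cons(word, len(word) - 1)
            and word[-1] not in "wxy")


def _replace(word: str, suffix: str, repl: str, m_min: int) -> str | None:
    if not word.endswith(suffix):
        return None
    stem = word[: len(word) - len(suffix)]
    if _measure(stem) > m_min:
        return stem + repl
    return word


_STEP2 = [("ational", "ate"), ("tional", "tion"), ("enci", "ence"),
          ("anci", "ance"), ("izer", "ize"), ("abli", "able"),
          ("alli", "al"), ("entli", "ent"), ("eli", "e"), ("ousli", "ous"),
          ("ization", "ize"), ("ation", "ate"), ("ator", "ate"),
          ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
          ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"),
          ("biliti", "ble")]
_STEP3 = [("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
          ("ical", "ic"), ("ful", ""), ("ness", "")]
_STEP4 = ["al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
          "ment", "ent", "ou", "ism", "ate", "iti", "ous", "ive", "ize"]


def porter_stem(word: str) -> str:
    """Porter's suffix-stripping algorithm over lowercase ASCII words.

    Tokens with digits or shorter than 3 characters pass through unchanged.
    """
    w = word.lower()
    if len(w) < 3 or not w.isalpha() or not w.isascii():
        return w
    # step 1a
    if w.endswith("sses"):
        w = w[:-2]
    elif w.endswith("ies"):
        w = w[:-2]
    elif w.endswith("ss"):
        pass
    elif w.endswith("s"):
        w = w[:-1]
    # step 1b
    if w.endswith("eed"):
        if _measure(w[:-3]) > 0:
            w = w[:-1]
    else:
        flag = False
        if w.endswith("ed") and _has_vowel(w[:-2]):
            w, flag = w[:-2], True
        elif w.endswith("ing") and _has_vowel(w[:-3]):
            w, flag = w[:-3], True
        if flag:
            if w.endswith(("at", "bl", "iz")):
                w += "e"
            elif _ends_double_cons(w) and w[-1] not in "lsz":
                w = w[:-1]
            elif _measure(w) == 1 and _cvc(w):
                w += "e"
    # step 1c
    if w.endswith("y") and _has_vowel(w[:-1]):
        w = w[:-1] + "i"
    # steps 2-3
    for table in (_STEP2, _STEP3):
        for suffix, repl in table:
            if w.endswith(suffix):
                w = _replace(w, suffix, repl, 0) or w
                break
    # step 4
    for suffix in _STEP4:
        if w.endswith(suffix):
            if suffix == "ion":
                break
            stem = w[: len(w) - len(suffix)]
            if _measure(stem) > 1:
                w = stem
            break
        if w.endswith("ion") and len(w) > 3 and w[-4] in "st":
            stem = w[:-3]
            if _measure(stem) > 1:
                w = stem
            break
    # step 5a
    if w.endswith("e"):
        stem = w[:-1]
        m = _measure(stem)
        if m > 1 or (m == 1 and not _cvc(stem)):
            w = stem
    # step 5b
    if _ends_double_cons(w) and w[-1] == "l" and _measure(w) > 1:
        w = w[:-1]
    return w


_CLOSED_CLASS = {
    "the": "DT", "a": "DT", "an": "DT", "this": "DT", "these": "DT",
    "that": "DT", "those": "DT", "each": "DT", "both": "DT", "all": "DT",
    "of": "IN", "in": "IN", "on": "IN", "at": "IN", "by": "IN", "for": "IN",
    "with": "IN", "from": "IN", "to": "TO", "as": "IN", "into": "IN",
    "through": "IN", "between": "IN", "via": "IN", "within": "IN",
    "and": "CC", "or": "CC", "but": "CC", "nor": "CC",
    "is": "VBZ", "are": "VBP", "was": "VBD", "were": "VBD", "be": "VB",
    "been": "VBN", "being": "VBG", "has": "VBZ", "have": "VBP",
    "had": "VBD", "can": "MD", "may": "MD", "might": "MD", "could": "MD",
    "should": "MD", "will": "MD", "would": "MD", "must": "MD",
    "not": "RB", "no": "DT", "we": "PRP", "it": "PRP", "its": "PRP$",
    "their": "PRP$", "our": "PRP$", "which": "WDT", "whose": "WP$",
    "when": "WRB", "where": "WRB", "here": "RB", "also": "RB",
    "however": "RB", "thus": "RB", "therefore": "RB",
}


def pos_tag(token_text: str) -> str:
    """Deterministic Penn-style tag for one token, from closed-class lookup
    plus suffix/shape heuristics."""
    low = token_text.lower()
    if low in _CLOSED_CLASS:
        return _CLOSED_CLASS[low]
    if token_text.isdigit():
        return "CD"
    if not token_text[:1].isalpha():
        return "SYM"
    if low.endswith("ly"):
        return "RB"
    if low.endswith("ing") and len(low) > 4:
        return "VBG"
    if low.endswith("ed") and len(low) > 3:
        return "VBD"
    if token_text.isupper():
        return "NN"  # symbols / acronyms
    if token_text[0].isupper():
        return "NNP"
    if low.endswith("s") and not low.endswith("ss") and len(low) > 3:
        return "NNS"
    return "NN"
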