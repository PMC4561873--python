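"""Abbreviation (short form, long form) pair detection.

Implements the classic parenthetical right-to-left alignment: a candidate
short form inside parentheses is aligned, last character first, against the
words preceding the opening parenthesis; every alphanumeric short-form
character must be found in order, and the first one must match the initial
character of a word. The matched window becomes the long form. Greek letters
in the short form match their spelled-out names ("α" matches "alpha").

Long forms introduced in parentheses after their short form
("ER (estrogen receptor)") are also recognized, by the symmetric check.
"""

from __future__ import annotations

import re

from .types import AbbrPair, expand_greek

MAX_SHORT_LEN = 10  # characters, after Greek expansion limit is on raw text

_PAREN = re.compile(r"\(([^()]+)\)")


def _valid_short_form(cand: str) -> bool:
    cand = cand.strip()
    if not cand or len(cand) > MAX_SHORT_LEN:
        return False
    if len(cand.split()) > 2:
        return False
    if not any(ch.isalpha() for ch in cand):
        return False
    first = cand.split()[0].lower().rstrip(".")
    if first in {"see", "e.g", "i.e", "eg", "ie", "reviewed", "data"}:
        return False
    return True


def _align(short: str, window_words: list[tuple[int, str]]
           ) -> tuple[int, int] | None:
    """Right-to-left alignment of ``short`` against candidate long-form
    words (each a (start_offset, text) pair, in order). Returns the
    character span of the matched long form, or None."""
    chars = [c for c in expand_greek(short).lower() if c.isalnum()]
    if not chars:
        return None
    # flatten window into (char, word_index, is_word_initial, offset)
    flat: list[tuple[str, int, bool, int]] = []
    for wi, (off, word) in enumerate(window_words):
        expanded = expand_greek(word).lower()
        seen_alnum = False
        for ch in expanded:
            if ch.isalnum():
                flat.append((ch, wi, not seen_alnum, off))
                seen_alnum = True
    si = len(chars) - 1
    fi = len(flat) - 1
    first_match: tuple[int, int] | None = None  # (word_index, offset)
    while si >= 0 and fi >= 0:
        need_initial = si == 0
        ch, wi, initial, off = flat[fi]
        if ch == chars[si] and (not need_initial or initial):
            first_match = (wi, off)
            si -= 1
        fi -= 1
    if si >= 0:
        return None
    start_off = first_match[1]
    last_off, last_word = window_words[-1]
    return start_off, last_off + len(last_word)


def find_pairs(text: str) -> list[AbbrPair]:
    """Detect abbreviation pairs in one document's text."""
    pairs: list[AbbrPair] = []
    for m in _PAREN.finditer(text):
        inner = m.group(1).strip()
        open_pos = m.start()
        before = text[:open_pos].rstrip()
        words = [(w.start(), w.group()) for w in re.finditer(r"\S+", before)]
        if not words:
            continue
        if _valid_short_form(inner):
            short = inner
            # search window limited to min(|sf|+5, |sf|*2) words
            n_sf = max(1, len([c for c in short if c.isalnum()]))
            win = min(n_sf + 5, n_sf * 2)
            window = words[-win:]
            span = _align(short, window)
            if span is not None:
                s_start = text.index(inner, m.start(1), m.end(1))
                long_start, long_end = span
                long_text = text[long_start:long_end]
                if len(short) <= len(long_text):
                    pairs.append(AbbrPair(
                        short_start=s_start, short_end=s_start + len(inner),
                        short_text=inner,
                        long_start=long_start, long_end=long_end,
                        long_text=long_text,
                    ))
                    continue
        # symmetric case: long form in parentheses after its short form
        prev_off, prev_word = words[-1]
        if (_valid_short_form(prev_word.strip(".,;:"))
                and len(inner.split()) >= 2):
            short = prev_word.strip(".,;:")
            inner_words = []
            for w in re.finditer(r"\S+", inner):
                inner_words.append((m.start(1) + w.start(), w.group()))
            span = _align(short, inner_words)
            if span is not None and span[0] == inner_words[0][0]:
                if len(short) <= len(inner):
                    pairs.append(AbbrPair(
                        short_start=prev_off,
                        short_end=prev_off + len(short),
                        short_text=short,
                        long_start=span[0], long_end=span[1],
                        long_text=text[span[0]:span[1]],
                    ))
    return pairs
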