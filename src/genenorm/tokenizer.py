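"""Fine-grained tokenization and sentence splitting.

Tokens are split not only at punctuation and whitespace but also at
letter/digit boundaries and at case transitions, so that every token is
class-pure: a one-case run of letters, a run of digits, or a single
punctuation/symbol character ("hTIF1" -> "h", "TIF", "1"). This mirrors the
aggressive splitting used by mutation/chemical taggers, which makes case
patterns and character counts sharp features for gene names.

Non-ASCII letters (Greek in particular) form their own tokens when adjacent
to Latin letters, so "ERα" -> "ER", "α".
"""

from __future__ import annotations

import re

from .types import SentenceSpan, Token

# character classes; tokens never mix classes
_WS, _DIGIT, _PUNCT = "ws", "digit", "punct"


def _char_class(ch: str) -> str:
    if ch.isspace():
        return _WS
    if ch.isdigit():
        return _DIGIT
    if ch.isalpha():
        ascii_ = "a" if ch.isascii() else "x"
        case = "U" if ch.isupper() else "l"
        return ascii_ + case
    return _PUNCT


def tokenize(text: str) -> list[Token]:
    """Split ``text`` into ordered, non-overlapping class-pure tokens.

    Concatenating token texts with the skipped separators reconstructs the
    input exactly; the empty string yields an empty list.
    """
    tokens: list[Token] = []
    start = None
    cls = None
    for i, ch in enumerate(text):
        c = _char_class(ch)
        if c == _WS or c == _PUNCT or c != cls:
            if start is not None:
                tokens.append(Token(text[start:i], start, i))
                start = None
            if c == _PUNCT:
                tokens.append(Token(ch, i, i + 1))
                cls = None
            elif c == _WS:
                cls = None
            else:
                start, cls = i, c
    if start is not None:
        tokens.append(Token(text[start:], start, len(text)))
    return tokens


# words after which a period does not end a sentence
_ABBREVIATIONS = {
    "e.g", "i.e", "etc", "vs", "cf", "ca", "al", "fig", "figs", "ref",
    "refs", "dr", "prof", "st", "no", "approx", "resp", "spp", "sp",
}

_BOUNDARY = re.compile(r"[.!?]+[)\]\"']*\s+")


def split_sentences(text: str) -> list[SentenceSpan]:
    """Split ``text`` into sentence spans that tile it without overlap.

    A boundary is sentence-final punctuation followed by whitespace and an
    uppercase letter or digit; a known abbreviation ("e.g.", "Fig.")
    immediately before the punctuation blocks the split. Replaceable: callers
    may supply their own spans anywhere the library accepts them.
    """
    if not text.strip():
        return []
    boundaries: list[int] = []
    for m in _BOUNDARY.finditer(text):
        nxt = m.end()
        if nxt >= len(text):
            continue
        if not (text[nxt].isupper() or text[nxt].isdigit()):
            continue
        head = text[: m.start() + 1]
        word = head.rstrip(".!?").split()
        if word and word[-1].rstrip(".").lower().lstrip("(") in _ABBREVIATIONS:
            continue
        boundaries.append(nxt)
    spans = []
    prev = 0
    for b in boundaries:
        spans.append(SentenceSpan(prev, b))
        prev = b
    spans.append(SentenceSpan(prev, len(text)))
    return spans


def sentence_tokens(text: str, spans: list[SentenceSpan] | None = None
                    ) -> list[list[Token]]:
    """Tokenize ``text`` grouped by sentence."""
    spans = split_sentences(text) if spans is None else spans
    all_tokens = tokenize(text)
    out: list[list[Token]] = []
    i = 0
    for sp in spans:
        sent: list[Token] = []
        while i < len(all_tokens) and all_tokens[i].start < sp.end:
            sent.append(all_tokens[i])
            i += 1
        out.append(sent)
    return out
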