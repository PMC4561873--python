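"""Token-level feature extraction for the sequence tagger.

Five feature families are produced per token: general linguistic features
(surface form, stem, POS tag, prefixes/suffixes of length 1-5), character
features (counts of uppercase, lowercase, letter, digit and special
characters), semantic features (membership in trigger-token lexicons and a
longest-match gene-vocabulary lookup, plus participation in a detected
abbreviation pair), case-pattern features (four simplified shape strings),
and contextual features (copies of the dictionary and linguistic features of
the three neighbours on each side).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

from .lingua import porter_stem, pos_tag
from .types import AbbrPair, Token

TEMPLATE_VERSION = "gnft-1"

_SPECIALS = set(";:,.->+_")

# feature keys copied to neighbouring positions (dictionary + linguistic)
_CONTEXT_KEYS = ("w", "stem", "pos", "lex_gene", "lex_gene_ctx",
                 "lex_disease", "lex_chem", "lex_domain", "lex_cell",
                 "lex_aa", "abbr")


def case_patterns(token_text: str) -> tuple[str, str, str, str]:
    """The four simplified shape forms of a token.

    p1 replaces each uppercase letter with "A", lowercase with "a", digit
    with "0" (other characters unchanged); p2 collapses runs of identical p1
    symbols; p3 lowercases all letters to "a" first, then collapses runs;
    p4 is a single summary symbol: "a" if the token contains any letter,
    else "0" if any digit, else its first character.
    """
    if not token_text:
        raise ValueError("case_patterns: empty token")
    p1_chars = []
    for ch in token_text:
        if ch.isalpha():
            p1_chars.append("A" if ch.isupper() else "a")
        elif ch.isdigit():
            p1_chars.append("0")
        else:
            p1_chars.append(ch)
    p1 = "".join(p1_chars)

    def collapse(s: str) -> str:
        out = []
        for ch in s:
            if not out or out[-1] != ch:
                out.append(ch)
        return "".join(out)

    p2 = collapse(p1)
    p3 = collapse(p1.replace("A", "a"))
    if any(ch.isalpha() for ch in token_text):
        p4 = "a"
    elif any(ch.isdigit() for ch in token_text):
        p4 = "0"
    else:
        p4 = token_text[0]
    return p1, p2, p3, p4


def char_counts(token_text: str) -> dict[str, int]:
    """Counts of uppercase, lowercase, letter, digit and special characters
    (specials drawn from ";:,.->+_")."""
    upper = sum(1 for c in token_text if c.isalpha() and c.isupper())
    lower = sum(1 for c in token_text if c.isalpha() and not c.isupper())
    digit = sum(1 for c in token_text if c.isdigit())
    special = sum(1 for c in token_text if c in _SPECIALS)
    return {
        "upper": upper,
        "lower": lower,
        "letters": upper + lower,
        "digits": digit,
        "specials": special,
    }


def affixes(token_text: str) -> dict[str, str]:
    """Prefixes and suffixes of lengths 1..5 (only lengths <= token length)."""
    out = {}
    for length in range(1, 6):
        if length <= len(token_text):
            out[f"pfx{length}"] = token_text[:length]
            out[f"sfx{length}"] = token_text[-length:]
    return out


def _load_list(name: str) -> frozenset[str]:
    text = resources.files("genenorm.data").joinpath(name).read_text("utf-8")
    return frozenset(
        line.strip().lower()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )


def load_wordlist(path) -> frozenset[str]:
    """Load a plain-text trigger list: UTF-8, one entry per line, "#"
    comments allowed, case-insensitive."""
    with open(path, encoding="utf-8") as fh:
        return frozenset(
            line.strip().lower()
            for line in fh
            if line.strip() and not line.startswith("#")
        )


@dataclass(frozen=True)
class SemanticLexiconSet:
    """Named trigger-token lists used as semantic features.

    ``gene_vocab`` holds full gene names/symbols and is matched by longest
    n-gram lookup; the remaining lists are single-token, case-insensitive.
    """

    gene_vocab: frozenset[str] = frozenset()
    gene_context: frozenset[str] = frozenset()
    disease: frozenset[str] = frozenset()
    chemical: frozenset[str] = frozenset()
    domain: frozenset[str] = frozenset()
    cell: frozenset[str] = frozenset()
    protein_symbol: frozenset[str] = frozenset()
    max_vocab_ngram: int = field(default=8)

    @classmethod
    def default(cls, gene_vocab=()) -> "SemanticLexiconSet":
        """The shipped trigger lists plus a caller-supplied gene vocabulary
        (e.g. all names of a gene lexicon)."""
        return cls(
            gene_vocab=frozenset(v.lower() for v in gene_vocab),
            gene_context=_load_list("gene_context.txt"),
            disease=_load_list("disease.txt"),
            chemical=_load_list("chemical.txt"),
            domain=_load_list("domain_tokens.txt"),
            cell=_load_list("cell.txt"),
            protein_symbol=_load_list("protein_symbol.txt"),
        )


def _gene_vocab_flags(tokens: list[Token], text_lower: list[str],
                      lexicons: SemanticLexiconSet) -> list[bool]:
    """Longest-match n-gram lookup of the gene vocabulary over the token
    sequence; all tokens covered by a match are flagged."""
    n = len(tokens)
    flags = [False] * n
    if not lexicons.gene_vocab:
        return flags
    def phrase(i: int, j: int) -> str:
        parts = [text_lower[i]]
        for k in range(i + 1, j):
            if tokens[k].start > tokens[k - 1].end:
                parts.append(" ")
            parts.append(text_lower[k])
        return "".join(parts)

    i = 0
    while i < n:
        matched = 0
        for j in range(min(n, i + lexicons.max_vocab_ngram), i, -1):
            if phrase(i, j) in lexicons.gene_vocab:
                matched = j - i
                break
        if matched:
            for k in range(i, i + matched):
                flags[k] = True
            i += matched
        else:
            i += 1
    return flags


def extract_features(
    tokens: list[Token],
    lexicons: SemanticLexiconSet | None = None,
    abbrev_pairs: list[AbbrPair] = (),
) -> list[dict[str, str | bool]]:
    """Feature map per token of one sentence, context window included.

    Deterministic given the inputs; boolean features are present with value
    True/False so neighbour copies are well-defined at every position.
    """
    if lexicons is None:
        lexicons = SemanticLexiconSet.default()
    low = [t.text.lower() for t in tokens]
    vocab_flags = _gene_vocab_flags(tokens, low, lexicons)

    abbr_flags = [
        any(p.short_start < t.end and t.start < p.short_end
            or p.long_start < t.end and t.start < p.long_end
            for p in abbrev_pairs)
        for t in tokens
    ]

    base: list[dict[str, str | bool]] = []
    for i, tok in enumerate(tokens):
        p1, p2, p3, p4 = case_patterns(tok.text)
        feats: dict[str, str | bool] = {
            "w": tok.text,
            "stem": porter_stem(tok.text),
            "pos": pos_tag(tok.text),
            "cp1": p1, "cp2": p2, "cp3": p3, "cp4": p4,
            "lex_gene": vocab_flags[i],
            "lex_gene_ctx": low[i] in lexicons.gene_context,
            "lex_disease": low[i] in lexicons.disease,
            "lex_chem": low[i] in lexicons.chemical,
            "lex_domain": low[i] in lexicons.domain,
            "lex_cell": low[i] in lexicons.cell,
            "lex_aa": low[i] in lexicons.protein_symbol,
            "abbr": abbr_flags[i],
        }
        feats.update(affixes(tok.text))
        for name, value in char_counts(tok.text).items():
            feats[f"n_{name}"] = str(value)
        base.append(feats)

    out: list[dict[str, str | bool]] = []
    for i in range(len(tokens)):
        feats = dict(base[i])
        for off in (-3, -2, -1, 1, 2, 3):
            j = i + off
            if 0 <= j < len(tokens):
                for key in _CONTEXT_KEYS:
                    feats[f"{key}@{off:+d}"] = base[j][key]
        out.append(feats)
    return out


def encode_features(feats: dict[str, str | bool]) -> list[str]:
    """Serialize one feature map to sorted ``key=value`` strings (booleans
    emit the bare key when True and are dropped when False)."""
    parts = []
    for key in sorted(feats):
        val = feats[key]
        if isinstance(val, bool):
            if val:
                parts.append(key)
        else:
            parts.append(f"{key}={val}")
    return parts
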