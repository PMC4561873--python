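"""Core in-memory containers shared across the pipeline.

Offsets are 0-based, half-open character offsets into the whole document
text, which is the concatenation ``title + "\\n" + abstract``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum


class MentionType(str, Enum):
    """Entity classes the tagger distinguishes.

    Gene mentions are normalized to concept identifiers; family and domain
    mentions are never normalized but serve as disambiguation context.
    """

    GENE = "Gene"
    FAMILY = "FamilyName"
    DOMAIN = "DomainMotif"


@dataclass(frozen=True)
class Token:
    """A class-pure text span: one-case letter run, digit run, or a single
    punctuation/symbol character. Whitespace is never a token."""

    text: str
    start: int
    end: int


@dataclass(frozen=True)
class SentenceSpan:
    start: int
    end: int


@dataclass
class Mention:
    """A contiguous entity span with a type and (after normalization)
    concept identifiers."""

    start: int
    end: int
    text: str
    type: MentionType
    source: str = "crf"  # "crf" or "rule"
    ids: list[str] = field(default_factory=list)
    taxid: str | None = None

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


@dataclass(frozen=True)
class AbbrPair:
    """A (short form, long form) abbreviation pair within one document."""

    short_start: int
    short_end: int
    short_text: str
    long_start: int
    long_end: int
    long_text: str


@dataclass(frozen=True)
class SpeciesTag:
    start: int
    end: int
    name: str
    taxid: str


@dataclass
class Document:
    doc_id: str
    title: str
    abstract: str
    mentions: list[Mention] = field(default_factory=list)
    species_tags: list[SpeciesTag] = field(default_factory=list)
    abbrev_pairs: list[AbbrPair] = field(default_factory=list)
    doc_ids: set[str] = field(default_factory=set)

    @property
    def text(self) -> str:
        if self.abstract:
            return self.title + "\n" + self.abstract
        return self.title

    def validate(self) -> None:
        text = self.text
        for m in self.mentions:
            if not (0 <= m.start < m.end <= len(text)):
                raise ValueError(
                    f"{self.doc_id}: mention span ({m.start},{m.end}) out of bounds"
                )
            if text[m.start : m.end] != m.text:
                raise ValueError(
                    f"{self.doc_id}: mention text {m.text!r} != slice "
                    f"{text[m.start:m.end]!r}"
                )


GREEK_TO_NAME = {
    "α": "alpha", "β": "beta", "γ": "gamma", "δ": "delta", "ε": "epsilon",
    "ζ": "zeta", "η": "eta", "θ": "theta", "ι": "iota", "κ": "kappa",
    "λ": "lambda", "μ": "mu", "ν": "nu", "ξ": "xi", "ο": "omicron",
    "π": "pi", "ρ": "rho", "σ": "sigma", "ς": "sigma", "τ": "tau",
    "υ": "upsilon", "φ": "phi", "χ": "chi", "ψ": "psi", "ω": "omega",
}
GREEK_TO_NAME.update({k.upper(): v for k, v in list(GREEK_TO_NAME.items())
                      if k.upper() != k})


def expand_greek(text: str) -> str:
    """Replace Greek letters by their spelled-out names ("α" -> "alpha")."""
    if not any(c in GREEK_TO_NAME for c in text):
        return text
    return "".join(GREEK_TO_NAME.get(c, c) for c in text)
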