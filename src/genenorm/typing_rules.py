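"""Document-level postprocessing rules that arbitrate mention types.

Four rules run in a fixed order after CRF decoding: (1) suffix triggers
("... proteins" -> family, "... domain" -> domain); (2) a mention whose text
is a strict prefix of another mention's text is retyped as a family
("TIF1" next to "TIF1alpha"); (3) a short form inherits the type of the
mention covering its long form; (4) occurrences of the same text
(case-insensitive) take the document-majority type, ties breaking by the
precedence Gene > FamilyName > DomainMotif. Rules change types only, never
spans, and the full pipeline is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from .types import AbbrPair, Mention, MentionType

_TYPE_PRECEDENCE = [MentionType.GENE, MentionType.FAMILY, MentionType.DOMAIN]


def _load_suffixes(name: str) -> tuple[str, ...]:
    text = resources.files("genenorm.data").joinpath(name).read_text("utf-8")
    entries = [line.strip().lower() for line in text.splitlines()
               if line.strip() and not line.startswith("#")]
    # longest first so "-related proteins" wins over "proteins"
    return tuple(sorted(entries, key=len, reverse=True))


@dataclass(frozen=True)
class SuffixLists:
    family: tuple[str, ...]
    domain: tuple[str, ...]

    @classmethod
    def default(cls) -> "SuffixLists":
        return cls(family=_load_suffixes("family_suffixes.txt"),
                   domain=_load_suffixes("domain_suffixes.txt"))


def _ends_with_trigger(text: str, triggers: tuple[str, ...]) -> bool:
    low = text.lower()
    for trig in triggers:
        if low == trig:
            continue  # the trigger alone is not a retyping cue
        if low.endswith(trig):
            boundary = low[-len(trig) - 1]
            if not boundary.isalnum():
                return True
    return False


def suffix_rule(mention: Mention, suffixes: SuffixLists | None = None
                ) -> Mention:
    """Retype by trailing trigger word; unchanged when no trigger matches."""
    suffixes = suffixes or SuffixLists.default()
    if _ends_with_trigger(mention.text, suffixes.family):
        mention.type = MentionType.FAMILY
        mention.source = "rule"
    elif _ends_with_trigger(mention.text, suffixes.domain):
        mention.type = MentionType.DOMAIN
        mention.source = "rule"
    return mention


def prefix_rule(mentions: list[Mention]) -> list[Mention]:
    """A mention that is a strict prefix of another mention in the same
    document becomes a family name.

    Composite superstrings ("BRCA1/2") do not trigger the rule: they are
    enumerations of sibling genes, not the name extensions ("TIF1" vs
    "TIF1alpha") the rule is meant to catch.
    """
    from . import composite

    texts = {m.text for m in mentions
             if len(composite.expand(m.text)) == 1}
    for m in mentions:
        if any(other != m.text and other.startswith(m.text)
               for other in texts):
            if m.type != MentionType.FAMILY:
                m.type = MentionType.FAMILY
                m.source = "rule"
    return mentions


def abbrev_type_rule(mentions: list[Mention],
                     pairs: list[AbbrPair]) -> list[Mention]:
    """Propagate the type of the long-form mention to every mention whose
    text equals the short form."""
    for pair in pairs:
        long_type: MentionType | None = None
        best_overlap = 0
        for m in mentions:
            overlap = (min(m.end, pair.long_end)
                       - max(m.start, pair.long_start))
            if overlap > best_overlap:
                best_overlap = overlap
                long_type = m.type
        if long_type is None:
            continue
        for m in mentions:
            if m.text == pair.short_text and m.type != long_type:
                m.type = long_type
                m.source = "rule"
    return mentions


def majority_rule(mentions: list[Mention]) -> list[Mention]:
    """Unify the type of repeated mention texts by document majority."""
    groups: dict[str, list[Mention]] = {}
    for m in mentions:
        groups.setdefault(m.text.lower(), []).append(m)
    for group in groups.values():
        if len(group) < 2:
            continue
        counts = {t: 0 for t in _TYPE_PRECEDENCE}
        for m in group:
            counts[m.type] += 1
        best = max(_TYPE_PRECEDENCE,
                   key=lambda t: (counts[t], -_TYPE_PRECEDENCE.index(t)))
        for m in group:
            if m.type != best:
                m.type = best
                m.source = "rule"
    return mentions


def apply_typing_rules(mentions: list[Mention], pairs: list[AbbrPair] = (),
                       suffixes: SuffixLists | None = None) -> list[Mention]:
    """The fixed rule pipeline: suffix -> prefix -> abbreviation -> majority."""
    suffixes = suffixes or SuffixLists.default()
    for m in mentions:
        suffix_rule(m, suffixes)
    prefix_rule(mentions)
    abbrev_type_rule(mentions, list(pairs))
    majority_rule(mentions)
    return mentions
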