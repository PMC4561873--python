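"""Species recognition and species assignment for gene mentions.

Species names are tagged by longest-match, case-insensitive dictionary
lookup. Each gene mention then receives exactly one taxonomy id by a fixed
priority: (1) a species-indicating prefix on the mention itself ("hTIF1" ->
human when "TIF1" is a known gene name); (2) the nearest species tag to the
left within the same sentence; (3) the nearest species tag anywhere in the
document; (4) the document-majority species; (5) a configurable default
(human, 9606).
"""

from __future__ import annotations

import re
from importlib import resources

from .tokenizer import split_sentences
from .types import Mention, SentenceSpan, SpeciesTag

DEFAULT_TAXID = "9606"

# species-indicating single-letter prefixes on gene symbols
PREFIX_TAXIDS = {
    "h": "9606",   # human
    "m": "10090",  # mouse
    "r": "10116",  # rat
    "d": "7227",   # fly
    "y": "4932",   # yeast
}


def load_species_lexicon(path=None) -> dict[str, str]:
    """Species lexicon: TSV rows ``taxid<TAB>name`` (one synonym per row).
    Returns a case-insensitive name -> taxid map; the shipped default covers
    the common model organisms."""
    if path is None:
        text = resources.files("genenorm.data").joinpath(
            "species.tsv").read_text("utf-8")
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    lex: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        taxid, name = line.split("\t", 1)
        lex[name.strip().lower()] = taxid.strip()
    return lex


def tag_species(text: str, lexicon: dict[str, str] | None = None
                ) -> list[SpeciesTag]:
    """Longest-match dictionary tagging of species names."""
    lexicon = lexicon if lexicon is not None else load_species_lexicon()
    lexicon = {k.lower(): v for k, v in lexicon.items()}
    if not lexicon:
        return []
    names = sorted(lexicon, key=len, reverse=True)
    pattern = re.compile(
        "|".join(r"(?<![A-Za-z0-9])" + re.escape(n) + r"(?![A-Za-z0-9])"
                 for n in names),
        re.IGNORECASE,
    )
    tags = []
    for m in pattern.finditer(text):
        tags.append(SpeciesTag(start=m.start(), end=m.end(),
                               name=m.group(),
                               taxid=lexicon[m.group().lower()]))
    return tags


def _normalized(name: str) -> str:
    return re.sub(r"[\s-]+", "", name).lower()


def assign_species(
    gene_mentions: list[Mention],
    species_tags: list[SpeciesTag],
    text: str,
    gene_names: set[str] = frozenset(),
    default_taxid: str = DEFAULT_TAXID,
    sentences: list[SentenceSpan] | None = None,
) -> list[str]:
    """Assign one taxid per gene mention (mentions are also updated in
    place). ``gene_names`` is the known gene vocabulary used to validate
    prefix-stripped remainders."""
    sentences = sentences if sentences is not None else split_sentences(text)
    norm_names = {_normalized(n) for n in gene_names}
    majority: str | None = None
    if species_tags:
        counts: dict[str, int] = {}
        first_pos: dict[str, int] = {}
        for i, t in enumerate(species_tags):
            counts[t.taxid] = counts.get(t.taxid, 0) + 1
            first_pos.setdefault(t.taxid, i)
        majority = max(counts, key=lambda k: (counts[k], -first_pos[k]))
    out = []
    for m in gene_mentions:
        taxid = None
        # (1) species prefix on the mention
        head = m.text[:1].lower()
        if head in PREFIX_TAXIDS and len(m.text) > 1:
            remainder = m.text[1:]
            if _normalized(remainder) in norm_names:
                taxid = PREFIX_TAXIDS[head]
        # (2) nearest tag to the left in the same sentence
        if taxid is None:
            sent = next((s for s in sentences
                         if s.start <= m.start < s.end), None)
            if sent is not None:
                left = [t for t in species_tags
                        if t.start >= sent.start and t.end <= m.start]
                if left:
                    taxid = max(left, key=lambda t: t.end).taxid
        # (3) nearest tag in the document
        if taxid is None and species_tags:
            taxid = min(
                species_tags,
                key=lambda t: min(abs(t.start - m.end), abs(m.start - t.end)),
            ).taxid
        # (4) document majority, (5) default
        if taxid is None:
            taxid = majority if majority is not None else default_taxid
        m.taxid = taxid
        out.append(taxid)
    return out
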