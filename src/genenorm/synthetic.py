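"""Synthetic gene lexicons and annotated corpora.

The generator emulates the structure of a mention- and identifier-annotated
abstract collection: every document carries gene, gene-family and
protein-domain mention spans, species cues, abbreviation definitions,
composite mentions and a document-level identifier set, with the three
mention classes mixed at roughly the 11.4 : 3.9 : 1 gene : family : domain
ratio of curated gene corpora. Lexicon entries get a symbol (letters plus a
digit), a multi-word full name whose words spell out the symbol letters
(so abbreviation definitions align), orthographic variants, shared family
terms within symbol series, and optional domain terms. Cross-species
ambiguity (orthologs and shared synonyms) is injected at a configurable
fraction; within one species, (name, taxid) stays unique so gold identifier
sets are exactly recoverable from the lexicon.

All randomness flows from one ``numpy`` generator seeded by the caller.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .normalizer import LexiconEntry
from .types import Document, Mention, MentionType, SpeciesTag

_SPECIES_TABLE = [
    ("9606", ("human", "Homo sapiens")),
    ("10090", ("mouse", "Mus musculus")),
    ("10116", ("rat", "Rattus norvegicus")),
    ("7227", ("Drosophila", "fly")),
    ("4932", ("yeast", "Saccharomyces cerevisiae")),
    ("7955", ("zebrafish", "Danio rerio")),
]

_LETTER_WORDS = {
    "A": ("activin", "adhesion"), "B": ("binding", "bone"),
    "C": ("cyclin", "calcium"), "D": ("death", "dehydrogenase"),
    "E": ("enhancer", "elongation"), "F": ("factor", "fibroblast"),
    "G": ("growth", "glutamate"), "H": ("homeobox", "heat"),
    "I": ("inhibitor", "insulin"), "J": ("junction", "janus"),
    "K": ("kinase", "keratin"), "L": ("ligand", "lysine"),
    "M": ("mediator", "myosin"), "N": ("nuclear", "neural"),
    "O": ("oxidase", "opioid"), "P": ("phosphatase", "polymerase"),
    "Q": ("quiescence", "quinone"), "R": ("receptor", "ribosomal"),
    "S": ("signal", "serine"), "T": ("transducer", "tyrosine"),
    "U": ("ubiquitin", "uridine"), "V": ("vesicle", "vascular"),
    "W": ("wingless", "tryptophan"), "X": ("xenobiotic", "exportin"),
    "Y": ("tyrosine", "yippee"), "Z": ("zinc", "zygotic"),
}

_DOMAIN_BANK = ("PNT", "LIM", "SH2", "SH3", "RING", "ETS", "PHD", "BTB",
                "WD40", "EGF")


@dataclass
class CorpusParams:
    """Knobs of the corpus generator; defaults are the study conditions."""

    # sentence-category probabilities (gene-heavy mixture approximating the
    # 7457:2527:656 gene:family:domain mention ratio of curated corpora)
    category_probs: dict = field(default_factory=lambda: {
        "gene": 0.34, "family": 0.20, "domain": 0.07,
        "abbrev": 0.10, "composite": 0.07, "filler": 0.22,
    })
    sentences_range: tuple[int, int] = (3, 6)
    genes_per_doc: tuple[int, int] = (1, 3)
    # surface-form mixture for gene mentions: symbol / full name / variant
    surface_probs: tuple[float, float, float] = (0.6, 0.2, 0.2)


def _load_templates() -> dict[str, list[str]]:
    text = resources.files("genenorm.data").joinpath(
        "templates.txt").read_text("utf-8")
    out: dict[str, list[str]] = {}
    for line in text.splitlines():
        line = line.rstrip()
        if not line or line.startswith("#"):
            continue
        cat, tpl = line.split("\t", 1)
        out.setdefault(cat, []).append(tpl)
    return out


def _symbol_stem(entry: LexiconEntry) -> str:
    return re.sub(r"\d+$", "", entry.names[0])


def generate_lexicon(n_genes: int, n_species: int = 3, seed: int = 0,
                     ambiguity_fraction: float = 0.1
                     ) -> tuple[list[LexiconEntry], dict[str, str]]:
    """Deterministically generate a gene lexicon and a species lexicon.

    Returns (entries, species name -> taxid map). A fraction of entries are
    cross-species duplicates — orthologs sharing all names, or entries that
    gained another gene's symbol as a synonym — so that symbol lookup alone
    is ambiguous but (name, taxid) is not.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not 1 <= n_species <= len(_SPECIES_TABLE):
        raise ValueError(f"n_species must be in 1..{len(_SPECIES_TABLE)}")
    rng = np.random.default_rng(seed)
    taxids = [t for t, _ in _SPECIES_TABLE[:n_species]]
    taxid_probs = np.array([0.7] + [0.3 / (n_species - 1)] * (n_species - 1)
                           ) if n_species > 1 else np.array([1.0])

    letters = [chr(ord("A") + i) for i in range(26)]
    used_stems: set[str] = set()
    used_word_seqs: set[str] = set()
    entries: list[LexiconEntry] = []
    next_id = 101

    def new_stem() -> str:
        while True:
            k = int(rng.integers(3, 5))
            stem = "".join(rng.choice(letters, size=k))
            if stem not in used_stems:
                used_stems.add(stem)
                return stem

    def words_for(stem: str) -> list[str]:
        # distinct full-name word sequence per stem (letters offer two
        # word choices each; walk the combinations until an unused one)
        base = [int(rng.integers(0, 2)) for _ in stem]
        for combo in range(2 ** len(stem)):
            picks = [(base[i] + (combo >> i)) % 2 for i in range(len(stem))]
            words = [_LETTER_WORDS[ch][p] for ch, p in zip(stem, picks)]
            seq = " ".join(words)
            if seq not in used_word_seqs:
                used_word_seqs.add(seq)
                return words
        words = [_LETTER_WORDS[ch][base[i]]
                 for i, ch in enumerate(stem)] + [stem.lower()]
        used_word_seqs.add(" ".join(words))
        return words

    while len(entries) < n_genes:
        taxid = str(rng.choice(taxids, p=taxid_probs))
        remaining = n_genes - len(entries)
        series = remaining >= 2 and rng.random() < 0.5
        stem = new_stem()
        size = int(rng.integers(2, min(4, remaining) + 1)) if series else 1
        words_fixed = words_for(stem)
        family = (" ".join(words_fixed),) if series else ()
        domains = tuple(
            rng.choice(_DOMAIN_BANK, size=int(rng.integers(1, 3)),
                       replace=False)
        ) if rng.random() < 0.6 else ()
        for digit in range(1, size + 1):
            gene_id = str(next_id)
            symbol = f"{stem}{digit}"
            names = [symbol, " ".join(words_fixed) + f" {digit}",
                     f"{stem}-{digit}"]
            if rng.random() < 0.25:
                greek = str(rng.choice(["alpha", "beta", "gamma"]))
                names.append(f"{symbol} {greek}")
            entries.append(LexiconEntry(
                gene_id=gene_id, taxid=taxid, names=tuple(names),
                family_terms=(family + (stem,)) if series else (),
                domain_terms=domains,
            ))
            next_id += 1
            if len(entries) >= n_genes:
                break

    # inject cross-species ambiguity
    n_amb = int(round(ambiguity_fraction * n_genes))
    if n_amb and n_species > 1:
        order = [int(k) for k in rng.permutation(len(entries))]
        used: set[int] = set()
        made = 0
        for idx in order:
            if made >= n_amb:
                break
            if idx in used:
                continue
            src = entries[idx]
            j = next((k for k in order
                      if k not in used and k != idx
                      and entries[k].taxid != src.taxid), None)
            if j is None:
                break
            used.update((idx, j))
            tgt = entries[j]
            if made % 2 == 0:
                # ortholog: target adopts all of the source's names
                entries[j] = LexiconEntry(
                    gene_id=tgt.gene_id, taxid=tgt.taxid, names=src.names,
                    family_terms=tgt.family_terms,
                    domain_terms=tgt.domain_terms)
            else:
                # shared synonym: target gains the source's symbol
                if src.names[0] not in tgt.names:
                    entries[j] = LexiconEntry(
                        gene_id=tgt.gene_id, taxid=tgt.taxid,
                        names=tgt.names + (src.names[0],),
                        family_terms=tgt.family_terms,
                        domain_terms=tgt.domain_terms)
            made += 1

    species_lex: dict[str, str] = {}
    for taxid, names in _SPECIES_TABLE[:n_species]:
        for n in names:
            species_lex[n] = taxid
    return entries, species_lex


class _DocBuilder:
    def __init__(self) -> None:
        self.text = ""
        self.mentions: list[Mention] = []
        self.species_tags: list[SpeciesTag] = []

    def add(self, s: str) -> int:
        start = len(self.text)
        self.text += s
        return start

    def add_mention(self, s: str, typ: MentionType, ids: list[str],
                    taxid: str | None = None) -> None:
        start = self.add(s)
        self.mentions.append(Mention(start=start, end=start + len(s),
                                     text=s, type=typ, ids=list(ids),
                                     taxid=taxid))

    def add_species(self, s: str, taxid: str) -> None:
        start = self.add(s)
        self.species_tags.append(SpeciesTag(start=start,
                                            end=start + len(s),
                                            name=s, taxid=taxid))


_PLACEHOLDER = re.compile(r"\{[GFDSAC]\}")


def generate_corpus(lexicon: list[LexiconEntry],
                    species_lexicon: dict[str, str],
                    n_docs: int, seed: int = 0,
                    params: CorpusParams | None = None) -> list[Document]:
    """Generate ``n_docs`` annotated documents drawn from ``lexicon``."""
    if not lexicon:
        raise ValueError("empty lexicon")
    params = params or CorpusParams()
    rng = np.random.default_rng(seed)
    templates = _load_templates()

    by_taxid: dict[str, list[LexiconEntry]] = {}
    for e in lexicon:
        by_taxid.setdefault(e.taxid, []).append(e)
    series_by_taxid: dict[str, list[list[LexiconEntry]]] = {}
    for taxid, group in by_taxid.items():
        stems: dict[str, list[LexiconEntry]] = {}
        for e in group:
            stems.setdefault(_symbol_stem(e), []).append(e)
        series_by_taxid[taxid] = [v for v in stems.values() if len(v) >= 2]

    species_names_by_taxid: dict[str, list[str]] = {}
    for name, taxid in species_lexicon.items():
        species_names_by_taxid.setdefault(taxid, []).append(name)

    cats = sorted(params.category_probs)
    cat_p = np.array([params.category_probs[c] for c in cats])
    cat_p = cat_p / cat_p.sum()

    docs: list[Document] = []
    for i in range(n_docs):
        taxid = str(rng.choice(sorted(t for t in by_taxid)))
        pool = by_taxid[taxid]
        n_genes = int(rng.integers(params.genes_per_doc[0],
                                   params.genes_per_doc[1] + 1))
        doc_genes = list(rng.choice(
            len(pool), size=min(n_genes, len(pool)), replace=False))
        doc_genes = [pool[j] for j in doc_genes]
        species_name = str(rng.choice(
            sorted(species_names_by_taxid.get(taxid, ["human"]))))

        def pick_gene():
            return doc_genes[int(rng.integers(0, len(doc_genes)))]

        # one surface form per gene per document (authors are consistent;
        # this also keeps a symbol and its suffixed synonym from colliding
        # as prefix variants inside one document)
        surfaces: dict[str, str] = {}
        for g in doc_genes:
            r = rng.random()
            p_sym, p_full, _ = params.surface_probs
            if r < p_sym or len(g.names) < 2:
                surfaces[g.gene_id] = g.names[0]
            elif r < p_sym + p_full:
                surfaces[g.gene_id] = g.names[1]
            elif len(g.names) > 2:
                surfaces[g.gene_id] = g.names[
                    int(rng.integers(2, len(g.names)))]
            else:
                surfaces[g.gene_id] = g.names[0]

        def gene_surface(entry: LexiconEntry) -> str:
            return surfaces[entry.gene_id]

        def fill(template: str, b: _DocBuilder) -> None:
            pos = 0
            for m in _PLACEHOLDER.finditer(template):
                b.add(template[pos:m.start()])
                code = m.group()[1]
                if code == "G":
                    g = pick_gene()
                    b.add_mention(gene_surface(g), MentionType.GENE,
                                  [g.gene_id], taxid)
                elif code == "S":
                    b.add_species(species_name, taxid)
                elif code == "F":
                    g = pick_gene()
                    stem = _symbol_stem(g)
                    form = ["{} family", "{} proteins"][
                        int(rng.integers(0, 2))]
                    b.add_mention(form.format(stem), MentionType.FAMILY, [])
                elif code == "D":
                    g = pick_gene()
                    term = (g.domain_terms[0] if g.domain_terms
                            else str(rng.choice(_DOMAIN_BANK)))
                    b.add_mention(f"{term} domain", MentionType.DOMAIN, [])
                elif code == "A":
                    g = pick_gene()
                    full = g.names[1] if len(g.names) > 1 else g.names[0]
                    b.add_mention(full, MentionType.GENE, [g.gene_id], taxid)
                    b.add(" (")
                    b.add_mention(g.names[0], MentionType.GENE,
                                  [g.gene_id], taxid)
                    b.add(")")
                elif code == "C":
                    series = series_by_taxid.get(taxid) or []
                    if not series:
                        g = pick_gene()
                        b.add_mention(gene_surface(g), MentionType.GENE,
                                      [g.gene_id], taxid)
                        pos = m.end()
                        continue
                    group = series[int(rng.integers(0, len(series)))]
                    stem = _symbol_stem(group[0])
                    if len(group) >= 3 and rng.random() < 0.4:
                        chosen = sorted(
                            rng.choice(len(group), size=3, replace=False))
                        digits = [g.names[0][len(stem):]
                                  for g in (group[k] for k in chosen)]
                        text = (f"{stem}s {digits[0]}, {digits[1]}, "
                                f"and {digits[2]}")
                        ids = [group[k].gene_id for k in chosen]
                    else:
                        chosen = sorted(
                            rng.choice(len(group), size=2, replace=False))
                        digits = [g.names[0][len(stem):]
                                  for g in (group[k] for k in chosen)]
                        text = f"{stem}{digits[0]}/{digits[1]}"
                        ids = [group[k].gene_id for k in chosen]
                    b.add_mention(text, MentionType.GENE, ids, taxid)
                pos = m.end()
            b.add(template[pos:])

        b = _DocBuilder()
        title_tpl = templates["title"][
            int(rng.integers(0, len(templates["title"])))]
        fill(title_tpl, b)
        title_end = len(b.text)
        b.add("\n")

        n_sent = int(rng.integers(params.sentences_range[0],
                                  params.sentences_range[1] + 1))
        species_cued = [t for t in templates["gene"] if "{S}" in t]
        for s in range(n_sent):
            if s > 0:
                b.add(" ")
            if s == 0:
                tpl = species_cued[int(rng.integers(0, len(species_cued)))]
            else:
                cat = cats[int(rng.choice(len(cats), p=cat_p))]
                tpl = templates[cat][
                    int(rng.integers(0, len(templates[cat])))]
            fill(tpl, b)

        title = b.text[:title_end]
        abstract = b.text[title_end + 1:]
        doc = Document(
            doc_id=str(10_000_000 + i), title=title, abstract=abstract,
            mentions=sorted(b.mentions, key=lambda m: (m.start, m.end)),
            species_tags=b.species_tags,
        )
        doc.doc_ids = {gid for m in doc.mentions
                       if m.type == MentionType.GENE for gid in m.ids}
        doc.validate()
        docs.append(doc)
    return docs
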