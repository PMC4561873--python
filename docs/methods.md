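# Methods

`genenorm` solves two coupled literature-mining tasks over PubMed-style
abstracts: **gene mention recognition** (finding the character offsets of
gene, gene-family and protein-domain names) and **gene normalization**
(returning the set of database concept identifiers a document discusses).
The two stages are deliberately separated: a statistical tagger proposes
typed spans, deterministic document-level rules arbitrate the three
entity classes, and a lexicon matcher resolves only the Gene-typed spans
to identifiers, using the family and domain spans as disambiguation
context rather than discarding them.

## Tokenization

Text is split at punctuation, whitespace, letter/digit boundaries and
case transitions, so every token is a class-pure unit: a one-case run of
letters, a run of digits, or a single punctuation character ("hTIF1" →
"h", "TIF", "1"). This aggressive splitting makes shape features sharp
(a trailing digit or a case flip is its own token) and lets a
species-indicating prefix letter separate from the symbol it decorates.
Both case-transition directions split; Greek and other non-ASCII letters
form their own tokens next to Latin letters. Offsets are 0-based,
half-open over `title + "\n" + abstract`. Sentence splitting is a small
rule set (terminal punctuation + whitespace + upper/digit start, with an
abbreviation stoplist); callers can substitute their own spans anywhere
sentence structure is consumed.

## Mention tagger

Sequence labeling uses the BIEO scheme (begin / inside / end / outside)
crossed with the three entity types — ten labels; single-token mentions
are labeled B. The model is a linear-chain conditional random field
trained by L-BFGS on the L2-regularized conditional log-likelihood,
written in-house on numpy/scipy: emissions are tied to the current label
through a sparse feature matrix, and the default **order-2** chain adds a
transition tensor over label triples, evaluated exactly by
forward–backward over pair states. Zero initialization, sorted feature
vocabularies and a deterministic optimizer make retraining reproducible
bit for bit. Defaults: order 2, L2 coefficient 1.0, ≤100 iterations,
`ftol` 1e-6; all recorded in the saved model's metadata together with the
feature-template version, stemmer/POS-tagger names and a fingerprint of
the semantic lexicons.

Five feature families are extracted per token: linguistic (surface,
Porter stem, rule-based POS tag, prefixes/suffixes of length 1–5),
character counts (upper, lower, letters, digits, specials `;:,.->+_`),
semantic (longest-match lookup against a gene vocabulary, trigger-token
lists for gene context / disease / chemical / domain / cell / amino-acid
names, and participation in a detected abbreviation pair), four case
patterns (char-by-char shape, collapsed, case-folded collapsed, and a
one-symbol summary), and context copies of the dictionary + linguistic
features for the three neighbours on each side. The stemmer is a Porter
implementation; the POS tagger is a deterministic closed-class +
suffix-heuristic rule tagger. Both are intentionally lightweight
stand-ins recorded in model metadata so they can be swapped without
silently mixing feature spaces. Character/case features of neighbours are
not copied into context positions — only dictionary and linguistic ones.

Decoded label sequences pass through a repair step (leading I→B, dangling
E→B, type conflicts resolve to the block's B type) that is idempotent and
guarantees well-formed, non-overlapping mentions. Gold spans that do not
align with token boundaries are snapped outward at training time with a
warning.

## Type arbitration rules

Four document-level rules run in fixed order; they change types only,
never spans, and the pipeline is idempotent:

1. **Suffix**: a trailing trigger retypes the mention ("… proteins",
   "… family" → family; "… domain", "… motif", "… finger" → domain).
   Trigger lists ship as plain-text files and are replaceable.
2. **Prefix**: a mention whose text is a strict prefix of another
   mention's text becomes a family name ("TIF1" beside "TIF1alpha").
   Composite superstrings ("BRCA1/2") are exempt — they are enumerations
   of sibling genes, not name extensions, and retyping their shared stem
   would destroy correct gene mentions.
3. **Abbreviation**: a short form inherits the type of the mention
   covering its long form.
4. **Majority**: occurrences of the same text (case-insensitive) take the
   document-majority type; ties break Gene > FamilyName > DomainMotif
   (gene being the dominant class in annotated corpora).

## Abbreviation detection

The classic parenthetical right-to-left alignment: a candidate short form
in parentheses (≤10 characters, ≤2 words, at least one letter) is aligned
against the preceding words — every alphanumeric short-form character
must appear in order, the first at a word-initial position — and the
matched window becomes the long form. The search window is limited to
min(|sf|+5, 2·|sf|) words. Greek letters match their spelled-out names
("ERα" ↔ "estrogen receptor alpha"). The reversed layout
("NGF (nerve growth factor)") is recognized symmetrically. This is a
documented stand-in for heavier abbreviation extractors; nested and
cross-document abbreviations are out of scope.

## Composite mentions

Three pattern families expand a single span into several concept names:
slash alternation on a shared numeric stem ("BRCA1/2", and full tokens
"BRCA1/BRCA2" split directly), pluralized stem with an enumerated list
("SMADs 1, 5, and 8"), and numeric ranges ("ERK1-3", expanded only for
ascending spans of ≤20 to guard against spurious numerals). Everything
else returns unchanged, which the suite checks as an identity property
over a thousand lexicon names. Constituents keep the original span;
document-level normalization is unaffected by that choice.

## Species assignment

Species names are tagged by longest-match case-insensitive lookup in a
TSV lexicon (taxid, name). Every gene mention then gets exactly one
taxonomy id by fixed priority: (1) a species-indicating prefix on the
mention itself (h/m/r/d/y for human, mouse, rat, fly, yeast) when the
remainder is a known gene name; (2) the nearest species tag to the left
in the same sentence; (3) the nearest tag in the document; (4) the
document-majority species; (5) a configurable default (9606, human —
the convention of human-centric benchmark tasks). Right-context tags are
deliberately ignored at step 2.

## Normalization

The lexicon (TSV: gene_id, taxid, pipe-separated names, family terms,
domain terms) is indexed twice: an exact map over normalized names
(lowercase, spaces/hyphens removed, Greek spelled out — "ESR-1", "ESR1"
and "ER α" collide deliberately) and an inverted token index with
weights w(t) = ln(1 + N/df(t)), N the entry count and df(t) the number of
entries containing stemmed token t. Bag-of-words scoring is the cosine
between weighted binary token vectors of the mention and of the entry's
**best single name** (term frequency capped at one; this realizes a flat
inference network with tf capped at 1). Exact matches take precedence;
otherwise bag-of-words candidates above θ (default 0.6) are kept.

Candidate re-ranking adds +β_f (default 0.2) when any family mention in
the document matches the candidate's family terms or names, and +β_d
(default 0.3) for domain mentions against its domain terms; context
mentions are stripped of generic trigger words ("family", "domain", …)
and matched at a separate threshold (default 0.5). Remaining ties break
toward the numerically smaller identifier. The species filter is *soft*:
candidates of the assigned taxid win, but if the filter would empty a
non-empty list the cross-species homologs are retained — needed for
multispecies text. Family and domain mentions are never normalized to
gene identifiers; a mention-list filter would fail exactly when a family
name is missing from the list, whereas typed mentions stay useful as
context regardless.

Per document: composites are expanded and each constituent resolved
separately; a short form whose long form resolved takes the long form's
candidate; the document identifier set is the union of top-ranked ids
over Gene mentions.

## Synthetic data

The generator emulates the statistical structure the pipeline exploits,
not biomedical language. Lexicon entries get a symbol (3–4 uppercase
letters + digit), a full name whose words spell out the symbol's letters
(guaranteeing abbreviation alignment and bag-of-words affinity), a hyphen
variant, sometimes a Greek-suffixed synonym, family terms shared within
symbol series (stem + 1..k), and domain terms from a small bank. Species
are drawn from six model organisms with a human-dominant (70%) mix.
Ambiguity is injected cross-species only — ortholog clones sharing all
names and shared-synonym pairs — so (name, taxid) stays unique and gold
identifier sets remain exactly recoverable from the lexicon; the default
ambiguous fraction is 0.1.

Documents are assembled from a pinned template file: a title plus 3–6
sentences over categories (gene 0.34, family 0.20, domain 0.07,
abbreviation definition 0.10, composite 0.07, gene-free filler 0.22),
which yields a gene-heavy mention mixture approximating the ≈ 11.4 : 3.9
: 1 gene : family : domain ratio of curated gene corpora. Every document
carries a species cue; each gene keeps one surface form per document
(authors are consistent, and this keeps a symbol and its suffixed synonym
from colliding as prefix variants in the same text). All randomness flows
from a single seeded generator, so corpora are byte-reproducible.

What passing on this corpus does **not** show: robustness to real
linguistic variation (anaphora, appositions, novel morphology), to
out-of-lexicon names, to noisy annotation, or to the long-tail ambiguity
of a full organism-scale lexicon. The synthetic scores are a correctness
check of the machinery under clean conditions, not a benchmark claim.

## Problem sizes and numerical choices

The standard evaluation (tests and the acceptance script) trains on 200
synthetic documents over a 200-gene lexicon and scores 50 held-out
documents — sizes chosen to exercise every pipeline stage, including the
order-2 CRF, at desk scale. Training is deterministic; decoding breaks
score ties by numpy argmax order, which is fixed. Degenerate inputs are
defined: empty text tokenizes to nothing, an empty corpus or a corpus
with no positive labels is rejected, empty candidate lists propagate as
"no identifier", and zero-denominator metrics report 0 with an
`undefined` flag.

## Known limitations

* The CRF is batch-trained in memory; corpora far beyond ~10⁴ sentences
  would need mini-batching or feature pruning.
* The abbreviation and composite modules implement the common pattern
  families only; coordination ellipsis over multi-word names ("alpha and
  beta catenin") is out of scope unless the shared stem is one token.
* The rule-based POS tagger is coarse; swapping in a trained tagger is a
  one-line change but alters the feature space (the model metadata guards
  against accidental mixing).
* Lexicon construction from a live gene database is out of scope; the
  TSV schema documents the expected columns.
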