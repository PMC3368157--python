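# Methods

This note records the models implemented in `bioeve`, the conventions that
were deliberately fixed so results are exactly reproducible, and what the
synthetic corpora do and do not establish.

## Ingestion and sentence splitting

All input text is normalized to Unicode NFC on read. Offsets are 0-based,
half-open, counted in code points, and every `Sentence` satisfies
`abstract[char_start:char_end] == text`; no downstream component ever
re-derives text from tokens.

The sentence splitter is rule-based and deterministic: a run of `.!?`
followed by whitespace and an upper-case letter or digit ends a sentence,
unless the token preceding a period is (a) on the shipped abbreviation
whitelist (`Fig.`, `et al.`, `i.e.`, …, editable at
`src/bioeve/data/abbreviations.txt`) or (b) a single word character plus
period, which protects species abbreviations like "E. coli". A rule-based
splitter was chosen over a statistical one because abstracts are short,
the failure modes are auditable, and determinism is needed for offset-
anchored annotations.

## Dictionary entity tagging

Tagging is greedy longest-match over token n-grams up to 6 tokens, left to
right, with matched spans consumed, so mentions never overlap. Tokens are
maximal word-character runs with internal hyphens kept ("IL-2" is one
token). Case policy: surfaces of ≤4 characters match exactly, longer
surfaces case-insensitively — short biomedical symbols ("p53", "ALL") are
case-informative in a way long names are not. When lexicons of different
entity classes match at the same position, class priority (gene > dna >
rna > cell_line > cell_type > chemical > disease) wins before span length;
any fixed priority would do, but one must be declared for the annotation
pass to be deterministic and idempotent.

## Sentence-level event classification

**Features.** Tokens are lowercased; tokens not starting with a letter are
discarded (so "−300" is dropped while "p55" survives). One sentence is one
document for idf purposes and idf(t) = ln(N/df(t)) with no smoothing —
tokens present in every training sentence get weight 0. Term weights are
tf·idf, L2-normalized. Boosting operates after normalization and
re-normalizes: gene-span tokens are removed and their summed weight is
moved to the single feature `protein`, which is multiplied by 2.0; tokens
present in the mined trigger table are multiplied by 2.0. Boost-then-
renormalize (rather than boost-before-normalize) keeps the boost factor's
meaning independent of sentence length. Renaming merges all gene tokens of
a sentence into one feature, so the classifier sees "a gene is mentioned
here, with this much weight" rather than which gene.

**Trigger table.** Per class, trigger-phrase tokens from the training data
are counted, stop words removed (shipped list, editable), and ordered by
descending frequency with lexicographic tie-break.

**Naive Bayes** is multinomial over the (fractional) TF-IDF weights with
Laplace (+1) smoothing of the per-class feature totals and maximum-
likelihood class priors; prediction is the maximum posterior with ties
broken by class declaration order. An empty vector falls back to the
priors.

**Semi-supervised EM** initializes on the labeled sentences and alternates
posterior responsibilities on the unlabeled set with re-estimation from
fractional counts, stopping when the MAP objective (observed-data
log-likelihood plus the Dirichlet log-prior implied by Laplace smoothing)
improves by less than `tol` (default 1e-4, max 50 iterations). This
objective is provably non-decreasing and is asserted per iteration.

*Known limitation.* With unit-L2 TF-IDF vectors each sentence carries a
total multinomial mass of only ≈1–3, so class-conditional likelihood
ratios are strongly compressed by smoothing and the mixture is weakly
identifiable: at convergence EM tends to merge components even when
initialized from an accurate supervised model, and whether a run improves
on the labeled-only baseline depends on the seed. The monotone objective
and the degenerate case (no unlabeled data ⇒ identical to plain naive
Bayes) are guaranteed and tested; an accuracy gain from unlabeled data is
not. Practitioners wanting EM gains should use raw counts or re-weight the
unlabeled contribution; both are deliberate non-defaults here because the
feature contract above fixes the representation.

**MaxEnt** is multinomial logistic regression trained by L-BFGS on the
L2-penalized conditional log-likelihood (Gaussian prior σ² = 1 on every
parameter including the bias, max 200 iterations, gradient tolerance
1e-5); multi-label sentences contribute one training instance per label.
Multi-label prediction, for both EM and MaxEnt, emits every class with
posterior ≥ max(1/9, half the top posterior) — a rule that always yields
at least one label.

## Trigger-phrase CRF

A linear-chain CRF over 19 labels (`O` plus `B-`/`I-` per event class).
Per-token features:

- 17 named orthographic/affix indicators: InitCaps, AllCaps, MixedCase,
  SingleDigit, DoubleDigit, NaturalNumber, RealNumber, Hyphen, LeadHyphen,
  TrailHyphen, Punctuation, Roman, Greek (spelled-out Greek letters, list
  editable), and PRE3/SUF3 (token length ≥ 3) and PRE4/SUF4 (≥ 4)
  lowercased affixes;
- the lowercased token itself (the training-vocabulary feature);
- optional lexicon memberships (`LEX=<name>`), used for trigger-word
  dictionaries;
- copies of both neighbors' features at offsets −1/+1.

Invalid BIO transitions (`I-T` after anything other than `B-T`/`I-T`, or
at sequence start) are excluded structurally with −∞ scores in both the
partition function and Viterbi, so no training signal or decode can
produce an ill-formed path. Training maximizes the L2-penalized
conditional log-likelihood (σ² = 10, max 300 iterations, tolerance 1e-5)
with exact forward–backward gradients, verified against finite
differences; initialization is at zero, making training deterministic.
Viterbi ties break toward the lower label index, so zero weights decode to
all-`O`. Emissions for a whole training batch are computed as one sparse
feature-matrix product; forward–backward then costs O(T·L²) per sequence.

## Evaluation protocols

Single-label sentence scoring: a prediction is correct iff it equals one
of the gold events tying for maximal multiplicity in the sentence. The
per-class report resolves incorrect predictions against the first modal
event in declaration order. Span scoring matches predictions to gold
one-to-one, greedily (gold in order, first unmatched matching prediction)
— greedy is deterministic and equals optimal matching whenever soft
windows do not overlap, which the tests verify against a maximum-matching
oracle. Exact mode requires identical token interval and event type; soft
mode relaxes each endpoint by one token. Coverage is 100 × matched gold /
total gold; reports carry per-class P/R/F1 in percent with unweighted
macro averages (the simplest declared convention; class-weighted averages
can be derived from the per-class rows).

## Faceted index

Multi-term queries are conjunctive (every term must appear; refinement
should only ever narrow), as are facet filters. Ranking is TF-IDF cosine
between the query and title+abstract with idf = ln(N/df) and doc-id
tie-break. Facet counts are computed over the complete result set, never a
sample or page — this is what guarantees the click-through contract
(refining by a displayed value returns exactly its displayed count),
which is asserted over randomized corpora. Tag-cloud weights are counts
relative to the leading value; autocomplete ranks prefix matches of the
combined text and facet vocabularies by collection frequency then
lexicographically. The index persists as a JSON header plus JSON-lines
documents; postings are rebuilt deterministically on load, so the stored
form stays human-inspectable.

## Synthetic corpora

The generator emits abstracts of pseudo-word sentences with planted,
fully-recorded annotations, in every input format the other modules read.
It emulates the *structure* of an annotated event corpus — sentence/
abstract sizes, per-class trigger vocabularies, entity mentions, class
imbalance — and none of the linguistics: no syntax, no ambiguity, no
overlapping mentions, no trigger polysemy. Passing tests on it therefore
establish algorithmic correctness (formulas, inference, bookkeeping,
separability recovery), not expected performance on real text.

The `genia-like-small` preset mirrors a BioNLP'09-style corpus at one
tenth scale: 80/15/26 train/dev/test abstracts, 7–12 sentences each
(≈9.4 on average), and event-class proportions 38 : 17 : 200 : 39 : 60 :
153 : 90 : 220 : 125 (Positive_regulation most frequent,
Protein_catabolism rarest). Its remaining parameters are calibrated so
that disjoint-trigger mode actually guarantees separability for the naive
Bayes formula fixed above, where the planted trigger's evidence must
exceed the largest class-prior gap (ln(220/17) ≈ 2.6 nats) despite
Laplace compression: a small background vocabulary (15 words) recurring
in most sentences makes background idf — and hence background weight —
small; two trigger words per class, drawn uniformly, keep per-word counts
high even in rare classes; entity mentions, which are class-independent
high-idf noise, are kept sparse (rate 0.3/sentence, lexicons of 12/8/8
surfaces). Sentences carry 0/1/2 events with probabilities 0.3/0.6/0.2 in
the default configuration and 0.3/0.6/0.1 in the preset.

Problem sizes used by the checks: classifier and CRF runs use the full
preset train/test splits (≈750 training sentences, ≈230 test sentences,
≈240 test trigger spans) with means over ten seeds; oracle comparisons
use corpora of ≤100 documents and exhaustive path enumeration up to
5-token sequences; the randomized-corpus invariants use 12–50 document
corpora over ≥20 seeds.

## Known limitations

- The EM instability described above.
- The dictionary tagger has no statistical NER fallback: mentions absent
  from the lexicons are invisible, and lexicon quality fully determines
  recall on real text.
- The part-of-speech feature variant is a declared hook without a tagger
  behind it.
- The sentence splitter's abbreviation list is small and English-specific.
- The faceted index is in-memory and single-machine; it targets desk-scale
  collections, not MEDLINE-scale ones.
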