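# Methods

## Problem and pipeline

`connextract` extracts *macroconnection* statements — sentence-level
assertions that two named brain regions are monosynaptically connected —
from abstracts whose brain-region mention spans are already annotated (by
hand or by an upstream recognizer). The classification unit is the
**candidate pair**: an unordered pair of region mentions inside one
sentence. The pipeline has four stages:

1. **Candidate generation.** Every unordered mention pair sharing a
   sentence (or, for the abstract-level baseline, a document) is a
   candidate; a sentence with *k* mentions yields *k(k−1)/2* pairs.
2. **Extraction.** Either rule-based predictors or a trained
   shallow-linguistic-kernel (SLK) SVM decide which candidates are stated
   connections.
3. **Evaluation.** Document-level k-fold cross-validation with pooled
   precision/recall/F and ROC/AUC.
4. **Aggregation.** Predicted mention pairs are normalized to lexicon
   region concepts and accumulated into an undirected connectivity matrix
   that is compared against a reference connectome.

Direction, strength and negation of connections are out of scope, as are
named-entity recognition and relations spanning sentences (the evaluation
explicitly excludes cross-sentence gold relations; the synthetic generator
still produces them so the bookkeeping is exercised).

## Extractors

**Co-occurrence** predicts every candidate positive. At sentence scope its
recall over within-sentence gold relations is exactly 1 by construction;
its precision equals the positive fraction of candidate pairs.

**Rule filters.** Two precision-raising filters compose by intersection:

* *mention-count cap*: keep pairs only from sentences with ≤ t region
  mentions (default t = 5, inclusive — sentences with six or more mentions
  tend to merely list regions);
* *keyword*: keep pairs only from sentences containing a
  connectivity-related keyword. The default list is
  {afferent, efferent, projects, projection, pathway, inputs}; matching
  defaults to Porter-stem equality of lowercased tokens so inflections
  ("projections"/"projects"/"projection") unify. An exact-token mode is
  kept for ablation. The keyword may appear anywhere in the sentence, not
  only between the two mentions.

The combination of both filters is the `keyword5` extractor.

**Shallow linguistic kernel.** Each candidate pair becomes a blinded token
sequence: the two candidate mention spans collapse to single `REGION_A` /
`REGION_B` placeholder tokens and any other region mention to `REGION_O`,
making instances pair-specific in multi-mention sentences and letting
weights generalize across region names. Five L2-normalized sparse blocks
are extracted:

* three global pattern blocks of token k-grams (1 ≤ k ≤ n, default n = 3):
  *fore-between* (tokens before the first entity plus the between span),
  *between*, and *between-after*;
* two local blocks (default window w = 2): for each offset within w tokens
  of each entity, the neighbour's surface form, Porter stem, POS tag and
  orthographic flags (initial capital, all caps, contains digit,
  punctuation), with explicit boundary features past the sentence edge.

The kernel is the sum of per-block dot products, i.e. the scalar product of
the concatenated normalized blocks, so a soft-margin **linear SVM on the
explicit vectors** is exactly equivalent to a precomputed-kernel SVM (a
property the test suite checks numerically). Training uses scikit-learn's
libsvm backend (C = 1.0, balanced class weights because positives are a
small minority of candidate pairs, fixed random seed); the fitted
hyperplane is exported to a plain weight map + bias so scoring is a pure
function and models serialize to versioned JSON. Prediction scores order
instances for ROC analysis with a deterministic tie-break
(score desc, doc id, sentence, mention ids).

POS tags come from a pluggable tagger contract; the default is a
deterministic rule-based tagger (closed-class lexicon plus suffix
heuristics emitting Penn-Treebank-style tags). It is a heuristic: tags are
coarse, but they are reproducible byte-for-byte and require no model
downloads; any callable `tokens -> tags` can replace it.

## Evaluation

Predictions and gold relations are compared as order-insensitive
`(document, mention-pair)` keys. Precision = tp/(tp+fp) (0 when nothing is
predicted), recall = tp/(tp+fn), F = harmonic mean (0 when P+R = 0). AUC
follows the Mann–Whitney convention with ties counted half. Folds shuffle
documents under a seed and deal round-robin, so sizes differ by at most
one and no abstract ever spans the train/test boundary. Pooled (micro)
metrics over the union of held-out predictions are the headline numbers;
per-fold metrics are reported alongside because pooling and fold-averaging
can differ. A held-out fold containing a single class raises an error with
remediation advice (merge folds or reseed) rather than silently skipping
the fold.

## Normalization and matrix comparison

Mentions map to lexicon regions by **bag-of-stems equality**: lowercase,
tokenize, drop a minimal stopword list ({the, of, and}) and punctuation,
Porter-stem, compare as *sets* (so word order and repetition are ignored).
A mention may resolve to several regions (ambiguous synonyms) — all
resolutions are kept, each contributing to the matrix; unresolvable
mentions contribute nothing and are counted. Self-pairs (identical region
ids) are dropped; ancestor–descendant pairs are retained.

The reference connectome is **up-propagated** before comparison: a
connection (A, B) implies (A′, B′) for every ancestor-or-self A′ of A and
B′ of B. Derived pairs keep the maximum count of the pairs implying them,
which makes the closure idempotent. Matrix comparison reports unique-pair
precision/recall and an occurrence-weighted precision (each extraction
occurrence counts, so repeatedly extracted true pairs weigh more); the two
ambiguity-accounting modes (per resolution vs per mention-pair occurrence)
are both derivable from the occurrence records.

**Anatomical depth** is the mean number of nodes on the root-to-region
path over all endpoints of connected pairs, with the root counting as 1;
the convention (count the region itself, root = 1) is a declared choice.
**Degree correlation** compares per-region partner counts between two
matrices over their common regions (Pearson and Spearman, ≥ 3 regions
required).

**Era split.** Occurrences are split by publication year (default: year
≥ 1987 is the later era). The p-value is the upper-tail hypergeometric
probability of observing at least the later era's validated count when
drawing that era's occurrences from the pooled population — population
N = all resolvable predicted occurrences, successes K = those validated in
the reference, sample n = later-era occurrences. The urn parameterization
is this package's reconstruction of the standard enrichment test.

## Synthetic study conditions

The generator writes corpora whose structure mirrors an annotated abstract
corpus at desk scale; its defaults are the package's study conditions and
all tests and the acceptance script run against them:

| parameter | default | rationale |
|---|---|---|
| documents | 200 | large enough for stable 10-fold CV, small enough for seconds-scale runs |
| sentences/doc | 4–8 | abstract-sized documents; sentence 0 acts as the title |
| positive-sentence fraction | 0.35 | yields ≈13–15% positive candidate pairs after list sentences dilute, matching the minority-positive regime of real corpora |
| three-mention positives | 0.15 | exercises `REGION_O` blinding and hard negatives inside keyword sentences |
| list sentences (6 mentions) | 0.10 | sentences that enumerate regions without stating relations |
| cross-sentence relations | 0.20 | mirrors the substantial fraction of gold relations not recoverable at sentence level |
| keyword insertion / noise | 1.0 / 0.0 | noiseless default: keyword presence is a perfect marker, so the keyword rule attains recall 1.0 and the corpus is linearly separable |
| lexicon | 40 regions, depth 4 | region names use unique descriptors so stem bags are unique; every region carries a word-order-permuted synonym |
| rat-tagged documents | 0.7 | rat is the dominant species, as in curated connectivity corpora |
| years / era split | 1975–2008, 1987 | validation rate of positive pairs against the reference is 0.6 before and 0.9 from the split year, emulating the accuracy jump between tract-tracing eras |

Positive sentences instantiate connectivity templates between region pairs
drawn from the reference connectome at the era-dependent rate above (and
from non-reference pairs otherwise); negatives use co-mention templates;
a truth ledger records every candidate pair's label, keyword presence,
span status, era, species and underlying region pair, so tests compare
pipeline outputs to generator bookkeeping instead of re-deriving truth.

What the generator does **not** emulate: real lexical diversity,
anaphora, abbreviations, nested or overlapping mentions, noisy mention
boundaries, and lexicon gaps (every generated mention resolves). Passing
tests therefore demonstrate correctness of the machinery and the expected
qualitative orderings (rules trade recall for precision, SLK dominates,
occurrence-thresholding raises matrix precision, later-era extractions
validate at a higher rate), not the absolute accuracy attainable on real
literature — on its noiseless defaults the classifier separates the
corpus perfectly.

## Numerical and design choices

* Offsets are 0-based half-open; the title is sentence 0; duplicate gold
  relations between one mention pair collapse; distinct mention pairs of
  the same region pair are distinct evaluation instances.
* The Porter stemmer is implemented in-package (validated against the
  algorithm's published example words); note irregular plurals
  ("cortex"/"cortices") do not unify under pure suffix stripping.
* Zero-denominator conventions: precision 0 with an explicit flag for
  empty prediction sets; F = 0 when P + R = 0.
* Empty feature blocks are allowed (norm 0); the self-kernel of a vector
  equals its number of non-empty blocks.
* Determinism: generator, fold assignment and SVM are seeded; reruns are
  byte-identical (logs aside).
* The mention-count cap is inclusive (≤ t); "less than" readings of the
  rule correspond to t−1.

## Known limitations

* The rule-based POS tagger is coarse; with a real tagger the local-context
  POS features would be more informative on natural text.
* The bag-of-stems resolver implements only name/synonym equality — no
  mention editors such as mapping to enclosing regions.
* Species matching is a dictionary filter, not a tagger; terms must appear
  verbatim (token-level) in metadata or text.
* Reference matrices are treated as undirected throughout, consistent with
  ignoring connection direction.
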