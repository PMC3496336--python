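# connextract

Text mining of neuroanatomical connectivity from abstracts. Given
documents with annotated brain-region mention spans, `connextract`
predicts which mention pairs state a *macroconnection* ("region A projects
to region B"), evaluates extractors by document-level cross-validation,
and aggregates predictions into a region-level connectivity matrix that is
compared against a reference connectome.

It is aimed at researchers building literature-derived connectomes or
benchmarking relation-extraction methods on neuroscience text.

## What is inside

* **Candidate generation** — every unordered pair of region mentions in a
  sentence (k mentions → k(k−1)/2 pairs) is a classification instance.
* **Baselines** — co-occurrence (predict everything; total recall, weak
  precision) and two rule filters: a cap of t = 5 region mentions per
  sentence and a connectivity-keyword requirement
  ({afferent, efferent, projects, projection, pathway, inputs}, matched by
  Porter stem). Their intersection is the `keyword5` extractor.
* **Shallow linguistic kernel (SLK) classifier** — candidate mentions are
  blinded to `REGION_A`/`REGION_B` placeholders, then five L2-normalized
  feature blocks are extracted: token k-grams (k ≤ 3) over the
  fore-between, between and between-after spans, plus word/stem/POS/
  orthographic features in a ±2-token window around each entity. The
  kernel is the scalar product of the concatenated blocks,
  K(x, y) = Σ_b ⟨x_b, y_b⟩, trained as a linear soft-margin SVM.
* **Evaluation** — precision, recall, F (harmonic mean), Mann–Whitney AUC;
  10-fold cross-validation that never splits an abstract across folds.
* **Aggregation** — bag-of-stems normalization of mentions to a region
  lexicon, hierarchy up-propagation of the reference matrix, unique- and
  occurrence-weighted precision, anatomical depth, degree correlations,
  and a hypergeometric test for era effects on validation rate.
* **Synthetic generator** — seeded corpora/lexicons/reference connectomes
  with a truth ledger, so the whole pipeline is testable offline.

See `docs/methods.md` for the model details and conventions.

## Worked example

```bash
connextract simulate --out-dir run --seed 42 --n-docs 60
# [simulate] documents=60 relations=125 regions=40 reference_edges=58

connextract cv --corpus run/corpus.jsonl --method keyword5 --k 5 --seed 0 --out run/cv.tsv
# [cv] method=keyword5 k=5 precision=0.8678 recall=1.0000 f_measure=0.9292 auc=
```

The combined rule recalls every within-sentence gold relation of this
noiseless corpus (keyword insertion is certain by default) at 86.8%
precision; the false positives are extra pairs in keyword sentences with
three or more mentions. Next, train and apply the classifier and compare
the aggregate matrix with the reference connectome:

```bash
connextract train --corpus run/corpus.jsonl --out run/model.json
# [train] documents=60 n_pos=105 n_neg=705 n_features=442

connextract extract --corpus run/corpus.jsonl --method slk --model run/model.json --out run/preds.tsv
# [extract] method=slk documents=60 predictions=105

connextract aggregate --predictions run/preds.tsv --corpus run/corpus.jsonl \
    --lexicon run/lexicon.tsv --reference run/reference_edges.tsv \
    --out-dir run/agg --min-counts 1,2
# [aggregate] predictions=83 region_pairs=58 unresolved_mention_fraction=0.0000
```

`run/agg/comparison.tsv` then shows the occurrence-threshold sweep: at
threshold 1 the 58 predicted region pairs validate against the
up-propagated reference at 72.4% (unique pairs) and 80.7% when counting
occurrences — repeatedly extracted connections are more often true — and
at threshold 2 (pairs extracted at least twice) precision reaches 100%
on the 18 remaining pairs. `run/agg/era_split.json` holds the
era-stratified validation rates with their hypergeometric p-value.

The `aggregate` step keeps only documents mentioning rat (the reference
connectome is a rat resource); change `--species` to alter this.

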