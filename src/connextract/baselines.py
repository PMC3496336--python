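"""Co-occurrence and rule-based connectivity extractors.

The naive baseline predicts a connection for every mention pair sharing a
sentence (or abstract).  Two rule filters raise its precision: a cap on the
number of region mentions per sentence (sentences listing many regions
rarely state relations among them) and a connectivity-keyword requirement.
Their composition is the "keyword 5-threshold" extractor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .corpus import AbstractDocument, CandidatePair, enumerate_candidate_pairs
from .stem import stem as porter_stem

__all__ = [
    "DEFAULT_KEYWORDS",
    "RuleConfig",
    "predict_cooccurrence",
    "filter_by_mention_count",
    "filter_by_keyword",
    "predict_keyword_threshold",
]

DEFAULT_KEYWORDS = frozenset(
    {"afferent", "efferent", "projects", "projection", "pathway", "inputs"}
)


@dataclass(frozen=True)
class RuleConfig:
    """Configuration for the rule filters.

    ``max_mentions_per_sentence`` keeps pairs only from sentences with at
    most that many region mentions (inclusive; None disables the filter).
    Keyword matching defaults to Porter-stem equality so inflections like
    "projections"/"projects"/"projection" unify; ``exact-token`` mode is
    retained for ablation.
    """

    max_mentions_per_sentence: int | None = 5
    keywords: frozenset[str] = field(default=DEFAULT_KEYWORDS)
    keyword_matching: str = "stem"

    def __post_init__(self) -> None:
        if (
            self.max_mentions_per_sentence is not None
            and self.max_mentions_per_sentence < 2
        ):
            raise ValueError("max_mentions_per_sentence must be >= 2")
        if self.keyword_matching not in ("stem", "exact-token"):
            raise ValueError(
                f"unknown keyword_matching {self.keyword_matching!r}"
            )


def predict_cooccurrence(
    corpus: list[AbstractDocument], scope: str = "sentence"
) -> list[CandidatePair]:
    """Predict every candidate pair positive (the naive baseline)."""
    pairs: list[CandidatePair] = []
    for doc in corpus:
        pairs.extend(enumerate_candidate_pairs(doc, scope))
    return pairs


def _mention_counts(corpus) -> dict[tuple[str, int], int]:
    counts: dict[tuple[str, int], int] = {}
    for doc in corpus:
        for m in doc.mentions:
            key = (doc.doc_id, m.sentence_index)
            counts[key] = counts.get(key, 0) + 1
    return counts


def filter_by_mention_count(
    pairs: list[CandidatePair],
    corpus: list[AbstractDocument],
    t: int | None,
) -> list[CandidatePair]:
    """Keep a pair iff its sentence has at most *t* region mentions."""
    if t is None:
        return list(pairs)
    if t < 2:
        raise ValueError("mention-count threshold must be >= 2")
    counts = _mention_counts(corpus)
    return [
        p for p in pairs if counts.get((p.doc_id, p.sentence_index), 0) <= t
    ]


def _sentence_has_keyword(sentence, keywords, matching: str) -> bool:
    if matching == "stem":
        targets = {porter_stem(k) for k in keywords}
        return any(t.stem in targets for t in sentence.tokens)
    targets = {k.lower() for k in keywords}
    return any(t.text.lower() in targets for t in sentence.tokens)


def filter_by_keyword(
    pairs: list[CandidatePair],
    corpus: list[AbstractDocument],
    keywords=DEFAULT_KEYWORDS,
    matching: str = "stem",
) -> list[CandidatePair]:
    """Keep a pair iff its sentence contains a connectivity keyword.

    The whole sentence is searched, not just the inter-mention span.
    """
    if not keywords:
        raise ValueError("keyword set must be non-empty")
    docs = {doc.doc_id: doc for doc in corpus}
    cache: dict[tuple[str, int], bool] = {}
    kept = []
    for p in pairs:
        key = (p.doc_id, p.sentence_index)
        if key not in cache:
            sent = docs[p.doc_id].sentences[p.sentence_index]
            cache[key] = _sentence_has_keyword(sent, keywords, matching)
        if cache[key]:
            kept.append(p)
    return kept


def predict_keyword_threshold(
    corpus: list[AbstractDocument],
    t: int | None = 5,
    keywords=DEFAULT_KEYWORDS,
    matching: str = "stem",
) -> list[CandidatePair]:
    """Sentence-level co-occurrence restricted by both rules.

    Equivalent to intersecting the two single-rule prediction sets; filter
    order is immaterial.
    """
    pairs = predict_cooccurrence(corpus, "sentence")
    pairs = filter_by_mention_count(pairs, corpus, t)
    return filter_by_keyword(pairs, corpus, keywords, matching)
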