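"""Extractor registry: a uniform contract over rules and the classifier.

An extraction method exposes ``name``, ``trainable``, ``scope``,
``fit(docs)`` (a no-op for rules) and ``predict(docs)`` returning
``(CandidatePair, score)`` tuples.  Rule methods return only the pairs they
predict, each with score 1.0; the trainable SLK method scores every
candidate pair so predictions can be ranked for ROC analysis.
"""

from __future__ import annotations

from . import baselines, slk
from .corpus import AbstractDocument, enumerate_candidate_pairs
from .pos import RuleBasedTagger, tag_tokens

__all__ = [
    "METHOD_NAMES",
    "CooccurrenceMethod",
    "MentionCountMethod",
    "KeywordMethod",
    "KeywordThresholdMethod",
    "SlkMethod",
    "make_method",
]


class _RuleMethod:
    trainable = False
    scope = "sentence"

    def fit(self, docs: list[AbstractDocument]) -> None:
        pass


class CooccurrenceMethod(_RuleMethod):
    def __init__(self, scope: str = "sentence"):
        self.scope = scope
        self.name = f"cooccurrence-{scope}"

    def predict(self, docs):
        return [
            (p, 1.0) for p in baselines.predict_cooccurrence(docs, self.scope)
        ]


class MentionCountMethod(_RuleMethod):
    """Co-occurrence limited to sentences with at most t region mentions."""

    def __init__(self, t: int = 5):
        self.t = t
        self.name = f"threshold-{t}"

    def predict(self, docs):
        pairs = baselines.predict_cooccurrence(docs, "sentence")
        return [
            (p, 1.0)
            for p in baselines.filter_by_mention_count(pairs, docs, self.t)
        ]


class KeywordMethod(_RuleMethod):
    def __init__(self, keywords=baselines.DEFAULT_KEYWORDS, matching="stem"):
        self.keywords = keywords
        self.matching = matching
        self.name = "keyword"

    def predict(self, docs):
        pairs = baselines.predict_cooccurrence(docs, "sentence")
        return [
            (p, 1.0)
            for p in baselines.filter_by_keyword(
                pairs, docs, self.keywords, self.matching
            )
        ]


class KeywordThresholdMethod(_RuleMethod):
    """The combined rule: keyword presence and a 5-mention sentence cap."""

    def __init__(
        self,
        t: int = 5,
        keywords=baselines.DEFAULT_KEYWORDS,
        matching: str = "stem",
    ):
        self.t = t
        self.keywords = keywords
        self.matching = matching
        self.name = "keyword5"

    def predict(self, docs):
        return [
            (p, 1.0)
            for p in baselines.predict_keyword_threshold(
                docs, self.t, self.keywords, self.matching
            )
        ]


class SlkMethod:
    """Shallow-linguistic-kernel SVM behind the extractor contract."""

    trainable = True
    scope = "sentence"

    def __init__(self, config: slk.SlkConfig | None = None, tagger=None):
        self.config = config or slk.SlkConfig()
        self.tagger = tagger or RuleBasedTagger()
        self.model: slk.SlkModel | None = None
        self.name = "slk"

    def _instances(self, docs):
        out = []
        for doc in docs:
            tagged_cache: dict[int, list] = {}
            for pair in enumerate_candidate_pairs(doc, "sentence"):
                idx = pair.sentence_index
                if idx not in tagged_cache:
                    tagged_cache[idx] = tag_tokens(
                        doc.sentences[idx].tokens, self.tagger
                    )
                out.append(
                    (
                        pair,
                        slk.make_instance(
                            doc, pair, tagged_tokens=tagged_cache[idx]
                        ),
                    )
                )
        return out

    def fit(self, docs):
        pairs_instances = self._instances(docs)
        instances = [inst for _, inst in pairs_instances]
        labels = [bool(p.label) for p, _ in pairs_instances]
        self.model = slk.train_slk(instances, labels, self.config)
        return self

    def predict(self, docs):
        if self.model is None:
            raise RuntimeError("SlkMethod.predict called before fit")
        return [
            (pair, slk.score(self.model, inst))
            for pair, inst in self._instances(docs)
        ]


METHOD_NAMES = (
    "cooccurrence-sentence",
    "cooccurrence-abstract",
    "threshold",
    "keyword",
    "keyword5",
    "slk",
)


def make_method(name: str, **kwargs):
    """Instantiate an extraction method by its registry name."""
    if name == "cooccurrence-sentence":
        return CooccurrenceMethod("sentence")
    if name == "cooccurrence-abstract":
        return CooccurrenceMethod("abstract")
    if name == "threshold":
        return MentionCountMethod(kwargs.get("t", 5))
    if name == "keyword":
        return KeywordMethod(
            kwargs.get("keywords", baselines.DEFAULT_KEYWORDS),
            kwargs.get("matching", "stem"),
        )
    if name == "keyword5":
        return KeywordThresholdMethod(
            kwargs.get("t", 5),
            kwargs.get("keywords", baselines.DEFAULT_KEYWORDS),
            kwargs.get("matching", "stem"),
        )
    if name == "slk":
        return SlkMethod(kwargs.get("config"))
    raise ValueError(
        f"unknown method {name!r}; choose from {', '.join(METHOD_NAMES)}"
    )
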