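"""Corpus domain model and JSON-lines I/O.

An :class:`AbstractDocument` holds one title+abstract string together with
standoff annotations: sentence offsets, brain-region mention spans, and gold
connectivity relations between mention pairs.  All offsets are 0-based,
half-open character offsets into the document text; the title is sentence 0.

Candidate pairs — the unit the extractors classify — are unordered pairs of
mentions, enumerated either within each sentence or across the whole
abstract.
"""

from __future__ import annotations

import itertools
import json
import re
from dataclasses import dataclass, field, replace

from .stem import stem as porter_stem

__all__ = [
    "Token",
    "Sentence",
    "BrainRegionMention",
    "ConnectivityRelation",
    "AbstractDocument",
    "CandidatePair",
    "CorpusValidationError",
    "tokenize",
    "split_sentences",
    "load_corpus",
    "save_corpus",
    "enumerate_candidate_pairs",
    "within_sentence_relations",
]


class CorpusValidationError(ValueError):
    """Raised when a document violates the corpus schema invariants."""


_TOKEN_RE = re.compile(r"[A-Za-z0-9]+|[^\sA-Za-z0-9]")


@dataclass(frozen=True)
class Token:
    text: str
    start: int
    end: int
    pos: str | None = None
    stem: str = ""

    def with_pos(self, pos: str) -> "Token":
        return replace(self, pos=pos)


@dataclass
class Sentence:
    index: int
    start: int
    end: int
    tokens: list[Token] = field(default_factory=list)


@dataclass(frozen=True)
class BrainRegionMention:
    mention_id: str
    sentence_index: int
    start: int
    end: int
    text: str


@dataclass(frozen=True)
class ConnectivityRelation:
    """Unordered gold relation between two mentions, stored canonically."""

    mention_id_a: str
    mention_id_b: str

    def key(self) -> frozenset[str]:
        return frozenset((self.mention_id_a, self.mention_id_b))


@dataclass
class AbstractDocument:
    doc_id: str
    text: str
    year: int
    species: list[str] = field(default_factory=list)
    sentences: list[Sentence] = field(default_factory=list)
    mentions: list[BrainRegionMention] = field(default_factory=list)
    relations: list[ConnectivityRelation] = field(default_factory=list)

    def mention_by_id(self, mention_id: str) -> BrainRegionMention:
        for m in self.mentions:
            if m.mention_id == mention_id:
                return m
        raise KeyError(mention_id)

    def validate(self) -> None:
        n = len(self.text)
        prev_end = 0
        for s in self.sentences:
            if not (0 <= s.start <= s.end <= n):
                raise CorpusValidationError(
                    f"{self.doc_id}: sentence {s.index} offsets out of range"
                )
            if s.start < prev_end:
                raise CorpusValidationError(
                    f"{self.doc_id}: sentences overlap at index {s.index}"
                )
            prev_end = s.end
        by_index = {s.index: s for s in self.sentences}
        ids = set()
        for m in self.mentions:
            if m.mention_id in ids:
                raise CorpusValidationError(
                    f"{self.doc_id}: duplicate mention id {m.mention_id!r}"
                )
            ids.add(m.mention_id)
            sent = by_index.get(m.sentence_index)
            if sent is None:
                raise CorpusValidationError(
                    f"{self.doc_id}: mention {m.mention_id!r} references "
                    f"unknown sentence {m.sentence_index}"
                )
            if not (sent.start <= m.start < m.end <= sent.end):
                raise CorpusValidationError(
                    f"{self.doc_id}: mention {m.mention_id!r} span outside "
                    f"its sentence"
                )
            if self.text[m.start:m.end] != m.text:
                raise CorpusValidationError(
                    f"{self.doc_id}: mention {m.mention_id!r} text does not "
                    f"match the document slice"
                )
        for r in self.relations:
            if r.mention_id_a == r.mention_id_b:
                raise CorpusValidationError(
                    f"{self.doc_id}: self-relation on {r.mention_id_a!r}"
                )
            for mid in (r.mention_id_a, r.mention_id_b):
                if mid not in ids:
                    raise CorpusValidationError(
                        f"{self.doc_id}: relation references unknown mention "
                        f"id {mid!r}"
                    )

    def canonicalize_relations(self) -> None:
        """Order each relation's endpoints by (sentence_index, start) and
        collapse duplicates."""
        order = {
            m.mention_id: (m.sentence_index, m.start) for m in self.mentions
        }
        seen: set[frozenset[str]] = set()
        canon: list[ConnectivityRelation] = []
        for r in self.relations:
            a, b = sorted((r.mention_id_a, r.mention_id_b), key=order.get)
            key = frozenset((a, b))
            if key in seen:
                continue
            seen.add(key)
            canon.append(ConnectivityRelation(a, b))
        self.relations = canon


@dataclass
class CandidatePair:
    doc_id: str
    sentence_index: int
    mention_a: BrainRegionMention
    mention_b: BrainRegionMention
    label: bool | None = None

    def key(self) -> tuple[str, frozenset[str]]:
        """Order-insensitive identity used when scoring against gold."""
        return (
            self.doc_id,
            frozenset((self.mention_a.mention_id, self.mention_b.mention_id)),
        )


def tokenize(text: str) -> list[Token]:
    """Split *text* into word and single-character punctuation tokens.

    Offsets are 0-based half-open; runs of alphanumeric characters form one
    token, every other non-space character is its own token, so the tokens
    partition the non-whitespace content.  Each token carries its Porter
    stem; POS tags are left unset.
    """
    return [
        Token(
            text=m.group(),
            start=m.start(),
            end=m.end(),
            stem=porter_stem(m.group()),
        )
        for m in _TOKEN_RE.finditer(text)
    ]


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Heuristic sentence offsets for convenience ingestion of raw text.

    Splits after sentence-final punctuation followed by whitespace.  Corpora
    normally carry explicit sentence offsets; this is not part of the core
    contract.
    """
    spans: list[tuple[int, int]] = []
    start = 0
    for m in re.finditer(r"[.!?](?:\s+|$)", text):
        end = m.start() + 1
        if end > start:
            spans.append((start, end))
        start = m.end()
    if start < len(text):
        spans.append((start, len(text)))
    return spans


# ---------------------------------------------------------------------------
# JSON-lines I/O


def _doc_to_json(doc: AbstractDocument) -> dict:
    return {
        "doc_id": doc.doc_id,
        "year": doc.year,
        "species": list(doc.species),
        "text": doc.text,
        "sentences": [{"start": s.start, "end": s.end} for s in doc.sentences],
        "mentions": [
            {
                "id": m.mention_id,
                "sentence": m.sentence_index,
                "start": m.start,
                "end": m.end,
            }
            for m in doc.mentions
        ],
        "relations": [
            {"a": r.mention_id_a, "b": r.mention_id_b} for r in doc.relations
        ],
    }


def _doc_from_json(obj: dict, tokenizer=tokenize) -> AbstractDocument:
    text = obj["text"]
    sentences = []
    for i, s in enumerate(obj["sentences"]):
        sent = Sentence(index=i, start=int(s["start"]), end=int(s["end"]))
        sent.tokens = [
            Token(
                text=t.text,
                start=t.start + sent.start,
                end=t.end + sent.start,
                stem=t.stem,
            )
            for t in tokenizer(text[sent.start : sent.end])
        ]
        sentences.append(sent)
    mentions = [
        BrainRegionMention(
            mention_id=str(m["id"]),
            sentence_index=int(m["sentence"]),
            start=int(m["start"]),
            end=int(m["end"]),
            text=text[int(m["start"]) : int(m["end"])],
        )
        for m in obj["mentions"]
    ]
    relations = [
        ConnectivityRelation(str(r["a"]), str(r["b"]))
        for r in obj["relations"]
    ]
    doc = AbstractDocument(
        doc_id=str(obj["doc_id"]),
        text=text,
        year=int(obj["year"]),
        species=[str(s) for s in obj.get("species", [])],
        sentences=sentences,
        mentions=mentions,
        relations=relations,
    )
    doc.validate()
    doc.canonicalize_relations()
    return doc


def load_corpus(path) -> list[AbstractDocument]:
    """Read a JSON-lines corpus, validating every document.

    Raises :class:`CorpusValidationError` naming the offending line on
    malformed JSON or schema violations.
    """
    docs: list[AbstractDocument] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusValidationError(
                    f"{path}:{lineno}: malformed JSON ({exc.msg})"
                ) from exc
            try:
                docs.append(_doc_from_json(obj))
            except (CorpusValidationError, KeyError, TypeError) as exc:
                raise CorpusValidationError(
                    f"{path}:{lineno}: {exc}"
                ) from exc
    return docs


def save_corpus(docs: list[AbstractDocument], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            fh.write(json.dumps(_doc_to_json(doc), ensure_ascii=False))
            fh.write("\n")


# ---------------------------------------------------------------------------
# Candidate pairs


def _gold_keys(doc: AbstractDocument) -> set[frozenset[str]]:
    return {r.key() for r in doc.relations}


def _ordered(
    m1: BrainRegionMention, m2: BrainRegionMention
) -> tuple[BrainRegionMention, BrainRegionMention]:
    return tuple(sorted((m1, m2), key=lambda m: (m.sentence_index, m.start)))


def enumerate_candidate_pairs(
    doc: AbstractDocument, scope: str = "sentence"
) -> list[CandidatePair]:
    """All unordered mention pairs, per sentence or per abstract.

    A sentence with k mentions yields k(k-1)/2 pairs.  The gold label is
    true iff the mention pair (either order) is a gold relation of the
    document.
    """
    if scope not in ("sentence", "abstract"):
        raise ValueError(f"unknown scope {scope!r}")
    gold = _gold_keys(doc)
    pairs: list[CandidatePair] = []
    if scope == "sentence":
        by_sentence: dict[int, list[BrainRegionMention]] = {}
        for m in doc.mentions:
            by_sentence.setdefault(m.sentence_index, []).append(m)
        for idx in sorted(by_sentence):
            ms = sorted(by_sentence[idx], key=lambda m: m.start)
            for a, b in itertools.combinations(ms, 2):
                pairs.append(
                    CandidatePair(
                        doc_id=doc.doc_id,
                        sentence_index=idx,
                        mention_a=a,
                        mention_b=b,
                        label=frozenset((a.mention_id, b.mention_id)) in gold,
                    )
                )
    else:
        ms = sorted(doc.mentions, key=lambda m: (m.sentence_index, m.start))
        for a, b in itertools.combinations(ms, 2):
            a, b = _ordered(a, b)
            pairs.append(
                CandidatePair(
                    doc_id=doc.doc_id,
                    sentence_index=a.sentence_index,
                    mention_a=a,
                    mention_b=b,
                    label=frozenset((a.mention_id, b.mention_id)) in gold,
                )
            )
    return pairs


def within_sentence_relations(
    doc: AbstractDocument,
) -> list[ConnectivityRelation]:
    """Gold relations whose two mentions share a sentence.

    Relations spanning sentences are excluded from all sentence-level
    evaluation; on the annotated corpus this drops roughly a quarter of the
    gold relations.
    """
    sent_of = {m.mention_id: m.sentence_index for m in doc.mentions}
    return [
        r
        for r in doc.relations
        if sent_of[r.mention_id_a] == sent_of[r.mention_id_b]
    ]
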