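"""Shallow linguistic kernel (SLK) relation classifier.

The classifier decides, for a candidate pair of brain-region mentions in one
sentence, whether the sentence states a connection between them.  It uses
only shallow information — token n-grams at the sentence (global) level and
word/stem/POS/orthographic features in small windows adjacent to each entity
(local level) — with no syntactic or dependency parsing.

Feature vectors have five blocks, each L2-normalized:

* ``GC_FB`` — n-grams over the tokens before the first entity plus the
  tokens between the entities (fore-between),
* ``GC_B`` — n-grams strictly between the entities,
* ``GC_BA`` — n-grams between the entities plus the tokens after the second
  entity (between-after),
* ``LC_A`` / ``LC_B`` — positional features in a window of ``w`` tokens on
  each side of each entity.

The kernel is the sum of the per-block dot products — the scalar product of
the concatenated normalized blocks — and a soft-margin linear SVM is trained
on the explicit vectors.  Candidate mentions are blinded to ``REGION_A`` /
``REGION_B`` placeholders (other region mentions to ``REGION_O``) so the
learned weights generalize across entity names and instances are
pair-specific in multi-mention sentences.

Defaults: maximum n-gram length 3 and local window 2.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.svm import SVC

from .corpus import AbstractDocument, CandidatePair, Token
from .pos import RuleBasedTagger, Tagger, tag_tokens

__all__ = [
    "SlkConfig",
    "RelationInstance",
    "BlindedInstance",
    "SlkVector",
    "SlkModel",
    "make_instance",
    "blind_entities",
    "global_context_features",
    "local_context_features",
    "build_vector",
    "slk_kernel",
    "train_slk",
    "score",
    "classify",
    "rank_predictions",
    "save_model",
    "load_model",
]

GLOBAL_BLOCKS = ("GC_FB", "GC_B", "GC_BA")
LOCAL_BLOCKS = ("LC_A", "LC_B")
BLOCKS = GLOBAL_BLOCKS + LOCAL_BLOCKS

_PLACEHOLDERS = ("REGION_A", "REGION_B", "REGION_O")


@dataclass(frozen=True)
class SlkConfig:
    ngram_max: int = 3
    window: int = 2
    C: float = 1.0
    class_weighting: str = "balanced"
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.ngram_max < 1:
            raise ValueError("ngram_max must be >= 1")
        if self.window < 0:
            raise ValueError("window must be >= 0")
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.class_weighting not in ("balanced", "none"):
            raise ValueError(
                f"unknown class_weighting {self.class_weighting!r}"
            )


@dataclass(frozen=True)
class RelationInstance:
    """One candidate pair prepared for feature extraction.

    ``span_a``/``span_b`` are half-open token-index ranges of the candidate
    mentions (``span_a`` first in the sentence); ``other_mention_spans``
    are the non-candidate region mentions.
    """

    tokens: tuple[Token, ...]
    span_a: tuple[int, int]
    span_b: tuple[int, int]
    other_mention_spans: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if not self.span_a[1] <= self.span_b[0]:
            if max(self.span_a[0], self.span_b[0]) < min(
                self.span_a[1], self.span_b[1]
            ):
                raise ValueError("candidate mention spans overlap")
            raise ValueError("span_a must precede span_b")


@dataclass(frozen=True)
class BlindedInstance:
    tokens: tuple[Token, ...]
    idx_a: int
    idx_b: int


@dataclass
class SlkVector:
    blocks: dict[str, dict[str, float]]

    def norm_ok(self, tol: float = 1e-9) -> bool:
        for block in self.blocks.values():
            if not block:
                continue
            n = math.sqrt(sum(v * v for v in block.values()))
            if abs(n - 1.0) > tol:
                return False
        return True


@dataclass
class SlkModel:
    weights: dict[str, float]
    bias: float
    config: SlkConfig
    n_pos: int = 0
    n_neg: int = 0


def _token_span(tokens, start: int, end: int) -> tuple[int, int]:
    idx = [i for i, t in enumerate(tokens) if t.start < end and t.end > start]
    if not idx:
        raise ValueError("mention span covers no tokens")
    return (idx[0], idx[-1] + 1)


def make_instance(
    doc: AbstractDocument,
    pair: CandidatePair,
    tagger: Tagger | None = None,
    tagged_tokens=None,
) -> RelationInstance:
    """Build a :class:`RelationInstance` for *pair* from its sentence.

    ``tagged_tokens`` lets callers reuse one tagging of the sentence across
    the pairs it contains.
    """
    sent = doc.sentences[pair.sentence_index]
    tokens = (
        tagged_tokens
        if tagged_tokens is not None
        else tag_tokens(sent.tokens, tagger or RuleBasedTagger())
    )
    span_a = _token_span(tokens, pair.mention_a.start, pair.mention_a.end)
    span_b = _token_span(tokens, pair.mention_b.start, pair.mention_b.end)
    candidate_ids = {pair.mention_a.mention_id, pair.mention_b.mention_id}
    others = tuple(
        _token_span(tokens, m.start, m.end)
        for m in doc.mentions
        if m.sentence_index == pair.sentence_index
        and m.mention_id not in candidate_ids
    )
    return RelationInstance(
        tokens=tuple(tokens),
        span_a=span_a,
        span_b=span_b,
        other_mention_spans=others,
    )


def blind_entities(instance: RelationInstance) -> BlindedInstance:
    """Replace each mention span by a single placeholder token.

    Candidate mentions become ``REGION_A`` / ``REGION_B``; other region
    mentions become ``REGION_O``.  Tokens outside mention spans pass through
    unchanged.  Overlaps between a candidate span and any other span are
    rejected.
    """
    repl: dict[int, str | None] = {}

    def mark(span: tuple[int, int], label: str) -> None:
        for i in range(span[0], span[1]):
            if i in repl:
                raise ValueError("overlapping mention spans")
            repl[i] = label if i == span[0] else None

    mark(instance.span_a, "REGION_A")
    mark(instance.span_b, "REGION_B")
    for span in instance.other_mention_spans:
        for i in range(span[0], span[1]):
            if i in repl and repl[i] is not None and repl[i] != "REGION_O":
                raise ValueError("other mention overlaps a candidate span")
        for i in range(span[0], span[1]):
            if i not in repl:
                repl[i] = "REGION_O" if i == span[0] else None

    out: list[Token] = []
    idx = {}
    for i, tok in enumerate(instance.tokens):
        if i in repl:
            label = repl[i]
            if label is None:
                continue
            placeholder = Token(
                text=label,
                start=tok.start,
                end=tok.end,
                pos="NN",
                stem=label.lower(),
            )
            if label in ("REGION_A", "REGION_B"):
                idx[label] = len(out)
            out.append(placeholder)
        else:
            out.append(tok)
    return BlindedInstance(
        tokens=tuple(out), idx_a=idx["REGION_A"], idx_b=idx["REGION_B"]
    )


def _ngram_counts(words: list[str], n: int) -> dict[str, float]:
    counts: dict[str, float] = {}
    for k in range(1, n + 1):
        for i in range(len(words) - k + 1):
            key = " ".join(words[i : i + k])
            counts[key] = counts.get(key, 0.0) + 1.0
    return counts


def global_context_features(
    blinded: BlindedInstance, n: int
) -> dict[str, dict[str, float]]:
    """The three global pattern blocks: fore-between, between, between-after.

    Counts all contiguous k-grams (1 <= k <= n) of lowercased token text;
    the placeholders themselves are excluded from every window.
    """
    words = [t.text.lower() for t in blinded.tokens]
    fore = words[: blinded.idx_a]
    between = words[blinded.idx_a + 1 : blinded.idx_b]
    after = words[blinded.idx_b + 1 :]
    return {
        "GC_FB": _ngram_counts(fore + between, n),
        "GC_B": _ngram_counts(between, n),
        "GC_BA": _ngram_counts(between + after, n),
    }


def _orth_features(tok: Token) -> list[str]:
    text = tok.text
    return [
        f"word={text.lower()}",
        f"stem={tok.stem}",
        f"pos={tok.pos}",
        f"cap={text[0].isupper()}",
        f"allcaps={text.isupper() and text.isalpha()}",
        f"digit={any(c.isdigit() for c in text)}",
        f"punct={not any(c.isalnum() for c in text)}",
    ]


def local_context_features(
    tokens: tuple[Token, ...],
    span: tuple[int, int],
    w: int,
    side_label: str,
) -> dict[str, float]:
    """Positional window features around one mention span.

    For each offset in [-w, -1] and [+1, +w], emits the neighbouring
    token's surface form, stem, POS tag and orthographic flags, keyed by
    side and offset; offsets falling outside the sentence emit a boundary
    feature.  ``w = 0`` yields an empty map.
    """
    feats: dict[str, float] = {}
    for offset in range(-w, 0):
        pos = span[0] + offset
        _emit(feats, tokens, pos, side_label, offset)
    for offset in range(1, w + 1):
        pos = span[1] - 1 + offset
        _emit(feats, tokens, pos, side_label, offset)
    return feats


def _emit(feats, tokens, pos, side_label, offset) -> None:
    prefix = f"{side_label}[{offset:+d}]"
    if pos < 0 or pos >= len(tokens):
        key = f"{prefix}|<boundary>"
        feats[key] = feats.get(key, 0.0) + 1.0
        return
    for f in _orth_features(tokens[pos]):
        key = f"{prefix}|{f}"
        feats[key] = feats.get(key, 0.0) + 1.0


def _l2_normalize(block: dict[str, float]) -> dict[str, float]:
    norm = math.sqrt(sum(v * v for v in block.values()))
    if norm == 0.0:
        return {}
    return {k: v / norm for k, v in block.items()}


def build_vector(instance: RelationInstance, config: SlkConfig) -> SlkVector:
    """Extract the five feature blocks and L2-normalize each."""
    for t in instance.tokens:
        if t.pos is None:
            raise ValueError(
                "instance tokens lack POS tags; run a tagger "
                "(connextract.pos.tag_tokens) before feature extraction"
            )
    blinded = blind_entities(instance)
    blocks = global_context_features(blinded, config.ngram_max)
    blocks["LC_A"] = local_context_features(
        blinded.tokens, (blinded.idx_a, blinded.idx_a + 1), config.window, "A"
    )
    blocks["LC_B"] = local_context_features(
        blinded.tokens, (blinded.idx_b, blinded.idx_b + 1), config.window, "B"
    )
    return SlkVector(blocks={k: _l2_normalize(blocks[k]) for k in BLOCKS})


def slk_kernel(x: SlkVector, y: SlkVector) -> float:
    """Sum of per-block dot products of two normalized vectors."""
    total = 0.0
    for name in BLOCKS:
        xb, yb = x.blocks[name], y.blocks[name]
        if len(yb) < len(xb):
            xb, yb = yb, xb
        total += sum(v * yb[k] for k, v in xb.items() if k in yb)
    return total


def _feature_key(block: str, key: str) -> str:
    return f"{block}::{key}"


def _to_matrix(vectors, feature_index):
    rows, cols, vals = [], [], []
    for i, vec in enumerate(vectors):
        for block, feats in vec.blocks.items():
            for key, val in feats.items():
                j = feature_index.get(_feature_key(block, key))
                if j is not None:
                    rows.append(i)
                    cols.append(j)
                    vals.append(val)
    return sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(vectors), len(feature_index))
    )


def train_slk(
    instances: list[RelationInstance],
    labels: list[bool],
    config: SlkConfig | None = None,
) -> SlkModel:
    """Fit a soft-margin linear SVM on the concatenated normalized blocks.

    With ``class_weighting="balanced"`` the misclassification cost of each
    class is scaled by its inverse frequency (positives are a small minority
    of candidate pairs).  Training requires both classes to be present.
    """
    config = config or SlkConfig()
    y = np.asarray([bool(l) for l in labels], dtype=bool)
    if len(instances) != len(y):
        raise ValueError("instances and labels differ in length")
    if y.all() or not y.any():
        raise ValueError("training requires >=1 positive and >=1 negative")
    vectors = [build_vector(inst, config) for inst in instances]
    feature_index: dict[str, int] = {}
    for vec in vectors:
        for block, feats in vec.blocks.items():
            for key in feats:
                feature_index.setdefault(
                    _feature_key(block, key), len(feature_index)
                )
    X = _to_matrix(vectors, feature_index)
    svm = SVC(
        kernel="linear",
        C=config.C,
        class_weight=(
            "balanced" if config.class_weighting == "balanced" else None
        ),
        random_state=config.random_seed,
    )
    svm.fit(X, y.astype(int))
    coef = np.asarray(svm.coef_.todense()).ravel()
    weights = {
        key: float(coef[j]) for key, j in feature_index.items() if coef[j]
    }
    return SlkModel(
        weights=weights,
        bias=float(svm.intercept_[0]),
        config=config,
        n_pos=int(y.sum()),
        n_neg=int((~y).sum()),
    )


def score(model: SlkModel, instance: RelationInstance) -> float:
    """Signed distance surrogate: weight.vector + bias."""
    vec = build_vector(instance, model.config)
    total = model.bias
    for block, feats in vec.blocks.items():
        for key, val in feats.items():
            w = model.weights.get(_feature_key(block, key))
            if w is not None:
                total += w * val
    return total


def classify(model: SlkModel, instance: RelationInstance) -> bool:
    return score(model, instance) > 0.0


def rank_predictions(scored_pairs):
    """Stable total order for ROC: score desc, then document/sentence/ids."""
    return sorted(
        scored_pairs,
        key=lambda ps: (
            -ps[1],
            ps[0].doc_id,
            ps[0].sentence_index,
            ps[0].mention_a.mention_id,
            ps[0].mention_b.mention_id,
        ),
    )


MODEL_FORMAT_VERSION = 1


def save_model(model: SlkModel, path) -> None:
    obj = {
        "format_version": MODEL_FORMAT_VERSION,
        "config": {
            "ngram_max": model.config.ngram_max,
            "window": model.config.window,
            "C": model.config.C,
            "class_weighting": model.config.class_weighting,
            "random_seed": model.config.random_seed,
        },
        "bias": model.bias,
        "n_pos": model.n_pos,
        "n_neg": model.n_neg,
        "weights": model.weights,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh)


def load_model(path) -> SlkModel:
    with open(path, encoding="utf-8") as fh:
        obj = json.load(fh)
    if obj.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"unsupported model format version {obj.get('format_version')!r}"
        )
    cfg = obj["config"]
    return SlkModel(
        weights={k: float(v) for k, v in obj["weights"].items()},
        bias=float(obj["bias"]),
        config=SlkConfig(
            ngram_max=int(cfg["ngram_max"]),
            window=int(cfg["window"]),
            C=float(cfg["C"]),
            class_weighting=str(cfg["class_weighting"]),
            random_seed=int(cfg["random_seed"]),
        ),
        n_pos=int(obj["n_pos"]),
        n_neg=int(obj["n_neg"]),
    )
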