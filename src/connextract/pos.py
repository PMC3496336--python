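"""Deterministic rule-based part-of-speech tagging.

The local-context features of the shallow linguistic kernel consume
Penn-Treebank-style tags.  The tagger contract is any callable mapping a
token-text sequence to a same-length tag sequence; the default
:class:`RuleBasedTagger` is a small closed-class lexicon plus suffix
heuristics, chosen so the suite needs no model downloads and tagging is
reproducible byte-for-byte.
"""

from __future__ import annotations

import re
from collections.abc import Callable, Sequence

__all__ = ["Tagger", "RuleBasedTagger", "tag_tokens"]

Tagger = Callable[[Sequence[str]], list[str]]

_CLOSED_CLASS = {
    "the": "DT", "a": "DT", "an": "DT", "this": "DT", "these": "DT",
    "that": "IN", "of": "IN", "in": "IN", "on": "IN", "from": "IN",
    "with": "IN", "within": "IN", "between": "IN", "by": "IN", "at": "IN",
    "into": "IN", "via": "IN", "through": "IN", "as": "IN", "for": "IN",
    "to": "TO",
    "and": "CC", "or": "CC", "but": "CC",
    "is": "VBZ", "are": "VBP", "was": "VBD", "were": "VBD", "be": "VB",
    "been": "VBN", "has": "VBZ", "have": "VBP", "had": "VBD",
    "not": "RB", "no": "DT",
    "we": "PRP", "it": "PRP", "its": "PRP$", "their": "PRP$", "our": "PRP$",
    "which": "WDT", "both": "DT", "each": "DT", "all": "DT", "other": "JJ",
}

# Common verbs of connectivity prose, kept closed so blinded instances tag
# identically regardless of surrounding entity names.
_VERBS = {
    "projects": "VBZ", "project": "VBP", "receives": "VBZ", "receive": "VBP",
    "sends": "VBZ", "send": "VBP", "innervates": "VBZ", "innervate": "VBP",
    "originate": "VBP", "originates": "VBZ", "terminate": "VBP",
    "terminates": "VBZ", "arise": "VBP", "arises": "VBZ",
    "examined": "VBN", "studied": "VBN", "observed": "VBN",
    "labeled": "VBN", "injected": "VBN", "analyzed": "VBN",
}

_PUNCT_RE = re.compile(r"^[^\w\s]$")
_NUM_RE = re.compile(r"^\d+$")


class RuleBasedTagger:
    """Suffix/lexicon heuristic tagger emitting Penn-Treebank-style tags."""

    def __call__(self, tokens: Sequence[str]) -> list[str]:
        return [self.tag_one(t) for t in tokens]

    @staticmethod
    def tag_one(text: str) -> str:
        if _PUNCT_RE.match(text):
            return text if text in ".,:" else "SYM"
        if _NUM_RE.match(text):
            return "CD"
        lower = text.lower()
        if lower in _CLOSED_CLASS:
            return _CLOSED_CLASS[lower]
        if lower in _VERBS:
            return _VERBS[lower]
        if text.startswith("REGION_"):
            return "NN"
        if lower.endswith("ly"):
            return "RB"
        if lower.endswith("ing"):
            return "VBG"
        if lower.endswith("ed"):
            return "VBD"
        if text[0].isupper():
            return "NNP"
        if lower.endswith("al") or lower.endswith("ic"):
            return "JJ"
        if lower.endswith("s"):
            return "NNS"
        return "NN"


def tag_tokens(tokens, tagger: Tagger | None = None):
    """Return *tokens* with POS tags filled in (tokens are immutable)."""
    tagger = tagger or RuleBasedTagger()
    tags = tagger([t.text for t in tokens])
    if len(tags) != len(tokens):
        raise ValueError("tagger returned wrong number of tags")
    return [t.with_pos(tag) for t, tag in zip(tokens, tags)]
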