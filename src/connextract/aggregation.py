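"""Mention normalization and connectome-level aggregation.

Predicted mention pairs are mapped to lexicon region concepts with a
bag-of-stems resolver (lowercase, drop stopwords, Porter-stem, compare as a
set), accumulated into an undirected region-pair connectivity matrix with
occurrence counts, and compared against a reference connectome whose edges
have been up-propagated through the region hierarchy (a connection between
A and B implies connections between all enclosing regions of A and B).
Self-connections are dropped throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .corpus import AbstractDocument, CandidatePair, tokenize
from .stem import stem as porter_stem

__all__ = [
    "LexiconRegion",
    "Lexicon",
    "ConnectivityMatrix",
    "MatrixBuildResult",
    "stem_bag",
    "normalize_mention",
    "up_propagate",
    "build_predicted_matrix",
    "compare_matrices",
    "anatomical_depth",
    "degree_correlation",
    "era_split_test",
    "species_filter",
    "load_lexicon",
    "save_lexicon",
    "load_reference_edges",
    "save_reference_edges",
    "save_matrix",
]

STOPWORDS = frozenset({"the", "of", "and"})


@dataclass(frozen=True)
class LexiconRegion:
    region_id: str
    preferred_name: str
    synonyms: tuple[str, ...] = ()
    parent_id: str | None = None


class Lexicon:
    """Region concepts with a rooted parent hierarchy and a stem-bag index."""

    def __init__(self, regions: list[LexiconRegion]):
        self.regions: dict[str, LexiconRegion] = {}
        for r in regions:
            if r.region_id in self.regions:
                raise ValueError(f"duplicate region id {r.region_id!r}")
            if not r.preferred_name:
                raise ValueError(f"region {r.region_id!r} has an empty name")
            self.regions[r.region_id] = r
        roots = [r for r in regions if r.parent_id is None]
        if len(roots) != 1:
            raise ValueError(
                f"lexicon must have exactly one root, found {len(roots)}"
            )
        self.root_id = roots[0].region_id
        self._ancestors: dict[str, tuple[str, ...]] = {}
        for r in regions:
            self._ancestors[r.region_id] = self._walk(r.region_id)
        self._index: dict[frozenset, list[str]] = {}
        for r in regions:
            for name in (r.preferred_name, *r.synonyms):
                bag = stem_bag(name)
                ids = self._index.setdefault(bag, [])
                if r.region_id not in ids:
                    ids.append(r.region_id)

    def _walk(self, region_id: str) -> tuple[str, ...]:
        path = []
        seen = set()
        cur: str | None = region_id
        while cur is not None:
            if cur in seen:
                raise ValueError(f"cycle in parent links at {cur!r}")
            seen.add(cur)
            region = self.regions.get(cur)
            if region is None:
                raise ValueError(f"unknown parent id {cur!r}")
            path.append(cur)
            cur = region.parent_id
        return tuple(path)

    def ancestors_or_self(self, region_id: str) -> tuple[str, ...]:
        """Path from the region up to the root, inclusive."""
        if region_id not in self._ancestors:
            raise KeyError(region_id)
        return self._ancestors[region_id]

    def depth(self, region_id: str) -> int:
        """Nodes on the root-to-region path; the root has depth 1."""
        return len(self.ancestors_or_self(region_id))

    def lookup_bag(self, bag: frozenset) -> list[str]:
        return sorted(self._index.get(bag, []))

    def __len__(self) -> int:
        return len(self.regions)


class ConnectivityMatrix:
    """Undirected region-pair multiset with occurrence counts.

    Pairs are stored canonically (lexicographic region-id order); self-pairs
    are silently dropped.
    """

    def __init__(self):
        self.counts: dict[tuple[str, str], int] = {}

    @classmethod
    def from_pairs(cls, pairs, count: int = 1) -> "ConnectivityMatrix":
        m = cls()
        for a, b in pairs:
            m.add(a, b, count)
        return m

    def add(self, a: str, b: str, count: int = 1) -> None:
        if a == b:
            return
        key = (a, b) if a < b else (b, a)
        self.counts[key] = self.counts.get(key, 0) + count

    def set_max(self, a: str, b: str, count: int) -> None:
        if a == b:
            return
        key = (a, b) if a < b else (b, a)
        self.counts[key] = max(self.counts.get(key, 0), count)

    def pairs(self) -> set[tuple[str, str]]:
        return set(self.counts)

    def regions(self) -> set[str]:
        return {r for pair in self.counts for r in pair}

    def degree(self) -> dict[str, int]:
        deg: dict[str, int] = {}
        for a, b in self.counts:
            deg[a] = deg.get(a, 0) + 1
            deg[b] = deg.get(b, 0) + 1
        return deg

    def threshold(self, min_count: int) -> "ConnectivityMatrix":
        out = ConnectivityMatrix()
        out.counts = {
            k: c for k, c in self.counts.items() if c >= min_count
        }
        return out

    def __contains__(self, pair) -> bool:
        a, b = pair
        key = (a, b) if a < b else (b, a)
        return key in self.counts

    def __len__(self) -> int:
        return len(self.counts)


def stem_bag(text: str) -> frozenset:
    """Bag of Porter stems: lowercase, tokenize, drop stopwords, stem.

    Returns a set, so word order and repetition are ignored; punctuation
    tokens are dropped.
    """
    bag = set()
    for tok in tokenize(text.lower()):
        if not tok.text.isalnum() or tok.text in STOPWORDS:
            continue
        bag.add(porter_stem(tok.text))
    return frozenset(bag)


def normalize_mention(mention_text: str, lexicon: Lexicon) -> list[str]:
    """Region ids whose name or synonym stem-bag equals the mention's.

    Multiple ids mean the mention is ambiguous; an empty list means it is
    unresolvable against this lexicon.
    """
    return lexicon.lookup_bag(stem_bag(mention_text))


def up_propagate(
    matrix: ConnectivityMatrix, lexicon: Lexicon
) -> ConnectivityMatrix:
    """Close the matrix under the region hierarchy.

    Every pair (A, B) implies (A', B') for all ancestors-or-self A' of A and
    B' of B, minus self-pairs.  Each derived pair keeps the maximum count of
    the pairs implying it, which makes the operation idempotent.
    """
    out = ConnectivityMatrix()
    for (a, b), count in matrix.counts.items():
        for a2 in lexicon.ancestors_or_self(a):
            for b2 in lexicon.ancestors_or_self(b):
                out.set_max(a2, b2, count)
    return out


@dataclass
class MatrixBuildResult:
    matrix: ConnectivityMatrix
    occurrences: list[dict] = field(default_factory=list)
    n_pair_occurrences: int = 0
    n_resolved_occurrences: int = 0
    n_unresolved_mentions: int = 0


def build_predicted_matrix(
    predicted_pairs: list[CandidatePair],
    corpus: list[AbstractDocument],
    lexicon: Lexicon,
    min_count: int = 1,
) -> MatrixBuildResult:
    """Aggregate predicted mention pairs into a region-pair matrix.

    Each predicted pair contributes the cross product of its two mentions'
    normalized region lists (ambiguous mentions thus contribute several
    region pairs); self-pairs are dropped, counts accumulate across the
    corpus, and pairs below *min_count* are removed.  The per-resolution
    occurrence records retain document id, year and an occurrence id of the
    originating mention pair so both ambiguity-accounting modes can be
    derived downstream.
    """
    years = {d.doc_id: d.year for d in corpus}
    result = MatrixBuildResult(matrix=ConnectivityMatrix())
    for occ_id, pair in enumerate(predicted_pairs):
        result.n_pair_occurrences += 1
        ids_a = normalize_mention(pair.mention_a.text, lexicon)
        ids_b = normalize_mention(pair.mention_b.text, lexicon)
        for mention, ids in (
            (pair.mention_a, ids_a),
            (pair.mention_b, ids_b),
        ):
            if not ids:
                result.n_unresolved_mentions += 1
        if not ids_a or not ids_b:
            continue
        resolved_any = False
        for ra in ids_a:
            for rb in ids_b:
                if ra == rb:
                    continue
                result.matrix.add(ra, rb)
                result.occurrences.append(
                    {
                        "occurrence_id": occ_id,
                        "doc_id": pair.doc_id,
                        "year": years.get(pair.doc_id),
                        "region_a": min(ra, rb),
                        "region_b": max(ra, rb),
                    }
                )
                resolved_any = True
        if resolved_any:
            result.n_resolved_occurrences += 1
    if min_count > 1:
        result.matrix = result.matrix.threshold(min_count)
    return result


def compare_matrices(
    predicted: ConnectivityMatrix, reference: ConnectivityMatrix
) -> dict:
    """Set-level precision/recall of predicted pairs against the reference.

    ``precision``/``recall`` count unique region pairs; the
    occurrence-weighted precision counts every occurrence of a predicted
    pair (so frequently re-extracted true pairs weigh more).  An empty
    prediction set reports precision 0 with ``empty_predictions=True``.
    """
    pred_pairs = predicted.pairs()
    ref_pairs = reference.pairs()
    inter = pred_pairs & ref_pairs
    n_occ = sum(predicted.counts.values())
    n_occ_true = sum(
        c for pair, c in predicted.counts.items() if pair in ref_pairs
    )
    return {
        "n_predicted": len(pred_pairs),
        "n_reference": len(ref_pairs),
        "n_intersection": len(inter),
        "precision": len(inter) / len(pred_pairs) if pred_pairs else 0.0,
        "recall": len(inter) / len(ref_pairs) if ref_pairs else 0.0,
        "occurrence_precision": n_occ_true / n_occ if n_occ else 0.0,
        "empty_predictions": not pred_pairs,
    }


def anatomical_depth(matrix: ConnectivityMatrix, lexicon: Lexicon) -> float:
    """Mean hierarchy depth over the endpoints of the connected pairs.

    Depth counts the nodes on the root-to-region path (root = 1); higher
    values mean the matrix connects more specific regions.
    """
    depths = [
        lexicon.depth(r) for pair in matrix.counts for r in pair
    ]
    if not depths:
        return 0.0
    return sum(depths) / len(depths)


def degree_correlation(
    matrix_1: ConnectivityMatrix, matrix_2: ConnectivityMatrix
) -> tuple[float, float]:
    """Pearson and Spearman correlation of region degrees.

    Degree is the number of distinct partners of a region; correlations are
    computed over regions present in both matrices (at least 3 required).
    """
    deg1, deg2 = matrix_1.degree(), matrix_2.degree()
    common = sorted(set(deg1) & set(deg2))
    if len(common) < 3:
        raise ValueError(
            f"need >=3 common regions, found {len(common)}"
        )
    x = [deg1[r] for r in common]
    y = [deg2[r] for r in common]
    pearson = float(stats.pearsonr(x, y).statistic)
    spearman = float(stats.spearmanr(x, y).statistic)
    return pearson, spearman


def era_split_test(
    occurrences: list[dict],
    reference: ConnectivityMatrix,
    split_year: int = 1987,
) -> dict:
    """Validation-rate comparison between publication eras.

    Each occurrence (a resolved predicted region pair with its document
    year) is validated if its pair is in the reference.  Documents with
    year >= *split_year* form the later era.  The p-value is the upper-tail
    hypergeometric probability of drawing at least the observed number of
    validated occurrences in the later era from the pooled population.
    """
    ref_pairs = reference.pairs()
    later, earlier = [], []
    for occ in occurrences:
        validated = (occ["region_a"], occ["region_b"]) in ref_pairs
        (later if occ["year"] >= split_year else earlier).append(validated)
    if not later or not earlier:
        raise ValueError("both eras must contain at least one occurrence")
    N = len(later) + len(earlier)
    K = sum(later) + sum(earlier)
    n = len(later)
    k = sum(later)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return {
        "rate_earlier": sum(earlier) / len(earlier),
        "rate_later": sum(later) / len(later),
        "n_earlier": len(earlier),
        "n_later": len(later),
        "n_validated": K,
        "p_value": p,
    }


def species_filter(
    corpus: list[AbstractDocument], species_terms
) -> list[AbstractDocument]:
    """Documents whose species metadata or text mentions any of the terms.

    Matching is case-insensitive at the token level (so "rat" does not
    match "stratum").
    """
    terms = {t.lower() for t in species_terms}
    kept = []
    for doc in corpus:
        if any(s.lower() in terms for s in doc.species):
            kept.append(doc)
            continue
        tokens = {t.text.lower() for t in tokenize(doc.text)}
        if tokens & terms:
            kept.append(doc)
    return kept


# ---------------------------------------------------------------------------
# TSV I/O


def load_lexicon(path) -> Lexicon:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    regions = [
        LexiconRegion(
            region_id=row["region_id"],
            preferred_name=row["preferred_name"],
            parent_id=row["parent_id"] or None,
            synonyms=tuple(
                s for s in row.get("synonyms", "").split("|") if s
            ),
        )
        for _, row in df.iterrows()
    ]
    return Lexicon(regions)


def save_lexicon(lexicon: Lexicon, path) -> None:
    rows = [
        {
            "region_id": r.region_id,
            "preferred_name": r.preferred_name,
            "parent_id": r.parent_id or "",
            "synonyms": "|".join(r.synonyms),
        }
        for r in sorted(lexicon.regions.values(), key=lambda r: r.region_id)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_reference_edges(path) -> ConnectivityMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    matrix = ConnectivityMatrix()
    for _, row in df.iterrows():
        matrix.add(row["region_id_a"], row["region_id_b"])
    return matrix


def save_reference_edges(matrix: ConnectivityMatrix, path) -> None:
    rows = [
        {"region_id_a": a, "region_id_b": b}
        for a, b in sorted(matrix.counts)
    ]
    pd.DataFrame(rows, columns=["region_id_a", "region_id_b"]).to_csv(
        path, sep="\t", index=False
    )


def save_matrix(
    matrix: ConnectivityMatrix, reference: ConnectivityMatrix, path
) -> None:
    ref_pairs = reference.pairs()
    rows = [
        {
            "region_id_a": a,
            "region_id_b": b,
            "count": c,
            "in_reference": int((a, b) in ref_pairs),
        }
        for (a, b), c in sorted(matrix.counts.items())
    ]
    pd.DataFrame(
        rows,
        columns=["region_id_a", "region_id_b", "count", "in_reference"],
    ).to_csv(path, sep="\t", index=False)
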