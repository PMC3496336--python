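"""Seeded generator of corpora, lexicons and reference connectomes.

The generator emulates the statistical structure of an annotated abstract
corpus at desk scale: titles and body sentences instantiate either
connectivity templates ("{A} projections to {B} in the rat.") between
region pairs drawn preferentially from the reference connectome, plain
co-mention templates ("{A} and {B} were examined."), or list sentences that
merely enumerate many regions without stating relations.  A fraction of
gold relations spans two sentences, mirroring real abstracts where roughly
a quarter of annotated relations are cross-sentence.

Every generated pair is recorded in a truth ledger (label, keyword
presence, span status, era, species, region identities), so tests can check
pipeline outputs against generator bookkeeping rather than re-deriving
them.  With ``noise = 0`` keyword presence perfectly marks connectivity
sentences, making keyword recall 1.0 and the corpus linearly separable for
the classifier; the validation rate of positive pairs against the reference
is era-dependent to exercise the era-split analysis.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass

import pandas as pd

from .aggregation import ConnectivityMatrix, Lexicon, LexiconRegion
from .baselines import DEFAULT_KEYWORDS
from .corpus import AbstractDocument, enumerate_candidate_pairs
from .corpus import _doc_from_json  # shared construction/validation path
from .stem import stem as porter_stem

__all__ = ["GeneratorConfig", "make_toy_lexicon", "generate_corpus"]


@dataclass(frozen=True)
class GeneratorConfig:
    n_documents: int = 200
    sentences_per_doc: tuple[int, int] = (4, 8)
    positive_pair_fraction: float = 0.35
    three_mention_probability: float = 0.15
    list_sentence_probability: float = 0.10
    cross_sentence_relation_fraction: float = 0.20
    keyword_insertion_probability: float = 1.0
    noise: float = 0.0
    lexicon_size: int = 40
    lexicon_depth: int = 4
    rat_fraction: float = 0.7
    year_range: tuple[int, int] = (1975, 2008)
    split_year: int = 1987
    reference_rate_pre: float = 0.6
    reference_rate_post: float = 0.9
    seed: int = 42

    def __post_init__(self) -> None:
        for name in (
            "positive_pair_fraction",
            "three_mention_probability",
            "list_sentence_probability",
            "cross_sentence_relation_fraction",
            "keyword_insertion_probability",
            "noise",
            "rat_fraction",
            "reference_rate_pre",
            "reference_rate_post",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.lexicon_size < 3:
            raise ValueError("lexicon_size must be >= 3")


_DESCRIPTORS = [
    "medial", "lateral", "dorsal", "ventral", "anterior", "posterior",
    "rostral", "caudal", "superior", "inferior", "central", "paraventricular",
    "reticular", "gigantocellular", "parabrachial", "entorhinal",
    "perirhinal", "retrosplenial", "infralimbic", "prelimbic", "cingulate",
    "piriform", "septal", "habenular", "mammillary", "supraoptic", "arcuate",
    "pontine", "olivary", "vestibular", "cochlear", "trigeminal",
    "hypoglossal", "solitary", "tegmental", "interpeduncular", "geniculate",
    "pulvinar", "accumbens", "subthalamic", "endopiriform", "parafascicular",
    "suprachiasmatic", "premammillary", "peripeduncular", "claustral",
    "gustatory", "barrington", "cuneiform", "intercollicular",
]

_NOUNS = ["nucleus", "cortex", "area", "region", "field", "complex"]

_POS_2 = [
    "{A} projections to {B} in the rat.",
    "The {A} sends efferent projections to {B}.",
    "{A} receives afferent inputs from {B}.",
    "A direct pathway from {A} to {B} was traced.",
    "Injections revealed that {A} projects to {B}.",
]
_POS_2_PLAIN = [
    "{A} is directly connected with {B}.",
    "Fibres from {A} terminate in {B}.",
]
_POS_3 = [
    "{A} projections to {B} and to {C} were observed.",
    "The {A} sends efferent fibres to {B} and to {C}.",
]
_NEG_2 = [
    "{A} and {B} were examined in detail.",
    "Neurons in {A} and {B} were labeled.",
    "We studied the cytoarchitecture of {A} and {B}.",
    "Cells in {A} and in {B} expressed the marker.",
]
_NEG_2_KEYWORD = [
    "The projection study examined {A} and {B}.",
]
_LIST = [
    "Labeled cells were found in {A}, {B}, {C}, {D}, {E} and {F}.",
    "Staining was present in {A}, {B}, {C}, {D}, {E} and {F}.",
]
_CROSS = [
    ("Tracer was injected into {A}.",
     "Retrogradely labeled neurons were found in {B}."),
]

_PLACEHOLDER_RE = re.compile(r"\{([A-F])\}")


def make_toy_lexicon(
    size: int = 40,
    depth: int = 4,
    seed: int = 42,
    n_reference_edges: int | None = None,
) -> tuple[Lexicon, ConnectivityMatrix]:
    """Rooted region tree with synonyms, plus a random reference connectome.

    Every region gets a word-order-permuted synonym and a stopworded
    variant, both of which resolve back to it by stem-bag equality; stem
    bags are unique across regions by construction (each name uses a
    distinct descriptor).  Reference edges connect random leaf pairs.
    """
    if size < 3:
        raise ValueError("size must be >= 3")
    rng = random.Random(seed)
    names = ["brain"]
    bags_seen = {frozenset({porter_stem("brain")})}
    i = 0
    while len(names) < size:
        if i < len(_DESCRIPTORS):
            desc = _DESCRIPTORS[i]
        else:
            desc = (
                _DESCRIPTORS[i % len(_DESCRIPTORS)]
                + " "
                + _DESCRIPTORS[(i // len(_DESCRIPTORS) - 1) % len(_DESCRIPTORS)]
            )
        noun = _NOUNS[i % len(_NOUNS)]
        name = f"{desc} {noun}"
        bag = frozenset(porter_stem(w) for w in name.split())
        i += 1
        if bag in bags_seen:
            continue
        bags_seen.add(bag)
        names.append(name)

    regions: list[LexiconRegion] = []
    ids = [f"R{j:03d}" for j in range(size)]
    levels = {ids[0]: 0}
    # one chain guarantees the requested maximum path length
    chain = ids[1:depth]
    for d, rid in enumerate(chain, start=1):
        levels[rid] = d
    for rid in ids[depth:]:
        levels[rid] = rng.randint(1, depth - 1)
    by_level: dict[int, list[str]] = {}
    for rid, lvl in levels.items():
        by_level.setdefault(lvl, []).append(rid)
    for j, rid in enumerate(ids):
        name = names[j]
        if j == 0:
            parent = None
        elif rid in chain:
            parent = ids[0] if levels[rid] == 1 else chain[levels[rid] - 2]
        else:
            parent = rng.choice(by_level[levels[rid] - 1])
        words = name.split()
        synonyms = []
        if len(words) > 1:
            synonyms.append(" ".join(reversed(words)))
        synonyms.append(f"the {name}")
        regions.append(
            LexiconRegion(
                region_id=rid,
                preferred_name=name,
                synonyms=tuple(synonyms),
                parent_id=parent,
            )
        )
    lexicon = Lexicon(regions)

    children = {r.parent_id for r in regions if r.parent_id}
    leaves = [r.region_id for r in regions if r.region_id not in children]
    possible = [
        (a, b) for i, a in enumerate(leaves) for b in leaves[i + 1 :]
    ]
    if n_reference_edges is None:
        n_reference_edges = min(2 * len(leaves), len(possible))
    n_reference_edges = min(n_reference_edges, len(possible))
    reference = ConnectivityMatrix.from_pairs(
        rng.sample(possible, n_reference_edges)
    )
    return lexicon, reference


def _fill_template(template: str, mentions: dict[str, str]):
    """Instantiate placeholders, returning text and mention char spans."""
    out = []
    spans = []
    pos = 0
    cursor = 0
    for m in _PLACEHOLDER_RE.finditer(template):
        out.append(template[cursor : m.start()])
        pos += m.start() - cursor
        text = mentions[m.group(1)]
        out.append(text)
        spans.append((m.group(1), pos, pos + len(text)))
        pos += len(text)
        cursor = m.end()
    out.append(template[cursor:])
    return "".join(out), spans


class _DocBuilder:
    def __init__(self, doc_id: str, year: int, species: list[str]):
        self.doc_id = doc_id
        self.year = year
        self.species = species
        self.text_parts: list[str] = []
        self.sentences: list[dict] = []
        self.mentions: list[dict] = []
        self.relations: list[dict] = []
        self.mention_regions: dict[str, str] = {}
        self._offset = 0
        self._mention_n = 0

    def add_sentence(self, text: str, spans, regions: dict[str, str]):
        """Append a sentence; returns placeholder -> mention_id mapping."""
        if self.text_parts:
            self._offset += 1  # joining space
        start = self._offset
        self.text_parts.append(text)
        self._offset += len(text)
        index = len(self.sentences)
        self.sentences.append({"start": start, "end": self._offset})
        mention_ids = {}
        for placeholder, s, e in spans:
            mid = f"m{self._mention_n}"
            self._mention_n += 1
            self.mentions.append(
                {
                    "id": mid,
                    "sentence": index,
                    "start": start + s,
                    "end": start + e,
                }
            )
            mention_ids[placeholder] = mid
            self.mention_regions[mid] = regions[placeholder]
        return mention_ids

    def add_relation(self, mid_a: str, mid_b: str):
        self.relations.append({"a": mid_a, "b": mid_b})

    def build(self) -> AbstractDocument:
        obj = {
            "doc_id": self.doc_id,
            "year": self.year,
            "species": self.species,
            "text": " ".join(self.text_parts),
            "sentences": self.sentences,
            "mentions": self.mentions,
            "relations": self.relations,
        }
        return _doc_from_json(obj)


def _mention_text(rng, lexicon: Lexicon, region_id: str) -> str:
    region = lexicon.regions[region_id]
    if region.synonyms and rng.random() < 0.3:
        permuted = [s for s in region.synonyms if not s.startswith("the ")]
        if permuted:
            return rng.choice(permuted)
    return region.preferred_name


def generate_corpus(
    config: GeneratorConfig,
    lexicon: Lexicon | None = None,
    reference: ConnectivityMatrix | None = None,
):
    """Generate ``(documents, truth_ledger)`` under the config's seed.

    The ledger has one row per within-sentence candidate pair and per
    cross-sentence gold relation, recording the gold label, whether the
    sentence carries a connectivity keyword, span status, era and species,
    and the underlying region pair with its reference-connectome status.
    """
    if lexicon is None or reference is None:
        lexicon, reference = make_toy_lexicon(
            config.lexicon_size, config.lexicon_depth, config.seed
        )
    if config.positive_pair_fraction > 0 and not reference.counts:
        raise ValueError(
            "positive pairs requested but the reference matrix is empty"
        )
    rng = random.Random(config.seed)
    region_ids = sorted(
        r for r in lexicon.regions if r != lexicon.root_id
    )
    ref_edges = sorted(reference.counts)
    keyword_stems = {porter_stem(k) for k in DEFAULT_KEYWORDS}

    docs: list[AbstractDocument] = []
    ledger_rows: list[dict] = []

    for d in range(config.n_documents):
        year = rng.randint(*config.year_range)
        species = (
            ["rat"]
            if rng.random() < config.rat_fraction
            else [rng.choice(["mouse", "macaque", "cat"])]
        )
        builder = _DocBuilder(f"doc{d:04d}", year, species)
        n_sentences = rng.randint(*config.sentences_per_doc)
        pending_cross: list[tuple[str, str]] = []

        s = 0
        while s < n_sentences:
            r = rng.random()
            if r < config.positive_pair_fraction:
                in_ref = rng.random() < (
                    config.reference_rate_post
                    if year >= config.split_year
                    else config.reference_rate_pre
                )
                if in_ref:
                    pair = rng.choice(ref_edges)
                else:
                    while True:
                        pair = tuple(sorted(rng.sample(region_ids, 2)))
                        if pair not in reference:
                            break
                cross = (
                    rng.random() < config.cross_sentence_relation_fraction
                    and s + 1 < n_sentences
                )
                if cross:
                    t_a, t_b = _CROSS[rng.randrange(len(_CROSS))]
                    texts = {"A": _mention_text(rng, lexicon, pair[0])}
                    sent, spans = _fill_template(t_a, texts)
                    ids_a = builder.add_sentence(sent, spans, {"A": pair[0]})
                    texts = {"B": _mention_text(rng, lexicon, pair[1])}
                    sent, spans = _fill_template(t_b, texts)
                    ids_b = builder.add_sentence(sent, spans, {"B": pair[1]})
                    builder.add_relation(ids_a["A"], ids_b["B"])
                    pending_cross.append((ids_a["A"], ids_b["B"]))
                    s += 2
                    continue
                with_keyword = (
                    rng.random() < config.keyword_insertion_probability
                    and rng.random() >= config.noise
                )
                three = (
                    rng.random() < config.three_mention_probability
                    and with_keyword
                )
                if three:
                    extra = rng.choice(
                        [x for x in region_ids if x not in pair]
                    )
                    template = rng.choice(_POS_3)
                    regions = {"A": pair[0], "B": pair[1], "C": extra}
                elif with_keyword:
                    template = rng.choice(_POS_2)
                    regions = {"A": pair[0], "B": pair[1]}
                else:
                    template = rng.choice(_POS_2_PLAIN)
                    regions = {"A": pair[0], "B": pair[1]}
                texts = {
                    k: _mention_text(rng, lexicon, v)
                    for k, v in regions.items()
                }
                sent, spans = _fill_template(template, texts)
                mids = builder.add_sentence(sent, spans, regions)
                builder.add_relation(mids["A"], mids["B"])
                if three:
                    builder.add_relation(mids["A"], mids["C"])
            elif r < (
                config.positive_pair_fraction
                + config.list_sentence_probability
            ):
                chosen = rng.sample(region_ids, 6)
                regions = dict(zip("ABCDEF", chosen))
                template = rng.choice(_LIST)
                texts = {
                    k: _mention_text(rng, lexicon, v)
                    for k, v in regions.items()
                }
                sent, spans = _fill_template(template, texts)
                builder.add_sentence(sent, spans, regions)
            else:
                noisy = rng.random() < config.noise
                template = rng.choice(
                    _NEG_2_KEYWORD if noisy else _NEG_2
                )
                pair = tuple(sorted(rng.sample(region_ids, 2)))
                regions = {"A": pair[0], "B": pair[1]}
                texts = {
                    k: _mention_text(rng, lexicon, v)
                    for k, v in regions.items()
                }
                sent, spans = _fill_template(template, texts)
                builder.add_sentence(sent, spans, regions)
            s += 1

        builder.add_sentence(
            f"Experiments were performed in the {species[0]}.", [], {}
        )
        doc = builder.build()
        docs.append(doc)

        # ledger: every within-sentence candidate pair ...
        sentence_keyword = {
            sent.index: any(
                t.stem in keyword_stems for t in sent.tokens
            )
            for sent in doc.sentences
        }
        mention_region = builder.mention_regions
        for pair_ in enumerate_candidate_pairs(doc, "sentence"):
            ra = mention_region[pair_.mention_a.mention_id]
            rb = mention_region[pair_.mention_b.mention_id]
            ledger_rows.append(
                {
                    "doc_id": doc.doc_id,
                    "sentence_index": pair_.sentence_index,
                    "mention_id_a": pair_.mention_a.mention_id,
                    "mention_id_b": pair_.mention_b.mention_id,
                    "label": bool(pair_.label),
                    "sentence_has_keyword": sentence_keyword[
                        pair_.sentence_index
                    ],
                    "spans_sentences": False,
                    "year": year,
                    "species": species[0],
                    "region_a": min(ra, rb),
                    "region_b": max(ra, rb),
                    "in_reference": (ra, rb) in reference,
                }
            )
        # ... plus cross-sentence gold relations
        for mid_a, mid_b in pending_cross:
            ra = mention_region[mid_a]
            rb = mention_region[mid_b]
            ledger_rows.append(
                {
                    "doc_id": doc.doc_id,
                    "sentence_index": -1,
                    "mention_id_a": mid_a,
                    "mention_id_b": mid_b,
                    "label": True,
                    "sentence_has_keyword": False,
                    "spans_sentences": True,
                    "year": year,
                    "species": species[0],
                    "region_a": min(ra, rb),
                    "region_b": max(ra, rb),
                    "in_reference": (ra, rb) in reference,
                }
            )

    ledger = pd.DataFrame(ledger_rows)
    return docs, ledger
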