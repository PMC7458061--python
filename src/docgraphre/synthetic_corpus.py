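"""Desk-scale synthetic corpora with a planted, controllable decision rule.

Each document is laid out as a sequence of *pair regions*, one per disease
concept.  A region holds one chemical mention and one disease mention,
either in the same sentence (intra) or in two adjacent sentences (inter),
and the region's concept pair is gold-positive with probability
``p_positive``.  Regions are separated by enough mention-free filler
sentences that cross-region concept pairs exceed the instance builder's
sentence-distance filter and never become candidates.

Two planted trigger rules are available:

* ``lexical`` — a trigger token sits immediately after the chemical
  mention in positive regions and at least 3 tokens away in negative
  regions; solvable from surface + position features alone.
* ``dependency_path`` — the trigger token occupies the *same linear slot*
  (immediately after the chemical mention) in both classes; what differs
  is the dependency tree: in positives the trigger is the sentence root
  and lies on the graph path between the two mentions, while in negatives
  it hangs three arcs below the root, off the path.  Token sequences are
  therefore class-uninformative by construction and the label is decidable
  only from the document graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus_io import (DependencyParse, Document, EntityMention, EntityType,
                        GoldRelation, Token, align_mentions)
from .instance_builder import build_all, Level

__all__ = ["SyntheticSpec", "generate_corpus", "corpus_stats"]

FILLER_VOCAB = [f"w{i:03d}" for i in range(200)]
CHEM_SURFACES = [f"chem{c}" for c in "ABCDE"]
DIS_SURFACES = [f"dis{c}" for c in "ABCDE"]
TRIGGER = "induceX"
POS_SUBSET = ["NOUN", "VERB", "ADJ", "ADV", "ADP", "DET", "PRON", "NUM",
              "CCONJ", "PUNCT"]
DEPRELS = ["nsubj", "obj", "obl", "amod", "advmod", "nmod", "conj", "det",
           "case", "mark"]

#: filler sentences between pair regions; keeps cross-region pairs beyond
#: the default sentence-distance filter (3) of the instance builder
REGION_GAP = 3


@dataclass
class SyntheticSpec:
    n_docs: int = 100
    sentences_per_doc: tuple[int, int] = (4, 8)
    tokens_per_sentence: tuple[int, int] = (7, 9)
    n_chemicals: int = 1
    n_diseases: int = 2
    p_positive: float = 0.5
    inter_fraction: float = 0.5
    trigger_rule: str = "dependency_path"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_positive <= 1.0 and
                0.0 <= self.inter_fraction <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.sentences_per_doc[0] > self.sentences_per_doc[1] or \
                self.tokens_per_sentence[0] > self.tokens_per_sentence[1]:
            raise ValueError("ranges must be non-empty")
        if self.inter_fraction > 0 and self.sentences_per_doc[1] < 2:
            raise ValueError("inter_fraction > 0 requires documents that "
                             "can hold at least 2 sentences")
        if self.trigger_rule not in ("lexical", "dependency_path"):
            raise ValueError(f"unknown trigger_rule {self.trigger_rule!r}")
        if self.tokens_per_sentence[0] < 7:
            raise ValueError("tokens_per_sentence minimum must be >= 7 to "
                             "hold the planted structures")
        if self.n_chemicals < 1 or self.n_diseases < 1:
            raise ValueError("need at least one chemical and one disease")


@dataclass
class _Sentence:
    surfaces: list[str]
    heads: list[int]            # 1-based, 0 = root
    deprels: list[str]
    chem: int | None = None     # within-sentence token index
    dis: int | None = None


def _random_tree(n: int, rng: np.random.Generator,
                 fixed_heads: dict[int, int] | None = None,
                 root: int | None = None) -> list[int]:
    """Random dependency tree via random attachment; returns 1-based heads.

    ``fixed_heads`` pins child -> head arcs (0-based); remaining tokens
    attach uniformly to an already-attached node.
    """
    fixed_heads = fixed_heads or {}
    if root is None:
        candidates = [i for i in range(n) if i not in fixed_heads]
        root = int(rng.choice(candidates))
    heads = [-1] * n
    heads[root] = 0
    attached = [root]
    pending = set(fixed_heads)
    # attach pinned arcs first, in dependency order
    while pending:
        progressed = False
        for child in sorted(pending):
            head = fixed_heads[child]
            if heads[head] != -1 or head == root:
                heads[child] = head + 1
                attached.append(child)
                pending.discard(child)
                progressed = True
        if not progressed:
            raise ValueError("fixed_heads do not hang off the root")
    rest = [i for i in range(n) if heads[i] == -1]
    rng.shuffle(rest)
    for child in rest:
        head = int(attached[rng.integers(len(attached))])
        heads[child] = head + 1
        attached.append(child)
    return heads


def _filler_sentence(n: int, rng: np.random.Generator) -> _Sentence:
    surfaces = [FILLER_VOCAB[i] for i in rng.integers(len(FILLER_VOCAB), size=n)]
    heads = _random_tree(n, rng)
    return _Sentence(surfaces=surfaces, heads=heads,
                     deprels=[DEPRELS[i] for i in rng.integers(len(DEPRELS), size=n)])


def _pick_distinct(rng: np.random.Generator, pool: list[int], k: int) -> list[int]:
    idx = rng.choice(len(pool), size=k, replace=False)
    return [pool[int(i)] for i in idx]


def _chem_sentence(n: int, rng: np.random.Generator, positive: bool,
                   rule: str, chem_surface: str,
                   dis_surface: str | None) -> _Sentence:
    """Sentence holding the chemical mention (and the disease, if intra)."""
    surfaces = [FILLER_VOCAB[i] for i in rng.integers(len(FILLER_VOCAB), size=n)]
    chem = int(rng.integers(0, n - 1))          # leave room for the trigger slot
    trig_slot = chem + 1
    free = [i for i in range(n) if i not in (chem, trig_slot)]

    if rule == "lexical":
        if positive:
            trig = trig_slot
            rest = free
        else:
            far = [i for i in free if abs(i - chem) >= 3]
            trig = int(far[rng.integers(len(far))]) if far else free[-1]
            rest = [i for i in free if i != trig]
        surfaces[trig] = TRIGGER
        dis = None
        if dis_surface is not None:
            dis = int(rest[rng.integers(len(rest))])
            surfaces[dis] = dis_surface
        surfaces[chem] = chem_surface
        heads = _random_tree(n, rng)
        return _Sentence(surfaces, heads,
                         [DEPRELS[i] for i in rng.integers(len(DEPRELS), size=n)],
                         chem=chem, dis=dis)

    # dependency_path: the trigger always occupies the slot after the
    # chemical; the tree decides the label.
    surfaces[trig_slot] = TRIGGER
    surfaces[chem] = chem_surface
    dis = None
    if dis_surface is not None:
        dis = int(free[rng.integers(len(free))])
        surfaces[dis] = dis_surface
        free = [i for i in free if i != dis]
    if positive:
        # trigger is the root; both mentions attach directly to it
        fixed = {chem: trig_slot}
        if dis is not None:
            fixed[dis] = trig_slot
        heads = _random_tree(n, rng, fixed_heads=fixed, root=trig_slot)
    else:
        # root is a filler; trigger hangs 3 arcs below, off the mention path
        chain = _pick_distinct(rng, free, 3)
        root, a, b = (int(x) for x in chain)
        fixed = {chem: root, a: root, b: a, trig_slot: b}
        if dis is not None:
            fixed[dis] = root
        heads = _random_tree(n, rng, fixed_heads=fixed, root=root)
    return _Sentence(surfaces, heads,
                     [DEPRELS[i] for i in rng.integers(len(DEPRELS), size=n)],
                     chem=chem, dis=dis)


def _dis_sentence(n: int, rng: np.random.Generator, rule: str,
                  dis_surface: str) -> _Sentence:
    """Adjacent sentence holding the disease mention of an inter region."""
    surfaces = [FILLER_VOCAB[i] for i in rng.integers(len(FILLER_VOCAB), size=n)]
    dis = int(rng.integers(n))
    surfaces[dis] = dis_surface
    if rule == "dependency_path":
        root = int(rng.choice([i for i in range(n) if i != dis]))
        heads = _random_tree(n, rng, fixed_heads={dis: root}, root=root)
    else:
        heads = _random_tree(n, rng)
    return _Sentence(surfaces, heads,
                     [DEPRELS[i] for i in rng.integers(len(DEPRELS), size=n)],
                     dis=dis)


def _assemble(doc_id: str, sentences: list[_Sentence],
              chem_ids: list[str | None], dis_ids: list[str | None],
              relations: list[GoldRelation],
              rng: np.random.Generator) -> Document:
    """Compose text/offsets/mentions/parses from per-sentence pieces."""
    tokens: list[list[Token]] = []
    mentions: list[EntityMention] = []
    parses: list[DependencyParse] = []
    offset = 0
    text_parts: list[str] = []
    for si, sent in enumerate(sentences):
        row: list[Token] = []
        for wi, surface in enumerate(sent.surfaces):
            start = offset
            end = start + len(surface)
            row.append(Token(surface=surface, char_start=start, char_end=end,
                             sentence_index=si,
                             pos_tag=POS_SUBSET[rng.integers(len(POS_SUBSET))]))
            offset = end + 1
            if sent.chem == wi and chem_ids[si] is not None:
                mentions.append(EntityMention(
                    entity_type=EntityType.CHEMICAL, concept_id=chem_ids[si],
                    char_start=start, char_end=end, text=surface))
            if sent.dis == wi and dis_ids[si] is not None:
                mentions.append(EntityMention(
                    entity_type=EntityType.DISEASE, concept_id=dis_ids[si],
                    char_start=start, char_end=end, text=surface))
        tokens.append(row)
        parses.append(DependencyParse(heads=list(sent.heads),
                                      deprels=list(sent.deprels)))
        text_parts.append(" ".join(sent.surfaces))
    doc = Document(
        doc_id=doc_id,
        title=text_parts[0],
        abstract=" ".join(text_parts[1:]),
        sentences=tokens,
        mentions=mentions,
        relations=relations,
        parses=parses,
    )
    align_mentions(doc)
    doc.validate()
    return doc


def _concept_id(rng: np.random.Generator, used: set[str]) -> str:
    while True:
        cid = f"D{rng.integers(0, 1_000_000):06d}"
        if cid not in used:
            used.add(cid)
            return cid


def generate_corpus(spec: SyntheticSpec) -> list[Document]:
    """Generate ``spec.n_docs`` documents with planted gold relations."""
    rng = np.random.default_rng(spec.seed)
    docs: list[Document] = []
    used_ids: set[str] = set()
    lo, hi = spec.tokens_per_sentence

    def sent_len() -> int:
        return int(rng.integers(lo, hi + 1))

    for di in range(spec.n_docs):
        chem_concepts = [_concept_id(rng, used_ids) for _ in range(spec.n_chemicals)]
        dis_concepts = [_concept_id(rng, used_ids) for _ in range(spec.n_diseases)]
        chem_surf = [CHEM_SURFACES[i % len(CHEM_SURFACES)]
                     for i in range(spec.n_chemicals)]
        dis_surf = [DIS_SURFACES[i % len(DIS_SURFACES)]
                    for i in range(spec.n_diseases)]

        sentences: list[_Sentence] = []
        chem_ids: list[str | None] = []
        dis_ids: list[str | None] = []
        relations: list[GoldRelation] = []

        def add_filler(k: int) -> None:
            for _ in range(k):
                sentences.append(_filler_sentence(sent_len(), rng))
                chem_ids.append(None)
                dis_ids.append(None)

        for region in range(spec.n_diseases):
            if region > 0:
                add_filler(REGION_GAP)
            ci = region % spec.n_chemicals
            positive = bool(rng.random() < spec.p_positive)
            inter = bool(rng.random() < spec.inter_fraction)
            if positive:
                relations.append(GoldRelation(
                    chemical_id=chem_concepts[ci],
                    disease_id=dis_concepts[region]))
            if inter:
                sentences.append(_chem_sentence(
                    sent_len(), rng, positive, spec.trigger_rule,
                    chem_surf[ci], dis_surface=None))
                chem_ids.append(chem_concepts[ci])
                dis_ids.append(None)
                sentences.append(_dis_sentence(
                    sent_len(), rng, spec.trigger_rule, dis_surf[region]))
                chem_ids.append(None)
                dis_ids.append(dis_concepts[region])
            else:
                sentences.append(_chem_sentence(
                    sent_len(), rng, positive, spec.trigger_rule,
                    chem_surf[ci], dis_surface=dis_surf[region]))
                chem_ids.append(chem_concepts[ci])
                dis_ids.append(dis_concepts[region])
        while len(sentences) < spec.sentences_per_doc[0]:
            add_filler(1)
        docs.append(_assemble(f"{9000000 + di}", sentences,
                              chem_ids, dis_ids, relations, rng))
    return docs


def corpus_stats(corpus: list[Document]) -> dict[str, int]:
    """Summary counts: documents, mentions, gold relations, instances."""
    instances = build_all(corpus)
    return {
        "documents": len(corpus),
        "mentions": sum(len(d.mentions) for d in corpus),
        "gold_relations": sum(len(d.relations) for d in corpus),
        "intra_instances": sum(1 for x in instances if x.level is Level.INTRA),
        "inter_instances": sum(1 for x in instances if x.level is Level.INTER),
        "positive_instances": sum(x.label for x in instances),
    }
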