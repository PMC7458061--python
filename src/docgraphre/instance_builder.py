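"""Heuristic construction of labeled candidate chemical-disease instances.

Every chemical concept / disease concept pair in a document yields at most
one candidate instance.  Pairs that co-occur in at least one sentence become
*intrasentence* instances built from the co-sentential mention pair at
minimal token distance.  All remaining pairs become *intersentence*
instances built from the mention pair minimizing sentence distance, unless
that distance exceeds ``max_sentence_distance``, in which case the pair is
dropped altogether.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable

from .corpus_io import Document, EntityMention, EntityType

__all__ = ["Level", "CandidateInstance", "construct_intra", "construct_inter",
           "build_all", "instances_to_tsv"]

DEFAULT_MAX_SENTENCE_DISTANCE = 3


class Level(str, Enum):
    INTRA = "intra"
    INTER = "inter"


@dataclass
class CandidateInstance:
    doc_id: str
    chemical_mention: EntityMention
    disease_mention: EntityMention
    chemical_id: str
    disease_id: str
    level: Level
    label: int
    sentence_distance: int

    @property
    def pair(self) -> tuple[str, str]:
        return (self.chemical_id, self.disease_id)


def _midpoint(m: EntityMention) -> float:
    s, e = m.token_span
    return (s + e) / 2.0


def _token_distance(c: EntityMention, d: EntityMention) -> float:
    return abs(_midpoint(c) - _midpoint(d))


def _grouped(doc: Document, etype: EntityType) -> dict[str, list[EntityMention]]:
    groups: dict[str, list[EntityMention]] = {}
    for m in doc.mentions:
        if m.entity_type is etype:
            if m.token_span is None:
                raise ValueError(f"doc {doc.doc_id}: mentions not aligned")
            groups.setdefault(m.concept_id, []).append(m)
    return groups


def _gold_pairs(doc: Document) -> set[tuple[str, str]]:
    return {(r.chemical_id, r.disease_id) for r in doc.relations}


def construct_intra(doc: Document) -> list[CandidateInstance]:
    """One intrasentence instance per co-sentential concept pair.

    Among all co-sentential mention pairs of a concept pair the one with
    minimal token distance between span midpoints is selected; ties break
    on earliest chemical mention, then earliest disease mention.
    """
    chems = _grouped(doc, EntityType.CHEMICAL)
    diss = _grouped(doc, EntityType.DISEASE)
    gold = _gold_pairs(doc)
    out: list[CandidateInstance] = []
    for cid in sorted(chems):
        for did in sorted(diss):
            best: tuple | None = None
            for cm in chems[cid]:
                for dm in diss[did]:
                    if cm.sentence_index != dm.sentence_index:
                        continue
                    key = (_token_distance(cm, dm), cm.token_span[0], dm.token_span[0])
                    if best is None or key < best[0]:
                        best = (key, cm, dm)
            if best is not None:
                _, cm, dm = best
                out.append(CandidateInstance(
                    doc_id=doc.doc_id,
                    chemical_mention=cm, disease_mention=dm,
                    chemical_id=cid, disease_id=did,
                    level=Level.INTRA,
                    label=int((cid, did) in gold),
                    sentence_distance=0,
                ))
    return out


def construct_inter(
    doc: Document,
    max_sentence_distance: int = DEFAULT_MAX_SENTENCE_DISTANCE,
) -> list[CandidateInstance]:
    """One intersentence instance per concept pair with no co-sentential
    co-occurrence anywhere in the document.

    The mention pair minimizing sentence distance is chosen (ties: minimal
    token distance, then earliest chemical mention, then earliest disease
    mention).  Pairs whose minimal sentence distance exceeds
    ``max_sentence_distance`` are dropped.
    """
    chems = _grouped(doc, EntityType.CHEMICAL)
    diss = _grouped(doc, EntityType.DISEASE)
    gold = _gold_pairs(doc)
    out: list[CandidateInstance] = []
    for cid in sorted(chems):
        for did in sorted(diss):
            co_sentential = any(
                cm.sentence_index == dm.sentence_index
                for cm in chems[cid] for dm in diss[did]
            )
            if co_sentential:
                continue
            best: tuple | None = None
            for cm in chems[cid]:
                for dm in diss[did]:
                    sdist = abs(cm.sentence_index - dm.sentence_index)
                    key = (sdist, _token_distance(cm, dm),
                           cm.token_span[0], dm.token_span[0])
                    if best is None or key < best[0]:
                        best = (key, cm, dm)
            if best is None:
                continue
            (sdist, _, _, _), cm, dm = best
            if sdist > max_sentence_distance:
                continue
            out.append(CandidateInstance(
                doc_id=doc.doc_id,
                chemical_mention=cm, disease_mention=dm,
                chemical_id=cid, disease_id=did,
                level=Level.INTER,
                label=int((cid, did) in gold),
                sentence_distance=sdist,
            ))
    return out


def build_all(
    corpus: Iterable[Document],
    max_sentence_distance: int = DEFAULT_MAX_SENTENCE_DISTANCE,
) -> list[CandidateInstance]:
    """All intra + inter instances of a corpus in deterministic order."""
    out: list[CandidateInstance] = []
    for doc in corpus:
        instances = construct_intra(doc) + construct_inter(doc, max_sentence_distance)
        instances.sort(key=lambda x: (x.doc_id, x.level.value,
                                      x.chemical_id, x.disease_id))
        out.extend(instances)
    return out


def instances_to_tsv(instances: list[CandidateInstance]) -> str:
    header = ("doc_id\tlevel\tchem_id\tdis_id\tchem_span\tdis_span"
              "\tsent_dist\tlabel")
    rows = [header]
    for x in instances:
        cs, ce = x.chemical_mention.token_span
        ds, de = x.disease_mention.token_span
        rows.append(
            f"{x.doc_id}\t{x.level.value}\t{x.chemical_id}\t{x.disease_id}"
            f"\t{cs}-{ce}\t{ds}-{de}\t{x.sentence_distance}\t{x.label}"
        )
    return "\n".join(rows) + "\n"
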