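"""Reading and writing PubTator corpora and CoNLL-U dependency parses.

Conventions used throughout the package:

* character offsets are 0-based, end-exclusive, and index the document
  text formed by joining title and abstract with a single space;
* token spans are 0-based *inclusive* intervals over the document-level
  token list (tokens of all sentences concatenated in order).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, TextIO

logger = logging.getLogger(__name__)

__all__ = [
    "EntityType",
    "Token",
    "EntityMention",
    "GoldRelation",
    "DependencyParse",
    "Document",
    "PubTatorParseError",
    "ConlluAlignmentError",
    "MentionAlignmentError",
    "read_pubtator",
    "write_pubtator",
    "read_conllu",
    "read_conllu_corpus",
    "align_mentions",
]


class EntityType(str, Enum):
    CHEMICAL = "Chemical"
    DISEASE = "Disease"


class PubTatorParseError(ValueError):
    """Malformed PubTator input; message names the offending line."""


class ConlluAlignmentError(ValueError):
    """CoNLL-U block does not align with the document tokenization."""


class MentionAlignmentError(ValueError):
    """A mention's character span matches no token."""


@dataclass
class Token:
    surface: str
    char_start: int
    char_end: int
    sentence_index: int
    pos_tag: str = "X"

    def __post_init__(self) -> None:
        if self.char_start >= self.char_end:
            raise ValueError(
                f"token {self.surface!r}: char_start {self.char_start} "
                f">= char_end {self.char_end}"
            )


@dataclass
class EntityMention:
    entity_type: EntityType
    concept_id: str
    char_start: int
    char_end: int
    text: str
    sentence_index: int = -1
    token_span: tuple[int, int] | None = None  # inclusive document-level interval

    def span_length(self) -> int:
        if self.token_span is None:
            raise ValueError("mention not aligned")
        return self.token_span[1] - self.token_span[0] + 1


@dataclass(frozen=True)
class GoldRelation:
    chemical_id: str
    disease_id: str


@dataclass
class DependencyParse:
    """One sentence's dependency tree: 1-based heads, 0 marks the root."""

    heads: list[int]
    deprels: list[str]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        n = len(self.heads)
        if len(self.deprels) != n:
            raise ValueError("heads and deprels length mismatch")
        roots = [i for i, h in enumerate(self.heads) if h == 0]
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root, found {len(roots)}")
        for i, h in enumerate(self.heads):
            if not 0 <= h <= n:
                raise ValueError(f"head index {h} out of range at token {i}")
        # reachability from the root proves the arcs form a tree
        children: dict[int, list[int]] = {}
        for i, h in enumerate(self.heads):
            children.setdefault(h - 1, []).append(i)
        seen: set[int] = set()
        stack = [roots[0]]
        while stack:
            node = stack.pop()
            if node in seen:
                raise ValueError("cycle detected in dependency parse")
            seen.add(node)
            stack.extend(children.get(node, []))
        if len(seen) != n:
            raise ValueError("dependency parse is not connected (cycle or orphan)")

    @property
    def root(self) -> int:
        """0-based index of the root token within the sentence."""
        return self.heads.index(0)


@dataclass
class Document:
    doc_id: str
    title: str
    abstract: str
    sentences: list[list[Token]] = field(default_factory=list)
    mentions: list[EntityMention] = field(default_factory=list)
    relations: list[GoldRelation] = field(default_factory=list)
    parses: list[DependencyParse] = field(default_factory=list)

    @property
    def text(self) -> str:
        return self.title + " " + self.abstract if self.abstract else self.title

    @property
    def tokens(self) -> list[Token]:
        return [t for sent in self.sentences for t in sent]

    def sentence_offsets(self) -> list[int]:
        """Document-level index of the first token of each sentence."""
        offsets, acc = [], 0
        for sent in self.sentences:
            offsets.append(acc)
            acc += len(sent)
        return offsets

    def validate(self) -> None:
        n = len(self.text)
        for m in self.mentions:
            if not (0 <= m.char_start < m.char_end <= n):
                raise ValueError(
                    f"doc {self.doc_id}: mention {m.concept_id} offsets "
                    f"[{m.char_start},{m.char_end}) outside text of length {n}"
                )
        pairs = [(r.chemical_id, r.disease_id) for r in self.relations]
        if len(pairs) != len(set(pairs)):
            raise ValueError(f"doc {self.doc_id}: duplicate gold relations")


# ---------------------------------------------------------------------------
# PubTator
# ---------------------------------------------------------------------------

def _split_concept_ids(raw: str) -> list[str]:
    """Composite annotations like ``D1|D2`` or ``D1+D2`` name several concepts."""
    out: list[str] = []
    for part in raw.replace("+", "|").split("|"):
        part = part.strip()
        if part:
            out.append(part)
    return out


def read_pubtator(stream: TextIO | Iterable[str] | str) -> list[Document]:
    """Parse a PubTator-format corpus into :class:`Document` objects.

    Mentions normalized to concept ``-1`` are dropped; composite concept
    identifiers are expanded into one mention per concept; duplicate
    relation lines are deduplicated with a warning.
    """
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = [ln.rstrip("\n") for ln in stream]

    docs: list[Document] = []
    cur: Document | None = None
    seen_rel: set[tuple[str, str]] = set()

    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            if cur is not None:
                docs.append(cur)
            cur = None
            seen_rel = set()
            continue
        if "|t|" in line or "|a|" in line:
            pmid, kind, payload = line.split("|", 2)
            if kind == "t":
                if cur is not None:
                    docs.append(cur)
                cur = Document(doc_id=pmid, title=payload, abstract="")
                seen_rel = set()
            elif kind == "a":
                if cur is None or cur.doc_id != pmid:
                    raise PubTatorParseError(
                        f"line {lineno}: abstract line for {pmid} without title"
                    )
                cur.abstract = payload
            else:  # pragma: no cover - guarded by the `in` checks above
                raise PubTatorParseError(f"line {lineno}: unknown header kind {kind!r}")
            continue

        fields = line.split("\t")
        if cur is None:
            raise PubTatorParseError(f"line {lineno}: annotation before any document")
        if len(fields) == 4 and fields[1] == "CID":
            pmid, _, chem, dis = fields
            if pmid != cur.doc_id:
                raise PubTatorParseError(f"line {lineno}: PMID mismatch {pmid}")
            key = (chem, dis)
            if key in seen_rel:
                logger.warning("doc %s: duplicate relation %s dropped", pmid, key)
                continue
            seen_rel.add(key)
            cur.relations.append(GoldRelation(chemical_id=chem, disease_id=dis))
        elif len(fields) == 6:
            pmid, start, end, text, etype, concept = fields
            if pmid != cur.doc_id:
                raise PubTatorParseError(f"line {lineno}: PMID mismatch {pmid}")
            try:
                cs, ce = int(start), int(end)
            except ValueError as exc:
                raise PubTatorParseError(f"line {lineno}: bad offsets") from exc
            if etype not in (EntityType.CHEMICAL.value, EntityType.DISEASE.value):
                raise PubTatorParseError(
                    f"line {lineno}: unknown entity type {etype!r}"
                )
            for cid in _split_concept_ids(concept):
                if cid == "-1":
                    continue
                cur.mentions.append(
                    EntityMention(
                        entity_type=EntityType(etype),
                        concept_id=cid,
                        char_start=cs,
                        char_end=ce,
                        text=text,
                    )
                )
        else:
            raise PubTatorParseError(
                f"line {lineno}: malformed PubTator line: {line!r}"
            )
    if cur is not None:
        docs.append(cur)
    for doc in docs:
        doc.validate()
    return docs


def write_pubtator(docs: list[Document]) -> str:
    """Serialize documents back to PubTator text (deterministic order)."""
    blocks: list[str] = []
    for doc in docs:
        doc.validate()
        lines = [f"{doc.doc_id}|t|{doc.title}", f"{doc.doc_id}|a|{doc.abstract}"]
        for m in sorted(doc.mentions, key=lambda m: (m.char_start, m.char_end, m.concept_id)):
            lines.append(
                f"{doc.doc_id}\t{m.char_start}\t{m.char_end}\t{m.text}"
                f"\t{m.entity_type.value}\t{m.concept_id}"
            )
        for r in doc.relations:
            lines.append(f"{doc.doc_id}\tCID\t{r.chemical_id}\t{r.disease_id}")
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + ("\n" if blocks else "")


# ---------------------------------------------------------------------------
# CoNLL-U
# ---------------------------------------------------------------------------

def _conllu_blocks(lines: Iterable[str]) -> Iterable[list[list[str]]]:
    """Yield sentence blocks as lists of 10-column rows (comments skipped)."""
    block: list[list[str]] = []
    for line in lines:
        line = line.rstrip("\n")
        if not line.strip():
            if block:
                yield block
                block = []
            continue
        if line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 10:
            raise ConlluAlignmentError(f"expected 10 CoNLL-U columns, got {len(cols)}")
        # skip multiword-token and empty-node rows
        if "-" in cols[0] or "." in cols[0]:
            continue
        block.append(cols)
    if block:
        yield block


def read_conllu(stream: TextIO | str, doc: Document) -> Document:
    """Attach one CoNLL-U parse per document sentence, in order.

    If the document is untokenized the CoNLL-U blocks *define* its
    sentences: each surface form is located in the document text left to
    right to recover character offsets.  Otherwise the CoNLL-U
    tokenization must match the document's sentences exactly.  The UPOS
    column populates each token's POS tag.
    """
    lines = stream.splitlines() if isinstance(stream, str) else list(stream)
    blocks = list(_conllu_blocks(lines))
    if not doc.sentences:
        doc.sentences = _tokenize_from_conllu(doc, blocks)
    if len(blocks) != len(doc.sentences):
        raise ConlluAlignmentError(
            f"doc {doc.doc_id}: {len(blocks)} CoNLL-U sentences "
            f"vs {len(doc.sentences)} document sentences"
        )
    parses: list[DependencyParse] = []
    for si, (block, sent) in enumerate(zip(blocks, doc.sentences)):
        if len(block) != len(sent):
            raise ConlluAlignmentError(
                f"doc {doc.doc_id} sentence {si}: token count mismatch "
                f"({len(block)} vs {len(sent)})"
            )
        for cols, tok in zip(block, sent):
            if cols[1] != tok.surface:
                raise ConlluAlignmentError(
                    f"doc {doc.doc_id} sentence {si}: surface mismatch "
                    f"{cols[1]!r} vs {tok.surface!r}"
                )
            tok.pos_tag = cols[3]
        try:
            heads = [int(c[6]) for c in block]
        except ValueError as exc:
            raise ConlluAlignmentError(
                f"doc {doc.doc_id} sentence {si}: non-integer HEAD"
            ) from exc
        parses.append(DependencyParse(heads=heads, deprels=[c[7] for c in block]))
    doc.parses = parses
    return doc


def _tokenize_from_conllu(doc: Document,
                          blocks: list[list[list[str]]]) -> list[list[Token]]:
    """Recover token character offsets by scanning the document text."""
    text = doc.text
    cursor = 0
    sentences: list[list[Token]] = []
    for si, block in enumerate(blocks):
        row: list[Token] = []
        for cols in block:
            surface = cols[1]
            start = text.find(surface, cursor)
            if start < 0:
                raise ConlluAlignmentError(
                    f"doc {doc.doc_id} sentence {si}: token {surface!r} "
                    f"not found in document text after offset {cursor}"
                )
            cursor = start + len(surface)
            row.append(Token(surface=surface, char_start=start,
                             char_end=cursor, sentence_index=si))
        sentences.append(row)
    return sentences


def read_conllu_corpus(stream: TextIO | str, docs: list[Document]) -> list[Document]:
    """Attach parses from a multi-document CoNLL-U file.

    Documents are delimited by ``# newdoc id = <doc_id>`` comments and must
    appear in the same order as ``docs``.
    """
    lines = stream.splitlines() if isinstance(stream, str) else list(stream)
    per_doc: dict[str, list[str]] = {}
    order: list[str] = []
    cur_id: str | None = None
    for line in lines:
        stripped = line.strip()
        if stripped.startswith("# newdoc id ="):
            cur_id = stripped.split("=", 1)[1].strip()
            per_doc[cur_id] = []
            order.append(cur_id)
            continue
        if cur_id is not None:
            per_doc[cur_id].append(line)
    if order != [d.doc_id for d in docs]:
        raise ConlluAlignmentError("CoNLL-U document ids do not match corpus order")
    for doc in docs:
        read_conllu("\n".join(per_doc[doc.doc_id]), doc)
    return docs


def write_conllu_corpus(docs: list[Document]) -> str:
    """Emit the documents' parses as a multi-document CoNLL-U file."""
    out: list[str] = []
    for doc in docs:
        out.append(f"# newdoc id = {doc.doc_id}")
        for sent, parse in zip(doc.sentences, doc.parses):
            for i, (tok, head, rel) in enumerate(
                zip(sent, parse.heads, parse.deprels), start=1
            ):
                out.append(
                    "\t".join(
                        [str(i), tok.surface, "_", tok.pos_tag, "_", "_",
                         str(head), rel, "_", "_"]
                    )
                )
            out.append("")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Mention alignment
# ---------------------------------------------------------------------------

def align_mentions(doc: Document) -> Document:
    """Fill each mention's token span from its character offsets.

    The span is the minimal document-level token interval whose tokens
    overlap ``[char_start, char_end)``; the mention is assigned to the
    sentence of its first token.  Mentions crossing a sentence boundary
    are kept (with a warning); mentions covering no token raise.
    """
    tokens = doc.tokens
    for m in doc.mentions:
        covered = [
            i for i, t in enumerate(tokens)
            if t.char_start < m.char_end and t.char_end > m.char_start
        ]
        if not covered:
            raise MentionAlignmentError(
                f"doc {doc.doc_id}: mention {m.concept_id} "
                f"[{m.char_start},{m.char_end}) matches no token"
            )
        first, last = covered[0], covered[-1]
        m.token_span = (first, last)
        m.sentence_index = tokens[first].sentence_index
        if tokens[last].sentence_index != m.sentence_index:
            logger.warning(
                "doc %s: mention %s crosses a sentence boundary; "
                "assigned to sentence %d",
                doc.doc_id, m.concept_id, m.sentence_index,
            )
    return doc
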