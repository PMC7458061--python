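"""The document-level dependency graph and its normalized adjacency.

Three edge types over document-level token indices:

* ``syntactic`` — one edge per non-root dependency arc within a sentence;
* ``adjacent_sentence`` — one edge between the dependency roots of each
  pair of consecutive sentences;
* ``self`` — a self-loop on every token.

The adjacency matrix collapses the edge types to weight 1, is symmetric,
and has a unit diagonal, so every node degree is at least one.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import scipy.sparse as sp

from .corpus_io import Document

__all__ = ["EdgeType", "DocumentGraph", "AdjacencyMatrix",
           "build_document_graph", "to_adjacency"]


class EdgeType(str, Enum):
    SYNTACTIC = "syntactic"
    ADJACENT_SENTENCE = "adjacent_sentence"
    SELF = "self"


@dataclass
class DocumentGraph:
    n_nodes: int
    edges: list[tuple[int, int, EdgeType]]
    node_sentence: list[int]

    def edges_of_type(self, etype: EdgeType) -> list[tuple[int, int]]:
        return [(i, j) for i, j, t in self.edges if t is etype]

    def to_tsv(self) -> str:
        rows = ["i\tj\ttype"]
        rows += [f"{i}\t{j}\t{t.value}" for i, j, t in self.edges]
        return "\n".join(rows) + "\n"


@dataclass
class AdjacencyMatrix:
    A: sp.csr_matrix  # binary, symmetric, unit diagonal

    @property
    def n(self) -> int:
        return self.A.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return np.asarray(self.A.sum(axis=1)).ravel()

    def neighbors(self, i: int) -> np.ndarray:
        return self.A.indices[self.A.indptr[i]:self.A.indptr[i + 1]]

    def dense(self) -> np.ndarray:
        return self.A.toarray()

    def to_matrix_market(self) -> str:
        import io
        from scipy.io import mmwrite
        buf = io.BytesIO()
        mmwrite(buf, self.A.tocoo())
        return buf.getvalue().decode()


def build_document_graph(doc: Document) -> DocumentGraph:
    """Assemble syntactic, adjacent-sentence, and self edges for a document."""
    if len(doc.parses) != len(doc.sentences):
        missing = len(doc.sentences) - len(doc.parses)
        raise ValueError(
            f"doc {doc.doc_id}: {missing} sentence(s) lack a dependency parse"
        )
    offsets = doc.sentence_offsets()
    edges: list[tuple[int, int, EdgeType]] = []
    roots: list[int] = []
    for si, (sent, parse) in enumerate(zip(doc.sentences, doc.parses)):
        if len(parse.heads) != len(sent):
            raise ValueError(f"doc {doc.doc_id}: parse/sentence length "
                             f"mismatch at sentence {si}")
        base = offsets[si]
        roots.append(base + parse.root)
        for dep, head in enumerate(parse.heads):
            if head == 0:
                continue
            edges.append((base + head - 1, base + dep, EdgeType.SYNTACTIC))
    for k in range(len(roots) - 1):
        edges.append((roots[k], roots[k + 1], EdgeType.ADJACENT_SENTENCE))
    n = offsets[-1] + len(doc.sentences[-1]) if doc.sentences else 0
    for i in range(n):
        edges.append((i, i, EdgeType.SELF))
    node_sentence = [t.sentence_index for t in doc.tokens]
    return DocumentGraph(n_nodes=n, edges=edges, node_sentence=node_sentence)


def to_adjacency(graph: DocumentGraph) -> AdjacencyMatrix:
    """Collapse the typed edge list into a binary symmetric adjacency with
    a unit diagonal (edge direction discarded)."""
    n = graph.n_nodes
    rows, cols = [], []
    for i, j, _ in graph.edges:
        rows.append(i)
        cols.append(j)
        if i != j:
            rows.append(j)
            cols.append(i)
    data = np.ones(len(rows), dtype=np.float64)
    A = sp.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
    A.data[:] = 1.0  # collapse duplicates to binary
    return AdjacencyMatrix(A=A)
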