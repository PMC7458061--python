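"""Per-token input features: contextual vector + POS + pairwise position
embeddings relative to the candidate chemical and disease mentions.

The contextual embedder is a pluggable interface; the default desk-scale
implementation is a deterministic hash embedder that mimics a contextual
language model (same surface form in a different immediate context yields
a different, but correlated, vector).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np

from .corpus_io import Document
from .instance_builder import CandidateInstance

logger = logging.getLogger(__name__)

__all__ = ["UPOS_TAGS", "EmbeddingTables", "ContextualEmbedder", "HashEmbedder",
           "PrecomputedEmbedder", "TokenFeatureMatrix", "position_index",
           "featurize"]

UPOS_TAGS = ["ADJ", "ADP", "ADV", "AUX", "CCONJ", "DET", "INTJ", "NOUN",
             "NUM", "PART", "PRON", "PROPN", "PUNCT", "SCONJ", "SYM",
             "VERB", "X"]
UNK_POS = "<UNK>"


def position_index(token_index: int, mention_span: tuple[int, int],
                   max_dist: int) -> int:
    """Signed distance from a token to the nearest end of a mention span.

    0 inside the span, negative to the left, positive to the right,
    clipped to ``[-max_dist, +max_dist]``.
    """
    if max_dist < 1:
        raise ValueError("max_dist must be >= 1")
    start, end = mention_span
    if start > end:
        raise ValueError(f"empty mention span {mention_span}")
    if token_index < start:
        return max(token_index - start, -max_dist)
    if token_index > end:
        return min(token_index - end, max_dist)
    return 0


@dataclass
class EmbeddingTables:
    """POS and clipped-distance embedding lookup tables.

    Rows are drawn once from a seeded generator; lookups are total (unknown
    POS tags map to a dedicated UNK row, distances are pre-clipped).
    """

    dim_pos: int = 100
    dim_dist: int = 100
    clip: int = 50
    seed: int = 0
    pos_vocab: dict[str, int] = field(init=False)
    M_p: np.ndarray = field(init=False)
    M_d: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        rng = np.random.default_rng(self.seed)
        self.pos_vocab = {tag: i for i, tag in enumerate(UPOS_TAGS)}
        self.pos_vocab[UNK_POS] = len(self.pos_vocab)
        scale = 0.1
        self.M_p = rng.normal(0.0, scale, (len(self.pos_vocab), self.dim_pos))
        self.M_d = rng.normal(0.0, scale, (2 * self.clip + 1, self.dim_dist))

    def pos_row(self, tag: str) -> np.ndarray:
        idx = self.pos_vocab.get(tag)
        if idx is None:
            logger.warning("unknown POS tag %r mapped to UNK", tag)
            idx = self.pos_vocab[UNK_POS]
        return self.M_p[idx]

    def dist_row(self, clipped_distance: int) -> np.ndarray:
        return self.M_d[clipped_distance + self.clip]


class ContextualEmbedder:
    """Interface: map one document's token surfaces to an ``n x dim`` matrix.

    Implementations may depend on context but must be deterministic for a
    fixed input.
    """

    dim: int

    def embed(self, surfaces: list[str]) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class HashEmbedder(ContextualEmbedder):
    """Deterministic pseudo-random embedder, weakly context-sensitive.

    Each token vector is a seeded hash function of its surface form plus a
    smaller additive contribution from the left and right neighbor
    surfaces; rows are unit-normalized.
    """

    NEIGHBOR_WEIGHT = 0.35

    def __init__(self, dim: int = 32, seed: int = 0):
        if dim < 1:
            raise ValueError("dim must be >= 1")
        self.dim = dim
        self.seed = seed
        self._cache: dict[tuple[str, str], np.ndarray] = {}

    def _base(self, word: str, salt: str) -> np.ndarray:
        key = (word, salt)
        vec = self._cache.get(key)
        if vec is None:
            digest = hashlib.blake2b(
                f"{self.seed}|{salt}|{word}".encode(), digest_size=8
            ).digest()
            rng = np.random.default_rng(int.from_bytes(digest, "little"))
            vec = rng.standard_normal(self.dim)
            self._cache[key] = vec
        return vec

    def embed(self, surfaces: list[str]) -> np.ndarray:
        n = len(surfaces)
        out = np.empty((n, self.dim))
        for i, w in enumerate(surfaces):
            v = self._base(w, "c").copy()
            if i > 0:
                v += self.NEIGHBOR_WEIGHT * self._base(surfaces[i - 1], "l")
            if i < n - 1:
                v += self.NEIGHBOR_WEIGHT * self._base(surfaces[i + 1], "r")
            out[i] = v / np.linalg.norm(v)
        return out


class PrecomputedEmbedder(ContextualEmbedder):
    """Reads per-document token vectors from a sidecar (NPY or TSV) file."""

    def __init__(self, vectors: dict[str, np.ndarray]):
        if not vectors:
            raise ValueError("no precomputed vectors given")
        self.vectors = vectors
        self.dim = next(iter(vectors.values())).shape[1]
        self._doc_id: str | None = None

    def for_document(self, doc_id: str) -> "PrecomputedEmbedder":
        self._doc_id = doc_id
        return self

    def embed(self, surfaces: list[str]) -> np.ndarray:
        if self._doc_id is None:
            raise ValueError("call for_document(doc_id) first")
        mat = self.vectors[self._doc_id]
        if mat.shape[0] != len(surfaces):
            raise ValueError(
                f"doc {self._doc_id}: {mat.shape[0]} precomputed rows "
                f"vs {len(surfaces)} tokens"
            )
        return mat

    @classmethod
    def from_npz(cls, path: str) -> "PrecomputedEmbedder":
        """NPZ archive: one ``n_tokens x dim`` array per doc_id key."""
        with np.load(path) as archive:
            return cls({k: archive[k] for k in archive.files})

    @classmethod
    def from_tsv(cls, text: str) -> "PrecomputedEmbedder":
        """TSV rows: doc_id <TAB> token_index <TAB> v1,v2,..."""
        acc: dict[str, list[np.ndarray]] = {}
        for line in text.splitlines():
            if not line.strip():
                continue
            doc_id, _, values = line.split("\t")
            acc.setdefault(doc_id, []).append(
                np.array([float(v) for v in values.split(",")])
            )
        return cls({k: np.vstack(v) for k, v in acc.items()})


@dataclass
class TokenFeatureMatrix:
    """Features for one candidate instance over its input window.

    ``window`` is the inclusive document-level token interval retained
    after truncation; mention spans are re-expressed in window coordinates.
    """

    matrix: np.ndarray  # n_window x (dim_ctx + dim_pos + 2*dim_dist)
    window: tuple[int, int]
    chem_span: tuple[int, int]
    dis_span: tuple[int, int]

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def _truncation_window(n_tokens: int, chem_span: tuple[int, int],
                       dis_span: tuple[int, int], max_len: int
                       ) -> tuple[int, int]:
    """Symmetric window of at most ``max_len`` tokens containing both spans."""
    if n_tokens <= max_len:
        return (0, n_tokens - 1)
    lo = min(chem_span[0], dis_span[0])
    hi = max(chem_span[1], dis_span[1])
    need = hi - lo + 1
    if need >= max_len:
        return (lo, hi)  # keep both spans even if over budget
    slack = max_len - need
    left = slack // 2
    start = max(0, lo - left)
    end = min(n_tokens - 1, start + max_len - 1)
    start = max(0, end - max_len + 1)
    return (start, end)


def featurize(instance: CandidateInstance, doc: Document,
              embedder: ContextualEmbedder, tables: EmbeddingTables,
              max_len: int = 384) -> TokenFeatureMatrix:
    """Build the instance's token feature matrix.

    Row layout (fixed order): contextual | POS | chemical-distance |
    disease-distance.
    """
    tokens = doc.tokens
    cspan = instance.chemical_mention.token_span
    dspan = instance.disease_mention.token_span
    if cspan is None or dspan is None:
        raise ValueError("instance mentions are not aligned")
    w0, w1 = _truncation_window(len(tokens), cspan, dspan, max_len)
    surfaces = [t.surface for t in tokens]
    if isinstance(embedder, PrecomputedEmbedder):
        embedder.for_document(doc.doc_id)
    ctx = embedder.embed(surfaces)[w0:w1 + 1]
    n = w1 - w0 + 1
    pos_part = np.empty((n, tables.dim_pos))
    cdist = np.empty((n, tables.dim_dist))
    ddist = np.empty((n, tables.dim_dist))
    for row, ti in enumerate(range(w0, w1 + 1)):
        pos_part[row] = tables.pos_row(tokens[ti].pos_tag)
        cdist[row] = tables.dist_row(position_index(ti, cspan, tables.clip))
        ddist[row] = tables.dist_row(position_index(ti, dspan, tables.clip))
    matrix = np.hstack([ctx, pos_part, cdist, ddist])
    return TokenFeatureMatrix(
        matrix=matrix,
        window=(w0, w1),
        chem_span=(cspan[0] - w0, cspan[1] - w0),
        dis_span=(dspan[0] - w0, dspan[1] - w0),
    )
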