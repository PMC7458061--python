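"""Training loop, prediction, intra/inter/merged evaluation, and ablation
sweeps for the relation classifier."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Adam
from .corpus_io import Document
from .doc_graph import build_document_graph, to_adjacency
from .instance_builder import CandidateInstance, Level
from .neural_model import (Batch, ModelConfig, ModelParameters, batch_loss,
                           forward_batch)
from .representation import (ContextualEmbedder, EmbeddingTables, HashEmbedder,
                             featurize)

logger = logging.getLogger(__name__)

__all__ = ["TrainingConfig", "LevelScores", "EvalReport", "Profile",
           "PROFILES", "encode_instances", "make_batches", "train", "predict",
           "evaluate", "ablate"]

PairKey = tuple[str, str, str]  # (doc_id, chemical_id, disease_id)


@dataclass
class TrainingConfig:
    learning_rate: float = 0.001
    batch_size: int = 32
    max_epochs: int = 20
    patience: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.batch_size, self.max_epochs,
               self.patience) <= 0:
            raise ValueError("training configuration values must be positive")


@dataclass
class LevelScores:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


@dataclass
class EvalReport:
    intra: LevelScores = field(default_factory=LevelScores)
    inter: LevelScores = field(default_factory=LevelScores)
    merged: LevelScores = field(default_factory=LevelScores)

    def row(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for level in ("intra", "inter", "merged"):
            s: LevelScores = getattr(self, level)
            out[f"{level}_P"] = s.precision
            out[f"{level}_R"] = s.recall
            out[f"{level}_F"] = s.f1
        return out


# ---------------------------------------------------------------------------
# Profiles (paper-scale defaults vs a small fast test profile)
# ---------------------------------------------------------------------------

@dataclass
class Profile:
    dim_ctx: int
    dim_pos: int
    dim_dist: int
    clip: int
    max_len: int
    model: dict
    training: dict


PROFILES: dict[str, Profile] = {
    "paper": Profile(
        dim_ctx=1024, dim_pos=100, dim_dist=100, clip=50, max_len=384,
        model=dict(lstm_dim=500, gcn_dim=500, gcn_layers=2, n_heads=5,
                   mlp_dim=500, dropout=0.5, attention_kind="multihead"),
        training=dict(learning_rate=0.001, batch_size=32, max_epochs=30,
                      patience=5),
    ),
    "test": Profile(
        dim_ctx=32, dim_pos=8, dim_dist=8, clip=20, max_len=128,
        model=dict(lstm_dim=32, gcn_dim=32, gcn_layers=2, n_heads=2,
                   mlp_dim=32, dropout=0.1, attention_kind="multihead"),
        training=dict(learning_rate=0.005, batch_size=32, max_epochs=20,
                      patience=5),
    ),
}


def default_pipeline(profile: str = "test", seed: int = 0
                     ) -> tuple[HashEmbedder, EmbeddingTables, Profile]:
    prof = PROFILES[profile]
    embedder = HashEmbedder(dim=prof.dim_ctx, seed=seed)
    tables = EmbeddingTables(dim_pos=prof.dim_pos, dim_dist=prof.dim_dist,
                             clip=prof.clip, seed=seed)
    return embedder, tables, prof


# ---------------------------------------------------------------------------
# Instance encoding and batching
# ---------------------------------------------------------------------------

@dataclass
class EncodedInstance:
    key: PairKey
    level: Level
    label: int
    X: np.ndarray           # n x input_dim
    A: np.ndarray           # n x n binary adjacency with unit diagonal
    chem_span: tuple[int, int]
    dis_span: tuple[int, int]

    @property
    def n(self) -> int:
        return self.X.shape[0]


def encode_instances(instances: list[CandidateInstance], docs: list[Document],
                     embedder: ContextualEmbedder, tables: EmbeddingTables,
                     max_len: int = 384) -> list[EncodedInstance]:
    """Featurize instances and attach window-restricted adjacencies."""
    by_id = {d.doc_id: d for d in docs}
    adj_cache: dict[str, np.ndarray] = {}
    out: list[EncodedInstance] = []
    for inst in instances:
        doc = by_id[inst.doc_id]
        feats = featurize(inst, doc, embedder, tables, max_len=max_len)
        A_full = adj_cache.get(inst.doc_id)
        if A_full is None:
            A_full = to_adjacency(build_document_graph(doc)).dense()
            adj_cache[inst.doc_id] = A_full
        w0, w1 = feats.window
        A = A_full[w0:w1 + 1, w0:w1 + 1]
        out.append(EncodedInstance(
            key=(inst.doc_id, inst.chemical_id, inst.disease_id),
            level=inst.level, label=inst.label,
            X=feats.matrix, A=A,
            chem_span=feats.chem_span, dis_span=feats.dis_span,
        ))
    return out


def make_batches(encoded: list[EncodedInstance], batch_size: int
                 ) -> list[Batch]:
    """Group length-sorted instances into padded batches."""
    order = sorted(range(len(encoded)), key=lambda i: encoded[i].n)
    batches: list[Batch] = []
    for start in range(0, len(order), batch_size):
        chunk = [encoded[i] for i in order[start:start + batch_size]]
        B = len(chunk)
        T = max(e.n for e in chunk)
        D = chunk[0].X.shape[1]
        X = np.zeros((B, T, D))
        mask = np.zeros((B, T))
        A = np.zeros((B, T, T))
        chem_mask = np.zeros((B, T))
        dis_mask = np.zeros((B, T))
        rev = np.tile(np.arange(T), (B, 1))
        labels = np.zeros(B, dtype=np.int64)
        for bi, e in enumerate(chunk):
            n = e.n
            X[bi, :n] = e.X
            mask[bi, :n] = 1.0
            A[bi, :n, :n] = e.A
            chem_mask[bi, e.chem_span[0]:e.chem_span[1] + 1] = 1.0
            dis_mask[bi, e.dis_span[0]:e.dis_span[1] + 1] = 1.0
            rev[bi, :n] = np.arange(n)[::-1]
            labels[bi] = e.label
        deg = A.sum(axis=2, keepdims=True)
        deg[deg < 1.0] = 1.0
        batches.append(Batch(X=X, mask=mask, A=A, deg=deg,
                             chem_mask=chem_mask, dis_mask=dis_mask,
                             rev_idx=rev, labels=labels))
    return batches


# ---------------------------------------------------------------------------
# Training / prediction / evaluation
# ---------------------------------------------------------------------------

def train(instances: list[CandidateInstance], docs: list[Document],
          model_cfg: ModelConfig, train_cfg: TrainingConfig,
          embedder: ContextualEmbedder, tables: EmbeddingTables,
          max_len: int = 384,
          dev_instances: list[CandidateInstance] | None = None,
          dev_docs: list[Document] | None = None
          ) -> tuple[ModelParameters, dict]:
    """Minimize cross-entropy with Adam; retain the parameters of the epoch
    with the best development merged F-measure (when a dev set is given)."""
    if not any(x.label for x in instances):
        raise ValueError("degenerate training set: no positive instances")
    encoded = encode_instances(instances, docs, embedder, tables, max_len)
    batches = make_batches(encoded, train_cfg.batch_size)
    params = ModelParameters(model_cfg)
    optimizer = Adam(params.tensors(), lr=train_cfg.learning_rate)
    rng = np.random.default_rng(train_cfg.seed)

    history: dict = {"epoch_loss": [], "dev_f": []}
    best_state = None
    best_f = -1.0
    stale = 0
    for epoch in range(train_cfg.max_epochs):
        order = rng.permutation(len(batches))
        total, count = 0.0, 0
        for bi in order:
            batch = batches[bi]
            optimizer.zero_grad()
            loss = batch_loss(params, batch, train=True, dropout_rng=rng)
            loss.backward()
            optimizer.step()
            total += float(loss.data) * batch.size
            count += batch.size
        epoch_loss = total / count
        history["epoch_loss"].append(epoch_loss)

        if dev_instances is not None and dev_docs is not None:
            preds = predict(params, dev_instances, dev_docs, embedder,
                            tables, max_len)
            report = evaluate(preds, dev_docs, dev_instances)
            dev_f = report.merged.f1
            history["dev_f"].append(dev_f)
            logger.info("epoch %d: loss %.4f dev merged F %.3f",
                        epoch, epoch_loss, dev_f)
            if dev_f > best_f:
                best_f, best_state, stale = dev_f, params.copy_state(), 0
            else:
                stale += 1
                if stale >= train_cfg.patience:
                    logger.info("early stop at epoch %d", epoch)
                    break
            if dev_f >= 1.0:
                break
        else:
            logger.info("epoch %d: loss %.4f", epoch, epoch_loss)
    if best_state is not None:
        params.load_state(best_state)
    return params, history


def predict(params: ModelParameters, instances: list[CandidateInstance],
            docs: list[Document], embedder: ContextualEmbedder,
            tables: EmbeddingTables, max_len: int = 384
            ) -> dict[PairKey, Level]:
    """Concept pairs predicted positive (o_positive > 0.5), with level tags."""
    if not instances:
        return {}
    encoded = encode_instances(instances, docs, embedder, tables, max_len)
    out: dict[PairKey, Level] = {}
    for batch, chunk in _batches_with_chunks(encoded, 64):
        probs = forward_batch(params, batch, train=False)["probs"]
        for e, p in zip(chunk, probs):
            if p[1] > 0.5:
                out[e.key] = e.level
    return out


def _batches_with_chunks(encoded: list[EncodedInstance], batch_size: int):
    order = sorted(range(len(encoded)), key=lambda i: encoded[i].n)
    for start in range(0, len(order), batch_size):
        idx = order[start:start + batch_size]
        chunk = [encoded[i] for i in idx]
        batch = make_batches(chunk, batch_size)[0]
        yield batch, chunk


def evaluate(predictions: dict[PairKey, Level] | set,
             docs: list[Document],
             instances: list[CandidateInstance]) -> EvalReport:
    """Micro-averaged P/R/F at the intra, inter, and merged levels.

    A gold pair is assigned to the intra level if the document has an intra
    instance for it, otherwise to the inter level; gold pairs unreachable
    by instance construction count as false negatives.
    """
    inst_level: dict[PairKey, Level] = {
        (x.doc_id, x.chemical_id, x.disease_id): x.level for x in instances
    }
    if isinstance(predictions, set):
        predictions = {k: inst_level[k] for k in predictions}
    gold: set[PairKey] = set()
    for doc in docs:
        for r in doc.relations:
            gold.add((doc.doc_id, r.chemical_id, r.disease_id))

    report = EvalReport()
    pred_keys = set(predictions)
    for key in pred_keys:
        level = predictions[key]
        bucket = report.intra if level is Level.INTRA else report.inter
        if key in gold:
            bucket.tp += 1
            report.merged.tp += 1
        else:
            bucket.fp += 1
            report.merged.fp += 1
    for key in gold - pred_keys:
        level = inst_level.get(key, Level.INTER)
        bucket = report.intra if level is Level.INTRA else report.inter
        bucket.fn += 1
        report.merged.fn += 1
    return report


# ---------------------------------------------------------------------------
# Ablation sweeps
# ---------------------------------------------------------------------------

def ablate(grid: dict[str, dict], train_docs: list[Document],
           eval_docs: list[Document], train_instances: list[CandidateInstance],
           eval_instances: list[CandidateInstance],
           base_model: ModelConfig, base_train: TrainingConfig,
           embedder: ContextualEmbedder, tables: EmbeddingTables,
           max_len: int = 384) -> dict[str, EvalReport | str]:
    """One training + evaluation per named config delta, shared seed.

    A delta may override any :class:`ModelConfig` or
    :class:`TrainingConfig` field; infeasible cells are recorded as
    ``"skipped: <reason>"``.
    """
    results: dict[str, EvalReport | str] = {}
    for name, delta in grid.items():
        model_kwargs = {k: v for k, v in vars(base_model).items()}
        train_kwargs = {k: v for k, v in vars(base_train).items()}
        for k, v in delta.items():
            if k in model_kwargs:
                model_kwargs[k] = v
            elif k in train_kwargs:
                train_kwargs[k] = v
            else:
                results[name] = f"skipped: unknown field {k}"
                break
        else:
            try:
                cfg = ModelConfig(**model_kwargs)
                tcfg = TrainingConfig(**train_kwargs)
            except ValueError as exc:
                results[name] = f"skipped: {exc}"
                continue
            params, _ = train(train_instances, train_docs, cfg, tcfg,
                              embedder, tables, max_len)
            preds = predict(params, eval_instances, eval_docs, embedder,
                            tables, max_len)
            results[name] = evaluate(preds, eval_docs, eval_instances)
    return results


def ablation_tsv(results: dict[str, EvalReport | str]) -> str:
    cols = ["cell", "intra_P", "intra_R", "intra_F", "inter_P", "inter_R",
            "inter_F", "merged_P", "merged_R", "merged_F"]
    rows = ["\t".join(cols)]
    for name, res in results.items():
        if isinstance(res, str):
            rows.append(f"{name}\t{res}")
            continue
        r = res.row()
        rows.append("\t".join([name] + [f"{r[c]:.4f}" for c in cols[1:]]))
    return "\n".join(rows) + "\n"
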