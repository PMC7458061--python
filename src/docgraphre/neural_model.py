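"""The relation classifier: BiLSTM encoder, self-attention branch, graph
convolution branch over the document dependency graph, max-pooling, and a
2-layer perceptron with softmax output.

Two entry levels are provided:

* single-instance operations (:func:`bilstm_forward`, :func:`attention`,
  :func:`gcn_layer`, :func:`gcn_stack`, :func:`pool_and_represent`,
  :func:`classify`) that take and return numpy arrays — convenient for
  inspection and for checking against independent oracles;
* a batched differentiable forward pass (:func:`forward_batch`) used for
  training, built from the same parameter tensors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from enum import Enum

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, concat, constant, matmul, softmax, stack, take_along_time

__all__ = ["AttentionKind", "ModelConfig", "ModelParameters", "HiddenStates",
           "AttentionOutput", "InstanceRepresentation", "Batch",
           "bilstm_forward", "attention", "gcn_layer", "gcn_stack",
           "pool_and_represent", "classify", "forward_batch", "batch_loss"]

_BIG = 1e9


class AttentionKind(str, Enum):
    NONE = "none"
    ADDITIVE = "additive"
    GENERAL = "general"
    SCALED_DOT = "scaled_dot"
    MULTIHEAD = "multihead"


@dataclass
class ModelConfig:
    input_dim: int
    lstm_dim: int = 500
    gcn_dim: int = 500
    gcn_layers: int = 2
    attention_kind: AttentionKind = AttentionKind.MULTIHEAD
    n_heads: int = 5
    mlp_dim: int = 500
    dropout: float = 0.5
    use_gcn: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.attention_kind, str):
            self.attention_kind = AttentionKind(self.attention_kind)
        if self.gcn_layers < 1:
            raise ValueError("gcn_layers must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        d = 2 * self.lstm_dim
        if self.attention_kind is AttentionKind.MULTIHEAD and d % self.n_heads:
            raise ValueError(
                f"BiLSTM output dim {d} not divisible by n_heads {self.n_heads}"
            )
        if not self.use_gcn and self.attention_kind is AttentionKind.NONE:
            raise ValueError("model needs at least one of the GCN and "
                             "attention branches")

    @property
    def bilstm_out_dim(self) -> int:
        return 2 * self.lstm_dim

    @property
    def final_dim(self) -> int:
        dim = 0
        if self.use_gcn:
            dim += 3 * self.gcn_dim
        if self.attention_kind is not AttentionKind.NONE:
            dim += self.bilstm_out_dim
        return dim

    def to_json(self) -> str:
        d = asdict(self)
        d["attention_kind"] = self.attention_kind.value
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        return cls(**json.loads(text))


_GATES = ("f", "o", "g", "i")


class ModelParameters:
    """All trainable tensors, initialized deterministically from the seed."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self._params: dict[str, Tensor] = {}
        rng = np.random.default_rng(config.seed)
        D, H = config.input_dim, config.lstm_dim
        d = config.bilstm_out_dim

        def glorot(name: str, fan_in: int, fan_out: int, shape=None):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            shape = shape or (fan_in, fan_out)
            self._params[name] = ad.parameter(rng.uniform(-limit, limit, shape))

        def zeros(name: str, shape):
            self._params[name] = ad.parameter(np.zeros(shape))

        for direction in ("fw", "bw"):
            for gate in _GATES:
                glorot(f"lstm.{direction}.W_{gate}", D, H)
                glorot(f"lstm.{direction}.U_{gate}", H, H)
                zeros(f"lstm.{direction}.b_{gate}", (H,))

        kind = config.attention_kind
        if kind is AttentionKind.ADDITIVE:
            glorot("att.W_1", d, d)
            glorot("att.W_2", d, d)
            glorot("att.v", d, 1)
        elif kind is AttentionKind.GENERAL:
            glorot("att.W_1", d, d)
        elif kind is AttentionKind.MULTIHEAD:
            glorot("att.W_q", d, d)
            glorot("att.W_k", d, d)
            glorot("att.W_v", d, d)
            glorot("att.W_o", d, d)

        if config.use_gcn:
            in_dim = d
            for layer in range(config.gcn_layers):
                glorot(f"gcn.{layer}.W", in_dim, config.gcn_dim)
                zeros(f"gcn.{layer}.b", (config.gcn_dim,))
                in_dim = config.gcn_dim

        fd = config.final_dim
        glorot("mlp.W_1", fd, config.mlp_dim)
        zeros("mlp.b_1", (config.mlp_dim,))
        glorot("mlp.W_2", config.mlp_dim, config.mlp_dim)
        zeros("mlp.b_2", (config.mlp_dim,))
        glorot("cls.W_o", config.mlp_dim, 2)
        zeros("cls.b_o", (2,))

    def __getitem__(self, name: str) -> Tensor:
        return self._params[name]

    def __setitem__(self, name: str, value: np.ndarray) -> None:
        self._params[name].data = np.asarray(value, dtype=np.float64)

    def names(self) -> list[str]:
        return list(self._params)

    def tensors(self) -> list[Tensor]:
        return list(self._params.values())

    def set_all_zero(self) -> None:
        for t in self._params.values():
            t.data[:] = 0.0

    def copy_state(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self._params.items()}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            self._params[k].data = v.copy()

    def save(self, path: str) -> None:
        np.savez(path if path.endswith(".npz") else path + ".npz",
                 **{k: v.data for k, v in self._params.items()})
        sidecar = (path[:-4] if path.endswith(".npz") else path) + ".json"
        with open(sidecar, "w") as fh:
            fh.write(self.config.to_json())

    @classmethod
    def load(cls, path: str) -> "ModelParameters":
        base = path[:-4] if path.endswith(".npz") else path
        with open(base + ".json") as fh:
            config = ModelConfig.from_json(fh.read())
        params = cls(config)
        with np.load(base + ".npz") as archive:
            params.load_state({k: archive[k] for k in archive.files})
        return params


# ---------------------------------------------------------------------------
# Result containers (single-instance API)
# ---------------------------------------------------------------------------

@dataclass
class HiddenStates:
    H: np.ndarray                       # n x 2*lstm_dim
    forward_h: np.ndarray               # n x lstm_dim
    backward_h: np.ndarray
    forward_c: np.ndarray
    backward_c: np.ndarray
    forward_gates: dict[str, np.ndarray] = field(default_factory=dict)
    backward_gates: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class AttentionOutput:
    output: np.ndarray                  # n x d_out
    weights: list[np.ndarray]           # one n x n matrix per head


@dataclass
class InstanceRepresentation:
    h_sent: np.ndarray
    h_c: np.ndarray
    h_d: np.ndarray
    h_att: np.ndarray | None
    h_final: np.ndarray
    output: np.ndarray                  # probability 2-vector


# ---------------------------------------------------------------------------
# Batched differentiable building blocks
# ---------------------------------------------------------------------------

@dataclass
class Batch:
    """Padded instance batch; all arrays are plain numpy constants."""

    X: np.ndarray          # (B, T, D) token features, zero padded
    mask: np.ndarray       # (B, T) 1 for real tokens
    A: np.ndarray          # (B, T, T) adjacency (binary, unit diag on real rows)
    deg: np.ndarray        # (B, T, 1) degrees clamped to >= 1
    chem_mask: np.ndarray  # (B, T)
    dis_mask: np.ndarray   # (B, T)
    rev_idx: np.ndarray    # (B, T) per-sequence time-reversal permutation
    labels: np.ndarray | None = None   # (B,)

    @property
    def size(self) -> int:
        return self.X.shape[0]


def _lstm_direction(X: Tensor, params: ModelParameters, direction: str,
                    rev_idx: np.ndarray | None):
    """Run one LSTM direction over (B, T, D); returns ((B,T,H) states, gates)."""
    cfg = params.config
    H = cfg.lstm_dim
    p = lambda n: params[f"lstm.{direction}.{n}"]
    W_all = concat([p(f"W_{g}") for g in _GATES], axis=1)    # D x 4H
    U_all = concat([p(f"U_{g}") for g in _GATES], axis=1)    # H x 4H
    b_all = concat([p(f"b_{g}") for g in _GATES], axis=0)    # 4H

    if rev_idx is not None:
        X = take_along_time(X, rev_idx)
    B, T, _ = X.shape
    xp = ad.unstack_time(matmul(X, W_all))                   # T x (B, 4H)
    h = constant(np.zeros((B, H)))
    c = constant(np.zeros((B, H)))
    hs, cs, gates = [], [], {"f": [], "i": [], "o": [], "g": []}
    for t in range(T):
        z = xp[t] + matmul(h, U_all) + b_all
        f = z[:, 0 * H:1 * H].sigmoid()
        o = z[:, 1 * H:2 * H].sigmoid()
        g = z[:, 2 * H:3 * H].tanh()
        i = z[:, 3 * H:4 * H].sigmoid()
        c = f * c + i * g
        h = o * c.tanh()
        hs.append(h)
        cs.append(c)
        for name, val in (("f", f), ("i", i), ("o", o), ("g", g)):
            gates[name].append(val)
    seq = stack(hs, axis=1)
    cseq = stack(cs, axis=1)
    if rev_idx is not None:
        seq = take_along_time(seq, rev_idx)
        cseq = take_along_time(cseq, rev_idx)
    return seq, cseq, gates


def bilstm_batch(X: Tensor, rev_idx: np.ndarray, params: ModelParameters):
    """BiLSTM over a padded batch; reversal indices keep padding in place so
    the backward direction consumes real tokens first."""
    fw, fw_c, fw_g = _lstm_direction(X, params, "fw", None)
    bw, bw_c, bw_g = _lstm_direction(X, params, "bw", rev_idx)
    return concat([fw, bw], axis=-1), (fw, fw_c, fw_g), (bw, bw_c, bw_g)


def _masked_scores(scores: Tensor, mask: np.ndarray | None,
                   extra_dims: int) -> Tensor:
    if mask is None:
        return scores
    shape = (mask.shape[0],) + (1,) * extra_dims + (mask.shape[1],)
    return scores + constant((mask.reshape(shape) - 1.0) * _BIG)


def attention_batch(H: Tensor, mask: np.ndarray | None,
                    params: ModelParameters):
    """Self-attention over (B, T, d); returns (output, weights tensor)."""
    cfg = params.config
    kind = cfg.attention_kind
    d = cfg.bilstm_out_dim
    if kind is AttentionKind.NONE:
        raise ValueError("attention_kind is none")
    if kind is AttentionKind.SCALED_DOT:
        scores = matmul(H, H.swap_last()) * (1.0 / np.sqrt(d))
        weights = softmax(_masked_scores(scores, mask, 1), axis=-1)
        return matmul(weights, H), weights
    if kind is AttentionKind.GENERAL:
        scores = matmul(matmul(H, params["att.W_1"]), H.swap_last())
        weights = softmax(_masked_scores(scores, mask, 1), axis=-1)
        return matmul(weights, H), weights
    if kind is AttentionKind.ADDITIVE:
        B, T, _ = H.shape
        a = matmul(H, params["att.W_1"]).reshape(B, T, 1, d)
        b = matmul(H, params["att.W_2"]).reshape(B, 1, T, d)
        scores = matmul((a + b).tanh(), params["att.v"]).reshape(B, T, T)
        weights = softmax(_masked_scores(scores, mask, 1), axis=-1)
        return matmul(weights, H), weights
    # multihead
    h = cfg.n_heads
    dh = d // h
    B, T, _ = H.shape

    def heads(name):
        return (matmul(H, params[name]).reshape(B, T, h, dh)
                .transpose(0, 2, 1, 3))                      # B x h x T x dh

    Q, K, V = heads("att.W_q"), heads("att.W_k"), heads("att.W_v")
    scores = matmul(Q, K.swap_last()) * (1.0 / np.sqrt(dh))  # B x h x T x T
    weights = softmax(_masked_scores(scores, mask, 2), axis=-1)
    ctx = matmul(weights, V)                                 # B x h x T x dh
    ctx = ctx.transpose(0, 2, 1, 3).reshape(B, T, d)
    return matmul(ctx, params["att.W_o"]), weights


def gcn_layer_batch(H: Tensor, A: np.ndarray, deg: np.ndarray,
                    W: Tensor, b: Tensor) -> Tensor:
    """h_i = relu( (1/d_i) sum_j A_ij (W h_j) + b ), batched."""
    return ((matmul(constant(A), matmul(H, W)) * (1.0 / deg)) + b).relu()


def _masked_max(H: Tensor, mask: np.ndarray) -> Tensor:
    gate = constant((mask[:, :, None] - 1.0) * _BIG)
    return (H + gate).max(axis=1)


def _dropout(t: Tensor, p: float, rng: np.random.Generator | None) -> Tensor:
    if rng is None or p <= 0.0:
        return t
    keep = (rng.random(t.shape) >= p) / (1.0 - p)
    return t * constant(keep)


def forward_batch(params: ModelParameters, batch: Batch,
                  train: bool = False,
                  dropout_rng: np.random.Generator | None = None) -> dict:
    """Full forward pass over a padded batch.

    Returns a dict with the logits tensor and the probability matrix;
    dropout is applied only when ``train`` is true.
    """
    cfg = params.config
    rng = dropout_rng if train else None
    X = constant(batch.X)
    H, _, _ = bilstm_batch(X, batch.rev_idx, params)
    H = _dropout(H, cfg.dropout, rng)

    parts: list[Tensor] = []
    if cfg.use_gcn:
        G = H
        for layer in range(cfg.gcn_layers):
            G = gcn_layer_batch(G, batch.A, batch.deg,
                                params[f"gcn.{layer}.W"],
                                params[f"gcn.{layer}.b"])
            G = _dropout(G, cfg.dropout, rng)
        parts.append(_masked_max(G, batch.mask))       # h_sent
        parts.append(_masked_max(G, batch.chem_mask))  # h_c
        parts.append(_masked_max(G, batch.dis_mask))   # h_d
    if cfg.attention_kind is not AttentionKind.NONE:
        att_out, _ = attention_batch(H, batch.mask, params)
        parts.append(_masked_max(att_out, batch.mask))  # h_att

    h_final = concat(parts, axis=-1)
    h_1 = (matmul(h_final, params["mlp.W_1"]) + params["mlp.b_1"]).relu()
    h_1 = _dropout(h_1, cfg.dropout, rng)
    h_2 = (matmul(h_1, params["mlp.W_2"]) + params["mlp.b_2"]).relu()
    logits = matmul(h_2, params["cls.W_o"]) + params["cls.b_o"]
    probs = ad.softmax(logits, axis=-1)
    return {"logits": logits, "probs": probs.data, "h_final": h_final}


def batch_loss(params: ModelParameters, batch: Batch,
               train: bool = True,
               dropout_rng: np.random.Generator | None = None) -> Tensor:
    """Mean cross-entropy over the batch labels."""
    if batch.labels is None:
        raise ValueError("batch carries no labels")
    out = forward_batch(params, batch, train=train, dropout_rng=dropout_rng)
    ls = ad.log_softmax(out["logits"], axis=-1)
    onehot = np.zeros((batch.size, 2))
    onehot[np.arange(batch.size), batch.labels] = 1.0
    return -(ls * constant(onehot)).sum() * (1.0 / batch.size)


# ---------------------------------------------------------------------------
# Single-instance operations (spec-level API, numpy in / numpy out)
# ---------------------------------------------------------------------------

def _single_batch(n: int) -> tuple[np.ndarray, np.ndarray]:
    mask = np.ones((1, n))
    rev = np.arange(n)[::-1].copy()[None, :]
    return mask, rev


def bilstm_forward(X: np.ndarray, params: ModelParameters) -> HiddenStates:
    """Encode one token feature matrix (n x input_dim) with the BiLSTM."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("X must be a non-empty n x input_dim matrix")
    if X.shape[1] != params.config.input_dim:
        raise ValueError(
            f"input width {X.shape[1]} != configured {params.config.input_dim}"
        )
    _, rev = _single_batch(X.shape[0])
    Xt = constant(X[None])
    H, (fw, fw_c, fw_g), (bw, bw_c, bw_g) = bilstm_batch(Xt, rev, params)

    def gate_mat(gates, reverse):
        out = {}
        for name, steps in gates.items():
            mat = np.stack([s.data[0] for s in steps])
            out[name] = mat[::-1].copy() if reverse else mat
        return out

    return HiddenStates(
        H=H.data[0],
        forward_h=fw.data[0],
        backward_h=bw.data[0],
        forward_c=fw_c.data[0],
        backward_c=bw_c.data[0],
        forward_gates=gate_mat(fw_g, reverse=False),
        backward_gates=gate_mat(bw_g, reverse=True),
    )


def attention(H: np.ndarray, kind: AttentionKind | str,
              params: ModelParameters) -> AttentionOutput:
    """Self-attention over one sequence (n x d)."""
    kind = AttentionKind(kind)
    if kind != params.config.attention_kind:
        raise ValueError(
            f"parameters were built for {params.config.attention_kind}, "
            f"requested {kind}"
        )
    out, weights = attention_batch(constant(np.asarray(H)[None]), None, params)
    w = weights.data
    if w.ndim == 4:
        head_weights = [w[0, i] for i in range(w.shape[1])]
    else:
        head_weights = [w[0]]
    return AttentionOutput(output=out.data[0], weights=head_weights)


def gcn_layer(H_in: np.ndarray, A: np.ndarray, W: np.ndarray, b: np.ndarray,
              rho=None) -> np.ndarray:
    """One graph convolution: h_i = rho((1/d_i) sum_j A_ij (W h_j) + b)."""
    A = np.asarray(A, dtype=np.float64)
    H_in = np.asarray(H_in, dtype=np.float64)
    if A.shape[0] != A.shape[1] or A.shape[0] != H_in.shape[0]:
        raise ValueError("A and H_in dimensions disagree")
    if not np.allclose(A, A.T):
        raise ValueError("adjacency must be symmetric")
    if not np.allclose(np.diag(A), 1.0):
        raise ValueError("adjacency must have a unit diagonal")
    deg = A.sum(axis=1, keepdims=True)
    pre = (A @ (H_in @ W)) / deg + b
    if rho is None:
        rho = lambda x: np.maximum(x, 0.0)
    return rho(pre)


def gcn_stack(H0: np.ndarray, A: np.ndarray, params: ModelParameters,
              L: int | None = None) -> np.ndarray:
    """L sequential graph convolutions with rectifier activations."""
    cfg = params.config
    L = cfg.gcn_layers if L is None else L
    if L < 1:
        raise ValueError("L must be >= 1")
    if L > cfg.gcn_layers:
        raise ValueError(f"parameters only hold {cfg.gcn_layers} GCN layers")
    H = np.asarray(H0, dtype=np.float64)
    for layer in range(L):
        H = gcn_layer(H, A, params[f"gcn.{layer}.W"].data,
                      params[f"gcn.{layer}.b"].data)
    return H


def pool_and_represent(H_L: np.ndarray, H_att: np.ndarray | None,
                       chem_span: tuple[int, int], dis_span: tuple[int, int],
                       params: ModelParameters | None = None
                       ) -> InstanceRepresentation:
    """Columnwise max-pooling into h_sent / h_c / h_d (+ h_att), then the
    classifier if parameters are supplied."""
    H_L = np.asarray(H_L, dtype=np.float64)
    n = H_L.shape[0]
    for name, (s, e) in (("chemical", chem_span), ("disease", dis_span)):
        if not (0 <= s <= e < n):
            raise ValueError(f"{name} span {(s, e)} out of range for n={n}")
    h_sent = H_L.max(axis=0)
    h_c = H_L[chem_span[0]:chem_span[1] + 1].max(axis=0)
    h_d = H_L[dis_span[0]:dis_span[1] + 1].max(axis=0)
    h_gcn = np.concatenate([h_sent, h_c, h_d])
    h_att = None if H_att is None else np.asarray(H_att).max(axis=0)
    h_final = h_gcn if h_att is None else np.concatenate([h_gcn, h_att])
    output = (classify(h_final, params) if params is not None
              else np.full(2, 0.5))
    return InstanceRepresentation(h_sent=h_sent, h_c=h_c, h_d=h_d,
                                 h_att=h_att, h_final=h_final, output=output)


def classify(h_final: np.ndarray, params: ModelParameters) -> np.ndarray:
    """Two affine+rectifier layers and a softmax over the two classes."""
    h_final = np.asarray(h_final, dtype=np.float64)
    if h_final.shape[-1] != params.config.final_dim:
        raise ValueError(
            f"h_final width {h_final.shape[-1]} != {params.config.final_dim}"
        )
    h_1 = np.maximum(h_final @ params["mlp.W_1"].data + params["mlp.b_1"].data, 0.0)
    h_2 = np.maximum(h_1 @ params["mlp.W_2"].data + params["mlp.b_2"].data, 0.0)
    logits = h_2 @ params["cls.W_o"].data + params["cls.b_o"].data
    shifted = logits - logits.max()
    e = np.exp(shifted)
    return e / e.sum()
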