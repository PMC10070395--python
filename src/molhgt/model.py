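"""Heterogeneous graph transformer over multi-view molecular graphs.

The model processes each view of a :class:`~molhgt.chemgraph.HeteroMolGraph`
independently and fuses the resulting view vectors:

1. *Initial embedding.* Each node attends over a typed context — itself plus
   its incoming edges — and each edge over itself plus its two endpoints.
   Attention is multi-head; within one head the per-type results are mixed by
   a learnable type matrix Omega and summed, so node and edge types with
   different feature dimensions coexist (this is what makes the graph
   heterogeneous). Scores are scaled by 1/sqrt(d_k), d_k = d / n_heads.
2. *Message passing* of depth T. The first step seeds node messages with the
   sum of incoming edge hiddens and edge messages with the source-node
   hidden. Later steps score each incoming edge message against the node
   query; edge messages are an affine map of
   ``M_E^1 + H^t(source) - H^{t-1}(reverse edge)``, subtracting the reverse
   direction as directed edge-message schemes do. Every step ends with a
   residual update ``H^t = H^{t-1} + M^t``.
3. *Readout and fusion.* A GRU consumes each view's node hiddens in
   canonical order; the final hidden state is the view vector Z_p. The
   pharm vector gates the junction vector, whose result gates the atom
   vector (``readout_attention``), yielding the molecule embedding Z fed to
   a linear prediction head.

All computation runs on :class:`molhgt.autodiff.Tensor`, so a scalar loss on
the predictions backpropagates into every parameter.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor, concat, gather_rows, segment_sum
from .chemgraph import (
    ATOM_FDIM,
    BOND_FDIM,
    FRAG_FDIM,
    JUNCTION_FDIM,
    REACTION_FDIM,
    HeteroMolGraph,
    ViewGraph,
)
from .nn import dropout, glorot_uniform, gru_sequence, init_gru, iter_params, zeros

__all__ = [
    "ModelConfig",
    "ViewEmbedding",
    "MessageState",
    "VARIANT_VIEWS",
    "multi_view_attention",
    "compile_view",
    "compile_graph",
    "init_params",
    "embed_initial",
    "message_passing_step",
    "view_readout",
    "readout_attention",
    "fuse_views",
    "predict",
    "forward",
    "save_checkpoint",
    "load_checkpoint",
    "FEATURIZER_TAG",
]

#: dimensional signature of the featurizers baked into a checkpoint
FEATURIZER_TAG = f"atom{ATOM_FDIM}-bond{BOND_FDIM}-frag{FRAG_FDIM}-rxn{REACTION_FDIM}"

#: view set required by each fusion variant (the seven ablations + full model)
VARIANT_VIEWS: dict[str, frozenset[str]] = {
    "full": frozenset({"alpha", "beta", "gamma"}),
    "alpha": frozenset({"alpha"}),
    "beta": frozenset({"beta"}),
    "gamma": frozenset({"gamma"}),
    "beta_alpha": frozenset({"alpha", "beta"}),
    "gamma_alpha": frozenset({"alpha", "gamma"}),
    "beta_gamma": frozenset({"beta", "gamma"}),
    "gamma_alpha_beta": frozenset({"alpha", "beta", "gamma"}),
}

_VIEW_SPECS = {
    "alpha": {"node_types": ("atom",), "edge_type": "bond", "dv": ATOM_FDIM, "de": BOND_FDIM},
    "beta": {"node_types": ("pharm",), "edge_type": "reaction", "dv": FRAG_FDIM, "de": REACTION_FDIM},
    "gamma": {
        "node_types": ("atom", "pharm"),
        "edge_type": "junction",
        "dv": max(ATOM_FDIM, FRAG_FDIM),
        "de": JUNCTION_FDIM,
    },
}


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the graph transformer.

    ``hidden_dim`` (d) must be divisible by ``num_heads`` (n); ``depth`` (T)
    counts message-passing steps including the initial aggregation step.
    ``sigma`` picks the attention-score normalization (softmax over present
    keys, or elementwise sigmoid); ``value_source`` picks the value operand
    of the step attention (the node's own hidden state — the literal model —
    or the incoming edge messages).
    """

    hidden_dim: int = 300
    num_heads: int = 4
    depth: int = 3
    dropout: float = 0.1
    sigma: str = "softmax"
    value_source: str = "node"
    views_enabled: tuple[str, ...] = ("alpha", "beta", "gamma")
    fusion_variant: str = "full"
    junction_membership: str = "all"
    seed: int = 0

    def __post_init__(self):
        if self.hidden_dim % self.num_heads:
            raise ValueError("hidden_dim must be divisible by num_heads")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.sigma not in ("softmax", "sigmoid"):
            raise ValueError("sigma must be 'softmax' or 'sigmoid'")
        if self.value_source not in ("node", "message"):
            raise ValueError("value_source must be 'node' or 'message'")
        if self.fusion_variant not in VARIANT_VIEWS:
            raise ValueError(
                f"unknown fusion_variant {self.fusion_variant!r}; "
                f"valid: {sorted(VARIANT_VIEWS)}"
            )
        missing = VARIANT_VIEWS[self.fusion_variant] - set(self.views_enabled)
        if missing:
            raise ValueError(
                f"fusion_variant {self.fusion_variant!r} needs views {sorted(missing)} "
                f"but views_enabled={self.views_enabled}"
            )

    @property
    def d_k(self) -> int:
        return self.hidden_dim // self.num_heads


@dataclass
class ViewEmbedding:
    """Per-view molecule vectors and their fusion."""

    Z_alpha: Tensor | None = None
    Z_beta: Tensor | None = None
    Z_gamma: Tensor | None = None
    Z_gamma_beta: Tensor | None = None
    Z: Tensor | None = None

    def get(self, tag: str) -> Tensor | None:
        return {"alpha": self.Z_alpha, "beta": self.Z_beta, "gamma": self.Z_gamma}[tag]


@dataclass
class MessageState:
    """Hidden states and messages of one view during propagation.

    ``t`` counts completed message-passing steps: 0 right after the initial
    embedding, up to ``depth`` when propagation is finished.
    """

    H_V: Tensor
    H_E: Tensor
    M_V: Tensor | None
    M_E: Tensor | None
    M_E_1: Tensor | None
    t: int


# ---------------------------------------------------------------------------
# compiled graph arrays
# ---------------------------------------------------------------------------


class CompiledView:
    """Index arrays and constant feature tensors for one view."""

    def __init__(self, view: ViewGraph):
        self.view_tag = view.view_tag
        self.n_nodes = view.n_nodes
        self.n_edges = view.n_edges
        self.X_v = Tensor(view.node_features)
        self.X_e = Tensor(view.edge_features)
        if view.n_edges:
            edges = np.asarray(view.directed_edges, dtype=np.intp)
            self.src, self.tgt = edges[:, 0], edges[:, 1]
        else:
            self.src = np.zeros(0, dtype=np.intp)
            self.tgt = np.zeros(0, dtype=np.intp)
        self.rev = np.asarray(view.reverse_index, dtype=np.intp)
        types = np.asarray(view.node_types)
        self.node_groups = {
            t: np.flatnonzero(types == t) for t in _VIEW_SPECS[view.view_tag]["node_types"]
        }
        # endpoint keys of each directed edge, grouped by endpoint node type
        self.endpoint_groups: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        if view.n_edges:
            edge_idx = np.concatenate([np.arange(view.n_edges)] * 2)
            node_idx = np.concatenate([self.src, self.tgt])
            ntype = types[node_idx]
            for t in _VIEW_SPECS[view.view_tag]["node_types"]:
                sel = ntype == t
                self.endpoint_groups[t] = (edge_idx[sel], node_idx[sel])


class CompiledGraph:
    def __init__(self, graph: HeteroMolGraph):
        self.graph = graph
        self.views = {
            tag: CompiledView(graph.view(tag)) for tag in ("alpha", "beta", "gamma")
        }


def compile_view(view: ViewGraph) -> CompiledView:
    return CompiledView(view)


def compile_graph(graph: HeteroMolGraph) -> CompiledGraph:
    return CompiledGraph(graph)


def _as_compiled_view(view) -> CompiledView:
    return view if isinstance(view, CompiledView) else CompiledView(view)


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


def _omega_stack(rng, n_heads: int, d_k: int) -> dict:
    return {f"h{h}": glorot_uniform(rng, (d_k, d_k)) for h in range(n_heads)}


def init_params(config: ModelConfig, n_tasks: int) -> dict:
    """Reproducibly initialize all parameters for a configuration.

    All three views are always allocated (disabled views simply go unused),
    so parameter trees are comparable across ablation variants.
    """
    rng = np.random.default_rng(config.seed)
    d, n, dk = config.hidden_dim, config.num_heads, config.d_k
    views: dict = {}
    for tag in ("alpha", "beta", "gamma"):
        spec = _VIEW_SPECS[tag]
        dv, de = spec["dv"], spec["de"]
        node_self = {
            t: {"W_V": glorot_uniform(rng, (dv, d)), "Omega": _omega_stack(rng, n, dk)}
            for t in spec["node_types"]
        }
        edge_ctx = {
            "W_Q": glorot_uniform(rng, (dv, d)),
            "W_K": glorot_uniform(rng, (de, d)),
            "W_V": glorot_uniform(rng, (de, d)),
            "Omega": _omega_stack(rng, n, dk),
        }
        node_ctx = {
            t: {
                "W_Q": glorot_uniform(rng, (de, d)),
                "W_K": glorot_uniform(rng, (dv, d)),
                "W_V": glorot_uniform(rng, (dv, d)),
                "Omega": _omega_stack(rng, n, dk),
            }
            for t in spec["node_types"]
        }
        views[tag] = {
            "embed": {
                "node": {"self": node_self, "edge_ctx": edge_ctx, "W_o": glorot_uniform(rng, (d, d))},
                "edge": {
                    "self": {"W_V": glorot_uniform(rng, (de, d)), "Omega": _omega_stack(rng, n, dk)},
                    "node_ctx": node_ctx,
                    "W_o": glorot_uniform(rng, (d, d)),
                },
            },
            "step": {
                "W_Q": glorot_uniform(rng, (d, d)),
                "W_K": glorot_uniform(rng, (d, d)),
                "W_V": glorot_uniform(rng, (d, d)),
                "Omega": _omega_stack(rng, n, dk),
                "W_lin": glorot_uniform(rng, (d, d)),
                "b_lin": zeros((1, d)),
            },
            "gru": init_gru(rng, d, d),
        }
    return {
        "views": views,
        "head": {"W": glorot_uniform(rng, (d, n_tasks)), "b": zeros((1, n_tasks))},
    }


# ---------------------------------------------------------------------------
# attention kernels
# ---------------------------------------------------------------------------


def multi_view_attention(Q_by_type, K_by_type, V_by_type, Omega_by_type, d_k: int,
                         sigma: str = "softmax") -> Tensor:
    """Typed attention: sum over types p of ``sigma(Q^p K^pT / sqrt(d_k)) V^p Omega^p``.

    With ``sigma="softmax"`` the normalization is row-wise over the keys of
    each type, so each query's weights over present type-p keys sum to 1;
    a type with an empty key set contributes a zero matrix.
    """
    out: Tensor | None = None
    n_queries = None
    for p in Q_by_type:
        Q = as_tensor(Q_by_type[p])
        K = as_tensor(K_by_type[p])
        V = as_tensor(V_by_type[p])
        Om = as_tensor(Omega_by_type[p])
        if Q.shape[1] != K.shape[1]:
            raise ValueError(f"type {p!r}: query width {Q.shape[1]} != key width {K.shape[1]}")
        if K.shape[0] != V.shape[0]:
            raise ValueError(f"type {p!r}: {K.shape[0]} keys but {V.shape[0]} values")
        if V.shape[1] != Om.shape[0]:
            raise ValueError(f"type {p!r}: value width {V.shape[1]} != Omega rows {Om.shape[0]}")
        n_queries = Q.shape[0]
        if K.shape[0] == 0:
            continue
        scores = (Q @ K.T) / math.sqrt(d_k)
        if sigma == "softmax":
            shifted = (scores - scores.data.max(axis=1, keepdims=True)).exp()
            weights = shifted / shifted.sum(axis=1, keepdims=True)
        else:
            weights = scores.sigmoid()
        contrib = (weights @ V) @ Om
        out = contrib if out is None else out + contrib
    if out is None:
        width = next(iter(Omega_by_type.values())).shape[1] if Omega_by_type else d_k
        return Tensor(np.zeros((n_queries or 0, width)))
    return out


def _segment_softmax(scores: Tensor, segments: np.ndarray, num_segments: int) -> Tensor:
    """Softmax of a flat score vector within segments (stable, autodiff-safe)."""
    shift = np.full(num_segments, -np.inf)
    np.maximum.at(shift, segments, scores.data)
    e = (scores - Tensor(shift[segments])).exp()
    denom = segment_sum(e, segments, num_segments)
    return e / gather_rows(denom, segments)


def _edge_scores(q_rows: Tensor, k_rows: Tensor, d_k: int) -> Tensor:
    return (q_rows * k_rows).sum(axis=1) / math.sqrt(d_k)


# ---------------------------------------------------------------------------
# initial embedding
# ---------------------------------------------------------------------------


def _embed_nodes(cv: CompiledView, p_node: dict, config: ModelConfig) -> Tensor:
    n, dk = config.num_heads, config.d_k
    N, M = cv.n_nodes, cv.n_edges
    # full-width projections once; the head loop slices columns
    self_proj = []
    for t, idx in cv.node_groups.items():
        if idx.size == 0:
            continue
        x = cv.X_v if idx.size == N else gather_rows(cv.X_v, idx)
        self_proj.append((t, idx, x @ p_node["self"][t]["W_V"]))
    if M:
        pe = p_node["edge_ctx"]
        Qf, Kf, Vf = cv.X_v @ pe["W_Q"], cv.X_e @ pe["W_K"], cv.X_e @ pe["W_V"]
    heads = []
    for h in range(n):
        cols = slice(h * dk, (h + 1) * dk)
        head = None
        # self context: singleton per node, attention weight identically 1
        for t, idx, proj in self_proj:
            contrib = proj[:, cols] @ p_node["self"][t]["Omega"][f"h{h}"]
            scattered = contrib if idx.size == N else segment_sum(contrib, idx, N)
            head = scattered if head is None else head + scattered
        # incoming-edge context
        if M:
            s = _edge_scores(gather_rows(Qf[:, cols], cv.tgt), Kf[:, cols], dk)
            if config.sigma == "softmax":
                w = _segment_softmax(s, cv.tgt, N)
            else:
                w = s.sigmoid()
            contrib = segment_sum(w.reshape(-1, 1) * Vf[:, cols], cv.tgt, N)
            contrib = contrib @ pe["Omega"][f"h{h}"]
            head = contrib if head is None else head + contrib
        heads.append(head if head is not None else Tensor(np.zeros((N, dk))))
    return concat(heads, axis=1) @ p_node["W_o"]


def _embed_edges(cv: CompiledView, p_edge: dict, config: ModelConfig) -> Tensor:
    n, dk, d = config.num_heads, config.d_k, config.hidden_dim
    M = cv.n_edges
    if M == 0:
        return Tensor(np.zeros((0, d)))
    self_proj = cv.X_e @ p_edge["self"]["W_V"]
    ctx_proj = []
    for t, (edge_idx, node_idx) in cv.endpoint_groups.items():
        if edge_idx.size == 0:
            continue
        pt = p_edge["node_ctx"][t]
        ctx_proj.append(
            (pt, edge_idx, node_idx,
             cv.X_e @ pt["W_Q"], cv.X_v @ pt["W_K"], cv.X_v @ pt["W_V"])
        )
    heads = []
    for h in range(n):
        cols = slice(h * dk, (h + 1) * dk)
        head = self_proj[:, cols] @ p_edge["self"]["Omega"][f"h{h}"]
        for pt, edge_idx, node_idx, Qf, Kf, Vf in ctx_proj:
            s = _edge_scores(
                gather_rows(Qf[:, cols], edge_idx), gather_rows(Kf[:, cols], node_idx), dk
            )
            if config.sigma == "softmax":
                w = _segment_softmax(s, edge_idx, M)
            else:
                w = s.sigmoid()
            contrib = segment_sum(
                w.reshape(-1, 1) * gather_rows(Vf[:, cols], node_idx), edge_idx, M
            )
            head = head + contrib @ pt["Omega"][f"h{h}"]
        heads.append(head)
    return concat(heads, axis=1) @ p_edge["W_o"]


def embed_initial(view, view_params: dict, config: ModelConfig,
                  training: bool = False, rng: np.random.Generator | None = None) -> MessageState:
    """Typed multi-head attention embedding of a view's nodes and edges.

    Each node attends over itself and its incoming edges; each edge over
    itself and its two endpoints, with type-specific projections and per-head
    Omega type mixing. Returns the state holding H(X_V) (N, d) and H(X_E)
    (M, d) with the step counter at 0.
    """
    cv = _as_compiled_view(view)
    H_V = _embed_nodes(cv, view_params["embed"]["node"], config)
    H_E = _embed_edges(cv, view_params["embed"]["edge"], config)
    if training and rng is not None:
        H_V = dropout(H_V, config.dropout, rng, training)
        if cv.n_edges:
            H_E = dropout(H_E, config.dropout, rng, training)
    return MessageState(H_V=H_V, H_E=H_E, M_V=None, M_E=None, M_E_1=None, t=0)


# ---------------------------------------------------------------------------
# message passing
# ---------------------------------------------------------------------------


def message_passing_step(state: MessageState, view, view_params: dict, config: ModelConfig,
                         training: bool = False,
                         rng: np.random.Generator | None = None) -> MessageState:
    """One propagation step with residual updates.

    Step 1 seeds messages: nodes sum their incoming edge hiddens, each edge
    takes its source node's hidden. Later steps attend node queries over the
    incoming edge messages and map edge messages through the affine
    ``M_E^1 + H^t(source) - H^{t-1}(reverse)`` update. Both hidden matrices
    then receive the residual ``H^t = H^{t-1} + M^t``.
    """
    if state.t >= config.depth:
        raise RuntimeError(f"propagation already at depth {state.t} = configured depth")
    cv = _as_compiled_view(view)
    p = view_params["step"]
    N, M = cv.n_nodes, cv.n_edges
    d, n, dk = config.hidden_dim, config.num_heads, config.d_k
    t_next = state.t + 1

    if t_next == 1:
        M_V = segment_sum(state.H_E, cv.tgt, N) if M else Tensor(np.zeros((N, d)))
        M_E = gather_rows(state.H_V, cv.src) if M else Tensor(np.zeros((0, d)))
        if training and rng is not None:
            M_V = dropout(M_V, config.dropout, rng, training)
            if M:
                M_E = dropout(M_E, config.dropout, rng, training)
        H_V = state.H_V + M_V
        H_E = state.H_E + M_E
        return MessageState(H_V=H_V, H_E=H_E, M_V=M_V, M_E=M_E, M_E_1=M_E, t=1)

    # node messages: attention of the node query over incoming edge messages
    if M:
        q_full = state.H_V @ p["W_Q"]
        k_full = state.M_E @ p["W_K"]
        v_full = (state.H_V if config.value_source == "node" else state.M_E) @ p["W_V"]
        heads = []
        for h in range(n):
            cols = slice(h * dk, (h + 1) * dk)
            s = _edge_scores(gather_rows(q_full[:, cols], cv.tgt), k_full[:, cols], dk)
            if config.sigma == "softmax":
                w = _segment_softmax(s, cv.tgt, N)
            else:
                w = s.sigmoid()
            if config.value_source == "node":
                weighted = w.reshape(-1, 1) * gather_rows(v_full[:, cols], cv.tgt)
            else:
                weighted = w.reshape(-1, 1) * v_full[:, cols]
            heads.append(segment_sum(weighted, cv.tgt, N) @ p["Omega"][f"h{h}"])
        M_V = concat(heads, axis=1)
    else:
        M_V = Tensor(np.zeros((N, d)))
    if training and rng is not None:
        M_V = dropout(M_V, config.dropout, rng, training)
    H_V = state.H_V + M_V

    if M:
        inner = state.M_E_1 + gather_rows(H_V, cv.src) - gather_rows(state.H_E, cv.rev)
        M_E = inner @ p["W_lin"] + p["b_lin"]
        if training and rng is not None:
            M_E = dropout(M_E, config.dropout, rng, training)
        H_E = state.H_E + M_E
    else:
        M_E = Tensor(np.zeros((0, d)))
        H_E = state.H_E
    new = MessageState(H_V=H_V, H_E=H_E, M_V=M_V, M_E=M_E, M_E_1=state.M_E_1, t=t_next)
    _check_finite(new)
    return new


def _check_finite(state: MessageState) -> None:
    for name in ("H_V", "H_E"):
        data = getattr(state, name).data
        if data.size and not np.all(np.isfinite(data)):
            raise FloatingPointError(f"non-finite values in {name} at step t={state.t}")


# ---------------------------------------------------------------------------
# readout, fusion, prediction
# ---------------------------------------------------------------------------


def view_readout(state: MessageState, view, gru_params: dict) -> Tensor:
    """GRU over the view's node hiddens in canonical order; final hidden is Z_p.

    Canonical order is the node index order of the view: atoms by canonical
    index, fragments by smallest member atom, junction nodes atoms-first.
    """
    cv = _as_compiled_view(view)
    if cv.n_nodes == 0:
        raise ValueError("cannot read out an empty view")
    return gru_sequence(gru_params, state.H_V)


def readout_attention(X: Tensor, Y: Tensor, d_k: int) -> Tensor:
    """Scalar-gated fusion: ``sigmoid(X . Y / sqrt(d_k)) * X`` for (1, d) rows."""
    X, Y = as_tensor(X), as_tensor(Y)
    if X.shape != Y.shape:
        raise ValueError(f"shape mismatch in readout attention: {X.shape} vs {Y.shape}")
    gate = ((X * Y).sum() / math.sqrt(d_k)).sigmoid()
    return gate.reshape(1, 1) * X


def fuse_views(emb: ViewEmbedding, config: ModelConfig) -> Tensor:
    """Combine view vectors according to the configured fusion variant."""
    variant = config.fusion_variant
    for tag in VARIANT_VIEWS[variant]:
        if emb.get(tag) is None:
            raise ValueError(f"fusion variant {variant!r} requires view {tag!r}")
    dk = config.d_k
    if variant == "full":
        emb.Z_gamma_beta = readout_attention(emb.Z_gamma, emb.Z_beta, dk)
        emb.Z = readout_attention(emb.Z_alpha, emb.Z_gamma_beta, dk)
    elif variant in ("alpha", "beta", "gamma"):
        emb.Z = emb.get(variant)
    elif variant == "beta_alpha":  # pharm aggregated to atom
        emb.Z = readout_attention(emb.Z_alpha, emb.Z_beta, dk)
    elif variant == "gamma_alpha":  # junction aggregated to atom
        emb.Z = readout_attention(emb.Z_alpha, emb.Z_gamma, dk)
    elif variant == "beta_gamma":  # pharm aggregated to junction
        emb.Z = readout_attention(emb.Z_gamma, emb.Z_beta, dk)
    else:  # gamma_alpha_beta: junction to atom, then to pharm
        emb.Z = readout_attention(emb.Z_beta, readout_attention(emb.Z_alpha, emb.Z_gamma, dk), dk)
    return emb.Z


def predict(Z: Tensor, head_params: dict) -> Tensor:
    """Linear prediction head: one raw score per task (apply sigmoid at
    evaluation time for classification probabilities)."""
    return as_tensor(Z) @ head_params["W"] + head_params["b"]


def forward(graph, params: dict, config: ModelConfig, training: bool = False,
            rng: np.random.Generator | None = None) -> tuple[Tensor, ViewEmbedding]:
    """Full pipeline on one molecule: embed, propagate, read out, fuse, predict.

    ``graph`` may be a :class:`HeteroMolGraph` or a pre-compiled
    :class:`CompiledGraph`. Deterministic for fixed inputs when dropout is
    off (``training=False``).
    """
    compiled = graph if isinstance(graph, CompiledGraph) else compile_graph(graph)
    emb = ViewEmbedding()
    for tag in config.views_enabled:
        cv = compiled.views[tag]
        state = embed_initial(cv, params["views"][tag], config, training, rng)
        for _ in range(config.depth):
            state = message_passing_step(state, cv, params["views"][tag], config, training, rng)
        z = view_readout(state, cv, params["views"][tag]["gru"])
        setattr(emb, f"Z_{tag}", z)
    Z = fuse_views(emb, config)
    if training and rng is not None:
        Z = dropout(Z, config.dropout, rng, training)
    scores = predict(Z, params["head"])
    return scores, emb


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------


def save_checkpoint(path, params: dict, config: ModelConfig, n_tasks: int,
                    meta: dict | None = None) -> None:
    """Single-archive checkpoint: parameter arrays + config + featurizer tag."""
    arrays = {path_: p.data for path_, p in iter_params(params)}
    from dataclasses import asdict

    header = {
        "config": {**asdict(config), "views_enabled": list(config.views_enabled)},
        "n_tasks": n_tasks,
        "featurizer": FEATURIZER_TAG,
        "meta": meta or {},
    }
    np.savez(path, __header__=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path) -> tuple[dict, ModelConfig, int, dict]:
    """Load a checkpoint, verifying featurizer/dimension compatibility."""
    with np.load(path) as archive:
        header = json.loads(bytes(archive["__header__"]).decode())
        arrays = {k: archive[k] for k in archive.files if k != "__header__"}
    if header["featurizer"] != FEATURIZER_TAG:
        raise ValueError(
            f"checkpoint featurizer {header['featurizer']} incompatible with {FEATURIZER_TAG}"
        )
    cfg_dict = dict(header["config"])
    cfg_dict["views_enabled"] = tuple(cfg_dict["views_enabled"])
    config = ModelConfig(**cfg_dict)
    n_tasks = int(header["n_tasks"])
    params = init_params(config, n_tasks)
    for path_, p in iter_params(params):
        stored = arrays.get(path_)
        if stored is None or stored.shape != p.data.shape:
            raise ValueError(f"checkpoint missing or mis-shaped parameter {path_!r}")
        p.data = stored.astype(np.float64)
    return params, config, n_tasks, header["meta"]
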