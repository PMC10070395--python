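"""Independent reference computations used by the test suite.

Everything here is deliberately written with explicit loops and plain NumPy
(or a different RDKit code path) so it shares no code with the package
implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np
from rdkit import Chem
from rdkit.Chem import BRICS
from rdkit.Chem.Scaffolds import MurckoScaffold


# ---------------------------------------------------------------------------
# chemistry oracles
# ---------------------------------------------------------------------------


def brics_partition(smiles: str) -> set[frozenset[int]]:
    """Fragment partition via RDKit's BreakBRICSBonds (dummy atoms appended
    after the original indices, which are preserved)."""
    mol = Chem.MolFromSmiles(smiles)
    n = mol.GetNumAtoms()
    broken = BRICS.BreakBRICSBonds(mol)
    return {
        frozenset(i for i in frag if i < n)
        for frag in Chem.GetMolFrags(broken)
    }


def murcko_groups(smiles_list) -> dict[str, set[int]]:
    """Scaffold grouping via GetScaffoldForMol (not the SMILES helper)."""
    groups: dict[str, set[int]] = {}
    for i, smi in enumerate(smiles_list):
        scaffold = Chem.MolToSmiles(
            MurckoScaffold.GetScaffoldForMol(Chem.MolFromSmiles(smi))
        )
        groups.setdefault(scaffold, set()).add(i)
    return groups


# ---------------------------------------------------------------------------
# metric oracles
# ---------------------------------------------------------------------------


def auc_by_pair_counting(labels, scores) -> float:
    """(concordant + 0.5 * tied) / (n_pos * n_neg), by exhaustive enumeration."""
    labels = list(labels)
    scores = list(scores)
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# attention / network oracles
# ---------------------------------------------------------------------------


def dense_attention(Q_by_type, K_by_type, V_by_type, Omega_by_type, d_k,
                    sigma="softmax") -> np.ndarray:
    """Typed attention by explicit exponentials and row normalization."""
    out = None
    for p, Q in Q_by_type.items():
        Q = np.asarray(Q, dtype=float)
        K = np.asarray(K_by_type[p], dtype=float)
        V = np.asarray(V_by_type[p], dtype=float)
        Om = np.asarray(Omega_by_type[p], dtype=float)
        if out is None:
            out = np.zeros((Q.shape[0], Om.shape[1]))
        if K.shape[0] == 0:
            continue
        for i in range(Q.shape[0]):
            raw = np.array([Q[i] @ K[j] / math.sqrt(d_k) for j in range(K.shape[0])])
            if sigma == "softmax":
                e = np.exp(raw - raw.max())
                w = e / e.sum()
            else:
                w = 1.0 / (1.0 + np.exp(-raw))
            mixed = sum(w[j] * V[j] for j in range(K.shape[0]))
            out[i] += mixed @ Om
    return out


def gru_recurrence(params, inputs) -> np.ndarray:
    """Step-by-step GRU with numpy row vectors; params maps names to arrays."""
    sig = lambda a: 1.0 / (1.0 + np.exp(-a))
    h = np.zeros(params["U_r"].shape[0])
    for x in np.asarray(inputs, dtype=float):
        r = sig(x @ params["W_r"] + h @ params["U_r"] + params["b_r"].ravel())
        z = sig(x @ params["W_z"] + h @ params["U_z"] + params["b_z"].ravel())
        n = np.tanh(x @ params["W_n"] + params["b_n"].ravel()
                    + r * (h @ params["U_n"] + params["b_hn"].ravel()))
        h = (1.0 - z) * n + z * h
    return h


def _softmax_groups(scores: dict[int, float]) -> dict[int, float]:
    vals = np.array(list(scores.values()))
    e = np.exp(vals - vals.max())
    w = e / e.sum()
    return dict(zip(scores.keys(), w))


def _p(params, *path):
    node = params
    for key in path:
        node = node[key]
    return np.asarray(node.data if hasattr(node, "data") else node, dtype=float)


def unrolled_forward(graph, params, config) -> tuple[np.ndarray, np.ndarray]:
    """Fully unrolled scalar-arithmetic forward pass for one molecule.

    Recomputes — with per-node/per-edge Python loops — the initial typed
    attention embedding, ``depth`` message-passing steps (first-step seeding,
    later-step attention over incoming edge messages, the reverse-edge edge
    update, residuals), the GRU readout per view, the gated fusion chain and
    the linear head. Returns ``(scores, Z)`` as plain arrays.
    """
    d, n, dk = config.hidden_dim, config.num_heads, config.d_k
    Z_views: dict[str, np.ndarray] = {}
    for tag in config.views_enabled:
        view = graph.view(tag)
        vp = params["views"][tag]
        N, M = view.n_nodes, view.n_edges
        X_v = np.asarray(view.node_features, dtype=float)
        X_e = np.asarray(view.edge_features, dtype=float)
        edges = list(view.directed_edges)
        rev = list(view.reverse_index)
        ntypes = list(view.node_types)

        # ---- initial embedding: nodes
        H_V = np.zeros((N, d))
        for i in range(N):
            head_parts = []
            for h in range(n):
                cols = slice(h * dk, (h + 1) * dk)
                pv = vp["embed"]["node"]["self"][ntypes[i]]
                acc = (X_v[i] @ _p(pv, "W_V")[:, cols]) @ _p(pv, "Omega", f"h{h}")
                incoming = [e for e, (s, t) in enumerate(edges) if t == i]
                if incoming:
                    pe = vp["embed"]["node"]["edge_ctx"]
                    q = X_v[i] @ _p(pe, "W_Q")[:, cols]
                    raw = {
                        e: q @ (X_e[e] @ _p(pe, "W_K")[:, cols]) / math.sqrt(dk)
                        for e in incoming
                    }
                    if config.sigma == "softmax":
                        w = _softmax_groups(raw)
                    else:
                        w = {e: 1.0 / (1.0 + np.exp(-v)) for e, v in raw.items()}
                    mix = sum(
                        w[e] * (X_e[e] @ _p(pe, "W_V")[:, cols]) for e in incoming
                    )
                    acc = acc + mix @ _p(pe, "Omega", f"h{h}")
                head_parts.append(acc)
            H_V[i] = np.concatenate(head_parts) @ _p(vp, "embed", "node", "W_o")

        # ---- initial embedding: edges
        H_E = np.zeros((M, d))
        for e, (u, v) in enumerate(edges):
            head_parts = []
            for h in range(n):
                cols = slice(h * dk, (h + 1) * dk)
                ps = vp["embed"]["edge"]["self"]
                acc = (X_e[e] @ _p(ps, "W_V")[:, cols]) @ _p(ps, "Omega", f"h{h}")
                by_type: dict[str, list[int]] = {}
                for node in (u, v):
                    by_type.setdefault(ntypes[node], []).append(node)
                for t, nodes in by_type.items():
                    pt = vp["embed"]["edge"]["node_ctx"][t]
                    q = X_e[e] @ _p(pt, "W_Q")[:, cols]
                    raw = {
                        j: q @ (X_v[j] @ _p(pt, "W_K")[:, cols]) / math.sqrt(dk)
                        for j in nodes
                    }
                    if config.sigma == "softmax":
                        w = _softmax_groups(raw)
                    else:
                        w = {j: 1.0 / (1.0 + np.exp(-val)) for j, val in raw.items()}
                    mix = sum(w[j] * (X_v[j] @ _p(pt, "W_V")[:, cols]) for j in nodes)
                    acc = acc + mix @ _p(pt, "Omega", f"h{h}")
                head_parts.append(acc)
            H_E[e] = np.concatenate(head_parts) @ _p(vp, "embed", "edge", "W_o")

        # ---- message passing
        M_E_1 = None
        M_E = None
        for step in range(1, config.depth + 1):
            if step == 1:
                M_V = np.zeros((N, d))
                for e, (u, v) in enumerate(edges):
                    M_V[v] += H_E[e]
                M_E = np.array([H_V[u] for (u, v) in edges]).reshape(M, d)
                M_E_1 = M_E.copy()
                H_V = H_V + M_V
                H_E = H_E + M_E
                continue
            sp = vp["step"]
            M_V = np.zeros((N, d))
            for i in range(N):
                incoming = [e for e, (s, t) in enumerate(edges) if t == i]
                if not incoming:
                    continue
                parts = []
                for h in range(n):
                    cols = slice(h * dk, (h + 1) * dk)
                    q = H_V[i] @ _p(sp, "W_Q")[:, cols]
                    raw = {
                        e: q @ (M_E[e] @ _p(sp, "W_K")[:, cols]) / math.sqrt(dk)
                        for e in incoming
                    }
                    if config.sigma == "softmax":
                        w = _softmax_groups(raw)
                    else:
                        w = {e: 1.0 / (1.0 + np.exp(-v)) for e, v in raw.items()}
                    if config.value_source == "node":
                        val = H_V[i] @ _p(sp, "W_V")[:, cols]
                        mix = sum(w[e] * val for e in incoming)
                    else:
                        mix = sum(
                            w[e] * (M_E[e] @ _p(sp, "W_V")[:, cols]) for e in incoming
                        )
                    parts.append(mix @ _p(sp, "Omega", f"h{h}"))
                M_V[i] = np.concatenate(parts)
            H_V = H_V + M_V
            if M:
                new_M_E = np.zeros((M, d))
                for e, (u, v) in enumerate(edges):
                    inner = M_E_1[e] + H_V[u] - H_E[rev[e]]
                    new_M_E[e] = inner @ _p(sp, "W_lin") + _p(sp, "b_lin").ravel()
                M_E = new_M_E
                H_E = H_E + M_E

        # ---- GRU readout
        Z_views[tag] = gru_recurrence(
            {k: _p(vp, "gru", k) for k in
             ("W_r", "W_z", "W_n", "U_r", "U_z", "U_n", "b_r", "b_z", "b_n", "b_hn")},
            H_V,
        )

    # ---- fusion
    def gate(x, y):
        return 1.0 / (1.0 + np.exp(-(x @ y) / math.sqrt(dk))) * x

    fv = config.fusion_variant
    if fv == "full":
        Z = gate(Z_views["alpha"], gate(Z_views["gamma"], Z_views["beta"]))
    elif fv in ("alpha", "beta", "gamma"):
        Z = Z_views[fv]
    elif fv == "beta_alpha":
        Z = gate(Z_views["alpha"], Z_views["beta"])
    elif fv == "gamma_alpha":
        Z = gate(Z_views["alpha"], Z_views["gamma"])
    elif fv == "beta_gamma":
        Z = gate(Z_views["gamma"], Z_views["beta"])
    else:
        Z = gate(Z_views["beta"], gate(Z_views["alpha"], Z_views["gamma"]))

    scores = Z @ _p(params, "head", "W") + _p(params, "head", "b").ravel()
    return scores, Z
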