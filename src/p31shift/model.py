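"""Small-data graph network for ³¹P shift regression.

One MetaLayer-style message-passing round, applied exactly once:

* edge update   φe(v_src, v_dst, e, u)          → e′  (per directed edge)
* node update   φv(v, mean of incoming e′, u)    → v′  (per atom)
* global update φu(mean v′, mean e′, u)          → u′  (per molecule)
* readout       φr(mean over phosphorus v′, u′)  → δ̂   (one scalar per graph)

Each update function is a two-layer perceptron of width ``hidden_dim`` with a
rectifier on the hidden layer and a linear output; all aggregations are means,
making predictions invariant to atom reordering. The single round restricts
the receptive field of each phosphorus node to its one-bond neighborhood plus
the molecule-level state — the deliberate locality constraint that keeps the
parameter count small for scarce-data training.

The network is plain float64 NumPy. The reverse pass is derived by hand and
checked against central finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .featurize import EDGE_WIDTH, GLOBAL_WIDTH, NODE_WIDTH, MolGraph


@dataclass(frozen=True)
class SDGNNConfig:
    hidden_dim: int = 64
    node_width: int = NODE_WIDTH
    edge_width: int = EDGE_WIDTH
    global_width: int = GLOBAL_WIDTH
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.hidden_dim, self.node_width, self.edge_width, self.global_width) < 1:
            raise ValueError("all widths must be positive")


# parameter collection: flat dict  block.tensor -> ndarray
Params = dict[str, np.ndarray]


def _init_mlp(rng: np.random.Generator, name: str, din: int, dh: int, dout: int, p: Params) -> None:
    for key, (fan_in, fan_out) in {"W1": (din, dh), "W2": (dh, dout)}.items():
        bound = np.sqrt(6.0 / (fan_in + fan_out))  # Glorot uniform
        p[f"{name}.{key}"] = rng.uniform(-bound, bound, size=(fan_in, fan_out))
    p[f"{name}.b1"] = np.zeros(dh)
    p[f"{name}.b2"] = np.zeros(dout)


def _mlp_forward(p: Params, name: str, x: np.ndarray):
    h_pre = x @ p[f"{name}.W1"] + p[f"{name}.b1"]
    h = np.maximum(h_pre, 0.0)
    y = h @ p[f"{name}.W2"] + p[f"{name}.b2"]
    return y, (x, h_pre, h)


def _mlp_backward(p: Params, name: str, cache, dy: np.ndarray, grads: Params) -> np.ndarray:
    x, h_pre, h = cache
    grads[f"{name}.W2"] += h.T @ dy
    grads[f"{name}.b2"] += dy.sum(axis=0)
    dh = (dy @ p[f"{name}.W2"].T) * (h_pre > 0.0)
    grads[f"{name}.W1"] += x.T @ dh
    grads[f"{name}.b1"] += dh.sum(axis=0)
    return dh @ p[f"{name}.W1"].T


def init_model(config: SDGNNConfig) -> Params:
    """Deterministically seeded weights for the four update blocks."""
    rng = np.random.default_rng(config.seed)
    hd, wn, we, wu = config.hidden_dim, config.node_width, config.edge_width, config.global_width
    p: Params = {}
    _init_mlp(rng, "edge", 2 * wn + we + wu, hd, hd, p)
    _init_mlp(rng, "node", wn + hd + wu, hd, hd, p)
    _init_mlp(rng, "global", hd + hd + wu, hd, hd, p)
    _init_mlp(rng, "readout", 2 * hd, hd, 1, p)
    return p


def count_parameters(params: Params) -> int:
    """Exact number of trainable scalars."""
    return int(sum(v.size for v in params.values()))


@dataclass
class Batch:
    """Column-stacked representation of a list of graphs."""

    x: np.ndarray          # (nV, Wn)
    edge_attr: np.ndarray  # (nE, We)
    u: np.ndarray          # (G, Wu)
    src: np.ndarray        # (nE,)
    dst: np.ndarray        # (nE,)
    vgraph: np.ndarray     # (nV,) graph id per node
    egraph: np.ndarray     # (nE,)
    p_idx: np.ndarray      # phosphorus node indices (global numbering)
    p_graph: np.ndarray    # graph id per phosphorus node
    y: np.ndarray          # (G,) targets, ppm
    n_graphs: int
    record_ids: list[str] = field(default_factory=list)


def make_batch(graphs: list[MolGraph]) -> Batch:
    xs, es, us, srcs, dsts, vgs, egs, pis, pgs, ys, rids = ([] for _ in range(11))
    offset = 0
    for g, graph in enumerate(graphs):
        if graph.p_indices.size == 0:
            raise ValueError(f"graph {graph.record_id} has no phosphorus index")
        xs.append(graph.x)
        us.append(graph.u)
        if graph.edge_index.size:
            srcs.append(graph.edge_index[0] + offset)
            dsts.append(graph.edge_index[1] + offset)
            es.append(graph.edge_attr)
            egs.append(np.full(graph.edge_index.shape[1], g, dtype=np.int64))
        vgs.append(np.full(graph.n_atoms, g, dtype=np.int64))
        pis.append(graph.p_indices + offset)
        pgs.append(np.full(graph.p_indices.size, g, dtype=np.int64))
        ys.append(graph.y)
        rids.append(graph.record_id)
        offset += graph.n_atoms
    we = graphs[0].edge_attr.shape[1] if graphs[0].edge_attr.ndim == 2 else EDGE_WIDTH
    return Batch(
        x=np.vstack(xs),
        edge_attr=np.vstack(es) if es else np.zeros((0, we)),
        u=np.vstack(us),
        src=np.concatenate(srcs) if srcs else np.zeros(0, dtype=np.int64),
        dst=np.concatenate(dsts) if dsts else np.zeros(0, dtype=np.int64),
        vgraph=np.concatenate(vgs),
        egraph=np.concatenate(egs) if egs else np.zeros(0, dtype=np.int64),
        p_idx=np.concatenate(pis),
        p_graph=np.concatenate(pgs),
        y=np.asarray(ys, dtype=np.float64),
        n_graphs=len(graphs),
        record_ids=rids,
    )


def _segment_mean(x: np.ndarray, idx: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Mean of rows per segment; empty segments yield zero rows."""
    out = np.zeros((n, x.shape[1]))
    counts = np.bincount(idx, minlength=n).astype(np.float64)
    if x.shape[0]:
        np.add.at(out, idx, x)
    out /= np.maximum(counts, 1.0)[:, None]
    return out, counts


def forward(params: Params, batch: Batch, return_cache: bool = False):
    """One message-passing round + readout; returns (G,) standardized-scale outputs."""
    nV, G = batch.x.shape[0], batch.n_graphs
    u_e = batch.u[batch.egraph]
    e_in = np.concatenate(
        [batch.x[batch.src], batch.x[batch.dst], batch.edge_attr, u_e], axis=1
    )
    e_out, c_edge = _mlp_forward(params, "edge", e_in)

    agg_e, indeg = _segment_mean(e_out, batch.dst, nV)
    v_in = np.concatenate([batch.x, agg_e, batch.u[batch.vgraph]], axis=1)
    v_out, c_node = _mlp_forward(params, "node", v_in)

    mean_v, n_nodes = _segment_mean(v_out, batch.vgraph, G)
    mean_e, n_edges = _segment_mean(e_out, batch.egraph, G)
    u_in = np.concatenate([mean_v, mean_e, batch.u], axis=1)
    u_out, c_glob = _mlp_forward(params, "global", u_in)

    p_mean, n_p = _segment_mean(v_out[batch.p_idx], batch.p_graph, G)
    r_in = np.concatenate([p_mean, u_out], axis=1)
    z, c_read = _mlp_forward(params, "readout", r_in)
    z = z[:, 0]

    if not return_cache:
        return z
    cache = dict(
        c_edge=c_edge, c_node=c_node, c_glob=c_glob, c_read=c_read,
        indeg=indeg, n_nodes=n_nodes, n_edges=n_edges, n_p=n_p,
    )
    return z, cache


def backward(params: Params, batch: Batch, cache: dict, dz: np.ndarray) -> Params:
    """Gradients of a scalar loss w.r.t. every parameter, given dloss/dz."""
    hd = params["node.W2"].shape[1]
    nV, G = batch.x.shape[0], batch.n_graphs
    wn = batch.x.shape[1]
    grads: Params = {k: np.zeros_like(v) for k, v in params.items()}

    d_rin = _mlp_backward(params, "readout", cache["c_read"], dz[:, None], grads)
    d_pmean, d_uout = d_rin[:, :hd], d_rin[:, hd:]

    d_uin = _mlp_backward(params, "global", cache["c_glob"], d_uout, grads)
    d_meanv, d_meane = d_uin[:, :hd], d_uin[:, hd : 2 * hd]

    d_vout = d_meanv[batch.vgraph] / np.maximum(cache["n_nodes"], 1.0)[batch.vgraph, None]
    np.add.at(
        d_vout,
        batch.p_idx,
        d_pmean[batch.p_graph] / np.maximum(cache["n_p"], 1.0)[batch.p_graph, None],
    )

    d_vin = _mlp_backward(params, "node", cache["c_node"], d_vout, grads)
    d_agge = d_vin[:, wn : wn + hd]

    if batch.src.size:
        d_eout = d_meane[batch.egraph] / np.maximum(cache["n_edges"], 1.0)[batch.egraph, None]
        d_eout += d_agge[batch.dst] / np.maximum(cache["indeg"], 1.0)[batch.dst, None]
        _mlp_backward(params, "edge", cache["c_edge"], d_eout, grads)
    return grads


class AdamW:
    """Adaptive moment estimation with decoupled weight decay."""

    def __init__(self, params: Params, lr: float, weight_decay: float = 0.0,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.lr, self.wd, self.betas, self.eps = lr, weight_decay, betas, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: Params, grads: Params) -> None:
        self.t += 1
        b1, b2 = self.betas
        for k in params:
            self.m[k] = b1 * self.m[k] + (1 - b1) * grads[k]
            self.v[k] = b2 * self.v[k] + (1 - b2) * grads[k] ** 2
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.wd * params[k])
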