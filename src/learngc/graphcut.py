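"""Exact binary energy minimization on the surface graph.

The segmentation energy is

    E(l) = sum_i W_t(i, l_i) + lambda * sum_{(i,j)} W_n(i,j) * [l_i != l_j],

with unary (t-link) costs taken linearly from the predicted scar probability
(assigning scar costs 1 - L-hat, assigning normal costs L-hat) and pairwise
(n-link) weights given by the predicted label similarity M-hat in Potts
form: a high similarity makes cutting the edge expensive, pulling neighbors
to the same label.  All weights are non-negative, so the Potts energy is
submodular and the global minimum is found exactly by a two-terminal
max-flow/min-cut.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from networkx.algorithms.flow import boykov_kolmogorov

from .msp import MSPConfig, extract_msp_batch
from .nets import NNet, TNet, n_net_predict, t_net_predict
from .surface import SurfaceMesh
from .volume import ImageVolume

__all__ = ["GraphModel", "energy", "min_cut", "brute_force_min",
           "graph_from_probabilities", "classify_scars"]


@dataclass
class GraphModel:
    """Surface graph with unary and pairwise potentials.

    ``cost_normal[i]`` is paid when node i is labeled 0 (normal wall) and
    ``cost_scar[i]`` when labeled 1; ``edge_weights[k]`` is paid (times
    ``lam``) when the endpoints of ``edges[k]`` disagree.
    """

    n_nodes: int
    edges: np.ndarray        # (E, 2) int
    cost_normal: np.ndarray  # (n,) cost of assigning label 0
    cost_scar: np.ndarray    # (n,) cost of assigning label 1
    edge_weights: np.ndarray  # (E,) >= 0
    lam: float = 0.4

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        self.cost_normal = np.asarray(self.cost_normal, dtype=float)
        self.cost_scar = np.asarray(self.cost_scar, dtype=float)
        self.edge_weights = np.asarray(self.edge_weights, dtype=float)
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")
        for arr in (self.cost_normal, self.cost_scar, self.edge_weights):
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValueError("all graph weights must be finite and non-negative")

    def save_edge_list(self, path: str) -> None:
        """Debug dump: plain-text node costs and edge weights."""
        with open(path, "w") as fh:
            fh.write(f"# lambda {self.lam}\n# node cost_normal cost_scar\n")
            for i in range(self.n_nodes):
                fh.write(f"n {i} {self.cost_normal[i]:.6g} {self.cost_scar[i]:.6g}\n")
            fh.write("# edge i j weight\n")
            for (i, j), w in zip(self.edges, self.edge_weights):
                fh.write(f"e {i} {j} {w:.6g}\n")


def graph_from_probabilities(l_hat: np.ndarray, edges: np.ndarray,
                             m_hat: np.ndarray, lam: float) -> GraphModel:
    """Build the graph from predicted scar probabilities and similarities."""
    l_hat = np.asarray(l_hat, dtype=float)
    return GraphModel(len(l_hat), edges, cost_normal=l_hat,
                      cost_scar=1.0 - l_hat, edge_weights=m_hat, lam=lam)


def energy(graph: GraphModel, labeling: np.ndarray) -> float:
    """Evaluate E(l) for a binary labeling."""
    l = np.asarray(labeling)
    if l.shape != (graph.n_nodes,):
        raise ValueError("labeling length must equal the node count")
    unary = np.where(l == 1, graph.cost_scar, graph.cost_normal).sum()
    if len(graph.edges):
        cut = l[graph.edges[:, 0]] != l[graph.edges[:, 1]]
        unary += graph.lam * graph.edge_weights[cut].sum()
    return float(unary)


def min_cut(graph: GraphModel) -> np.ndarray:
    """Globally minimal labeling of the Potts energy via exact max-flow.

    Construction: cutting s->i pays the label-0 cost, cutting i->t pays the
    label-1 cost, and each n-link appears in both directions with capacity
    lambda * W; nodes left on the source side get label 1 (scar).
    """
    g = nx.DiGraph()
    src, sink = "s", "t"
    for i in range(graph.n_nodes):
        g.add_edge(src, i, capacity=float(graph.cost_normal[i]))
        g.add_edge(i, sink, capacity=float(graph.cost_scar[i]))
    if graph.lam > 0 and len(graph.edges):
        # merge parallel edges: each undirected pair carries the summed weight
        lo = graph.edges.min(axis=1)
        hi = graph.edges.max(axis=1)
        merged: dict[tuple[int, int], float] = {}
        for i, j, w in zip(lo, hi, graph.edge_weights):
            merged[(int(i), int(j))] = merged.get((int(i), int(j)), 0.0) + float(w)
        for (i, j), w in merged.items():
            cap = graph.lam * w
            g.add_edge(i, j, capacity=cap)
            g.add_edge(j, i, capacity=cap)
    _, (source_side, _) = nx.minimum_cut(g, src, sink, flow_func=boykov_kolmogorov)
    labeling = np.zeros(graph.n_nodes, dtype=int)
    labeling[[i for i in source_side if i != src]] = 1
    return labeling


def brute_force_min(graph: GraphModel) -> tuple[np.ndarray, float]:
    """Exhaustive-enumeration minimum; only for small graphs (n <= ~16)."""
    n = graph.n_nodes
    if n > 20:
        raise ValueError("brute force is limited to small graphs")
    codes = np.arange(2**n, dtype=np.uint32)
    bits = (codes[:, None] >> np.arange(n)) & 1  # (2^n, n)
    e = bits @ graph.cost_scar + (1 - bits) @ graph.cost_normal
    if len(graph.edges):
        disagree = bits[:, graph.edges[:, 0]] != bits[:, graph.edges[:, 1]]
        e = e + graph.lam * (disagree @ graph.edge_weights)
    best = int(np.argmin(e))
    return bits[best].astype(int), float(e[best])


def classify_scars(image: ImageVolume, mesh: SurfaceMesh, t_net: TNet,
                   n_net: NNet | None, lam: float, msp_cfg: MSPConfig,
                   return_probabilities: bool = False):
    """Predict the scar map on the surface with the full learned graph.

    Patches are extracted with zero shift (testing phase), T-NET gives the
    per-node scar probability, N-NET the per-edge similarity, and the exact
    min-cut of the resulting graph is the labeling.  With ``lam`` = 0 the
    energy decouples and the labeling is per-node thresholding of L-hat at
    0.5 (ties conservatively to normal wall).
    """
    if not t_net.trained:
        raise ValueError("T-NET is untrained; train or load a checkpoint first")
    test_cfg = MSPConfig(msp_cfg.dims, msp_cfg.n_scales, msp_cfg.base_spacing_mm)
    test_cfg.shift.R = 0.0
    patches, _ = extract_msp_batch(image, mesh, np.arange(mesh.n_nodes), test_cfg)
    l_hat = t_net_predict(t_net, patches)

    if lam == 0 or n_net is None:
        if lam > 0:
            raise ValueError("lambda > 0 requires a trained N-NET")
        labeling = (l_hat > 0.5).astype(int)
    else:
        if not n_net.trained:
            raise ValueError("N-NET is untrained; train or load a checkpoint first")
        e = mesh.edges
        m_hat = n_net_predict(n_net, patches[e[:, 0]], patches[e[:, 1]],
                              mesh.edge_lengths)
        graph = graph_from_probabilities(l_hat, e, m_hat, lam)
        labeling = min_cut(graph)
    if return_probabilities:
        return labeling, l_hat
    return labeling
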