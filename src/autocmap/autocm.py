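"""Auto-Contractive Map training and semantic-connectivity-map extraction.

The Auto-Contractive Map (Auto-CM) is an unsupervised three-layer network
with as many units per layer as variables. For an input pattern m ∈ [0,1]^N
and contraction parameter C > 1 the signal transfer is

    hidden:  h_s   = m_s · (1 − v_s / C)
    net:     Net_i = Σ_s h_s · (1 − w_{s,i} / C)
    output:  o_i   = h_i · (1 − Net_i / C)

and the contractive weight adaptation, applied record by record, is

    Δv_s     = α · (m_s − h_s) · (1 − v_s / C)
    Δw_{s,i} = α · (h_s − o_i) · (1 − w_{s,i} / C) · h_i

Weights start at a small positive constant (exactly zero is a fixed point of
the v adaptation, since h = m there).

As the monoconnections v saturate toward C the hidden signal vanishes and
training freezes; the trained w matrix then encodes the joint association of
every variable with every other. Symmetrized and normalized, w yields the
link-strength matrix in [0,1]; 1 − strength is a distance, and the minimum
spanning tree over those distances is the semantic connectivity map in which
adjacent nodes have the highest mutual affinity and high-degree nodes are
hubs.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "AutoCMParams",
    "AutoCMModel",
    "LinkStrengthMatrix",
    "SemanticMap",
    "train_autocm",
    "link_strengths",
    "strengths_to_distances",
    "minimum_spanning_tree",
    "export_map",
]


@dataclass(frozen=True)
class AutoCMParams:
    """Training hyper-parameters.

    contraction: the C parameter (> 1); by convention C = N (the variable
    count) when left at None, which keeps every contraction factor in (0, 1].
    tolerance is the mean absolute weight change per epoch that stops
    training.
    """

    contraction: float | None = None
    learning_rate: float = 0.1
    max_epochs: int = 2000
    tolerance: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.contraction is not None and not self.contraction > 1:
            raise ValueError("contraction C must be > 1")
        if not self.learning_rate > 0:
            raise ValueError("learning_rate must be > 0")
        if not 0 < self.tolerance < 1:
            raise ValueError("tolerance must be in (0, 1)")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


@dataclass
class AutoCMModel:
    """Trained Auto-CM state."""

    v: np.ndarray  # input→hidden monoconnections, length N
    w: np.ndarray  # hidden→output weight matrix, N × N
    contraction: float
    epochs_run: int
    converged: bool
    training_trace: list[float] = field(default_factory=list)  # mean |Δw| per epoch


@dataclass
class LinkStrengthMatrix:
    """Symmetric variable–variable link strengths in [0,1], unit diagonal."""

    strengths: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        s = np.asarray(self.strengths, dtype=float)
        if s.ndim != 2 or s.shape[0] != s.shape[1]:
            raise ValueError("strengths must be square")
        if not np.allclose(s, s.T, atol=1e-12):
            raise ValueError("strengths must be symmetric")
        if s.min() < -1e-12 or s.max() > 1 + 1e-12:
            raise ValueError("strengths must lie in [0,1]")
        self.strengths = s


@dataclass
class SemanticMap:
    """Minimum-spanning-tree map over the variables.

    edges: (label_i, label_j, strength, distance) with label_i < label_j.
    hub_scores: label → (degree, summed incident strength).
    central_node: maximum degree, ties broken by summed strength then label.
    """

    nodes: list[str]
    edges: list[tuple[str, str, float, float]]
    hub_scores: dict[str, tuple[int, float]]
    central_node: str


def train_autocm(matrix: np.ndarray, params: AutoCMParams | None = None) -> AutoCMModel:
    """Train the Auto-CM on an encoded records × variables matrix in [0,1].

    Records are presented cyclically in fixed dataset order (no shuffling),
    so training is exactly reproducible. Stops when the mean absolute weight
    change over an epoch drops below ``tolerance`` or after ``max_epochs``.
    """
    params = params or AutoCMParams()
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("matrix must be 2-D (records × variables)")
    r, n = m.shape
    if n < 2:
        raise ValueError("need at least 2 variables")
    if r < 2:
        raise ValueError("need at least 2 records")
    if np.isnan(m).any() or m.min() < 0 or m.max() > 1:
        raise ValueError("matrix values must lie in [0,1] with no NaN")

    c = float(params.contraction) if params.contraction is not None else float(n)
    alpha = params.learning_rate
    w0 = 0.001 * c  # small positive start; v = 0 exactly would never adapt
    v = np.full(n, w0)
    w = np.full((n, n), w0)

    trace: list[float] = []
    converged = False
    epochs = 0
    for epoch in range(params.max_epochs):
        dw_sum = 0.0
        for k in range(r):
            x = m[k]
            h = x * (1.0 - v / c)
            net = h @ (1.0 - w / c)
            out = h * (1.0 - net / c)
            dv = alpha * (x - h) * (1.0 - v / c)
            dw = alpha * ((h[:, None] - out[None, :]) * (1.0 - w / c) * h[None, :])
            v = v + dv
            w = w + dw
            dw_sum += float(np.abs(dw).mean())
            if not np.isfinite(w).all() or not np.isfinite(v).all():
                raise FloatingPointError(
                    f"non-finite Auto-CM weights at epoch {epoch + 1}, record {k + 1}"
                )
        epochs = epoch + 1
        trace.append(dw_sum / r)
        if trace[-1] < params.tolerance:
            converged = True
            break

    return AutoCMModel(v=v, w=w, contraction=c, epochs_run=epochs,
                       converged=converged, training_trace=trace)


def link_strengths(
    model: AutoCMModel, labels: list[str] | None = None
) -> LinkStrengthMatrix:
    """Normalize the trained w matrix into symmetric link strengths in [0,1].

    w is symmetrized by the arithmetic mean (the map is undirected) and
    divided by its global maximum, so the strongest link is exactly 1.
    Transiently negative trained weights are floored at 0 so the printed
    [0,1] range always holds. Diagonal is set to 1 by convention.
    """
    w = np.asarray(model.w, dtype=float)
    sym = (w + w.T) / 2.0
    peak = sym.max()
    if peak <= 0:
        raise ValueError("degenerate model: no positive trained weight")
    s = np.clip(sym / peak, 0.0, 1.0)
    np.fill_diagonal(s, 1.0)
    return LinkStrengthMatrix(strengths=s, labels=labels)


def strengths_to_distances(strengths: LinkStrengthMatrix | np.ndarray) -> np.ndarray:
    """Distance matrix d = 1 − s: zero diagonal, strictly decreasing in strength."""
    s = strengths.strengths if isinstance(strengths, LinkStrengthMatrix) else np.asarray(strengths, dtype=float)
    if s.min() < 0 or s.max() > 1:
        raise ValueError("strengths must lie in [0,1]")
    d = 1.0 - s
    np.fill_diagonal(d, 0.0)
    return d


def minimum_spanning_tree(distances: np.ndarray, labels: list[str]) -> SemanticMap:
    """Minimum spanning tree over a symmetric distance matrix.

    Edges are inserted in lexicographic (label_i, label_j) order so Kruskal's
    stable sort breaks distance ties lexicographically. Hub score = (degree,
    summed incident strength); the central node maximizes degree, then summed
    strength, then lexicographic order.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.isfinite(d).all():
        raise ValueError("distance matrix must be finite")
    if not np.allclose(d, d.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    if len(labels) != n:
        raise ValueError("labels length must match matrix size")

    order = sorted(range(n), key=lambda i: labels[i])
    g = nx.Graph()
    g.add_nodes_from(sorted(labels))
    for a in range(n):
        for b in range(a + 1, n):
            i, j = order[a], order[b]
            li, lj = labels[i], labels[j]
            if lj < li:
                li, lj = lj, li
            g.add_edge(li, lj, weight=float(d[i, j]))
    tree = nx.minimum_spanning_tree(g, algorithm="kruskal")

    edges: list[tuple[str, str, float, float]] = []
    for li, lj, data in tree.edges(data=True):
        if lj < li:
            li, lj = lj, li
        dist = data["weight"]
        edges.append((li, lj, 1.0 - dist, dist))
    edges.sort()

    hub: dict[str, tuple[int, float]] = {}
    for lab in labels:
        deg = tree.degree(lab)
        ssum = sum(1.0 - dt["weight"] for _, _, dt in tree.edges(lab, data=True))
        hub[lab] = (deg, ssum)
    best = max((hub[lab][0], hub[lab][1]) for lab in labels)
    central = min(lab for lab in labels if (hub[lab][0], hub[lab][1]) == best)
    return SemanticMap(nodes=list(labels), edges=edges, hub_scores=hub,
                       central_node=central)


def _map_to_graph(smap: SemanticMap) -> nx.Graph:
    g = nx.Graph()
    for node in smap.nodes:
        g.add_node(node, central=(node == smap.central_node))
    for li, lj, s, dist in smap.edges:
        g.add_edge(li, lj, strength=round(float(s), 6), distance=round(float(dist), 6))
    return g


def export_map(smap: SemanticMap, fmt: str, path: str) -> str:
    """Write the map as 'graphml', 'dot' or 'csv' (flat edge list).

    DOT edge labels carry the strength to 2 decimals (the style used on the
    published map figures, e.g. "0.99"); the central node is flagged.
    """
    if fmt == "graphml":
        nx.write_graphml(_map_to_graph(smap), path)
    elif fmt == "dot":
        buf = io.StringIO()
        buf.write("graph semantic_map {\n")
        for node in smap.nodes:
            style = ' style=filled fillcolor=red' if node == smap.central_node else ""
            buf.write(f'  "{node}" [label="{node}"{style}];\n')
        for li, lj, s, _ in smap.edges:
            buf.write(f'  "{li}" -- "{lj}" [label="{s:.2f}"];\n')
        buf.write("}\n")
        with open(path, "w") as fh:
            fh.write(buf.getvalue())
    elif fmt == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["source", "target", "strength", "distance"])
            for li, lj, s, dist in smap.edges:
                writer.writerow([li, lj, f"{s:.6f}", f"{dist:.6f}"])
    else:
        raise ValueError(f"unknown export format {fmt!r} (graphml, dot, csv)")
    return path
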