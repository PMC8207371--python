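"""Whole-network statistics on dichotomized association matrices.

Four standard measures, all computed on binary ties (weights removed):

* **density** — observed ties over possible ties, 2T / n(n-1);
* **degree centrality** — per node, its count of ties; the network
  summary reports the mean over all nodes, isolates included;
* **centralization** — Freeman degree centralization,
  sum_i (d_max - d_i) / ((n-1)(n-2)), 0 for regular graphs and 1 for a
  star;
* **diameter** — the longest finite geodesic (shortest-path) distance
  over reachable pairs. Field networks routinely contain isolates and
  disconnected fragments, so infinite distances are excluded rather
  than poisoning the statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import shortest_path

from .networks import AssociationMatrix


def _binary_weights(m: AssociationMatrix) -> np.ndarray:
    if not m.is_binary():
        raise ValueError("statistics are defined on dichotomized (binary) matrices")
    return m.weights


@dataclass(frozen=True)
class NetworkSummary:
    """One report row: node count plus the four whole-network measures."""

    nodes: int
    density: float
    diameter: int
    centralization: float
    avg_degree_centrality: float

    def rounded(self) -> "NetworkSummary":
        """Report precision: density and centralization 2 dp, degree 1 dp."""
        return NetworkSummary(
            self.nodes,
            round(self.density, 2),
            self.diameter,
            round(self.centralization, 2),
            round(self.avg_degree_centrality, 1),
        )


def density(m: AssociationMatrix) -> float:
    """Proportion of possible ties realized: 2T / n(n-1)."""
    w = _binary_weights(m)
    n = m.n_nodes
    if n < 2:
        raise ValueError("density requires at least 2 nodes")
    return float(w.sum() / (n * (n - 1)))


def degree_centrality(m: AssociationMatrix) -> tuple[np.ndarray, float]:
    """Per-node tie counts (row sums) and their mean over all nodes."""
    w = _binary_weights(m)
    degrees = w.sum(axis=1)
    return degrees, float(degrees.mean())


def centralization(m: AssociationMatrix) -> float:
    """Freeman degree centralization: sum(d_max - d_i) / ((n-1)(n-2))."""
    w = _binary_weights(m)
    n = m.n_nodes
    if n < 3:
        raise ValueError("centralization requires at least 3 nodes")
    degrees = w.sum(axis=1)
    return float((degrees.max() - degrees).sum() / ((n - 1) * (n - 2)))


def diameter(m: AssociationMatrix) -> int:
    """Longest finite geodesic over all reachable pairs; >= 1 given any tie."""
    w = _binary_weights(m)
    if w.sum() == 0:
        raise ValueError("diameter is undefined on a network with no ties")
    dist = shortest_path(w, method="D", unweighted=True, directed=False)
    finite = dist[np.isfinite(dist)]
    return int(finite.max())


def summarize(m: AssociationMatrix) -> NetworkSummary:
    """All four statistics plus node count, at full precision."""
    _, mean_deg = degree_centrality(m)
    return NetworkSummary(
        nodes=m.n_nodes,
        density=density(m),
        diameter=diameter(m),
        centralization=centralization(m),
        avg_degree_centrality=mean_deg,
    )
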