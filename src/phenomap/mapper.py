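"""Mapper: build a patient-similarity network from two lens coordinates.

The lens plane is covered by the cross product of two 1-D interval covers
(``resolution`` base intervals per lens, widened by ``gain`` about their
centres so neighbours overlap by (gain-1)/gain of a base width; with
``equalized`` the base boundaries sit at empirical quantiles so each base
interval holds an equal share of patients). Patients inside each 2-D cover
cell are clustered by single linkage on the precomputed distance matrix,
cut at the first empty bin of a fixed-bin histogram of merge heights.
Each cluster becomes a node; two nodes are connected iff they share at
least one patient, with edge weight = number of shared patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator

__all__ = [
    "CoverInterval",
    "CoverCell",
    "build_cover",
    "cluster_cell",
    "build_graph",
    "MapperNetwork",
    "write_graphml",
    "read_graphml_members",
    "write_edge_list",
]


@dataclass(frozen=True)
class CoverInterval:
    lo: float
    hi: float
    last: bool  # last interval along its lens → closed-closed membership

    def contains(self, x: np.ndarray) -> np.ndarray:
        if self.last:
            return (x >= self.lo) & (x <= self.hi)
        return (x >= self.lo) & (x < self.hi)


@dataclass
class CoverCell:
    """One 2-D cover cell: a pair of (overlap-extended) lens intervals."""

    index: tuple
    interval_1: CoverInterval
    interval_2: CoverInterval
    members: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def _axis_intervals(values: np.ndarray, resolution: int, gain: float, equalized: bool):
    """Base intervals per lens, then widen each by ``gain`` about its centre."""
    if equalized:
        qs = np.quantile(values, np.linspace(0.0, 1.0, resolution + 1))
        # enforce monotone boundaries under heavy ties
        qs = np.maximum.accumulate(qs)
    else:
        qs = np.linspace(values.min(), values.max(), resolution + 1)
    intervals = []
    for i in range(resolution):
        lo, hi = qs[i], qs[i + 1]
        half_extra = (hi - lo) * (gain - 1.0) / 2.0
        intervals.append(
            CoverInterval(lo - half_extra, hi + half_extra, last=(i == resolution - 1))
        )
    return intervals


def build_cover(lens, resolution: int = 29, gain: float = 1.6, equalized: bool = True):
    """Cross-product cover of the 2-D lens space; cells may be empty.

    ``lens`` is an (n, 2) array or DataFrame. Returns a list of CoverCell
    in row-major order over (interval_1, interval_2) indices, with member
    positions (integer row indices into the lens array).
    """
    L = np.asarray(lens, dtype=float)
    if L.ndim != 2 or L.shape[1] != 2:
        raise ValueError("lens must be (n, 2)")
    if not np.all(np.isfinite(L)):
        raise ValueError("lens values must be finite")
    if resolution < 1:
        raise ValueError("resolution must be >= 1")
    if not gain > 1.0:
        raise ValueError("gain must be > 1")
    n = L.shape[0]
    if n == 0:
        return []
    ax1 = _axis_intervals(L[:, 0], resolution, gain, equalized)
    ax2 = _axis_intervals(L[:, 1], resolution, gain, equalized)
    in1 = [iv.contains(L[:, 0]) for iv in ax1]
    in2 = [iv.contains(L[:, 1]) for iv in ax2]
    cells = []
    for i, iv1 in enumerate(ax1):
        for j, iv2 in enumerate(ax2):
            members = np.nonzero(in1[i] & in2[j])[0]
            cells.append(CoverCell((i, j), iv1, iv2, members))
    return cells


def cluster_cell(members: np.ndarray, D: np.ndarray, histogram_bins: int = 10):
    """Partition a cover cell's members by single linkage with the
    first-gap histogram cut.

    Build the single-linkage dendrogram over the members using the
    restriction of ``D``; histogram the merge heights into
    ``histogram_bins`` bins spanning [min height, max height]; cut at the
    left edge of the first empty bin. No empty bin (or a degenerate cell)
    means one cluster. Returns a list of member-index arrays.
    """
    members = np.asarray(members, dtype=int)
    m = len(members)
    if m == 0:
        return []
    if m == 1:
        return [members.copy()]
    sub = D[np.ix_(members, members)]
    Z = linkage(squareform(sub, checks=False), method="single")
    heights = Z[:, 2]
    hmin, hmax = heights.min(), heights.max()
    if hmax <= hmin:  # all merges at one height: a single cluster
        return [members.copy()]
    counts, edges = np.histogram(heights, bins=histogram_bins, range=(hmin, hmax))
    empty = np.nonzero(counts == 0)[0]
    if len(empty) == 0:
        return [members.copy()]
    cut = edges[empty[0]]
    labels = fcluster(Z, t=cut, criterion="distance")
    return [members[labels == lab] for lab in np.unique(labels)]


def build_graph(cells, clusters_per_cell) -> nx.Graph:
    """Nerve of the clustered cover.

    One node per cluster (ids assigned row-major over cells, then cluster
    index), node attribute ``members`` = frozenset of patient positions and
    ``cell`` = the cell index; an edge joins two nodes sharing >= 1
    patient, weighted by the overlap size.
    """
    g = nx.Graph()
    owner: dict[int, list[int]] = {}
    node_id = 0
    for cell, clusters in zip(cells, clusters_per_cell):
        for members in clusters:
            if len(members) == 0:
                continue
            g.add_node(node_id, members=frozenset(int(x) for x in members), cell=cell.index)
            for p in members:
                owner.setdefault(int(p), []).append(node_id)
            node_id += 1
    for nodes in owner.values():
        for u, v in combinations(nodes, 2):
            if g.has_edge(u, v):
                g[u][v]["weight"] += 1
            else:
                g.add_edge(u, v, weight=1)
    return g


class MapperNetwork(BaseEstimator):
    """scikit-learn style estimator wrapping the full Mapper construction.

    ``fit(lens, distance=D)`` builds the cover, clusters every non-empty
    cell, and assembles the nerve. Fitted attributes: ``cover_``,
    ``graph_`` (networkx Graph), ``n_nodes_``, ``n_edges_``.
    """

    def __init__(
        self,
        resolution: int = 29,
        gain: float = 1.6,
        equalized: bool = True,
        cluster_histogram_bins: int = 10,
    ):
        self.resolution = resolution
        self.gain = gain
        self.equalized = equalized
        self.cluster_histogram_bins = cluster_histogram_bins

    def fit(self, lens, y=None, *, distance: np.ndarray):
        if self.cluster_histogram_bins < 2:
            raise ValueError("cluster_histogram_bins must be >= 2")
        index = lens.index if isinstance(lens, pd.DataFrame) else None
        self.patient_ids_ = (
            np.asarray(index) if index is not None else np.arange(np.asarray(lens).shape[0])
        )
        self.cover_ = build_cover(lens, self.resolution, self.gain, self.equalized)
        clusters = [
            cluster_cell(cell.members, distance, self.cluster_histogram_bins)
            for cell in self.cover_
        ]
        self.graph_ = build_graph(self.cover_, clusters)
        self.n_nodes_ = self.graph_.number_of_nodes()
        self.n_edges_ = self.graph_.number_of_edges()
        return self


def _attribute_graph(g: nx.Graph, patient_ids=None, node_values=None) -> nx.Graph:
    out = nx.Graph()
    for u, data in g.nodes(data=True):
        members = sorted(data["members"])
        attrs = {
            "size": len(members),
            "cell": str(data.get("cell", "")),
            "members": ";".join(
                str(patient_ids[m]) if patient_ids is not None else str(m) for m in members
            ),
        }
        if node_values:
            for name, per_patient in node_values.items():
                attrs[name] = float(np.mean([per_patient[m] for m in members]))
        out.add_node(u, **attrs)
    for u, v, data in g.edges(data=True):
        out.add_edge(u, v, weight=int(data.get("weight", 1)))
    return out


def write_graphml(g: nx.Graph, path, patient_ids=None, node_values=None):
    """Export with node size/means and edge weights; ``node_values`` maps
    attribute name -> per-patient vector (means taken over node members)."""
    nx.write_graphml(_attribute_graph(g, patient_ids, node_values), path)


def read_graphml_members(path) -> nx.Graph:
    """Rebuild a Mapper graph from GraphML written by :func:`write_graphml`.

    Node ``members`` come back as frozensets of patient-id strings, so the
    phenogrouping stage can run from the exported file alone.
    """
    raw = nx.read_graphml(path)
    g = nx.Graph()
    for u, data in raw.nodes(data=True):
        members = frozenset(str(data["members"]).split(";")) if data.get("members") else frozenset()
        g.add_node(int(u), members=members, cell=data.get("cell", ""))
    for u, v, data in raw.edges(data=True):
        g.add_edge(int(u), int(v), weight=int(data.get("weight", 1)))
    return g


def write_edge_list(g: nx.Graph, path):
    rows = [
        {"source": u, "target": v, "weight": data.get("weight", 1)}
        for u, v, data in g.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(path, index=False)
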