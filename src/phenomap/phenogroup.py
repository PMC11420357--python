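"""Phenogroups: outlier removal, Louvain autogrouping, and merge-to-k.

Nodes disconnected from the largest component of the Mapper network are
outliers; their patients (unless also present in a kept node) leave the
analysis. Louvain community detection partitions the main component into
autogroups; autogroups are then merged down to ``k`` phenogroups by
repeatedly taking the group with the most outbound edges relative to its
node count and merging it into the adjacent group it shares the most edges
with. Because Mapper nodes overlap, a patient can end up in more than one
phenogroup; the overlap is preserved, not resolved.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms.community import louvain_communities
from sklearn.base import BaseEstimator

__all__ = [
    "Phenogroup",
    "remove_outliers",
    "louvain_autogroup",
    "merge_to_k",
    "assign_patients",
    "PhenogroupClusterer",
]


@dataclass
class Phenogroup:
    label: int
    node_set: frozenset
    patient_set: frozenset


def remove_outliers(g: nx.Graph):
    """Keep the largest connected component (ties broken toward the
    component containing the lowest node id).

    Returns ``(main_graph, outlier_patients)`` where outliers are patients
    appearing only in removed nodes — a patient with any foothold in the
    main component is kept.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    comps = list(nx.connected_components(g))
    comps.sort(key=lambda c: (-len(c), min(c)))
    main = g.subgraph(comps[0]).copy()
    kept_patients = set().union(*(g.nodes[u]["members"] for u in main.nodes))
    all_patients = set().union(*(g.nodes[u]["members"] for u in g.nodes))
    return main, all_patients - kept_patients


def louvain_autogroup(g: nx.Graph, seed: int = 0) -> dict:
    """Louvain modularity maximization on the weighted graph.

    Returns node -> contiguous group label; labels ordered by each
    community's lowest node id so the output is stable for a given seed.
    A community that does not induce a connected subgraph (a rare but
    documented Louvain artifact) is split into its connected components,
    so every autogroup is connected by construction.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    comms = louvain_communities(g, weight="weight", resolution=1, seed=seed)
    pieces = []
    for comm in comms:
        pieces.extend(nx.connected_components(g.subgraph(comm)))
    pieces = sorted((set(p) for p in pieces), key=min)
    return {u: lab for lab, comm in enumerate(pieces) for u in comm}


def _group_stats(g: nx.Graph, assignment: dict):
    labels = sorted(set(assignment.values()))
    nodes = {lab: [u for u, l in assignment.items() if l == lab] for lab in labels}
    outbound = {lab: 0 for lab in labels}
    between = {}
    for u, v in g.edges():
        lu, lv = assignment[u], assignment[v]
        if lu == lv:
            continue
        outbound[lu] += 1
        outbound[lv] += 1
        key = (min(lu, lv), max(lu, lv))
        between[key] = between.get(key, 0) + 1
    return labels, nodes, outbound, between


def merge_to_k(g: nx.Graph, assignment: dict, k: int) -> dict:
    """Iteratively merge autogroups until ``k`` remain.

    Score(G) = (# edges with exactly one endpoint in G) / |G|; the group
    with maximal score merges into the neighbour sharing the most edges
    with it. Ties: selection prefers the smaller group then the lower
    label; the merge target prefers the larger group then the lower label.
    Unweighted edge counts throughout. Returns node -> phenogroup label
    (relabelled to 0..k-1 by lowest contained node id).
    """
    assignment = dict(assignment)
    n_groups = len(set(assignment.values()))
    if not 1 <= k <= n_groups:
        raise ValueError(f"cannot merge {n_groups} groups to k={k}")
    while n_groups > k:
        labels, nodes, outbound, between = _group_stats(g, assignment)
        # selection: max score, tie -> smaller group, then lower label
        src = max(labels, key=lambda l: (outbound[l] / len(nodes[l]), -len(nodes[l]), -l))
        neighbours = {}
        for (a, b), cnt in between.items():
            if a == src:
                neighbours[b] = cnt
            elif b == src:
                neighbours[a] = cnt
        if not neighbours:
            raise RuntimeError(f"group {src} has no adjacent group; graph disconnected?")
        # target: most shared edges, tie -> larger group, then lower label
        dst = max(neighbours, key=lambda l: (neighbours[l], len(nodes[l]), -l))
        for u in nodes[src]:
            assignment[u] = dst
        n_groups -= 1
    # contiguous relabel, ordered by lowest node id in each group
    order = {}
    for lab in sorted(set(assignment.values()), key=lambda l: min(u for u, a in assignment.items() if a == l)):
        order[lab] = len(order)
    return {u: order[lab] for u, lab in assignment.items()}


def assign_patients(g: nx.Graph, assignment: dict) -> dict:
    """Patient -> set of phenogroup labels (>= 1 each; overlaps preserved)."""
    out: dict = {}
    for u, lab in assignment.items():
        for p in g.nodes[u]["members"]:
            out.setdefault(p, set()).add(lab)
    return out


def phenogroups_from_assignment(g: nx.Graph, assignment: dict):
    groups = []
    for lab in sorted(set(assignment.values())):
        node_set = frozenset(u for u, l in assignment.items() if l == lab)
        patients = frozenset().union(*(g.nodes[u]["members"] for u in node_set))
        groups.append(Phenogroup(lab, node_set, patients))
    return groups


class PhenogroupClusterer(BaseEstimator):
    """Estimator: Mapper graph -> k phenogroups.

    ``fit(graph)`` removes outliers, runs Louvain, merges to
    ``n_phenogroups``. Fitted attributes: ``main_graph_``,
    ``outlier_patients_``, ``n_autogroups_``, ``node_labels_``,
    ``phenogroups_`` (list of Phenogroup), ``patient_labels_``
    (patient -> sorted tuple of labels), ``labels_`` (patient -> first
    label, for evaluation against a flat clustering).
    """

    def __init__(self, n_phenogroups: int = 5, seed: int = 0):
        self.n_phenogroups = n_phenogroups
        self.seed = seed

    def fit(self, graph: nx.Graph, y=None):
        main, outliers = remove_outliers(graph)
        auto = louvain_autogroup(main, seed=self.seed)
        self.n_autogroups_ = len(set(auto.values()))
        k = min(self.n_phenogroups, self.n_autogroups_)
        self.node_labels_ = merge_to_k(main, auto, k)
        self.main_graph_ = main
        self.outlier_patients_ = outliers
        self.phenogroups_ = phenogroups_from_assignment(main, self.node_labels_)
        pat = assign_patients(main, self.node_labels_)
        self.patient_labels_ = {p: tuple(sorted(s)) for p, s in pat.items()}
        self.labels_ = {p: labs[0] for p, labs in self.patient_labels_.items()}
        # each phenogroup's nodes must induce a connected subgraph
        for grp in self.phenogroups_:
            sub = main.subgraph(grp.node_set)
            if sub.number_of_nodes() and not nx.is_connected(sub):
                raise RuntimeError(f"phenogroup {grp.label} is not connected")
        return self


def assignments_to_frame(patient_labels: dict, patient_ids=None) -> pd.DataFrame:
    """CSV-ready table: patient_id, semicolon-joined labels."""
    rows = []
    for p, labs in sorted(patient_labels.items()):
        pid = patient_ids[p] if patient_ids is not None else p
        rows.append({"patient_id": pid, "labels": ";".join(str(l) for l in labs)})
    return pd.DataFrame(rows, columns=["patient_id", "labels"])
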