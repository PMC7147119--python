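"""Bipartite herb-target and compound-target networks.

Thin typed layer over :mod:`networkx` for the graphs a formula analysis
produces: nodes are herbs, compounds, or targets; edges span two
distinct types and carry a provenance flag (``known`` or ``predicted``).
Degree is the number of incident edges; hubs are nodes whose degree
strictly exceeds a per-type threshold.  Exports (GraphML, SIF, edge CSV)
use a deterministic node order (type, then id) and round-trip losslessly
through the matching importers.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

from .disease import CandidateTargetSet
from .ingredients import FormulaCatalog, _normalize_name

__all__ = [
    "BipartiteNetwork",
    "DegreeReport",
    "build_ct_network",
    "build_ht_network",
    "degree_report",
    "export_graph",
    "import_graph",
]

NODE_TYPES = ("herb", "compound", "target")
PROVENANCE = ("known", "predicted")

#: SIF relation tokens: edges into a target node are "targets",
#: herb-compound membership edges are "contains".
_SIF_RELATION = {"target": "targets", "compound": "contains"}


class BipartiteNetwork:
    """Typed undirected graph whose edges span two distinct node types."""

    def __init__(self) -> None:
        self.graph = nx.Graph()

    def add_node(self, node: str, node_type: str) -> None:
        if node_type not in NODE_TYPES:
            raise ValueError(f"unknown node type {node_type!r}")
        existing = self.graph.nodes.get(node)
        if existing and existing["type"] != node_type:
            raise ValueError(f"node {node!r} already typed {existing['type']!r}")
        self.graph.add_node(node, type=node_type)

    def add_edge(self, u: str, v: str, provenance: str = "known") -> None:
        if u == v:
            raise ValueError("self-loops are not allowed")
        if provenance not in PROVENANCE:
            raise ValueError(f"unknown provenance {provenance!r}")
        for n in (u, v):
            if n not in self.graph:
                raise KeyError(f"edge endpoint {n!r} not in network")
        if self.graph.nodes[u]["type"] == self.graph.nodes[v]["type"]:
            raise ValueError("edges must span two distinct node types")
        self.graph.add_edge(u, v, provenance=provenance)

    def node_type(self, node: str) -> str:
        return self.graph.nodes[node]["type"]

    def nodes_of_type(self, node_type: str) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True)
                      if d["type"] == node_type)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> list[tuple[str, str, str]]:
        """Canonical (u, v, provenance) list, endpoints ordered by (type, id)."""
        out = []
        for u, v, data in self.graph.edges(data=True):
            a, b = sorted((u, v), key=self._node_sort_key)
            out.append((a, b, data["provenance"]))
        return sorted(out)

    def _node_sort_key(self, node: str) -> tuple[int, str]:
        return NODE_TYPES.index(self.graph.nodes[node]["type"]), node

    def sorted_nodes(self) -> list[str]:
        return sorted(self.graph.nodes, key=self._node_sort_key)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BipartiteNetwork):
            return NotImplemented
        return (
            {n: d["type"] for n, d in self.graph.nodes(data=True)}
            == {n: d["type"] for n, d in other.graph.nodes(data=True)}
            and self.edges() == other.edges()
        )


def build_ct_network(
    catalog: FormulaCatalog,
    edges: Iterable[tuple[str, str, str]],
) -> BipartiteNetwork:
    """Compound-target network from (drug id, target, provenance) edges.

    Drug ids are resolved against the catalog (compound id, canonical
    key, or name key) and replaced by the catalog's compound id, so one
    molecule appearing under several aliases yields one node.  Only
    compounds with at least one edge enter the network.
    """
    index = catalog.compound_index()
    net = BipartiteNetwork()
    resolved = []
    for drug, target, provenance in edges:
        rec = index.get(drug) or index.get("NAME:" + _normalize_name(drug))
        if rec is None:
            continue
        resolved.append((rec.compound_id, target, provenance))
    if not resolved:
        raise ValueError("no edges reference catalog compounds")
    for cid, target, provenance in sorted(resolved):
        net.add_node(cid, "compound")
        net.add_node(target, "target")
        net.add_edge(cid, target, provenance)
    return net


def build_ht_network(attribution: CandidateTargetSet) -> BipartiteNetwork:
    """Herb-target network: herb h -- target t iff t in per_herb[h]."""
    net = BipartiteNetwork()
    for herb in sorted(attribution.per_herb):
        targets = attribution.per_herb[herb]
        if not targets:
            continue
        net.add_node(herb, "herb")
        for t in sorted(targets):
            net.add_node(t, "target")
            net.add_edge(herb, t, "known")
    return net


@dataclass
class DegreeReport:
    """Node degrees with per-type ranked tables and hub lists."""

    degrees: dict[str, int]
    tables: dict[str, pd.DataFrame]
    hubs: dict[str, list[str]]


def degree_report(
    net: BipartiteNetwork,
    thresholds: dict[str, int] | None = None,
) -> DegreeReport:
    """Degrees, ranked per-type tables, and hubs above per-type thresholds.

    Hubs are nodes with degree *strictly greater* than their type's
    threshold, sorted by (degree desc, id asc).  Default thresholds keep
    the conventional report cutoffs of 5 edges per compound and 100
    compounds per target; both are dataset-scale-dependent and freely
    configurable.
    """
    thresholds = {"compound": 5, "target": 100, "herb": 0, **(thresholds or {})}
    degrees = {n: int(d) for n, d in net.graph.degree()}
    tables: dict[str, pd.DataFrame] = {}
    hubs: dict[str, list[str]] = {}
    for node_type in NODE_TYPES:
        nodes = net.nodes_of_type(node_type)
        if not nodes:
            continue
        ranked = sorted(nodes, key=lambda n: (-degrees[n], n))
        tables[node_type] = pd.DataFrame(
            {"node": ranked, "degree": [degrees[n] for n in ranked]}
        )
        cut = thresholds.get(node_type, 0)
        hubs[node_type] = [n for n in ranked if degrees[n] > cut]
    return DegreeReport(degrees=degrees, tables=tables, hubs=hubs)


def export_graph(net: BipartiteNetwork, path: str | Path, format: str) -> Path:
    """Write the network as GraphML, SIF, or edge-list CSV.

    All three formats round-trip through :func:`import_graph`.  The SIF
    body uses the standard three-column form with relation tokens
    ``targets`` / ``contains``; node types and edge provenance, which
    plain SIF cannot carry, are stored in ``#``-prefixed metadata lines
    that SIF-oblivious tools ignore.
    """
    path = Path(path)
    if format == "graphml":
        ordered = nx.Graph()
        for n in net.sorted_nodes():
            ordered.add_node(n, type=net.node_type(n))
        for u, v, prov in net.edges():
            ordered.add_edge(u, v, provenance=prov)
        nx.write_graphml(ordered, path)
    elif format == "sif":
        with open(path, "w") as fh:
            for n in net.sorted_nodes():
                fh.write(f"#node\t{n}\t{net.node_type(n)}\n")
            for u, v, prov in net.edges():
                relation = _SIF_RELATION[net.node_type(v)]
                fh.write(f"#provenance\t{u}\t{v}\t{prov}\n")
                fh.write(f"{u}\t{relation}\t{v}\n")
    elif format == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(["source", "source_type", "target", "target_type",
                             "provenance"])
            for u, v, prov in net.edges():
                writer.writerow([u, net.node_type(u), v, net.node_type(v), prov])
    else:
        raise ValueError(f"unknown export format {format!r}")
    return path


def import_graph(path: str | Path, format: str) -> BipartiteNetwork:
    """Read a network previously written by :func:`export_graph`."""
    path = Path(path)
    net = BipartiteNetwork()
    if format == "graphml":
        g = nx.read_graphml(path)
        for n, data in g.nodes(data=True):
            net.add_node(n, data["type"])
        for u, v, data in g.edges(data=True):
            net.add_edge(u, v, data["provenance"])
    elif format == "sif":
        provenance: dict[frozenset[str], str] = {}
        edges: list[tuple[str, str]] = []
        for line in path.read_text().splitlines():
            if line.startswith("#node\t"):
                _, node, node_type = line.split("\t")
                net.add_node(node, node_type)
            elif line.startswith("#provenance\t"):
                _, u, v, prov = line.split("\t")
                provenance[frozenset((u, v))] = prov
            elif line.strip():
                u, _, v = line.split("\t")
                edges.append((u, v))
        for u, v in edges:
            net.add_edge(u, v, provenance.get(frozenset((u, v)), "known"))
    elif format == "csv":
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                net.add_node(row["source"], row["source_type"])
                net.add_node(row["target"], row["target_type"])
                net.add_edge(row["source"], row["target"], row["provenance"])
    else:
        raise ValueError(f"unknown import format {format!r}")
    return net
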