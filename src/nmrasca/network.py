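"""Biomarker sub-network extraction from a metabolite-reaction graph.

The metabolic network is a directed bipartite graph: metabolite nodes
feed reaction nodes (substrate arcs) and reaction nodes feed metabolite
nodes (product arcs).  For every unordered pair of biomarker metabolites
the lightest connecting reaction sequence is computed — by default the
cost of entering a metabolite node is its degree, which steers paths away
from ubiquitous hub compounds — and the union of all accepted paths,
with per-node provenance, forms the sub-network handed to visual mining.

Side compounds (ATP, NADH, water, ...) are excluded as traversal nodes
via an editable list; ties between equal-weight paths are broken
lexicographically on the node-id sequence so results are deterministic.
"""

from __future__ import annotations

import heapq
import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger("nmrasca")

__all__ = [
    "MetabolicNetwork",
    "PairPath",
    "SubNetwork",
    "load_network",
    "load_sbml",
    "connect_pair",
    "union_subnetwork",
]

#: common side compounds; user lists override this default
DEFAULT_SIDE_COMPOUNDS = frozenset(
    {"ATP", "ADP", "AMP", "NAD+", "NADH", "NADP+", "NADPH", "H2O", "H+",
     "CO2", "Pi", "PPi", "CoA", "O2"}
)


@dataclass
class MetabolicNetwork:
    """Directed bipartite metabolite/reaction graph."""

    graph: nx.DiGraph
    side_compounds: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for node, data in self.graph.nodes(data=True):
            if data.get("type") not in ("metabolite", "reaction"):
                raise ValueError(f"node {node!r} lacks a metabolite/reaction type")
        for u, v in self.graph.edges():
            tu = self.graph.nodes[u]["type"]
            tv = self.graph.nodes[v]["type"]
            if tu == tv:
                raise ValueError(f"non-bipartite edge {u!r} -> {v!r} (both {tu})")

    @property
    def metabolites(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["type"] == "metabolite")

    @property
    def reactions(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["type"] == "reaction")

    def degree_of(self, metabolite: str) -> int:
        return self.graph.in_degree(metabolite) + self.graph.out_degree(metabolite)

    def to_edgelist(self, path: str | Path) -> None:
        rows = []
        for u, v in sorted(self.graph.edges()):
            kind = "substrate" if self.graph.nodes[u]["type"] == "metabolite" else "product"
            rows.append({"source": u, "target": v, "type": kind})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_network(
    path: str | Path,
    fmt: str = "edgelist",
    side_compounds: Iterable[str] | None = None,
) -> MetabolicNetwork:
    """Read a metabolite-reaction network from an edge-list TSV or SBML.

    Edge-list columns: ``source``, ``target``, ``type`` (substrate:
    metabolite -> reaction; product: reaction -> metabolite) and an
    optional truthy ``reversible`` that mirrors the arc.
    """
    if fmt == "sbml":
        return load_sbml(path, side_compounds=side_compounds)
    df = pd.read_csv(path, sep="\t")
    for col in ("source", "target", "type"):
        if col not in df.columns:
            raise ValueError(f"edge list missing column {col!r}")
    g = nx.DiGraph()
    for row in df.itertuples(index=False):
        src, dst, kind = str(row.source), str(row.target), str(row.type)
        if kind == "substrate":
            met, rxn = src, dst
            g.add_node(met, type="metabolite")
            g.add_node(rxn, type="reaction")
            g.add_edge(met, rxn)
            if getattr(row, "reversible", False):
                g.add_edge(rxn, met)
        elif kind == "product":
            rxn, met = src, dst
            g.add_node(rxn, type="reaction")
            g.add_node(met, type="metabolite")
            g.add_edge(rxn, met)
            if getattr(row, "reversible", False):
                g.add_edge(met, rxn)
        else:
            raise ValueError(f"unknown edge type {kind!r}")
    _warn_dangling(g)
    net = MetabolicNetwork(
        graph=g,
        side_compounds=frozenset(side_compounds) if side_compounds is not None
        else frozenset(),
    )
    logger.info(
        "loaded network: %d metabolites, %d reactions",
        len(net.metabolites), len(net.reactions),
    )
    return net


def load_sbml(path: str | Path, side_compounds: Iterable[str] | None = None) -> MetabolicNetwork:
    """Minimal SBML import (via cobra); reversible reactions get arcs both ways."""
    from cobra.io import read_sbml_model

    model = read_sbml_model(str(path))
    g = nx.DiGraph()
    for rxn in model.reactions:
        g.add_node(rxn.id, type="reaction")
        for met, coef in rxn.metabolites.items():
            g.add_node(met.id, type="metabolite")
            if coef < 0:
                g.add_edge(met.id, rxn.id)
                if rxn.reversibility:
                    g.add_edge(rxn.id, met.id)
            else:
                g.add_edge(rxn.id, met.id)
                if rxn.reversibility:
                    g.add_edge(met.id, rxn.id)
    _warn_dangling(g)
    return MetabolicNetwork(
        graph=g,
        side_compounds=frozenset(side_compounds) if side_compounds is not None
        else frozenset(),
    )


def _warn_dangling(g: nx.DiGraph) -> None:
    for node, data in g.nodes(data=True):
        if data["type"] == "reaction":
            has_sub = any(True for _ in g.predecessors(node))
            has_prod = any(True for _ in g.successors(node))
            if not (has_sub or has_prod):
                logger.warning("dangling reaction %r (no substrate or product)", node)


# ---------------------------------------------------------------------------
# Path computation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairPath:
    """Lightest reaction sequence between two biomarkers (or unreachable)."""

    source: str
    target: str
    nodes: tuple[str, ...]      # alternating metabolite/reaction sequence
    weight: float
    reachable: bool

    @property
    def reactions(self) -> tuple[str, ...]:
        return self.nodes[1::2]

    @property
    def metabolites(self) -> tuple[str, ...]:
        return self.nodes[0::2]


def _node_cost(net: MetabolicNetwork, node: str, weighting: str) -> float:
    if weighting == "degree" and net.graph.nodes[node]["type"] == "metabolite":
        return float(net.degree_of(node))
    return 1.0


def _lightest_path(
    net: MetabolicNetwork,
    source: str,
    target: str,
    weighting: str,
    blocked: frozenset[str],
) -> tuple[float, tuple[str, ...]] | None:
    """Dijkstra on (weight, node-id sequence) keys: deterministic tie-break.

    The path weight is the sum, over traversed arcs, of the cost of the
    node being entered; lexicographic comparison of the node sequences
    orders equal-weight paths, and prefix order is preserved under
    extension, so the first settlement of the target is optimal.
    """
    g = net.graph
    heap: list[tuple[float, tuple[str, ...]]] = [(0.0, (source,))]
    settled: set[str] = set()
    while heap:
        dist, path = heapq.heappop(heap)
        node = path[-1]
        if node == target:
            return dist, path
        if node in settled:
            continue
        settled.add(node)
        for nxt in g.successors(node):
            if nxt in settled or (nxt in blocked and nxt != target):
                continue
            heapq.heappush(heap, (dist + _node_cost(net, nxt, weighting), path + (nxt,)))
    return None


def connect_pair(
    net: MetabolicNetwork,
    metabolite_a: str,
    metabolite_b: str,
    weighting: str = "degree",
    side_compounds: Iterable[str] | None = None,
) -> PairPath:
    """Lightest path from one biomarker to another.

    ``weighting='degree'`` (default) charges each traversed metabolite its
    network degree; ``'unweighted'`` charges 1 per arc.  Side compounds
    are never used as intermediate nodes.  Unreachable pairs yield a
    sentinel with ``reachable=False``, not an exception.
    """
    if weighting not in ("degree", "unweighted"):
        raise ValueError(f"unknown weighting {weighting!r}")
    g = net.graph
    for m in (metabolite_a, metabolite_b):
        if m not in g or g.nodes[m]["type"] != "metabolite":
            raise KeyError(f"unknown metabolite {m!r}")
    blocked = frozenset(side_compounds if side_compounds is not None else net.side_compounds)
    blocked = blocked - {metabolite_a, metabolite_b}
    hit = _lightest_path(net, metabolite_a, metabolite_b, weighting, blocked)
    if hit is None:
        return PairPath(metabolite_a, metabolite_b, (), float("inf"), reachable=False)
    weight, nodes = hit
    return PairPath(metabolite_a, metabolite_b, nodes, weight, reachable=True)


# ---------------------------------------------------------------------------
# Union sub-network
# ---------------------------------------------------------------------------

@dataclass
class SubNetwork:
    """Union of accepted pairwise paths with per-node provenance."""

    graph: nx.DiGraph
    provenance: dict[str, set[tuple[str, str]]]
    paths: list[PairPath]
    unreachable_pairs: list[tuple[str, str]]

    def export(self, path: str | Path, fmt: str = "graphml") -> None:
        g = self.graph.copy()
        for node in g.nodes:
            pairs = sorted(self.provenance.get(node, set()))
            g.nodes[node]["provenance"] = ";".join(f"{a}|{b}" for a, b in pairs)
        if fmt == "graphml":
            nx.write_graphml(g, path)
        elif fmt == "gml":
            nx.write_gml(g, str(path))
        else:
            raise ValueError(f"unknown export format {fmt!r}")


def union_subnetwork(
    net: MetabolicNetwork,
    biomarkers: Sequence[str],
    weighting: str = "degree",
    side_compounds: Iterable[str] | None = None,
) -> SubNetwork:
    """Union of the lightest paths over all unordered biomarker pairs.

    Output is invariant to the biomarker input order (pairs are processed
    sorted).  If no pair is reachable the sub-network is empty and every
    pair is reported unreachable.
    """
    markers = sorted(dict.fromkeys(biomarkers))
    if len(markers) < 2:
        raise ValueError("need at least 2 biomarkers")
    sub = nx.DiGraph()
    provenance: dict[str, set[tuple[str, str]]] = {}
    paths: list[PairPath] = []
    unreachable: list[tuple[str, str]] = []
    for a, b in itertools.combinations(markers, 2):
        pp = connect_pair(net, a, b, weighting=weighting, side_compounds=side_compounds)
        if not pp.reachable:
            unreachable.append((a, b))
            continue
        paths.append(pp)
        for node in pp.nodes:
            sub.add_node(node, **net.graph.nodes[node])
            provenance.setdefault(node, set()).add((a, b))
        for u, v in zip(pp.nodes, pp.nodes[1:]):
            sub.add_edge(u, v)
    if not paths:
        logger.warning("all %d biomarker pairs unreachable; empty sub-network",
                       len(unreachable))
    return SubNetwork(graph=sub, provenance=provenance, paths=paths,
                      unreachable_pairs=unreachable)
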