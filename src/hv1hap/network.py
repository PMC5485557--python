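"""Haplotype networks: minimum-distance spanning structures per haplogroup.

Haplotypes of one haplogroup are connected by links labelled with the
number of nucleotide differences (event-set distance) between their
profiles; node weight is the commonness of the haplotype (how many
sequences carry it).  The structure kept is a minimum spanning tree of the
complete distance graph with deterministic tie-breaking, plus every
equal-cost alternative edge flagged as a reticulation, so tied topologies
are visible rather than silently resolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import networkx as nx

from .mutation_model import profile_distance
from .registry import Registry

__all__ = [
    "HaplotypeNetwork",
    "NetworkExportError",
    "build_network",
    "export_network",
    "import_network_tsv",
    "FORMATS",
]

FORMATS = ("GML", "DOT", "TSV")


class NetworkExportError(ValueError):
    """Unknown export format or malformed network file."""


@dataclass
class HaplotypeNetwork:
    """Nodes with commonness weights; edges with nucleotide distances.

    ``edges`` maps an unordered name pair (stored sorted) to its distance;
    ``alternative`` marks the equal-cost non-tree links (reticulations).
    """

    nodes: dict[str, int] = field(default_factory=dict)
    edges: dict[tuple[str, str], int] = field(default_factory=dict)
    alternative: set[tuple[str, str]] = field(default_factory=set)

    def tree_edges(self) -> dict[tuple[str, str], int]:
        return {k: v for k, v in self.edges.items() if k not in self.alternative}

    def total_distance(self) -> int:
        return sum(self.tree_edges().values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HaplotypeNetwork):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and self.edges == other.edges
            and self.alternative == other.alternative
        )


def _pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def build_network(
    reg: Registry,
    haplogroup: str,
    weights: Optional[dict[str, int]] = None,
) -> HaplotypeNetwork:
    """Build the haplogroup's minimum-distance spanning network.

    The complete pairwise distance matrix is reduced per connected
    component to a minimum spanning tree (Kruskal on edges sorted by
    (distance, endpoint names), so the result is deterministic); any
    non-tree edge whose distance equals the largest distance on the tree
    path between its endpoints could appear in some other minimum tree and
    is retained, flagged as alternative.
    """
    defs = reg.in_group(haplogroup)
    weights = weights or {}
    net = HaplotypeNetwork(nodes={d.name: int(weights.get(d.name, 1)) for d in defs})
    if len(defs) < 2:
        return net
    complete = nx.Graph()
    complete.add_nodes_from(d.name for d in defs)
    for i, a in enumerate(defs):
        for b in defs[i + 1 :]:
            complete.add_edge(a.name, b.name, weight=profile_distance(a.profile, b.profile))
    ordered = sorted(
        complete.edges(data="weight"), key=lambda e: (e[2], _pair(e[0], e[1]))
    )
    tree = nx.Graph()
    tree.add_nodes_from(complete.nodes)
    uf = nx.utils.UnionFind(complete.nodes)
    for u, v, w in ordered:
        if uf[u] != uf[v]:
            uf.union(u, v)
            tree.add_edge(u, v, weight=w)
            net.edges[_pair(u, v)] = int(w)
    # retain equal-cost alternatives: an edge belongs to some minimum tree
    # iff its weight equals the bottleneck (max edge) on the tree path
    for u, v, w in ordered:
        if _pair(u, v) in net.edges:
            continue
        path = nx.shortest_path(tree, u, v)
        bottleneck = max(
            tree[a][b]["weight"] for a, b in zip(path, path[1:])
        )
        if w == bottleneck:
            net.edges[_pair(u, v)] = int(w)
            net.alternative.add(_pair(u, v))
    return net


def _to_nx(net: HaplotypeNetwork) -> nx.Graph:
    g = nx.Graph()
    for name, weight in net.nodes.items():
        g.add_node(name, weight=int(weight))
    for (u, v), d in net.edges.items():
        g.add_edge(u, v, distance=int(d), alternative=(u, v) in net.alternative)
    return g


def export_network(net: HaplotypeNetwork, fmt: str, path: Union[str, Path]) -> None:
    """Write a network as GML, DOT or a TSV that round-trips losslessly."""
    fmt = fmt.upper()
    path = Path(path)
    if fmt == "GML":
        nx.write_gml(_to_nx(net), str(path))
    elif fmt == "DOT":
        lines = ["graph haplotype_network {"]
        for name in sorted(net.nodes):
            lines.append(f'  "{name}" [weight={net.nodes[name]}];')
        for (u, v) in sorted(net.edges):
            d = net.edges[(u, v)]
            style = ', style="dashed"' if (u, v) in net.alternative else ""
            lines.append(f'  "{u}" -- "{v}" [label={d}{style}];')
        lines.append("}")
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif fmt == "TSV":
        lines = []
        for name in sorted(net.nodes):
            lines.append(f"node\t{name}\t{net.nodes[name]}")
        for (u, v) in sorted(net.edges):
            alt = "alternative" if (u, v) in net.alternative else "tree"
            lines.append(f"edge\t{u}\t{v}\t{net.edges[(u, v)]}\t{alt}")
        path.write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
    else:
        raise NetworkExportError(f"unknown network format {fmt!r}; expected one of {FORMATS}")


def import_network_tsv(path: Union[str, Path]) -> HaplotypeNetwork:
    """Read back a TSV written by :func:`export_network`."""
    net = HaplotypeNetwork()
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if parts[0] == "node" and len(parts) == 3:
            net.nodes[parts[1]] = int(parts[2])
        elif parts[0] == "edge" and len(parts) == 5:
            pair = _pair(parts[1], parts[2])
            net.edges[pair] = int(parts[3])
            if parts[4] == "alternative":
                net.alternative.add(pair)
        else:
            raise NetworkExportError(f"{path}:{lineno}: malformed network line")
    return net
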