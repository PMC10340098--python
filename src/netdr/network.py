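"""Weighted functional interaction network and direct-neighbor gene modules.

The FIN is an undirected graph over gene identifiers whose edge weights in
(0, 1] encode functional similarity.  Edges below a weight floor carry too
little evidence and are pruned; nodes left without any edge are dropped.
A gene module (DAPN or DGN) is a seed gene set mapped onto the FIN together
with all direct (1-hop) neighbors, plus the induced subnetwork.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx


class NetworkError(ValueError):
    """Invalid network content or an operation on an unusable network."""


class EdgeListParseError(NetworkError):
    """A malformed row in an edge-list file; message names the line."""


class WeightedNetwork:
    """Undirected weighted gene–gene graph with weights in (0, 1].

    Thin wrapper around :class:`networkx.Graph` that enforces the FIN
    invariants: no self-loops, no duplicate pairs, weights in (0, 1].
    """

    __slots__ = ("graph",)

    def __init__(self, graph: nx.Graph):
        self.graph = graph

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str, float]]) -> "WeightedNetwork":
        """Build from (gene_a, gene_b, weight) triples.

        Self-loops are dropped; duplicate pairs keep the maximum weight.
        """
        g = nx.Graph()
        for a, b, w in edges:
            if a == b:
                continue
            w = float(w)
            if not (0.0 < w <= 1.0):
                raise NetworkError(f"edge ({a}, {b}) weight {w!r} outside (0, 1]")
            if g.has_edge(a, b):
                if w > g[a][b]["weight"]:
                    g[a][b]["weight"] = w
            else:
                g.add_edge(a, b, weight=w)
        return cls(g)

    # -- basic accessors ---------------------------------------------------
    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def has_node(self, gene: str) -> bool:
        return self.graph.has_node(gene)

    def neighbors(self, gene: str) -> Iterator[str]:
        return self.graph.neighbors(gene)

    def weight(self, a: str, b: str) -> float:
        return self.graph[a][b]["weight"]

    def edges(self) -> Iterator[tuple[str, str, float]]:
        for a, b, d in self.graph.edges(data="weight"):
            yield a, b, d

    def __contains__(self, gene: str) -> bool:
        return self.graph.has_node(gene)

    def __repr__(self) -> str:  # pragma: no cover
        return f"WeightedNetwork({self.n_nodes} nodes, {self.n_edges} edges)"

    def copy(self) -> "WeightedNetwork":
        return WeightedNetwork(self.graph.copy())


@dataclass(frozen=True)
class GeneModule:
    """A seed gene set mapped onto the FIN with its direct neighborhood.

    ``members = seeds ∪ {v : v adjacent to some seed}``; ``subnetwork`` is the
    source network induced on ``members``.  ``kind`` tags the module as a
    drug-affected protein network ("DAPN") or disease gene network ("DGN").
    """

    seeds: frozenset[str]
    members: frozenset[str]
    subnetwork: WeightedNetwork
    kind: str = field(default="DAPN")

    def __post_init__(self):
        if not self.seeds <= self.members:
            raise NetworkError("module seeds must be a subset of members")

    @property
    def n_members(self) -> int:
        return len(self.members)


def _looks_numeric(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def load_network(edge_list_path: str | Path, weight_floor: float = 0.1) -> WeightedNetwork:
    """Load a 3-column edge list and prune edges below ``weight_floor``.

    Format: tab- (or whitespace-) separated ``gene_a  gene_b  weight`` rows;
    an optional header is detected by a non-numeric third field on line 1.
    Edges with weight strictly below the floor are excluded (a weight equal
    to the floor survives), duplicate pairs keep the maximum weight,
    self-loops are dropped, and nodes left with no edge are removed.

    Raises
    ------
    EdgeListParseError
        On a row with the wrong column count or a non-numeric weight; the
        message names the offending line number.
    NetworkError
        If no edge survives pruning.
    """
    if not 0.0 <= weight_floor <= 1.0:
        raise ValueError(f"weight_floor must be in [0, 1], got {weight_floor}")
    path = Path(edge_list_path)
    edges: list[tuple[str, str, float]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != 3:
                raise EdgeListParseError(
                    f"{path.name}:{lineno}: expected 3 columns, found {len(fields)}"
                )
            a, b, w_tok = fields
            if lineno == 1 and not _looks_numeric(w_tok):
                continue  # header row
            try:
                w = float(w_tok)
            except ValueError:
                raise EdgeListParseError(
                    f"{path.name}:{lineno}: non-numeric weight {w_tok!r}"
                ) from None
            edges.append((a, b, w))
    net = WeightedNetwork.from_edges(edges)
    return prune_network(net, weight_floor)


def prune_network(net: WeightedNetwork, weight_floor: float) -> WeightedNetwork:
    """Drop edges with weight strictly below the floor, then isolated nodes.

    Idempotent: pruning an already-pruned network at the same floor is a
    no-op.  Raises :class:`NetworkError` if nothing survives.
    """
    g = nx.Graph()
    for a, b, w in net.edges():
        if w >= weight_floor:
            g.add_edge(a, b, weight=w)
    if g.number_of_edges() == 0:
        raise NetworkError(
            f"no edges survive pruning at weight floor {weight_floor}; empty network"
        )
    return WeightedNetwork(g)


def build_module(net: WeightedNetwork, seeds: Iterable[str], kind: str = "DAPN") -> GeneModule:
    """Map seed genes onto the network and take their direct neighborhood.

    Seeds absent from the network are silently intersected away; if *no*
    seed maps, raises :class:`NetworkError` listing the missing genes.
    """
    seed_set = set(seeds)
    present = seed_set & net.nodes
    if not present:
        missing = ", ".join(sorted(seed_set)[:10])
        raise NetworkError(
            f"no seed gene present in network (missing: {missing}"
            + ("..." if len(seed_set) > 10 else ")")
        )
    members = set(present)
    for s in present:
        members.update(net.neighbors(s))
    sub = nx.Graph()
    sub.add_nodes_from(members)
    for a, b, w in net.edges():
        if a in members and b in members:
            sub.add_edge(a, b, weight=w)
    return GeneModule(
        seeds=frozenset(present),
        members=frozenset(members),
        subnetwork=WeightedNetwork(sub),
        kind=kind,
    )


def write_module(module: GeneModule, node_path: str | Path, edge_path: str | Path) -> None:
    """Export a module as node (``gene\tis_seed``) and edge TSV tables."""
    with Path(node_path).open("w") as fh:
        fh.write("gene\tis_seed\n")
        for gene in sorted(module.members):
            fh.write(f"{gene}\t{int(gene in module.seeds)}\n")
    with Path(edge_path).open("w") as fh:
        fh.write("gene_a\tgene_b\tweight\n")
        for a, b, w in sorted(module.subnetwork.edges()):
            fh.write(f"{a}\t{b}\t{w:.10g}\n")


def write_network(net: WeightedNetwork, path: str | Path) -> None:
    """Write the network as a 3-column TSV edge list."""
    with Path(path).open("w") as fh:
        fh.write("gene_a\tgene_b\tweight\n")
        for a, b, w in sorted(net.edges()):
            fh.write(f"{a}\t{b}\t{w:.10g}\n")
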