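"""Ligand-water-DNA contact graphs: bridges, shells, clusters and mediation counts.

The contact graph is an undirected networkx graph whose nodes are polar-atom
labels ("NCH", "W204", "OP2 dG10") tagged with a kind (``ligand``, ``water``,
``dna``, ...) and whose edges are accepted hydrogen bonds.  On top of it:

* *bridges* — simple paths ligand -> water^k -> DNA (1 <= k <= ``max_waters``),
  the water-mediated contacts between a bound small molecule and the
  quadruplex;
* *shells* — first-shell waters touch a non-water node directly, second-shell
  waters touch only first-shell waters, the rest are bulk-like;
* *clusters* — connected components of the water-water subgraph with their
  non-water anchor atoms;
* *mediation summary* — direct ligand-DNA hydrogen bonds versus ligand atoms
  reaching the DNA only through water.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx

from .hbond import HydrogenBond

__all__ = [
    "BridgePath",
    "WaterCluster",
    "MediationSummary",
    "WatersPerQuadruplex",
    "build_graph",
    "find_bridges",
    "classify_shells",
    "water_clusters",
    "mediation_summary",
    "waters_per_quadruplex",
]


def water_nodes_of(structure) -> list:
    """Water-oxygen :class:`~gqwaters.hbond.BondAtom` nodes of a structure,
    including waters with no accepted hydrogen bond (bulk-like singletons)."""
    from .hbond import BondAtom

    nodes = []
    for res in structure.waters:
        oxy = next((a for a in res.atoms if a.element.upper() == "O"), None)
        if oxy is not None:
            nodes.append(BondAtom(res.label, "water", oxy.b_factor))
    return nodes


def build_graph(hbonds: Iterable[HydrogenBond], extra_nodes: Iterable = ()) -> nx.Graph:
    """Assemble the undirected contact graph from accepted hydrogen bonds.

    ``extra_nodes`` (e.g. from :func:`water_nodes_of`) adds edgeless atoms so
    that isolated waters appear as bulk-like singletons downstream.
    """
    g = nx.Graph()
    for endpoint in extra_nodes:
        if endpoint.label not in g:
            g.add_node(endpoint.label, kind=endpoint.kind, b_factor=endpoint.b_factor)
    for bond in hbonds:
        for endpoint in (bond.atom_a, bond.atom_b):
            if endpoint.label not in g:
                g.add_node(
                    endpoint.label, kind=endpoint.kind, b_factor=endpoint.b_factor
                )
            elif g.nodes[endpoint.label].get("b_factor") is None:
                g.nodes[endpoint.label]["b_factor"] = endpoint.b_factor
        if bond.atom_a.label == bond.atom_b.label:
            continue  # no self-loops
        g.add_edge(
            bond.atom_a.label,
            bond.atom_b.label,
            distance=bond.distance,
            category=bond.category,
            group=bond.group,
        )
    return g


@dataclass(frozen=True)
class BridgePath:
    """A water-mediated ligand-to-DNA contact path."""

    ligand_atom: str
    waters: tuple[str, ...]
    dna_atom: str
    total_length: float

    @property
    def k(self) -> int:
        return len(self.waters)


def _kind(g: nx.Graph, node: str) -> str:
    return g.nodes[node].get("kind", "other")


def find_bridges(graph: nx.Graph, max_waters: int = 4) -> list[BridgePath]:
    """Enumerate all simple ligand->water^k->DNA paths with 1 <= k <= max_waters.

    Paths are deduplicated and sorted by (ligand atom, k, total length, labels).
    """
    if max_waters < 1:
        raise ValueError("max_waters must be >= 1")
    ligands = [n for n in graph if _kind(graph, n) == "ligand"]
    bridges: set[BridgePath] = set()

    def extend(ligand: str, chain: list[str], length: float) -> None:
        tip = chain[-1]
        for nxt in graph[tip]:
            d = graph[tip][nxt]["distance"]
            knd = _kind(graph, nxt)
            if knd == "dna":
                bridges.add(
                    BridgePath(ligand, tuple(chain), nxt, round(length + d, 6))
                )
            elif knd == "water" and nxt not in chain and len(chain) < max_waters:
                chain.append(nxt)
                extend(ligand, chain, length + d)
                chain.pop()

    for ligand in sorted(ligands):
        for w in graph[ligand]:
            if _kind(graph, w) == "water":
                extend(ligand, [w], graph[ligand][w]["distance"])
    return sorted(
        bridges,
        key=lambda b: (b.ligand_atom, b.k, b.total_length, b.waters, b.dna_atom),
    )


def classify_shells(graph: nx.Graph) -> dict[str, str]:
    """Label every water node ``first``, ``second`` or ``bulk-like``.

    First shell: adjacent to at least one non-water node.  Second shell: not
    first, adjacent to at least one first-shell water.  Everything else is
    bulk-like.  The three labels partition the water nodes.
    """
    waters = [n for n in graph if _kind(graph, n) == "water"]
    labels: dict[str, str] = {}
    first = {
        w
        for w in waters
        if any(_kind(graph, nb) != "water" for nb in graph[w])
    }
    for w in waters:
        if w in first:
            labels[w] = "first"
        elif any(nb in first for nb in graph[w]):
            labels[w] = "second"
        else:
            labels[w] = "bulk-like"
    return labels


@dataclass(frozen=True)
class WaterCluster:
    """A connected component of the water-water subgraph plus its anchors."""

    members: tuple[str, ...]
    anchors: tuple[str, ...]
    group_label: Optional[str] = None

    @property
    def size(self) -> int:
        return len(self.members)


def water_clusters(graph: nx.Graph) -> list[WaterCluster]:
    """Connected components of the water-water subgraph, singletons included.

    Anchors are the non-water nodes adjacent to any member.  A cluster's group
    label is taken from its edges' groove annotations when they agree.
    """
    waters = [n for n in graph if _kind(graph, n) == "water"]
    sub = graph.subgraph(waters)
    clusters = []
    for comp in nx.connected_components(sub):
        members = tuple(sorted(comp))
        anchors = sorted(
            {
                nb
                for w in comp
                for nb in graph[w]
                if _kind(graph, nb) != "water"
            }
        )
        groups = {
            graph[u][v].get("group")
            for w in comp
            for u, v in graph.edges(w)
            if graph[u][v].get("group") is not None
        }
        label = groups.pop() if len(groups) == 1 else None
        clusters.append(WaterCluster(members, tuple(anchors), label))
    return sorted(clusters, key=lambda c: (-c.size, c.members))


@dataclass
class MediationSummary:
    """Direct versus water-mediated ligand contacts."""

    n_direct_ligand_dna: int
    direct_edges: list[tuple[str, str, float]]
    water_adjacent_ligand_atoms: list[str]
    bridged_ligand_atoms: list[str]
    per_atom: dict[str, dict] = field(default_factory=dict)

    @property
    def n_water_adjacent(self) -> int:
        return len(self.water_adjacent_ligand_atoms)

    @property
    def n_bridged(self) -> int:
        return len(self.bridged_ligand_atoms)


def mediation_summary(graph: nx.Graph, max_waters: int = 4) -> MediationSummary:
    """Count direct ligand-DNA hydrogen bonds and water-mediating ligand atoms.

    ``water_adjacent_ligand_atoms`` are distinct ligand atoms hydrogen-bonded
    to at least one water; ``bridged_ligand_atoms`` additionally reach a DNA
    atom through a chain of <= ``max_waters`` waters.
    """
    ligands = sorted(n for n in graph if _kind(graph, n) == "ligand")
    if not ligands:
        raise ValueError("contact graph has no ligand nodes")
    direct = []
    for lig in ligands:
        for nb in graph[lig]:
            if _kind(graph, nb) == "dna":
                direct.append((lig, nb, graph[lig][nb]["distance"]))
    water_adj = [
        lig for lig in ligands if any(_kind(graph, nb) == "water" for nb in graph[lig])
    ]
    bridges = find_bridges(graph, max_waters=max_waters)
    bridged = sorted({b.ligand_atom for b in bridges})
    per_atom = {}
    for lig in ligands:
        per_atom[lig] = {
            "direct_dna": sorted(
                nb for nb in graph[lig] if _kind(graph, nb) == "dna"
            ),
            "waters": sorted(
                nb for nb in graph[lig] if _kind(graph, nb) == "water"
            ),
            "n_bridges": sum(1 for b in bridges if b.ligand_atom == lig),
        }
    return MediationSummary(
        n_direct_ligand_dna=len(direct),
        direct_edges=sorted(direct),
        water_adjacent_ligand_atoms=water_adj,
        bridged_ligand_atoms=bridged,
        per_atom=per_atom,
    )


@dataclass(frozen=True)
class WatersPerQuadruplex:
    per_gq: int
    exact: float


def waters_per_quadruplex(water_count: int, gq_count: int) -> WatersPerQuadruplex:
    """Waters per quadruplex in the asymmetric unit (integer + exact ratio)."""
    if gq_count < 1:
        raise ValueError("gq_count must be >= 1")
    if water_count < 0:
        raise ValueError("water_count must be >= 0")
    return WatersPerQuadruplex(water_count // gq_count, water_count / gq_count)
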