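"""Minimal-distance allosteric communication pathways.

Fragments become nodes of an undirected graph; an edge joins two
fragments when they are in spatial contact in a reference structure
(minimum inter-Cα distance below a cutoff) and their coupling nMI exceeds
a floor.  The edge cost is -ln(nMI), so multiplicative coupling along a
path becomes additive cost and strongly coupled routes are short.
Optimal source->sink routes are found with Dijkstra's algorithm from a
virtual super-source.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .mi import MIMatrix
from .traj_io import Trajectory, select_calpha

__all__ = [
    "CouplingGraph",
    "PathResult",
    "build_graph",
    "shortest_path",
    "hub_path_overlap",
    "fragments_for_residues",
]

_SUPER_SOURCE = "__source__"


@dataclass
class CouplingGraph:
    """Contact-gated coupling network over fragment nodes."""

    graph: nx.Graph  # nodes: fragment indices; edge attrs: nmi, cost, distance
    labels: list[str]
    cutoff: float  # nm
    min_nmi: float

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class PathResult:
    """One optimal communication route from a source set to a sink."""

    nodes: list[int]  # fragment indices, source -> sink
    labels: list[str]
    total_cost: float
    edge_costs: list[float]
    sink: int
    reachable: bool = True


def _fragment_coords(
    matrix: MIMatrix, reference: Trajectory, frame: int
) -> list[np.ndarray]:
    """Reference Cα coordinates (4 x 3) of each fragment column."""
    chains = {c.chain_id: c for c in select_calpha(reference)}
    coords = []
    for chain_id, first_res in matrix.columns:
        if chain_id not in chains:
            raise ValueError(f"reference structure lacks chain {chain_id!r}")
        ch = chains[chain_id]
        pos = np.searchsorted(ch.res_ids, first_res)
        if pos + 4 > len(ch) or ch.res_ids[pos] != first_res:
            raise ValueError(
                f"fragment {chain_id}:{first_res} not resolvable in reference"
            )
        idx = ch.atom_indices[pos : pos + 4]
        coords.append(reference.coords[frame, idx])
    return coords


def build_graph(
    matrix: MIMatrix | "np.ndarray",
    reference: Trajectory,
    frame: int = 0,
    cutoff: float = 0.75,
    min_nmi: float = 0.01,
) -> CouplingGraph:
    """Build the contact-gated coupling graph from an nMI matrix.

    Edge rule: minimum inter-Cα distance between the two 4-residue
    fragments in the reference frame <= ``cutoff`` (nm), the pair is
    unmasked, and nMI >= ``min_nmi``.  Edge cost is -ln(nMI).
    """
    if not isinstance(matrix, MIMatrix):
        raise TypeError("build_graph needs an MIMatrix (labels and mask required)")
    frag_xyz = _fragment_coords(matrix, reference, frame)
    p = matrix.n_fragments
    g = nx.Graph()
    g.add_nodes_from(range(p))
    for i in range(p):
        for j in range(i + 1, p):
            if not matrix.mask[i, j]:
                continue
            nmi = matrix.values[i, j]
            if nmi < min_nmi:
                continue
            diff = frag_xyz[i][:, None, :] - frag_xyz[j][None, :, :]
            dmin = float(np.sqrt((diff**2).sum(axis=2)).min())
            if dmin > cutoff:
                continue
            g.add_edge(i, j, nmi=float(nmi), cost=float(-np.log(nmi)), distance=dmin)
    if g.number_of_edges() == 0:
        raise ValueError(
            "coupling graph has no edges; relax the contact cutoff or min_nmi"
        )
    return CouplingGraph(graph=g, labels=list(matrix.labels), cutoff=cutoff, min_nmi=min_nmi)


def shortest_path(
    cgraph: CouplingGraph,
    sources: list[int],
    sinks: list[int],
    k: int = 1,
) -> list[PathResult]:
    """Up to ``k`` lowest-cost Dijkstra routes from the source set to sinks.

    A virtual super-source with zero-cost links to every source node makes
    one Dijkstra pass cover all sources.  One best path per sink; sinks
    are then sorted by total cost (ties: lexicographic node sequence).
    Unreachable sinks are reported explicitly with ``reachable=False``.
    """
    if not sources or not sinks:
        raise ValueError("sources and sinks must be non-empty")
    g = cgraph.graph
    for n in list(sources) + list(sinks):
        if n not in g:
            raise KeyError(f"fragment {n} not in graph")

    aug = g.copy()
    aug.add_node(_SUPER_SOURCE)
    for s in sources:
        aug.add_edge(_SUPER_SOURCE, s, cost=0.0)

    dist, paths = nx.single_source_dijkstra(aug, _SUPER_SOURCE, weight="cost")
    results: list[PathResult] = []
    for t in sinks:
        if t not in dist:
            results.append(
                PathResult(
                    nodes=[], labels=[], total_cost=float("inf"),
                    edge_costs=[], sink=t, reachable=False,
                )
            )
            continue
        # among equal-cost routes pick the lexicographically smallest node list
        best = None
        for path in nx.all_shortest_paths(aug, _SUPER_SOURCE, t, weight="cost"):
            trimmed = path[1:]  # drop the virtual source
            if best is None or trimmed < best:
                best = trimmed
        costs = [g[a][b]["cost"] for a, b in zip(best[:-1], best[1:])]
        results.append(
            PathResult(
                nodes=best,
                labels=[cgraph.labels[n] for n in best],
                total_cost=float(dist[t]),
                edge_costs=costs,
                sink=t,
            )
        )
    results.sort(key=lambda r: (not r.reachable, r.total_cost, r.nodes))
    return results[:k] if k is not None else results


def hub_path_overlap(
    paths: list[PathResult], hub_fragments: list[int]
) -> tuple[float, dict[int, bool]]:
    """Fraction of hub fragments lying on at least one path."""
    on_path_nodes = set()
    for p in paths:
        if p.reachable:
            on_path_nodes.update(p.nodes)
    flags = {h: h in on_path_nodes for h in hub_fragments}
    frac = sum(flags.values()) / len(flags) if flags else 0.0
    return float(frac), flags


def fragments_for_residues(
    columns: list[tuple[str, int]], residues: list[tuple[str, int]]
) -> list[int]:
    """Fragment columns touching any listed (chain, residue).

    A fragment starting at residue r covers residues r..r+3.
    """
    wanted = set(residues)
    out = []
    for idx, (chain, first) in enumerate(columns):
        if any((chain, first + d) in wanted for d in range(4)):
            out.append(idx)
    return out
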