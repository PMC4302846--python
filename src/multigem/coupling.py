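"""Coupled-reaction modules from thresholded flux correlations.

Reactions i, j with |rho_ij| above a cutoff (0.95 by default, a deliberately
high threshold) define the edges of an undirected coupling graph; its maximal
cliques are fully coupled reaction modules.  Cliques are enumerated with the
Bron-Kerbosch recursion using pivoting and a degeneracy vertex ordering,
which stays tractable on the dense near-clique graphs that high-threshold
correlation graphs produce.  Modules are annotated with the tissues, periods
and base-model organelle compartments their members span; common-pool
transporters inside a cross-tissue module are flagged as tissue linkers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .core import ModelError, WholePlantModel
from .sampling import CorrelationMatrix

__all__ = [
    "CouplingGraph",
    "CliqueReport",
    "ModuleAnnotation",
    "build_graph",
    "enumerate_maximal_cliques",
    "annotate_modules",
    "bron_kerbosch",
]

DEFAULT_RHO_CUTOFF = 0.95


@dataclass
class CouplingGraph:
    graph: nx.Graph
    rho_cutoff: float

    @property
    def vertices(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self.graph.edges}

    def sign(self, a: str, b: str) -> int:
        """+1 for positive, -1 for negative correlation on an edge."""
        return int(np.sign(self.graph.edges[a, b]["rho"]))


def build_graph(corr: CorrelationMatrix, rho_cutoff: float = DEFAULT_RHO_CUTOFF) -> CouplingGraph:
    """Adjacency on |rho_ij| > rho_cutoff over the included fluxes."""
    if not 0.0 < rho_cutoff <= 1.0:
        raise ModelError(f"rho_cutoff must lie in (0, 1], got {rho_cutoff}")
    g = nx.Graph()
    g.add_nodes_from(corr.flux_ids)
    n = len(corr.flux_ids)
    idx_i, idx_j = np.where(np.triu(np.abs(corr.rho) > rho_cutoff, k=1))
    for i, j in zip(idx_i, idx_j):
        g.add_edge(corr.flux_ids[i], corr.flux_ids[j],
                   rho=float(corr.rho[i, j]))
    return CouplingGraph(g, rho_cutoff)


# ---------------------------------------------------------------------------
# Bron-Kerbosch
# ---------------------------------------------------------------------------


def _degeneracy_order(adj: dict[str, set[str]]) -> list[str]:
    """Vertices in degeneracy order (repeatedly peel a minimum-degree vertex)."""
    degree = {v: len(nbrs) for v, nbrs in adj.items()}
    remaining = set(adj)
    order = []
    while remaining:
        v = min(remaining, key=lambda u: (degree[u], u))
        order.append(v)
        remaining.remove(v)
        for u in adj[v]:
            if u in remaining:
                degree[u] -= 1
    return order


def bron_kerbosch(adj: dict[str, set[str]]) -> list[frozenset[str]]:
    """All maximal cliques of a simple graph given as an adjacency map.

    The outer loop follows a degeneracy ordering; the recursion uses the
    standard pivot rule (expand only vertices not adjacent to a
    max-candidate-degree pivot).
    """
    cliques: list[frozenset[str]] = []

    def expand(r: set[str], p: set[str], x: set[str]) -> None:
        if not p and not x:
            cliques.append(frozenset(r))
            return
        pivot = max(p | x, key=lambda u: (len(adj[u] & p), u))
        for v in sorted(p - adj[pivot]):
            expand(r | {v}, p & adj[v], x & adj[v])
            p = p - {v}
            x = x | {v}

    order = _degeneracy_order(adj)
    pos = {v: i for i, v in enumerate(order)}
    for v in order:
        later = {u for u in adj[v] if pos[u] > pos[v]}
        earlier = {u for u in adj[v] if pos[u] < pos[v]}
        expand({v}, later, earlier)
    return cliques


@dataclass
class ModuleAnnotation:
    tissues: set[str] = field(default_factory=set)
    periods: set[str] = field(default_factory=set)
    compartments: set[str] = field(default_factory=set)
    tissue_linkers: list[str] = field(default_factory=list)
    sign_pattern: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def cross_tissue(self) -> bool:
        return len(self.tissues) > 1


@dataclass
class CliqueReport:
    cliques: list[tuple[str, ...]]  # each sorted; list ordered for determinism
    rho_cutoff: float
    annotations: list[ModuleAnnotation] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.cliques)

    def by_size(self) -> list[tuple[str, ...]]:
        return sorted(self.cliques, key=lambda c: (-len(c), c))


def enumerate_maximal_cliques(
    graph: CouplingGraph, min_size: int = 2
) -> CliqueReport:
    """Complete, duplicate-free set of maximal cliques, lexicographically
    ordered by their sorted member ids.  Singletons are omitted by default
    (``min_size=1`` reports isolated vertices too)."""
    adj = {v: set(graph.graph[v]) for v in graph.graph.nodes}
    cliques = [tuple(sorted(c)) for c in bron_kerbosch(adj) if len(c) >= min_size]
    return CliqueReport(sorted(cliques), graph.rho_cutoff)


def annotate_modules(
    report: CliqueReport, model: WholePlantModel, graph: CouplingGraph | None = None
) -> CliqueReport:
    """Attach tissue/period/compartment labels to every clique.

    Compartments are those of the base metabolites each member reaction
    touches; transport columns in a module spanning more than one tissue are
    flagged as the module's tissue linkers.  Raises on a member with no
    provenance in the model.
    """
    flux_index = model.flux_index
    annotations = []
    for clique in report.cliques:
        ann = ModuleAnnotation()
        for fid in clique:
            if fid not in flux_index:
                raise ModelError(f"no provenance for flux {fid!r}")
            info = flux_index[fid]
            if info.tissue:
                ann.tissues.add(info.tissue)
            if info.period:
                ann.periods.add(info.period)
            if info.kind in ("reaction", "exchange") and info.base_reaction:
                rxn = model.base.reaction(info.base_reaction)
                for met in rxn.stoichiometry:
                    ann.compartments.add(model.base.metabolite(met).compartment)
            elif info.kind in ("transport", "accumulation") and info.species:
                if model.base.has_metabolite(info.species):
                    ann.compartments.add(
                        model.base.metabolite(info.species).compartment
                    )
        if ann.cross_tissue:
            ann.tissue_linkers = [
                fid for fid in clique if flux_index[fid].kind == "transport"
            ]
        if graph is not None:
            for i, a in enumerate(clique):
                for b in clique[i + 1:]:
                    ann.sign_pattern[(a, b)] = graph.sign(a, b)
        annotations.append(ann)
    return CliqueReport(report.cliques, report.rho_cutoff, annotations)
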