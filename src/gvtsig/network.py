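"""Candidate-induced PPI subnetworks and the one-layer outer-gene extension.

Step 3 of the pipeline.  The candidate gene list is projected onto a
confidence-weighted interaction graph (STRING-style, confidence in [0, 1]):
only edges at or above a confidence cutoff are retained.  Optionally the
subnetwork is extended by *outer genes* — non-candidate genes one
interaction hop away from a candidate — which add network context without
enlarging the candidate list itself.

Candidates with no high-confidence interactions remain in the subnetwork as
degree-0 nodes: the absence of curated interactions (as for recently
described proteins) is not evidence against the candidate.
"""

from __future__ import annotations

from dataclasses import dataclass
import networkx as nx

from .errors import ConfigError
from .quantfilter import CandidateSet

__all__ = ["SubNetwork", "build_subnetwork", "extend_outer"]


@dataclass
class SubNetwork:
    """A confidence-filtered subgraph around a candidate gene list.

    ``core_genes`` are the candidates present in the source network;
    ``outer_genes`` (possibly empty) are one-hop neighbours added by
    :func:`extend_outer`.  Every retained edge has
    ``confidence >= min_confidence``.
    """

    graph: nx.Graph
    core_genes: frozenset[str]
    outer_genes: frozenset[str]
    min_confidence: float

    def __post_init__(self) -> None:
        if self.core_genes & self.outer_genes:
            raise ValueError("core and outer gene sets must be disjoint")

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)


def _candidate_genes(candidates) -> set[str]:
    if isinstance(candidates, CandidateSet):
        return set(candidates.genes)
    return set(candidates)


def build_subnetwork(network: nx.Graph, candidates,
                     min_confidence: float = 0.7) -> SubNetwork:
    """Induce the candidate subnetwork at a confidence cutoff.

    Nodes are the candidate genes present in ``network`` (isolated
    candidates kept as degree-0 nodes); edges are the network edges between
    two candidates with ``confidence >= min_confidence``.  ``candidates``
    may be a :class:`~gvtsig.quantfilter.CandidateSet` or any iterable of
    gene symbols.
    """
    if not 0 <= min_confidence <= 1:
        raise ConfigError(f"min_confidence must be in [0, 1], got {min_confidence}")
    genes = _candidate_genes(candidates)
    present = genes & set(network.nodes)
    sub = nx.Graph()
    sub.add_nodes_from(present)
    for a, b, data in network.edges(data=True):
        if a in present and b in present and data["confidence"] >= min_confidence:
            sub.add_edge(a, b, confidence=data["confidence"])
    return SubNetwork(graph=sub, core_genes=frozenset(present),
                      outer_genes=frozenset(), min_confidence=min_confidence)


def extend_outer(network: nx.Graph, sub: SubNetwork,
                 include_outer_outer: bool = False) -> SubNetwork:
    """Add the one-layer extension: outer genes one hop from the core.

    Outer genes are non-core genes adjacent to at least one core gene via an
    edge passing the confidence cutoff; those core--outer edges are added.
    Edges between two outer genes are excluded by default (the extension
    exists to add context around core genes); ``include_outer_outer=True``
    retains them for sensitivity analyses.  Core genes are unchanged, so
    re-extension adds nothing at depth 1.
    """
    graph = nx.Graph()
    graph.add_nodes_from(sub.graph.nodes)
    graph.add_edges_from(sub.graph.edges(data=True))
    outer: set[str] = set()
    for core in sub.core_genes:
        if core not in network:
            continue
        for nbr in network.neighbors(core):
            conf = network[core][nbr]["confidence"]
            if nbr not in sub.core_genes and conf >= sub.min_confidence:
                outer.add(nbr)
                graph.add_edge(core, nbr, confidence=conf)
    if include_outer_outer:
        for a in outer:
            for b in network.neighbors(a):
                if b in outer and b != a:
                    conf = network[a][b]["confidence"]
                    if conf >= sub.min_confidence:
                        graph.add_edge(a, b, confidence=conf)
    return SubNetwork(graph=graph, core_genes=sub.core_genes,
                      outer_genes=frozenset(outer),
                      min_confidence=sub.min_confidence)
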