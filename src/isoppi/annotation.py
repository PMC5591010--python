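"""Build the domain-resolved reference interactome.

A reference PPI (A, B) is annotated with a domain-domain interaction (DDI)
when one endpoint carries one interacting domain of the DDI and the other
endpoint carries the complementary domain. Only PPIs with at least one DDI
annotation enter the domain-resolved interactome; everything else is
discarded, because the loss rule has nothing to test on them.

When both orientations of a DDI apply to one edge (both proteins carry both
domains), both oriented instances are stored: an isoform of either endpoint
can then keep the interaction through either orientation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Set

from .model import (
    DDIInstance,
    DDISet,
    DomainProfileSet,
    DomainResolvedInteractome,
    Interactome,
    ProteinId,
    canonical_edge,
)

__all__ = ["annotate_edges_with_ddis", "domain_resolved_stats", "DomainResolvedStats"]


def annotate_edges_with_ddis(
    net: Interactome, profiles: DomainProfileSet, ddis: DDISet
) -> DomainResolvedInteractome:
    """Map DDIs onto the PPIs of *net*, keeping only annotated edges.

    For each edge (A, B) with A the canonical (lexicographically smaller)
    endpoint, the annotation set is every oriented pair (dA, dB) with
    dA in domains(A), dB in domains(B) and {dA, dB} an interacting domain
    pair. Proteins without a domain profile simply annotate nothing.
    """
    dri = DomainResolvedInteractome()
    for edge in net.edges:
        a, b = canonical_edge(*sorted(edge))
        doms_a = profiles.domains(a)
        doms_b = profiles.domains(b)
        instances = {
            DDIInstance(da, db)
            for da in doms_a
            for db in doms_b
            if ddis.interacts(da, db)
        }
        if instances:
            dri.set_edge(a, b, instances)
    return dri


@dataclass
class DomainResolvedStats:
    """Summary of a domain-resolved interactome."""

    n_nodes: int
    n_edges: int
    instance_count_distribution: Dict[int, int]
    single_annotation_fraction: float
    degree: Dict[ProteinId, int] = field(default_factory=dict)

    def hubs(self, cutoff: int) -> Set[ProteinId]:
        """Proteins with vertex degree strictly greater than *cutoff*."""
        return {p for p, d in self.degree.items() if d > cutoff}


def domain_resolved_stats(dri: DomainResolvedInteractome) -> DomainResolvedStats:
    """Node/edge counts, per-edge DDI-instance count distribution, fraction
    of edges carrying a single annotation, and the vertex-degree table."""
    counts = Counter(len(insts) for insts in dri.edges.values())
    n_edges = len(dri)
    degree: Counter = Counter()
    for a, b in dri.edges:
        degree[a] += 1
        degree[b] += 1
    single_frac = counts.get(1, 0) / n_edges if n_edges else 0.0
    return DomainResolvedStats(
        n_nodes=len(dri.nodes),
        n_edges=n_edges,
        instance_count_distribution=dict(counts),
        single_annotation_fraction=single_frac,
        degree=dict(degree),
    )
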