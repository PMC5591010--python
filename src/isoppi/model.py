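"""Core data types for domain-resolved interactomes and isoform interactomes.

Identifier conventions follow UniProt: a reference protein is named by its
accession (``P00533``) and an alternative splice isoform by an accession plus
a dash-separated index (``P00533-2``). Domain content is represented as a
*set* of domain accessions per protein or isoform: a domain present in
multiple copies counts as present while at least one copy remains, because
the interaction-loss rule only asks whether a domain was lost entirely.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, NamedTuple, Optional, Set, Tuple

import pandas as pd

ProteinId = str
DomainAccession = str

__all__ = [
    "ProteinId",
    "DomainAccession",
    "IsoformId",
    "parse_isoform_id",
    "DomainProfileSet",
    "DDISet",
    "Interactome",
    "DDIInstance",
    "DomainResolvedInteractome",
    "GeneIsoformMap",
    "IsoformEdge",
    "IsoformInteractome",
    "AnnotationProfileSet",
    "ExpressionMatrix",
    "PairCategory",
    "ConfusionCounts",
    "canonical_edge",
]


class IsoformIdError(ValueError):
    """Raised when an isoform identifier cannot be parsed."""


@dataclass(frozen=True, order=True)
class IsoformId:
    """A protein isoform: reference (``P00533``) or alternative (``P00533-2``).

    ``isoform_index`` is ``None`` for the reference isoform and an integer
    >= 2 for alternatives. The UniProt alias ``ACC-1`` is normalised to the
    reference on parse.
    """

    accession: ProteinId
    isoform_index: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.accession:
            raise IsoformIdError("empty accession")
        if "-" in self.accession:
            raise IsoformIdError(
                f"accession {self.accession!r} must not carry an isoform suffix"
            )
        if self.isoform_index is not None and self.isoform_index < 2:
            raise IsoformIdError(
                f"alternative isoform index must be >= 2, got {self.isoform_index}"
            )

    @property
    def is_reference(self) -> bool:
        return self.isoform_index is None

    @property
    def parent(self) -> ProteinId:
        return self.accession

    def render(self) -> str:
        if self.isoform_index is None:
            return self.accession
        return f"{self.accession}-{self.isoform_index}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


def parse_isoform_id(text: str) -> IsoformId:
    """Parse ``ACC`` or ``ACC-k`` into an :class:`IsoformId`.

    ``ACC-1`` is treated as an alias of the reference isoform (UniProt
    convention). A non-integer or zero/negative suffix is a parse error.
    """
    text = text.strip()
    if not text:
        raise IsoformIdError("empty isoform identifier")
    if "-" not in text:
        return IsoformId(text)
    acc, _, suffix = text.rpartition("-")
    if not acc:
        raise IsoformIdError(f"malformed isoform identifier {text!r}")
    try:
        k = int(suffix)
    except ValueError as exc:
        raise IsoformIdError(f"non-integer isoform suffix in {text!r}") from exc
    if k < 1:
        raise IsoformIdError(f"isoform suffix must be >= 1 in {text!r}")
    if k == 1:
        return IsoformId(acc)
    return IsoformId(acc, k)


# ---------------------------------------------------------------------------
# domain profiles and DDIs
# ---------------------------------------------------------------------------


class DomainProfileSet:
    """Per-protein / per-isoform sets of domain accessions.

    Keys are rendered identifier strings (``P00533``, ``P00533-2``). Entries
    may be empty sets; an explicit empty set means "annotated, no domains",
    which the prediction step distinguishes from "never annotated".
    """

    def __init__(self, entries: Optional[Mapping[str, Iterable[DomainAccession]]] = None):
        self._entries: Dict[str, Set[DomainAccession]] = {}
        if entries:
            for key, doms in entries.items():
                self._entries[key] = {d.strip() for d in doms}

    def add(self, entity: str, domain: DomainAccession) -> None:
        self._entries.setdefault(entity, set()).add(domain.strip())

    def set_profile(self, entity: str, domains: Iterable[DomainAccession]) -> None:
        self._entries[entity] = {d.strip() for d in domains}

    def domains(self, entity: str) -> Set[DomainAccession]:
        """Domain set for *entity*; empty set if the entity is unannotated."""
        return self._entries.get(entity, set())

    def __contains__(self, entity: str) -> bool:
        return entity in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries)

    def items(self):
        return self._entries.items()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DomainProfileSet):
            return NotImplemented
        return self._entries == other._entries

    def __repr__(self) -> str:  # pragma: no cover
        return f"DomainProfileSet({len(self._entries)} entities)"


class DDISet:
    """Unordered pairs of interacting domain families.

    ``(d1, d2)`` and ``(d2, d1)`` are the same pair; self-pairs ``(d, d)``
    are permitted (homotypic domain interactions).
    """

    def __init__(self, pairs: Optional[Iterable[Tuple[DomainAccession, DomainAccession]]] = None):
        self._pairs: Set[FrozenSet[DomainAccession]] = set()
        if pairs:
            for d1, d2 in pairs:
                self.add(d1, d2)

    def add(self, d1: DomainAccession, d2: DomainAccession) -> None:
        self._pairs.add(frozenset((d1.strip(), d2.strip())))

    def __contains__(self, pair: Tuple[DomainAccession, DomainAccession]) -> bool:
        d1, d2 = pair
        return frozenset((d1, d2)) in self._pairs

    def interacts(self, d1: DomainAccession, d2: DomainAccession) -> bool:
        return frozenset((d1, d2)) in self._pairs

    @property
    def domains(self) -> Set[DomainAccession]:
        """Every domain participating in at least one DDI."""
        out: Set[DomainAccession] = set()
        for pair in self._pairs:
            out |= pair
        return out

    def pairs(self) -> Set[FrozenSet[DomainAccession]]:
        return set(self._pairs)

    def __len__(self) -> int:
        return len(self._pairs)

    def __iter__(self):
        return iter(self._pairs)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DDISet):
            return NotImplemented
        return self._pairs == other._pairs

    def __or__(self, other: "DDISet") -> "DDISet":
        out = DDISet()
        out._pairs = self._pairs | other._pairs
        return out

    def __repr__(self) -> str:  # pragma: no cover
        return f"DDISet({len(self._pairs)} pairs)"


# ---------------------------------------------------------------------------
# interactomes
# ---------------------------------------------------------------------------


def canonical_edge(a: ProteinId, b: ProteinId) -> Tuple[ProteinId, ProteinId]:
    """Canonical (lexicographically smaller first) ordering of an edge."""
    return (a, b) if a <= b else (b, a)


@dataclass
class Interactome:
    """Undirected, deduplicated, self-edge-free binary PPI network."""

    nodes: Set[ProteinId] = field(default_factory=set)
    edges: Set[FrozenSet[ProteinId]] = field(default_factory=set)

    @classmethod
    def from_edges(
        cls, pairs: Iterable[Tuple[ProteinId, ProteinId]], nodes: Optional[Iterable[ProteinId]] = None
    ) -> "Interactome":
        """Build a network from (possibly redundant, possibly self-looped) pairs.

        Self-edges are dropped and reciprocal duplicates collapsed, mirroring
        standard interactome ingestion.
        """
        net = cls()
        if nodes:
            net.nodes.update(nodes)
        for a, b in pairs:
            if a == b:
                continue
            net.nodes.update((a, b))
            net.edges.add(frozenset((a, b)))
        return net

    def add_edge(self, a: ProteinId, b: ProteinId) -> None:
        if a == b:
            return
        self.nodes.update((a, b))
        self.edges.add(frozenset((a, b)))

    def has_edge(self, a: ProteinId, b: ProteinId) -> bool:
        return frozenset((a, b)) in self.edges

    def neighbors(self, p: ProteinId) -> Set[ProteinId]:
        return {q for e in self.edges if p in e for q in e if q != p}

    def degree(self, p: ProteinId) -> int:
        return sum(1 for e in self.edges if p in e)

    def edge_tuples(self) -> List[Tuple[ProteinId, ProteinId]]:
        """Edges as canonical sorted tuples, in deterministic order."""
        return sorted(tuple(sorted(e)) for e in self.edges)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edge_tuples())
        return g

    def __len__(self) -> int:
        return len(self.edges)


class DDIInstance(NamedTuple):
    """One DDI annotation on an edge, oriented against the canonical (a, b)
    endpoint order: ``domain_on_a`` sits on the lexicographically smaller
    endpoint."""

    domain_on_a: DomainAccession
    domain_on_b: DomainAccession


class DomainResolvedInteractome:
    """PPI edges carrying at least one oriented DDI annotation each."""

    def __init__(
        self,
        edges: Optional[Mapping[Tuple[ProteinId, ProteinId], Iterable[DDIInstance]]] = None,
    ):
        self._edges: Dict[Tuple[ProteinId, ProteinId], FrozenSet[DDIInstance]] = {}
        if edges:
            for (a, b), insts in edges.items():
                self.set_edge(a, b, insts)

    def set_edge(self, a: ProteinId, b: ProteinId, instances: Iterable[DDIInstance]) -> None:
        key = canonical_edge(a, b)
        insts = frozenset(instances)
        if not insts:
            raise ValueError(f"edge {key} must carry at least one DDI instance")
        if key != (a, b):
            # reorient instances to canonical order
            insts = frozenset(DDIInstance(i.domain_on_b, i.domain_on_a) for i in insts)
        self._edges[key] = insts

    def instances(self, a: ProteinId, b: ProteinId) -> FrozenSet[DDIInstance]:
        key = canonical_edge(a, b)
        return self._edges[key]

    def instances_for_side(self, side: ProteinId, partner: ProteinId) -> Set[DomainAccession]:
        """Domains of *side* participating in this edge's DDI instances."""
        key = canonical_edge(side, partner)
        insts = self._edges[key]
        if key[0] == side:
            return {i.domain_on_a for i in insts}
        return {i.domain_on_b for i in insts}

    def has_edge(self, a: ProteinId, b: ProteinId) -> bool:
        return canonical_edge(a, b) in self._edges

    @property
    def edges(self) -> Dict[Tuple[ProteinId, ProteinId], FrozenSet[DDIInstance]]:
        return dict(self._edges)

    @property
    def nodes(self) -> Set[ProteinId]:
        out: Set[ProteinId] = set()
        for a, b in self._edges:
            out.update((a, b))
        return out

    def partners(self, p: ProteinId) -> Set[ProteinId]:
        return {b if a == p else a for (a, b) in self._edges if p in (a, b)}

    def degree(self, p: ProteinId) -> int:
        return len(self.partners(p))

    def to_interactome(self) -> Interactome:
        return Interactome.from_edges(list(self._edges))

    def __len__(self) -> int:
        return len(self._edges)

    def __iter__(self):
        return iter(self._edges)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DomainResolvedInteractome):
            return NotImplemented
        return self._edges == other._edges


class GeneIsoformMap:
    """Ordered isoform lists per gene: the reference isoform first, then
    alternatives in input order."""

    def __init__(self, entries: Optional[Mapping[ProteinId, Iterable[IsoformId]]] = None):
        self._map: Dict[ProteinId, List[IsoformId]] = {}
        if entries:
            for acc, isoforms in entries.items():
                for iso in isoforms:
                    self.add(acc, iso)

    def add(self, accession: ProteinId, isoform: Optional[IsoformId] = None) -> None:
        """Register *accession* (creating its reference entry) and optionally
        append an alternative isoform."""
        if accession not in self._map:
            self._map[accession] = [IsoformId(accession)]
        if isoform is not None and not isoform.is_reference:
            if isoform.parent != accession:
                raise ValueError(
                    f"isoform {isoform.render()} does not belong to {accession}"
                )
            if isoform not in self._map[accession]:
                self._map[accession].append(isoform)

    def isoforms(self, accession: ProteinId) -> List[IsoformId]:
        return list(self._map.get(accession, [IsoformId(accession)]))

    def alternatives(self, accession: ProteinId) -> List[IsoformId]:
        return [iso for iso in self._map.get(accession, []) if not iso.is_reference]

    def genes(self) -> List[ProteinId]:
        return list(self._map)

    def __contains__(self, accession: ProteinId) -> bool:
        return accession in self._map

    def __len__(self) -> int:
        return len(self._map)

    def items(self):
        return self._map.items()


class IsoformEdge(NamedTuple):
    """One (isoform, reference-partner) edge with its predicted status."""

    isoform: IsoformId
    partner: ProteinId
    status: str  # "reference" | "retained" | "lost"


@dataclass
class IsoformInteractome:
    """Reference edges plus retained/lost predictions for alternative isoforms."""

    edges: Set[IsoformEdge] = field(default_factory=set)

    def add(self, edge: IsoformEdge) -> None:
        if edge.status not in ("reference", "retained", "lost"):
            raise ValueError(f"invalid status {edge.status!r}")
        if (edge.status == "reference") != edge.isoform.is_reference:
            raise ValueError("status 'reference' is reserved for reference isoforms")
        self.edges.add(edge)

    def by_status(self, status: str) -> Set[IsoformEdge]:
        return {e for e in self.edges if e.status == status}

    def status_of(self, isoform: IsoformId, partner: ProteinId) -> str:
        for e in self.edges:
            if e.isoform == isoform and e.partner == partner:
                return e.status
        raise KeyError((isoform.render(), partner))

    def sorted_edges(self) -> List[IsoformEdge]:
        return sorted(self.edges, key=lambda e: (e.isoform.render(), e.partner, e.status))

    def __len__(self) -> int:
        return len(self.edges)


# ---------------------------------------------------------------------------
# annotation profiles and expression
# ---------------------------------------------------------------------------


class AnnotationProfileSet:
    """Per-protein sets of annotation terms in a single namespace (GO aspect
    or disease vocabulary)."""

    VALID_NAMESPACES = ("MF", "BP", "CC", "all", "disease")

    def __init__(
        self,
        namespace: str,
        entries: Optional[Mapping[ProteinId, Iterable[str]]] = None,
    ):
        if namespace not in self.VALID_NAMESPACES:
            raise ValueError(f"unknown namespace {namespace!r}")
        self.namespace = namespace
        self._entries: Dict[ProteinId, Set[str]] = {}
        if entries:
            for p, terms in entries.items():
                self._entries[p] = set(terms)

    def add(self, protein: ProteinId, term: str) -> None:
        self._entries.setdefault(protein, set()).add(term)

    def set_terms(self, protein: ProteinId, terms: Iterable[str]) -> None:
        self._entries[protein] = set(terms)

    def terms(self, protein: ProteinId) -> Set[str]:
        return self._entries.get(protein, set())

    def proteins(self) -> List[ProteinId]:
        return list(self._entries)

    def items(self):
        return self._entries.items()

    def __contains__(self, protein: ProteinId) -> bool:
        return protein in self._entries

    def __len__(self) -> int:
        return len(self._entries)


# Expression data is carried as a pandas DataFrame: rows = proteins, columns
# = tissues, NaN = not quantified. A thin alias keeps signatures readable.
ExpressionMatrix = pd.DataFrame


class PairCategory(enum.Enum):
    """Classification of two proteins by the isoform subsets (of a shared
    target gene) they interact with."""

    SAME_SUBSET = "same_subset"
    DIFFERENT_SUBSET = "different_subset"
    DIFFERENT_GENES = "different_genes"
    EXCLUDED_MIXED = "excluded_mixed"


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 tally for loss prediction; positive class = experimental loss."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def tpr(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else math.nan

    @property
    def fpr(self) -> float:
        denom = self.fp + self.tn
        return self.fp / denom if denom else math.nan

    def as_table(self) -> List[List[int]]:
        """[[tp, fn], [fp, tn]] — rows: experimental loss / retention."""
        return [[self.tp, self.fn], [self.fp, self.tn]]
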