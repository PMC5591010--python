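"""Interaction profiles, gene-level remodeling statistics and partner-pair
classification.

An isoform's *interaction profile* is the set of reference partners it
retains, taken over its parent gene's partners in the domain-resolved
interactome. Two proteins x and y interacting with the same target gene are
*same-subset* if exactly the same isoforms of that gene interact with both,
and *different-subset* otherwise; the reference isoform is part of every
subset (it interacts with every domain-resolved partner by construction), so
differences are always driven by alternative isoforms.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Set, Tuple, Union

from .model import (
    DomainResolvedInteractome,
    GeneIsoformMap,
    Interactome,
    IsoformId,
    IsoformInteractome,
    PairCategory,
    ProteinId,
)

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionProfile",
    "interaction_profiles",
    "gene_remodeling_summary",
    "RemodelingSummary",
    "classify_partner_pairs",
    "PartnerPairLabel",
    "sample_different_gene_pairs",
    "remodeling_ratio",
]


@dataclass(frozen=True)
class InteractionProfile:
    """Partners retained by one isoform, over its parent's partner set."""

    isoform: IsoformId
    partners_retained: FrozenSet[ProteinId]


def interaction_profiles(net: IsoformInteractome) -> List[InteractionProfile]:
    """One profile per isoform appearing in *net*, reference included.

    Reference-isoform profiles are the full partner set of their gene's
    domain-resolved edges; alternative-isoform profiles keep only retained
    partners.
    """
    # reference partner sets per gene, from the undirected reference edges
    ref_partners: Dict[ProteinId, Set[ProteinId]] = {}
    for e in net.edges:
        if e.status == "reference":
            ref_partners.setdefault(e.isoform.parent, set()).add(e.partner)
            ref_partners.setdefault(e.partner, set()).add(e.isoform.parent)
    retained: Dict[IsoformId, Set[ProteinId]] = {}
    seen_alts: Set[IsoformId] = set()
    for e in net.edges:
        if e.status == "reference":
            continue
        seen_alts.add(e.isoform)
        if e.status == "retained":
            retained.setdefault(e.isoform, set()).add(e.partner)
        else:
            retained.setdefault(e.isoform, set())
    out = [
        InteractionProfile(IsoformId(gene), frozenset(partners))
        for gene, partners in ref_partners.items()
    ]
    out.extend(
        InteractionProfile(iso, frozenset(retained.get(iso, set())))
        for iso in seen_alts
    )
    return sorted(out, key=lambda p: p.isoform.render())


@dataclass
class RemodelingSummary:
    """Gene-level remodeling statistics over genes with >= 2 isoforms."""

    n_genes: int
    frac_genes_with_loss: float
    frac_isoform_pairs_different: float
    per_gene_frac_isoforms_losing: float
    per_gene_frac_pairs_different: float


def _profiles_by_gene(
    profiles: Iterable[InteractionProfile],
) -> Dict[ProteinId, List[InteractionProfile]]:
    by_gene: Dict[ProteinId, List[InteractionProfile]] = {}
    for p in profiles:
        by_gene.setdefault(p.isoform.parent, []).append(p)
    return by_gene


def gene_remodeling_summary(profiles: Iterable[InteractionProfile]) -> RemodelingSummary:
    """Remodeling statistics over genes with at least two isoforms.

    - ``frac_genes_with_loss``: genes where >= 1 isoform loses >= 1 partner.
    - ``frac_isoform_pairs_different``: pooled over all unordered within-gene
      isoform pairs (reference included), "different" iff the retained
      partner sets differ.
    - ``per_gene_*``: the corresponding within-gene fractions averaged over
      genes.
    """
    by_gene = _profiles_by_gene(profiles)
    eligible = {g: ps for g, ps in by_gene.items() if len(ps) >= 2}
    if not eligible:
        raise ValueError("no genes with two or more isoforms")
    n_genes_with_loss = 0
    n_pairs = 0
    n_pairs_diff = 0
    per_gene_losing: List[float] = []
    per_gene_diff: List[float] = []
    for gene, ps in eligible.items():
        ref_set = next(
            p.partners_retained for p in ps if p.isoform.is_reference
        )
        alts = [p for p in ps if not p.isoform.is_reference]
        losing = [p for p in alts if p.partners_retained != ref_set]
        if losing:
            n_genes_with_loss += 1
        per_gene_losing.append(len(losing) / len(alts) if alts else 0.0)
        pairs = list(combinations(ps, 2))
        diff = [1 for p1, p2 in pairs if p1.partners_retained != p2.partners_retained]
        n_pairs += len(pairs)
        n_pairs_diff += len(diff)
        per_gene_diff.append(len(diff) / len(pairs))
    return RemodelingSummary(
        n_genes=len(eligible),
        frac_genes_with_loss=n_genes_with_loss / len(eligible),
        frac_isoform_pairs_different=n_pairs_diff / n_pairs if n_pairs else 0.0,
        per_gene_frac_isoforms_losing=sum(per_gene_losing) / len(per_gene_losing),
        per_gene_frac_pairs_different=sum(per_gene_diff) / len(per_gene_diff),
    )


@dataclass
class PartnerPairLabel:
    """Classification of one partner pair, with per-target-gene labels."""

    category: PairCategory
    per_gene: Dict[ProteinId, PairCategory] = field(default_factory=dict)

    @property
    def target_genes(self) -> Set[ProteinId]:
        return set(self.per_gene)


def classify_partner_pairs(
    profiles: Iterable[InteractionProfile],
    dri: DomainResolvedInteractome,
) -> Dict[FrozenSet[ProteinId], PartnerPairLabel]:
    """Classify pairs of proteins that interact with a common target gene.

    For each target gene g with >= 2 isoforms and each unordered pair (x, y)
    of distinct domain-resolved partners of g, the pair is ``same_subset``
    for g iff exactly the same isoforms of g retain x and y, else
    ``different_subset``. Pairs labelled inconsistently across target genes
    are ``excluded_mixed``. Pairs sharing no target gene are not produced
    here (see :func:`sample_different_gene_pairs`).
    """
    by_gene = _profiles_by_gene(profiles)
    labels: Dict[FrozenSet[ProteinId], PartnerPairLabel] = {}
    for gene, ps in sorted(by_gene.items()):
        if len(ps) < 2:
            continue
        partners = sorted(dri.partners(gene))
        if len(partners) < 2:
            continue
        # subset(x, g): isoforms of g whose profile retains x
        subset: Dict[ProteinId, FrozenSet[IsoformId]] = {
            x: frozenset(p.isoform for p in ps if x in p.partners_retained)
            for x in partners
        }
        for x, y in combinations(partners, 2):
            cat = (
                PairCategory.SAME_SUBSET
                if subset[x] == subset[y]
                else PairCategory.DIFFERENT_SUBSET
            )
            key = frozenset((x, y))
            label = labels.setdefault(key, PartnerPairLabel(cat))
            label.per_gene[gene] = cat
            if any(c != label.category for c in label.per_gene.values()):
                label.category = PairCategory.EXCLUDED_MIXED
    return labels


def sample_different_gene_pairs(
    dri: DomainResolvedInteractome,
    n_pairs: Union[int, str],
    seed: int,
    exclude: Optional[Set[FrozenSet[ProteinId]]] = None,
) -> List[FrozenSet[ProteinId]]:
    """Sample protein pairs that interact with products of different genes
    only: pairs of domain-resolved proteins sharing no common partner.

    ``n_pairs="all"`` enumerates every eligible pair. Sampling is uniform
    without replacement and deterministic given *seed*; if fewer eligible
    pairs exist than requested, all are returned with a warning.
    """
    exclude = exclude or set()
    proteins = sorted(dri.nodes)
    partner_sets = {p: dri.partners(p) for p in proteins}
    eligible = [
        frozenset((x, y))
        for x, y in combinations(proteins, 2)
        if not (partner_sets[x] & partner_sets[y])
        and y not in partner_sets[x]  # directly interacting pairs are ineligible
        and frozenset((x, y)) not in exclude
    ]
    if n_pairs == "all":
        return eligible
    if not isinstance(n_pairs, int) or n_pairs < 0:
        raise ValueError(f"n_pairs must be a non-negative int or 'all', got {n_pairs!r}")
    if n_pairs >= len(eligible):
        if n_pairs > len(eligible):
            logger.warning(
                "requested %d different-gene pairs but only %d eligible; returning all",
                n_pairs, len(eligible),
            )
        return eligible
    rng = random.Random(seed)
    return rng.sample(eligible, n_pairs)


def remodeling_ratio(
    category_map: Mapping[FrozenSet[ProteinId], PartnerPairLabel],
    hub_degree_cutoff: Optional[int] = None,
    binary_net: Optional[Interactome] = None,
) -> float:
    """Ratio of different-subset to same-subset partner pairs.

    With *hub_degree_cutoff* set, target genes whose reference protein has
    degree > cutoff in the full *binary_net* are removed first, pair labels
    are recomputed from the surviving target genes, and pairs with no
    surviving target gene drop out. Remodeled pairs can only arise from
    isoforms of well-connected targets, so the filter keys on the target
    gene.
    """
    if not category_map:
        raise ValueError("empty category map")
    if hub_degree_cutoff is not None:
        if binary_net is None:
            raise ValueError("hub filtering requires the binary reference interactome")
        hubs = {p for p in binary_net.nodes if binary_net.degree(p) > hub_degree_cutoff}
        n_same = n_diff = 0
        for label in category_map.values():
            kept = {g: c for g, c in label.per_gene.items() if g not in hubs}
            if not kept:
                continue
            cats = set(kept.values())
            if len(cats) > 1:
                continue  # mixed across surviving target genes: excluded
            cat = cats.pop()
            if cat == PairCategory.SAME_SUBSET:
                n_same += 1
            elif cat == PairCategory.DIFFERENT_SUBSET:
                n_diff += 1
    else:
        n_same = sum(
            1 for v in category_map.values() if v.category == PairCategory.SAME_SUBSET
        )
        n_diff = sum(
            1 for v in category_map.values() if v.category == PairCategory.DIFFERENT_SUBSET
        )
    if n_same == 0:
        raise ValueError("no same-subset pairs; remodeling ratio undefined")
    return n_diff / n_same
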