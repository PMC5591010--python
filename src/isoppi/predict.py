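"""Predict retained/lost interactions for alternative splice isoforms.

The core rule: given a reference PPI annotated with one or more DDIs, an
alternative isoform of one endpoint *loses* the interaction if it loses every
domain through which the annotated DDIs act on its side; if at least one
annotation survives, the interaction is *retained*. The partner is always
held at its reference isoform — isoform-isoform combinations are never
predicted.

A *partial*-annotation variant is used for validation against experimental
isoform interaction data, where many reference PPIs cannot be fully
DDI-annotated: there the multi-isoform protein's interacting domains alone
decide, and an isoform loses the interaction only if it loses all of them.
"""

from __future__ import annotations

from typing import Dict, FrozenSet, Iterable, Mapping, Set, Tuple

from .model import (
    ConfusionCounts,
    DDIInstance,
    DDISet,
    DomainAccession,
    DomainProfileSet,
    DomainResolvedInteractome,
    GeneIsoformMap,
    Interactome,
    IsoformEdge,
    IsoformId,
    IsoformInteractome,
    ProteinId,
    canonical_edge,
)

__all__ = [
    "predict_edge_status_full",
    "predict_edge_status_partial",
    "classify_edge_annotation",
    "build_isoform_interactome",
    "build_validation_predictions",
    "validate_against_experiment",
]

RETAINED = "retained"
LOST = "lost"


def predict_edge_status_full(
    self_side_domains_of_instances: Iterable[DomainAccession],
    isoform_domains: Set[DomainAccession],
) -> str:
    """Full-annotation loss rule for one edge and one alternative isoform.

    *self_side_domains_of_instances* are the domains through which the edge's
    DDI instances act on the isoform's side. The interaction is retained iff
    the isoform keeps at least one of them; the partner side is never tested.
    """
    self_domains = set(self_side_domains_of_instances)
    if not self_domains:
        raise ValueError("edge carries no DDI instances; not domain-resolved")
    return RETAINED if self_domains & isoform_domains else LOST


def predict_edge_status_partial(
    self_interacting_domains: Set[DomainAccession],
    isoform_domains: Set[DomainAccession],
) -> str:
    """Partial-annotation loss rule: lost iff the isoform loses every
    DDI-participating domain of its reference protein."""
    if not self_interacting_domains:
        raise ValueError("reference protein has no DDI-participating domains")
    return RETAINED if self_interacting_domains & isoform_domains else LOST


def classify_edge_annotation(
    edge: Tuple[ProteinId, ProteinId],
    profiles: DomainProfileSet,
    ddis: DDISet,
    multi_isoform_side: ProteinId,
) -> str:
    """Classify an edge's DDI annotation as ``full``, ``partial`` or ``none``.

    ``full``: both endpoints carry complementary domains of some DDI.
    ``partial``: only the multi-isoform endpoint carries a domain that occurs
    in any DDI. ``none``: not even that.
    """
    a, b = edge
    if multi_isoform_side not in (a, b):
        raise ValueError(f"{multi_isoform_side} is not an endpoint of {edge}")
    doms_a, doms_b = profiles.domains(a), profiles.domains(b)
    for da in doms_a:
        for db in doms_b:
            if ddis.interacts(da, db):
                return "full"
    interacting = ddis.domains
    if profiles.domains(multi_isoform_side) & interacting:
        return "partial"
    return "none"


def build_isoform_interactome(
    dri: DomainResolvedInteractome,
    gmap: GeneIsoformMap,
    profiles: DomainProfileSet,
) -> IsoformInteractome:
    """Expand a domain-resolved interactome with per-isoform predictions.

    Each domain-resolved edge contributes one status=``reference`` record
    (oriented by the canonical endpoint order), and, for every alternative
    isoform of either endpoint, one ``retained``/``lost`` record against the
    reference partner. Every alternative isoform to be predicted must have an
    explicit domain profile — possibly the empty set — so "no domains" is
    never conflated with "not annotated".
    """
    net = IsoformInteractome()
    for (a, b), insts in dri.edges.items():
        net.add(IsoformEdge(IsoformId(a), b, "reference"))
        for side, partner, self_domains in (
            (a, b, {i.domain_on_a for i in insts}),
            (b, a, {i.domain_on_b for i in insts}),
        ):
            if side not in gmap:
                continue
            for iso in gmap.alternatives(side):
                key = iso.render()
                if key not in profiles:
                    raise ValueError(
                        f"alternative isoform {key} has no explicit domain profile"
                    )
                status = predict_edge_status_full(self_domains, profiles.domains(key))
                net.add(IsoformEdge(iso, partner, status))
    return net


def build_validation_predictions(
    net: Interactome,
    gmap: GeneIsoformMap,
    profiles: DomainProfileSet,
    ddis: DDISet,
    multi_isoform_side_of: Mapping[FrozenSet[ProteinId], ProteinId],
) -> Dict[Tuple[str, ProteinId], str]:
    """Predict isoform edge statuses in validation mode.

    Combines the full rule (edges with full DDI annotation) and the partial
    rule (edges where only the multi-isoform endpoint carries interacting
    domains); edges with no annotation are dropped. Returns a map
    (isoform rendered id, partner) -> status.
    """
    predictions: Dict[Tuple[str, ProteinId], str] = {}
    interacting = ddis.domains
    for edge_fs, side in multi_isoform_side_of.items():
        a, b = sorted(edge_fs)
        if not net.has_edge(a, b):
            raise ValueError(f"edge ({a}, {b}) not in reference interactome")
        partner = b if side == a else a
        kind = classify_edge_annotation((a, b), profiles, ddis, side)
        if kind == "none":
            continue
        if len(gmap.alternatives(side)) < 1:
            continue  # partial annotation requires a multi-isoform protein
        if kind == "full":
            insts = {
                (da, db)
                for da in profiles.domains(side)
                for db in profiles.domains(partner)
                if ddis.interacts(da, db)
            }
            self_domains = {da for da, _ in insts}
        else:
            self_domains = profiles.domains(side) & interacting
        for iso in gmap.alternatives(side):
            key = iso.render()
            if key not in profiles:
                raise ValueError(f"isoform {key} has no explicit domain profile")
            predictions[(key, partner)] = predict_edge_status_partial(
                self_domains, profiles.domains(key)
            )
    return predictions


def validate_against_experiment(
    pred: Mapping[Tuple[str, ProteinId], str],
    truth: Mapping[Tuple[str, ProteinId], str],
) -> ConfusionCounts:
    """Tally predictions against experimental loss/retention labels.

    Positive class = experimental interaction loss. Only keys present in
    both maps are evaluated; an empty intersection is an error.
    """
    common = set(pred) & set(truth)
    if not common:
        raise ValueError("no (isoform, partner) keys shared between prediction and truth")
    tp = fn = fp = tn = 0
    for key in common:
        predicted_lost = pred[key] == LOST
        actually_lost = truth[key] == LOST
        if actually_lost and predicted_lost:
            tp += 1
        elif actually_lost:
            fn += 1
        elif predicted_lost:
            fp += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fn=fn, fp=fp, tn=tn)
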