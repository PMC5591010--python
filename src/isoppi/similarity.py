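"""Functional, disease and expression divergence measures for protein pairs.

Three per-pair scores, each computed over reference proteins:

- GO similarity: Jaccard index of GO term sets (per aspect or all three
  aspects pooled); pairs where both proteins lack any annotation are dropped.
- Disease-subnetwork sharing: Jaccard index of disease profiles extended by
  first-degree neighbors in the binary reference interactome.
- Tissue co-expression: Pearson correlation of log2 expression over the
  tissues where both proteins are quantified, requiring at least
  ``min_tissues`` common tissues (default 8 of 16).
"""

from __future__ import annotations

import logging
import math
from typing import Dict, FrozenSet, Iterable, List, Set, Tuple

import numpy as np
from scipy import stats as sps

from .model import AnnotationProfileSet, ExpressionMatrix, Interactome, ProteinId

logger = logging.getLogger(__name__)

__all__ = [
    "jaccard",
    "go_similarity",
    "disease_subnetwork_profiles",
    "disease_sharing",
    "coexpression",
]

Pair = Tuple[ProteinId, ProteinId]


def jaccard(a: Set[str], b: Set[str]) -> float:
    """|a ∩ b| / |a ∪ b|. Both-empty input is an error (callers pre-filter)."""
    union = a | b
    if not union:
        raise ValueError("jaccard undefined for two empty sets")
    return len(a & b) / len(union)


def go_similarity(
    pairs: Iterable[Pair],
    profiles: AnnotationProfileSet,
    aspect: str = "all",
) -> Dict[Pair, float]:
    """Jaccard GO similarity per pair.

    Pairs in which both proteins have no GO annotations are excluded; a pair
    with exactly one empty profile scores 0 (forced by the formula).
    """
    if profiles.namespace not in ("MF", "BP", "CC", "all"):
        raise ValueError(f"GO similarity requires a GO namespace, got {profiles.namespace}")
    if aspect != profiles.namespace:
        raise ValueError(
            f"profile namespace {profiles.namespace!r} does not match aspect {aspect!r}"
        )
    out: Dict[Pair, float] = {}
    for x, y in pairs:
        tx, ty = profiles.terms(x), profiles.terms(y)
        if not tx and not ty:
            continue
        out[(x, y)] = jaccard(tx, ty)
    return out


def disease_subnetwork_profiles(
    annotations: AnnotationProfileSet, binary_net: Interactome
) -> AnnotationProfileSet:
    """Extend disease profiles by first-degree neighbors.

    A protein belongs to a disease subnetwork if it, or any of its neighbors
    in the binary reference interactome, is annotated with the disease.
    Proteins absent from the network keep their own annotations (warned).
    """
    if annotations.namespace != "disease":
        raise ValueError("disease subnetwork profiles require disease annotations")
    out = AnnotationProfileSet("disease")
    proteins = set(annotations.proteins()) | binary_net.nodes
    for p in sorted(proteins):
        terms = set(annotations.terms(p))
        if p in binary_net.nodes:
            for q in binary_net.neighbors(p):
                terms |= annotations.terms(q)
        elif p in annotations:
            logger.warning("protein %s absent from binary interactome; using own annotations", p)
        if terms or p in annotations:
            out.set_terms(p, terms)
    return out


def disease_sharing(
    pairs: Iterable[Pair], subnet_profiles: AnnotationProfileSet
) -> Dict[Pair, float]:
    """Fraction of shared disease subnetworks per pair.

    Only pairs in which both proteins belong to at least one disease
    subnetwork are scored.
    """
    out: Dict[Pair, float] = {}
    for x, y in pairs:
        tx, ty = subnet_profiles.terms(x), subnet_profiles.terms(y)
        if not tx or not ty:
            continue
        out[(x, y)] = jaccard(tx, ty)
    return out


def coexpression(
    pairs: Iterable[Pair],
    expr: ExpressionMatrix,
    min_tissues: int = 8,
) -> Dict[Pair, float]:
    """Pearson tissue co-expression per pair.

    For each pair, correlation is computed over the tissues where both
    proteins are quantified (non-missing); pairs with fewer than
    *min_tissues* common tissues are dropped, as are pairs where either
    restricted vector has zero variance (correlation undefined).
    """
    if min_tissues < 2:
        raise ValueError("min_tissues must be >= 2")
    out: Dict[Pair, float] = {}
    for x, y in pairs:
        if x not in expr.index or y not in expr.index:
            continue
        vx = expr.loc[x].to_numpy(dtype=float)
        vy = expr.loc[y].to_numpy(dtype=float)
        mask = ~(np.isnan(vx) | np.isnan(vy))
        if mask.sum() < min_tissues:
            continue
        ax, ay = vx[mask], vy[mask]
        if np.std(ax) == 0 or np.std(ay) == 0:
            logger.warning("zero variance for pair (%s, %s); correlation undefined", x, y)
            continue
        r = sps.pearsonr(ax, ay).statistic
        if math.isnan(r):
            continue
        out[(x, y)] = float(r)
    return out
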