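"""Synthetic inputs with planted ground truth, plus the EGFR and CASP9
case-study fixtures.

The generators emulate each input the pipeline consumes: a random undirected
interactome; a domain vocabulary with interacting domain pairs planted so
that a controllable fraction of edges becomes DDI-annotated; alternative
isoforms produced by independent per-domain deletions, with ground-truth
retained/lost labels computed by this module's own implementation of the
loss rule (so predictor/generator agreement is a genuine dual-implementation
check); GO/disease term profiles with a planted difference in term sharing
between pair categories; and a tissues x proteins log2 expression matrix
with controllable pairwise correlation.

Every generator is deterministic given its seed, and every planted
interacting-domain pair is fresh (used on exactly one edge), which
guarantees that DDI mapping recovers exactly the planted annotated-edge
subset. Decoy domains never participate in any DDI.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Set, Tuple, Union

import numpy as np
import pandas as pd

from .model import (
    AnnotationProfileSet,
    DDISet,
    DomainProfileSet,
    ExpressionMatrix,
    GeneIsoformMap,
    Interactome,
    IsoformId,
    PairCategory,
    ProteinId,
)

logger = logging.getLogger(__name__)

__all__ = [
    "generate_interactome",
    "plant_domains_and_ddis",
    "generate_isoforms",
    "generate_annotations",
    "generate_expression",
    "case_study_fixture",
    "CaseStudyBundle",
    "SyntheticDataset",
    "simulate_dataset",
]

# Default study conditions for the full synthetic pipeline. Network size is a
# desk-scale stand-in; the annotation density (~6.7% of edges DDI-annotated)
# and the mean number of alternative isoforms per gene (~1.34) mirror the
# densities observed in curated human interactome annotation.
DEFAULT_N_PROTEINS = 1000
DEFAULT_N_EDGES = 3000
DEFAULT_FRAC_ANNOTATED = 0.067
DEFAULT_MEAN_ALTERNATIVES = 1.34
DEFAULT_DOMAIN_LOSS_PROB = 0.3
DEFAULT_N_TISSUES = 16


def _protein_name(i: int) -> ProteinId:
    return f"SP{i:05d}"


def generate_interactome(n_proteins: int, n_edges: int, seed: int) -> Interactome:
    """Uniform random simple undirected graph on *n_proteins* nodes."""
    max_edges = n_proteins * (n_proteins - 1) // 2
    if n_edges > max_edges:
        raise ValueError(
            f"{n_edges} edges infeasible for {n_proteins} proteins (max {max_edges})"
        )
    rng = np.random.default_rng(seed)
    nodes = [_protein_name(i) for i in range(n_proteins)]
    chosen: Set[Tuple[int, int]] = set()
    if max_edges and n_edges > max_edges // 2:
        all_pairs = [(i, j) for i in range(n_proteins) for j in range(i + 1, n_proteins)]
        idx = rng.choice(len(all_pairs), size=n_edges, replace=False)
        chosen = {all_pairs[k] for k in idx}
    else:
        while len(chosen) < n_edges:
            i, j = rng.integers(0, n_proteins, size=2)
            if i == j:
                continue
            chosen.add((min(i, j), max(i, j)))
    net = Interactome.from_edges(
        [(nodes[i], nodes[j]) for i, j in sorted(chosen)], nodes=nodes
    )
    return net


def plant_domains_and_ddis(
    net: Interactome,
    n_domains: int,
    frac_edges_annotated: float,
    seed: int,
) -> Tuple[DomainProfileSet, DDISet]:
    """Assign domains so a chosen fraction of edges is DDI-annotated.

    A random ceil(frac * |E|) subset of edges each receives a fresh pair of
    interacting domains (one on each endpoint). All proteins additionally
    receive 1-3 decoy domains from a vocabulary of *n_domains* names that
    participate in no DDI. DDI mapping on the result recovers exactly the
    chosen edge subset.
    """
    if not 0.0 <= frac_edges_annotated <= 1.0:
        raise ValueError("frac_edges_annotated must be in [0, 1]")
    rng = np.random.default_rng(seed)
    edges = net.edge_tuples()
    k = math.ceil(frac_edges_annotated * len(edges))
    profiles = DomainProfileSet()
    for p in sorted(net.nodes):
        profiles.set_profile(p, set())
    ddis = DDISet()
    if k:
        idx = rng.choice(len(edges), size=k, replace=False)
        for n, e in enumerate(sorted(int(i) for i in idx)):
            a, b = edges[e]
            da, db = f"IDom{2 * n:05d}", f"IDom{2 * n + 1:05d}"
            profiles.add(a, da)
            profiles.add(b, db)
            ddis.add(da, db)
    if n_domains > 0:
        decoys = [f"Decoy{j:05d}" for j in range(n_domains)]
        for p in sorted(net.nodes):
            for j in rng.choice(n_domains, size=int(rng.integers(1, 4)), replace=False):
                profiles.add(p, decoys[j])
    return profiles, ddis


def _reference_truth_status(
    isoform_domains: Set[str], partner_domains: Set[str], ddis: DDISet
) -> str:
    # generator-side re-statement of the loss rule, independent of the
    # DDIInstance bookkeeping used by the predictor
    for di in isoform_domains:
        for dp in partner_domains:
            if ddis.interacts(di, dp):
                return "retained"
    return "lost"


def generate_isoforms(
    net: Interactome,
    profiles: DomainProfileSet,
    ddis: DDISet,
    mean_isoforms_per_gene: float = DEFAULT_MEAN_ALTERNATIVES,
    domain_loss_prob: float = DEFAULT_DOMAIN_LOSS_PROB,
    seed: int = 0,
) -> Tuple[GeneIsoformMap, DomainProfileSet, Dict[Tuple[str, ProteinId], str]]:
    """Create alternative isoforms by random domain deletion.

    Each gene receives Poisson(*mean_isoforms_per_gene*) alternative
    isoforms; each alternative keeps each reference domain independently with
    probability 1 - *domain_loss_prob*. Returns the gene map, a profile set
    extending *profiles* with explicit (possibly empty) isoform profiles, and
    the ground-truth status map (rendered isoform id, partner) -> status over
    all DDI-annotated reference edges, computed with this module's own
    implementation of the loss rule.
    """
    if not 0.0 <= domain_loss_prob <= 1.0:
        raise ValueError("domain_loss_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    gmap = GeneIsoformMap()
    iso_profiles = DomainProfileSet({k: v for k, v in profiles.items()})
    for p in sorted(net.nodes):
        gmap.add(p)
        n_alt = int(rng.poisson(mean_isoforms_per_gene))
        ref_domains = sorted(profiles.domains(p))
        for k in range(2, 2 + n_alt):
            iso = IsoformId(p, k)
            gmap.add(p, iso)
            kept = {d for d in ref_domains if rng.random() >= domain_loss_prob}
            iso_profiles.set_profile(iso.render(), kept)
    truth: Dict[Tuple[str, ProteinId], str] = {}
    for a, b in net.edge_tuples():
        doms_a, doms_b = profiles.domains(a), profiles.domains(b)
        if _reference_truth_status(doms_a, doms_b, ddis) != "retained":
            continue  # edge not DDI-annotated: no predictions exist for it
        for side, partner, partner_doms in ((a, b, doms_b), (b, a, doms_a)):
            for iso in gmap.alternatives(side):
                truth[(iso.render(), partner)] = _reference_truth_status(
                    iso_profiles.domains(iso.render()), partner_doms, ddis
                )
    return gmap, iso_profiles, truth


def generate_annotations(
    category_map: Mapping[FrozenSet[ProteinId], Union[PairCategory, str]],
    same_subset_share_prob: float = 0.8,
    different_subset_share_prob: float = 0.2,
    vocab_size: int = 200,
    terms_per_pair: int = 5,
    private_terms: int = 2,
    namespace: str = "all",
    seed: int = 0,
) -> AnnotationProfileSet:
    """Draw term profiles with a planted sharing difference between pair
    categories.

    For each pair, *terms_per_pair* terms are drawn from a vocabulary of
    *vocab_size* names; each is given to both proteins with the category's
    share probability, otherwise to one protein only. Each protein further
    receives *private_terms* terms drawn independently. Expected Jaccard
    similarity of same-subset pairs exceeds that of different-subset pairs
    iff same_subset_share_prob > different_subset_share_prob.
    """
    for p in (same_subset_share_prob, different_subset_share_prob):
        if not 0.0 <= p <= 1.0:
            raise ValueError("share probabilities must be in [0, 1]")
    rng = np.random.default_rng(seed)
    vocab = [f"T{j:05d}" for j in range(vocab_size)]
    out = AnnotationProfileSet(namespace)
    share_prob = {
        PairCategory.SAME_SUBSET: same_subset_share_prob,
        PairCategory.DIFFERENT_SUBSET: different_subset_share_prob,
    }

    def as_category(c: Union[PairCategory, str]) -> PairCategory:
        return c if isinstance(c, PairCategory) else PairCategory(c)

    proteins: Set[ProteinId] = set()
    for key in category_map:
        proteins |= set(key)
    for pair_key in sorted(category_map, key=lambda k: tuple(sorted(k))):
        cat = as_category(category_map[pair_key])
        if cat not in share_prob:
            continue
        x, y = sorted(pair_key)
        p_share = share_prob[cat]
        for _ in range(terms_per_pair):
            term = vocab[int(rng.integers(0, vocab_size))]
            if rng.random() < p_share:
                out.add(x, term)
                out.add(y, term)
            else:
                out.add(x if rng.random() < 0.5 else y, term)
    for p in sorted(proteins):
        for _ in range(private_terms):
            out.add(p, vocab[int(rng.integers(0, vocab_size))])
    return out


def generate_expression(
    proteins: Iterable[ProteinId],
    n_tissues: int = DEFAULT_N_TISSUES,
    pair_correlation_map: Optional[Mapping[FrozenSet[ProteinId], float]] = None,
    noise_sd: float = 0.0,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> ExpressionMatrix:
    """Gaussian latent-profile log2 expression with target pair correlations.

    For a pair with target correlation r, both members load on a shared
    latent tissue profile with weight sqrt(|r|) (one side negated for
    r < 0), giving expected Pearson correlation r at noise_sd = 0; extra
    independent noise attenuates it by 1 / (1 + noise_sd^2). A protein
    occurring in several pairs keeps its first assignment. Values are on a
    log2-like scale (affine transform; correlations unaffected).
    """
    if n_tissues < 2:
        raise ValueError("n_tissues must be >= 2")
    rng = np.random.default_rng(seed)
    proteins = sorted(set(proteins))
    tissues = [f"tissue_{t + 1:02d}" for t in range(n_tissues)]
    values: Dict[ProteinId, np.ndarray] = {}
    if pair_correlation_map:
        for key in sorted(pair_correlation_map, key=lambda k: tuple(sorted(k))):
            r = float(pair_correlation_map[key])
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"target correlation {r} outside [-1, 1]")
            x, y = sorted(key)
            if x in values and y in values:
                # overlapping pair maps are expected; first assignment wins
                logger.debug("pair (%s, %s) already assigned; skipping", x, y)
                continue
            z = rng.standard_normal(n_tissues)
            w = math.sqrt(abs(r))
            u = math.sqrt(1.0 - abs(r))
            vx = w * z + u * rng.standard_normal(n_tissues)
            sign = 1.0 if r >= 0 else -1.0
            vy = sign * w * z + u * rng.standard_normal(n_tissues)
            if x not in values:
                values[x] = vx
            if y not in values:
                values[y] = vy
    for p in proteins:
        if p not in values:
            values[p] = rng.standard_normal(n_tissues)
    mat = np.vstack([values[p] for p in proteins])
    if noise_sd:
        mat = mat + noise_sd * rng.standard_normal(mat.shape)
    mat = 2.0 * mat + 6.0  # log2-expression-like location/scale
    if missing_rate:
        mask = rng.random(mat.shape) < missing_rate
        mat = np.where(mask, np.nan, mat)
    return pd.DataFrame(mat, index=proteins, columns=tissues)


# ---------------------------------------------------------------------------
# case-study fixtures
# ---------------------------------------------------------------------------


@dataclass
class CaseStudyBundle:
    """All inputs needed to run the pipeline on one worked example."""

    name: str
    interactome: Interactome
    profiles: DomainProfileSet
    ddis: DDISet
    gmap: GeneIsoformMap


# EGFR (P00533) with its ligand EGF (P01133) and adaptor GRB2 (P62993): EGF
# binds the extracellular ligand-binding (LB) domain, GRB2 the intracellular
# protein kinase (PK) domain; the three truncated isoforms keep only LB.
_EGFR = {
    "proteins": ["P00533", "P01133", "P62993"],
    "edges": [("P00533", "P01133"), ("P00533", "P62993")],
    "domains": {
        "P00533": {"LB", "PK"},
        "P01133": {"EGF_ligand"},
        "P62993": {"SH3"},
        "P00533-2": {"LB"},
        "P00533-3": {"LB"},
        "P00533-4": {"LB"},
    },
    "ddis": [("LB", "EGF_ligand"), ("PK", "SH3")],
    "isoforms": {"P00533": [2, 3, 4], "P01133": [], "P62993": []},
}

# CASP9 (P55211) with APAF1 (O14727, CARD-CARD apoptosome assembly) and XIAP
# (P98170, BIR3 on the catalytic domain plus a zinc-finger contact with
# CARD). Isoform domain content reflects what the annotation step sees:
# P55211-2 keeps a CASc annotation despite its internal truncation.
_CASP9 = {
    "proteins": ["O14727", "P55211", "P98170"],
    "edges": [("P55211", "O14727"), ("P55211", "P98170")],
    "domains": {
        "P55211": {"CARD", "CASc"},
        "O14727": {"CARD"},
        "P98170": {"BIR3", "ZnF"},
        "P55211-2": {"CARD", "CASc"},
        "P55211-3": {"CARD"},
        "P55211-4": {"CASc"},
    },
    "ddis": [("CARD", "CARD"), ("CASc", "BIR3"), ("CARD", "ZnF")],
    "isoforms": {"P55211": [2, 3, 4], "O14727": [], "P98170": []},
}

_FIXTURES = {"EGFR": _EGFR, "CASP9": _CASP9}


def case_study_fixture(name: str) -> CaseStudyBundle:
    """Return the EGFR or CASP9 worked-example input bundle."""
    try:
        spec = _FIXTURES[name]
    except KeyError:
        raise ValueError(f"unknown fixture {name!r}; choose from {sorted(_FIXTURES)}")
    net = Interactome.from_edges(spec["edges"], nodes=spec["proteins"])
    profiles = DomainProfileSet(spec["domains"])
    ddis = DDISet(spec["ddis"])
    gmap = GeneIsoformMap()
    for acc, indices in spec["isoforms"].items():
        gmap.add(acc)
        for k in indices:
            gmap.add(acc, IsoformId(acc, k))
    return CaseStudyBundle(name=name, interactome=net, profiles=profiles, ddis=ddis, gmap=gmap)


# ---------------------------------------------------------------------------
# full-dataset orchestration
# ---------------------------------------------------------------------------


@dataclass
class SyntheticDataset:
    """One complete synthetic input set with its planted ground truth."""

    interactome: Interactome
    profiles: DomainProfileSet
    ddis: DDISet
    gmap: GeneIsoformMap
    ground_truth: Dict[Tuple[str, ProteinId], str]


def simulate_dataset(
    n_proteins: int = DEFAULT_N_PROTEINS,
    n_edges: int = DEFAULT_N_EDGES,
    n_decoy_domains: int = 200,
    frac_edges_annotated: float = DEFAULT_FRAC_ANNOTATED,
    mean_isoforms_per_gene: float = DEFAULT_MEAN_ALTERNATIVES,
    domain_loss_prob: float = DEFAULT_DOMAIN_LOSS_PROB,
    seed: int = 0,
) -> SyntheticDataset:
    """Generate interactome, domains/DDIs and isoforms in one call.

    Sub-generators receive distinct seeds derived from *seed* so stages stay
    independently reproducible.
    """
    net = generate_interactome(n_proteins, n_edges, seed)
    profiles, ddis = plant_domains_and_ddis(
        net, n_decoy_domains, frac_edges_annotated, seed + 1
    )
    gmap, all_profiles, truth = generate_isoforms(
        net, profiles, ddis, mean_isoforms_per_gene, domain_loss_prob, seed + 2
    )
    return SyntheticDataset(
        interactome=net, profiles=all_profiles, ddis=ddis, gmap=gmap, ground_truth=truth
    )
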