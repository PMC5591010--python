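"""Readers and writers for every file format the pipeline touches.

All tabular formats are plain UTF-8 TSV. Every reader skips blank lines and
lines starting with ``#``. Writers emit a single header line and sorted rows
so that identical inputs give byte-identical outputs.

Supported formats
-----------------
- PPI edge lists: 2+ column TSV, or a PSI-MITAB 2.5 subset (interactor
  identifier columns only).
- DDI tables: 2-column TSV of domain accessions (3did/DOMINE style).
- Domain assignments: HMMER3 ``hmmscan --domtblout`` per-domain tables, or a
  plain 2-column (entity, domain) TSV.
- Gene-isoform maps: 2-column TSV (reference accession, isoform id) or FASTA
  headers carrying UniProt-style isoform accessions.
- Annotation tables: GAF-like (protein, term, aspect) or 2-column TSV.
- Expression matrices: TSV with a tissue-name header; blank/NA cells are
  recorded as missing, never as zero.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .model import (
    AnnotationProfileSet,
    DDISet,
    DomainProfileSet,
    DomainResolvedInteractome,
    ExpressionMatrix,
    GeneIsoformMap,
    Interactome,
    IsoformEdge,
    IsoformId,
    IsoformInteractome,
    parse_isoform_id,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

# GAF aspect codes -> namespace tags
_ASPECT_MAP = {"F": "MF", "P": "BP", "C": "CC"}


# first-column tokens of headers our own writers emit
_HEADER_TOKENS = {
    "protein_a", "domain_a", "entity", "reference", "protein", "isoform",
    "interactor_a", "#ID(s) interactor A",
}


def _data_lines(path: PathLike) -> Iterable[str]:
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            first = line.split("\t")[0].split()[0] if line.split() else ""
            if first in _HEADER_TOKENS:
                continue
            yield line


# ---------------------------------------------------------------------------
# PPI edge lists
# ---------------------------------------------------------------------------


def _mitab_identifier(field: str) -> str:
    """Extract the bare accession from a MITAB identifier like
    ``uniprotkb:P00533``."""
    first = field.split("|")[0].strip()
    if ":" in first:
        return first.split(":", 1)[1].strip()
    return first


def read_edge_list(path: PathLike, format: str = "tsv") -> Interactome:
    """Read an undirected PPI network from a TSV edge list or MITAB file.

    Self-edges are dropped and reciprocal duplicates collapsed; dropped-row
    counts are logged. Rows with fewer than two identifiers are skipped with
    a warning.
    """
    if format not in ("tsv", "mitab"):
        raise ValueError(f"unknown edge list format {format!r}")
    pairs: List[Tuple[str, str]] = []
    n_self = 0
    n_skipped = 0
    for line in _data_lines(path):
        fields = line.split("\t")
        if format == "tsv" and len(fields) == 1:
            fields = line.split()
        if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
            n_skipped += 1
            logger.warning("skipping edge row with <2 identifiers: %r", line)
            continue
        if format == "mitab":
            a, b = _mitab_identifier(fields[0]), _mitab_identifier(fields[1])
        else:
            a, b = fields[0].strip(), fields[1].strip()
        if a == b:
            n_self += 1
            continue
        pairs.append((a, b))
    net = Interactome.from_edges(pairs)
    n_dup = len(pairs) - len(net.edges)
    logger.info(
        "read %d edges from %s (%d self-edges dropped, %d duplicates collapsed, %d rows skipped)",
        len(net.edges), path, n_self, n_dup, n_skipped,
    )
    return net


def write_edge_list(net: Interactome, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein_a\tprotein_b\n")
        for a, b in net.edge_tuples():
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# DDI tables
# ---------------------------------------------------------------------------


def read_ddi_table(paths: Union[PathLike, Sequence[PathLike]]) -> DDISet:
    """Read and union one or more 2-column domain-pair TSVs.

    Unordered duplicates across files are collapsed; self-pairs are kept.
    Extra columns (e.g. DOMINE source flags) are ignored.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    ddis = DDISet()
    for path in paths:
        for line in _data_lines(path):
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                logger.warning("skipping DDI row with <2 fields: %r", line)
                continue
            ddis.add(fields[0], fields[1])
    return ddis


def write_ddi_table(ddis: DDISet, path: PathLike) -> None:
    rows = sorted(tuple(sorted(pair)) if len(pair) == 2 else (next(iter(pair)),) * 2
                  for pair in ddis)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("domain_a\tdomain_b\n")
        for d1, d2 in rows:
            fh.write(f"{d1}\t{d2}\n")


# ---------------------------------------------------------------------------
# domain assignments
# ---------------------------------------------------------------------------


def read_domain_hits(
    path: PathLike,
    format: str = "tsv",
    evalue_cutoff: float = 1e-5,
    roster: Optional[Iterable[str]] = None,
) -> DomainProfileSet:
    """Read per-entity domain sets from hmmscan domtblout or a 2-column TSV.

    For domtblout, hits are filtered on the per-domain independent E-value
    (i-Evalue, column 13) against *evalue_cutoff*; the cutoff is ignored for
    the TSV format. Entities listed in *roster* are guaranteed an (possibly
    empty) entry, so downstream code can distinguish "no surviving domains"
    from "never scanned".
    """
    profiles = DomainProfileSet()
    if roster:
        for entity in roster:
            profiles.set_profile(entity, set())
    if format == "tsv":
        for line in _data_lines(path):
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 2:
                logger.warning("skipping domain row with <2 fields: %r", line)
                continue
            profiles.add(fields[0].strip(), fields[1].strip())
        return profiles
    if format != "domtblout":
        raise ValueError(f"unknown domain hits format {format!r}")
    for line in _data_lines(path):
        fields = line.split()
        # HMMER3 domtblout: target(0) tacc(1) tlen(2) query(3) qacc(4) qlen(5)
        # full E-value(6) ... dom#(9) of(10) c-Evalue(11) i-Evalue(12) ...
        if len(fields) < 13:
            logger.warning("skipping malformed domtblout row: %r", line)
            continue
        domain, entity = fields[0], fields[3]
        try:
            ievalue = float(fields[12])
        except ValueError:
            logger.warning("skipping row with unparseable i-Evalue: %r", line)
            continue
        if ievalue <= evalue_cutoff:
            profiles.add(entity, domain)
    return profiles


def write_domain_profiles(profiles: DomainProfileSet, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("entity\tdomain\n")
        for entity in sorted(profiles):
            doms = profiles.domains(entity)
            if not doms:
                # explicit empty profile marker line is not emitted; empty
                # profiles are re-established through a roster on read
                continue
            for d in sorted(doms):
                fh.write(f"{entity}\t{d}\n")


# ---------------------------------------------------------------------------
# gene-isoform maps
# ---------------------------------------------------------------------------


def read_isoform_map(path: PathLike, format: str = "tsv") -> GeneIsoformMap:
    """Read a gene -> isoform map from a 2-column TSV or FASTA headers.

    TSV rows are (reference accession, isoform identifier); alternatives keep
    file order. An isoform whose parent never appears as a reference gets its
    parent auto-created with a warning.
    """
    gmap = GeneIsoformMap()
    if format == "fasta":
        from Bio import SeqIO

        for record in SeqIO.parse(str(path), "fasta"):
            ident = record.id
            # UniProt header style: sp|P55211-4|NAME
            if "|" in ident:
                parts = ident.split("|")
                ident = parts[1] if len(parts) > 1 else parts[0]
            iso = parse_isoform_id(ident)
            gmap.add(iso.parent, iso if not iso.is_reference else None)
        return gmap
    for line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) == 1:
            fields = line.split()
        if len(fields) < 2:
            logger.warning("skipping isoform map row with <2 fields: %r", line)
            continue
        ref, iso_text = fields[0].strip(), fields[1].strip()
        iso = parse_isoform_id(iso_text)
        if iso.parent != ref:
            logger.warning(
                "isoform %s listed under %s; keeping its own parent", iso_text, ref
            )
        gmap.add(iso.parent, iso if not iso.is_reference else None)
        if ref != iso.parent:
            gmap.add(ref)
    return gmap


def write_isoform_map(gmap: GeneIsoformMap, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("reference\tisoform\n")
        for gene in sorted(gmap.genes()):
            for iso in gmap.isoforms(gene):
                fh.write(f"{gene}\t{iso.render()}\n")


# ---------------------------------------------------------------------------
# annotation tables
# ---------------------------------------------------------------------------


def read_annotation_table(path: PathLike, namespace: str = "all") -> AnnotationProfileSet:
    """Read GO or disease annotations into per-protein term sets.

    Accepts GAF-like (protein, term, aspect) rows or 2-column (protein, term)
    rows. For GO, *namespace* selects an aspect (MF/BP/CC) or pools all
    three (``all``); rows with unknown aspect codes are skipped with a
    warning. For ``disease`` all rows are taken.
    """
    profiles = AnnotationProfileSet(namespace)
    for line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) == 1:
            fields = line.split()
        if len(fields) < 2:
            logger.warning("skipping annotation row with <2 fields: %r", line)
            continue
        protein, term = fields[0].strip(), fields[1].strip()
        if namespace == "disease" or len(fields) < 3 or not fields[2].strip():
            profiles.add(protein, term)
            continue
        aspect = fields[2].strip()
        tag = _ASPECT_MAP.get(aspect, aspect if aspect in ("MF", "BP", "CC") else None)
        if tag is None:
            logger.warning("skipping row with unknown aspect %r", aspect)
            continue
        if namespace == "all" or tag == namespace:
            profiles.add(protein, term)
    return profiles


def write_annotation_table(profiles: AnnotationProfileSet, path: PathLike) -> None:
    aspect = {"MF": "F", "BP": "P", "CC": "C"}.get(profiles.namespace, "")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein\tterm\taspect\n")
        for protein in sorted(profiles.proteins()):
            for term in sorted(profiles.terms(protein)):
                fh.write(f"{protein}\t{term}\t{aspect}\n")


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------


def read_expression_matrix(path: PathLike) -> ExpressionMatrix:
    """Read a proteins x tissues log2 expression TSV.

    Blank and ``NA`` cells become NaN (missing, not zero). Duplicate protein
    rows are an error because the protein -> profile mapping would be
    ambiguous.
    """
    df = pd.read_csv(
        path, sep="\t", index_col=0, comment="#",
        na_values=["NA", "na", "NaN", ""],
    )
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate protein rows in expression matrix: {dupes}")
    if df.columns.has_duplicates:
        raise ValueError("duplicate tissue columns in expression matrix")
    return df.astype(float)


def write_expression_matrix(expr: ExpressionMatrix, path: PathLike) -> None:
    expr.sort_index().to_csv(path, sep="\t", na_rep="NA", index_label="protein")


# ---------------------------------------------------------------------------
# domain-resolved and isoform interactomes
# ---------------------------------------------------------------------------


def write_domain_resolved(dri: DomainResolvedInteractome, path: PathLike) -> None:
    """One row per DDI instance: (protein_a, protein_b, domain_on_a, domain_on_b)."""
    rows = []
    for (a, b), insts in dri.edges.items():
        for inst in insts:
            rows.append((a, b, inst.domain_on_a, inst.domain_on_b))
    rows.sort()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein_a\tprotein_b\tdomain_on_a\tdomain_on_b\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def read_domain_resolved(path: PathLike) -> DomainResolvedInteractome:
    from collections import defaultdict

    from .model import DDIInstance

    acc = defaultdict(set)
    for line in _data_lines(path):
        fields = line.split("\t")
        if fields[0] == "protein_a":
            continue
        a, b, da, db = fields[:4]
        acc[(a, b)].add(DDIInstance(da, db))
    dri = DomainResolvedInteractome()
    for (a, b), insts in acc.items():
        dri.set_edge(a, b, insts)
    return dri


def write_isoform_interactome(net: IsoformInteractome, path: PathLike) -> None:
    """Write (isoform, partner, status) rows in deterministic sorted order."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("isoform\tpartner\tstatus\n")
        for edge in net.sorted_edges():
            fh.write(f"{edge.isoform.render()}\t{edge.partner}\t{edge.status}\n")


def read_isoform_interactome(path: PathLike) -> IsoformInteractome:
    net = IsoformInteractome()
    for line in _data_lines(path):
        fields = line.split("\t")
        if fields[0] == "isoform":
            continue
        iso_text, partner, status = fields[:3]
        net.add(IsoformEdge(parse_isoform_id(iso_text), partner, status))
    return net
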