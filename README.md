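# isoppi

Domain-based prediction of isoform-resolved protein–protein interaction
networks, with the downstream network-remodeling, functional-divergence and
validation analyses.

## The problem

Experimental interactome maps (HI-II-14, IntAct, …) record interactions
between *reference* protein isoforms, yet most human genes produce several
splice isoforms whose interaction capabilities can differ. `isoppi`
predicts, for every alternative isoform of a protein in a reference
interactome, which of its reference interactions it retains and which it
loses — using only domain content and known domain–domain interactions
(DDIs).

## The method

1. **Domain-resolved interactome.** Each reference PPI (A, B) is annotated
   with a DDI {d₁, d₂} when one endpoint carries d₁ and the other d₂
   (domains from Pfam scans, DDIs from structure-derived tables such as
   3did/DOMINE). Only PPIs with ≥ 1 DDI annotation are kept.
2. **Loss rule.** For an annotated edge and an alternative isoform *I* of
   endpoint A with domain set D(I):

   *I* loses the edge ⇔ no annotated DDI instance acts through a domain of
   A that survives in D(I); otherwise the edge is retained. The partner is
   always held at its reference isoform.
3. **Partial-annotation variant (validation).** Where the partner carries no
   complementary domain, the multi-isoform protein's DDI-participating
   domains alone decide: the isoform loses the edge iff it loses all of
   them.
4. **Downstream analyses.** Interaction profiles per isoform; gene-level
   remodeling fractions; classification of partner pairs into *same-subset*
   vs *different-subset* (of one gene's isoforms) with the
   different-to-same remodeling ratio and a hub-exclusion filter; Jaccard GO
   similarity, disease-subnetwork sharing (first-degree-neighbor-extended
   disease profiles) and Pearson tissue co-expression for the pair
   categories; two-sided bootstrap difference-of-means and two-sided
   Fisher's exact tests.

A synthetic-data module generates every input with planted ground truth
(annotated-edge subsets, isoform domain deletions, annotation-sharing
effects, pairwise expression correlations), and ships the EGFR and CASP9
worked examples.

## Worked example

```python
import isoppi as ip

bundle = ip.case_study_fixture("EGFR")
dri = ip.annotate_edges_with_ddis(bundle.interactome, bundle.profiles, bundle.ddis)
net = ip.build_isoform_interactome(dri, bundle.gmap, bundle.profiles)
for edge in net.sorted_edges():
    print(edge.isoform.render(), edge.partner, edge.status)
```

prints

```
P00533 P01133 reference
P00533 P62993 reference
P00533-2 P01133 retained
P00533-2 P62993 lost
P00533-3 P01133 retained
P00533-3 P62993 lost
P00533-4 P01133 retained
P00533-4 P62993 lost
```

EGF (P01133) binds the extracellular ligand-binding domain that all four
EGFR isoforms keep, so it is retained everywhere; GRB2 (P62993) binds the
intracellular kinase domain that the three truncated isoforms lack, so they
all lose it. The `examples/` directory contains narrative scripts for the
case studies, the end-to-end synthetic pipeline, the divergence analyses
and the validation statistics; each prints its results with a short
explanation.

A thin CLI mirrors the library:

```bash
isoppi fixture EGFR -o egfr/
isoppi predict --edges egfr/edges.tsv --domains egfr/domains.tsv \
               --ddis egfr/ddis.tsv --isoforms egfr/isoforms.tsv -o pred.tsv
isoppi test --method fisher --table 53 118 12 105
```

## Layout

- `src/isoppi/model.py` — identifiers, domain profiles, DDI sets, networks.
- `src/isoppi/io.py` — TSV/MITAB/domtblout/GAF/FASTA readers, sorted writers.
- `src/isoppi/annotation.py` — DDI mapping onto PPIs.
- `src/isoppi/predict.py` — full/partial loss rules, isoform interactome,
  validation tallies.
- `src/isoppi/profiles.py` — interaction profiles, remodeling statistics,
  partner-pair classification.
- `src/isoppi/similarity.py` — GO/disease/co-expression divergence measures.
- `src/isoppi/stats.py` — bootstrap and Fisher tests.
- `src/isoppi/synth.py` — synthetic-data generators and case-study fixtures.
- `src/isoppi/cli.py` — the `isoppi` command.

See `docs/methods.md` for the modeling assumptions, parameter choices and
limitations.
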