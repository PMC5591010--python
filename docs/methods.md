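# Methods

## Model and assumptions

`isoppi` treats a protein's interaction capability as fully mediated by its
structural domains. A reference PPI (A, B) is *domain-resolved* when some
known domain–domain interaction (DDI) {d₁, d₂} has d₁ on one endpoint and d₂
on the other; each such oriented assignment is stored as a *DDI instance*.
When both proteins carry both domains of a DDI, both orientations are
stored: an isoform of either endpoint can then keep the edge through either
instance. The loss rule quantifies over all instances of an edge — an
alternative isoform of A loses (A, B) exactly when every instance's A-side
domain is absent from the isoform, with B held at its reference isoform.
Isoform–isoform combinations are never predicted: predictions are one
isoform at a time against reference partners, so the isoform interactome
contains one record per domain-resolved edge (status `reference`, oriented
by the lexicographically smaller endpoint) plus one `retained`/`lost` record
per (alternative isoform, partner).

Key simplifications, inherent to the approach:

- **Presence/absence only.** Domain content is a set; a domain present in
  several copies counts as present while one copy remains. Copy number,
  residue-level truncation within a surviving hit, binding affinity and
  post-translational regulation are all invisible to the rule. The CASP9
  fixture illustrates this deliberately: the beta isoform keeps a catalytic
  domain *annotation* despite an internal truncation, because that is what a
  domain scan of its sequence reports, and the prediction (retention of the
  XIAP interaction) is correct for that reason.
- **Loss only.** The rule can retain or lose reference edges; it cannot
  predict interactions gained by an isoform, nor interactions absent from
  the reference interactome.
- **Annotation coverage bounds recall.** Edges without any DDI annotation are
  dropped before prediction, so genome-scale counts depend entirely on the
  domain/DDI snapshots used as input.

## Identifier and file conventions

Reference proteins are accessions (`P00533`), alternatives carry a dash
suffix (`P00533-2`, k ≥ 2); `ACC-1` is normalised to the reference on parse.
Inputs are plain TSV (edge lists, 2-column DDI tables, gene–isoform maps,
GAF-like annotation tables, expression matrices with NA for missing), plus
PSI-MITAB (identifier columns only), HMMER3 `hmmscan --domtblout` and FASTA
headers. Domain hits are filtered on the per-domain independent E-value
(i-Evalue) because the rule concerns individual domain presence; the default
cutoff is 1e-5, with 1e-3 appropriate for the laxer scans used in
experimental-dataset validation. Overlapping Pfam hits are not resolved —
presence is all the rule needs. An alternative isoform must have an
*explicit* domain profile (possibly empty) before it is predicted; this
keeps "scanned, no surviving domains" distinct from "never scanned", which
changes a prediction from `lost` to an error.

## Partner-pair classification and remodeling

For each target gene with ≥ 2 isoforms, every unordered pair of its
domain-resolved partners is labeled `same_subset` when exactly the same
isoforms of the gene retain both partners, else `different_subset`; pairs
labeled inconsistently across target genes are excluded as mixed (they are
rare). The reference isoform belongs to every subset by construction, so
differences are always driven by alternatives. The remodeling ratio is
#different / #same. The hub filter removes *target genes* whose degree in
the full binary reference interactome (not the domain-resolved one) exceeds
the cutoff, then relabels: remodeled pairs can only be created by isoforms
of well-connected targets, which makes the target gene the right filtering
key. Pairs "interacting with products of different genes only" are sampled
uniformly (seeded; exhaustive mode available) from protein pairs that share
no domain-resolved partner and are not themselves interacting.

## Divergence measures

GO similarity is the Jaccard index of term sets, per aspect (MF/BP/CC) or
with the three aspects pooled; pairs where both proteins are unannotated are
dropped, and a pair with one empty set scores 0. Disease sharing uses
neighborhood-extended profiles — a protein's disease subnetwork profile is
its own associations unioned with those of its first-degree neighbors in
the binary interactome — and again the Jaccard index over pairs where both
profiles are non-empty; proteins annotated only via neighbors are included.
Tissue co-expression is the Pearson correlation over the tissues in which
both proteins are quantified (non-missing; zeros count as quantified),
requiring at least 8 common tissues of the 16 modeled, with
zero-variance vectors dropped as undefined.

## Statistical tests

The group comparison uses a two-sided bootstrap test on the difference of
means: both groups are independently redrawn with replacement at their
original sizes, and p = min(1, 2·min(P̂(diff* ≤ 0), P̂(diff* ≥ 0))) with
add-one smoothing (count+1)/(n+1), so p is never 0 and is bounded below by
2/(n_resamples+1). This is a percentile bootstrap, not a permutation test —
the choice matters for unequal group sizes, where resampling preserves each
group's own variance. Defaults are 100,000 resamples for within-gene
category comparisons and 1,000 for comparisons against different-gene
pairs. Null calibration is checked empirically: across 200 repetitions of
identically distributed groups at 2,000 resamples, the Kolmogorov–Smirnov
distance of the p-values from uniform stays below 0.1.

Fisher's exact test is two-sided by the probability-mass rule (summing all
tables at fixed margins whose probability does not exceed the observed
one), computed through `scipy.stats.fisher_exact`; the test suite verifies
it against a direct hypergeometric enumeration for margins ≤ 30. The
reported odds ratio is the sample odds ratio a·d/(b·c), NaN at 0/0. No
multiple-testing correction is applied anywhere.

## Synthetic data: what it emulates and what it does not

The generators produce a uniform random simple graph; planted domain
annotations in which each annotated edge gets a *fresh* interacting-domain
pair (one domain per endpoint) plus decoy domains on every protein —
freshness guarantees DDI mapping recovers exactly the planted edge subset,
at the cost of not emulating promiscuous domains shared across edges;
alternative isoforms via independent per-domain Bernoulli deletions, with
ground truth computed by the generator's own restatement of the loss rule
(a separate code path from the predictor, so their exact agreement is a
dual-implementation consistency check, **not** evidence of accuracy on real
data); annotation profiles in which pair categories share terms with
different probabilities; and a Gaussian latent-profile expression matrix
hitting target pairwise Pearson correlations (attenuated by 1/(1+σ²) under
extra noise).

Default conditions: 1,000 proteins, 3,000 edges, 6.7 % of edges annotated
and a mean of 1.34 alternative isoforms per gene (matching the densities of
curated human interactome annotation at scale), per-domain loss probability
0.3 (chosen once as a realistic splice-deletion rate; not derived from any
dataset), 200 decoy domains, 16 tissues, annotation share probabilities
(0.8, 0.2) with a 200-term vocabulary, 5 pair terms and 2 private terms per
protein. What passing tests show: the pipeline implements its stated rules
exactly and its statistics are calibrated and powered under these planted
conditions. What they do not show: predictive accuracy on real isoform
interaction data, which depends on domain-scan and DDI-table quality.

The EGFR and CASP9 bundles are not synthetic in the same sense: they encode
the published domain architecture and DDI routes of those genes'
interactions (ligand-binding vs kinase domain of EGFR; CARD–CARD,
CASc–BIR3 and CARD–zinc-finger routes of CASP9) at presence/absence level,
with isoform numbering following the UniProt entries.

## Numerical and degenerate-input choices

Edges are identified by the unordered accession pair and stored against the
lexicographically smaller-first orientation; all writers sort rows, so equal
inputs give byte-identical outputs. Jaccard on two empty sets and a
remodeling ratio with zero same-subset pairs are errors rather than
sentinel values, forcing callers to pre-filter. TPR/FPR with an empty
denominator are NaN. Bootstrap resampling is chunked so memory stays bounded
at 100,000 resamples. The problem sizes used by the test suite and the
acceptance script (networks of 10²–10³ proteins, 200 bootstrap-calibration
repetitions, 100 power repetitions) were chosen as the smallest scales at
which the checked properties are stable.

## Known limitations

- Predictions inherit every bias of the input domain scans and DDI tables;
  hub proteins are better annotated in literature-curated interactomes,
  which inflates their share of remodeled pairs (hence the hub-exclusion
  analysis).
- The partial-annotation rule trades precision for coverage and should only
  be used, as here, to enlarge validation sets.
- The bootstrap variant is one of several reasonable definitions of a
  "two-sided bootstrap test"; alternatives (e.g. studentized or permutation
  forms) would give slightly different p-values.
- MITAB ingestion reads identifier columns only; evidence-count filtering
  (e.g. "two or more experiments") must happen upstream.
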