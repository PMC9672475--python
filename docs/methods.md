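# Methods

`tlmnet` implements a machine-learning pipeline for telomere length
maintenance (TLM) genetics in the two classical yeast models, budding
yeast (*Saccharomyces cerevisiae*) and fission yeast
(*Schizosaccharomyces pombe*). It addresses two tasks:

1. **Phenotype classification** — given a gene whose knockout (or
   hypomorphic allele) perturbs telomere length, predict whether
   telomeres become *short* or *long*.
2. **TLM gene discovery** — rank genes not currently annotated as TLM by
   the probability that they belong to the TLM network, optionally
   transferring evidence across species through orthologs.

## Label model

Raw screen annotations ("very short", "short", "slightly short",
"slightly long", "long", "very long", plus the hypomorphic "DAmP Short"
/ "DAmP Long" and "normal") are reduced to a binary short/long label:
every short-flavoured category maps to *short*, every long-flavoured one
to *long*. A gene observed as both *normal* and a length variant takes
the variant label (the severity of an observed deviation outweighs a
wild-type observation); genes observed only as *normal* carry no
phenotype and leave the labeled set. A gene annotated with both short
and long variants is treated as a curation conflict and rejected rather
than silently resolved — the data model has no rule that could justify
either choice.

## Features

Three feature families are built from curated gene collections:

* **GI proportion** (pathways, GO BP terms): for sample gene *g* and set
  *S*, the fraction of *S* whose members have a non-zero genetic
  interaction (GI) with *g*. GI edges come from scored SGA-style edge
  lists filtered at the lenient significance threshold p < 0.05, keeping
  the lowest-p measurement per gene pair (ties broken by larger |score|,
  then file order — deterministic). Binary GI sources (fission yeast)
  store presence/absence. The denominator is the size of the
  (background-intersected) set, i.e. the value is a fraction *of the
  group*, not of the gene's interaction partners; the alternative
  reading exists but a group-normalized feature is comparable across
  sets of different sizes, which is what a linear model needs.
* **Complex membership** (complex catalogs, GO CC terms): 0/1
  indicators. For the phenotype task, genes belonging to no complex are
  dropped from the sample list (they carry no information in this
  family); the discovery task keeps all genes with all-zero rows because
  its sample universe is fixed by the ortholog table, not by the
  catalog.
* **Anchor proximity** (discovery method 5): a random walk with restart
  on the binary PPI network, `W = A D⁻¹` (column-normalized adjacency),
  `p_k = α p₀ + (1-α) W p_{k-1}` with restart α = 0.2 and `p₀` uniform
  over the anchor genes (curated endpoints of telomere-maintenance
  processes). The walk iterates until the L1 change between iterates
  falls below 1e-8 (the damping factor 0.8 makes the map a contraction,
  so convergence is geometric and the tolerance is reached in a few
  dozen iterations). Zero-degree nodes keep all-zero columns: mass
  stepping into an isolated node leaks, so Σp may fall below 1 on
  fragmented networks; this is preferred over self-loop augmentation
  because the normalization is defined as `A D⁻¹` and nothing else.

GO term sets are filtered to 3–30 background genes before feature
construction (broad terms are uninformative, tiny terms unstable);
pathway and complex catalogs are used as curated. Feature tables merge
on the intersection of their samples, features concatenating.

## Evaluation protocol

Classifiers are assessed by 5× repeated stratified 10-fold
cross-validation. Inside every training fold, and never outside it:

1. per-feature standardization statistics are learned (constant columns,
   sd < 1e-12, map to zero);
2. features are ranked by a Bernoulli naive-Bayes importance — the
   add-one-smoothed log P(feature = 1 | positive class) after binarizing
   standardized values at 0 ("above the training average") — and the top
   *k* are kept with *k* equal to the number of training samples, so the
   model never sees more features than samples;
3. the classifier is fitted.

Ties in the importance ranking keep table order, making selection
deterministic and monotone in *k*. The held-out fold is scored with the
Matthews correlation coefficient (computed from the confusion table,
with the convention that a zero denominator factor yields 0) and ROC
AUC. Medians across the 50 fold scores are the headline summaries;
distribution comparisons use the two-sided Mann-Whitney U test (normal
approximation with tie and continuity corrections by default; an exact
mode exists for small tie-free samples). Per-repeat shuffles derive
their seeds as master + repeat index, so a run is exactly reproducible
from one integer.

The model registry pins six standard learners (XGBoost, random forest,
extra trees, polynomial-kernel SVC, linear SVC, cross-validated logistic
regression) with fixed hyperparameter overrides; everything else stays
at library defaults, and no hyperparameter search is performed.

## Orthology and conservation

Fission→budding ortholog candidates may be many-to-one; ambiguity is
resolved by the maximal Smith-Waterman local alignment score under
BLOSUM62 with affine gaps costing 11 to open and 1 to extend (a
length-L gap costs 11 + (L−1)·1, the BLAST protein convention). Score
ties prefer the lexicographically smaller systematic name so resolution
is order-independent. Conservation statistics count, over resolved
pairs, genes that are TLM in both species, in either, and — within the
shared set — pairs preserving the short/long phenotype, split by
phenotype. Percentages round half-up at the requested precision.
Significance of phenotype preservation is assessed with a two-sided
binomial test against a 0.5 match probability; this is the package's own
choice of test for that quantity and is labeled as such.

## Discovery methods

Five strategies predict TLM membership for fission-yeast genes:

1. **label transfer** — TLM iff the resolved ortholog is TLM (no model);
2. **cross-species transfer** — train on budding-yeast rows of the
   shared feature space (KEGG features join across species on the
   pathway id; complex features join on a GO accession unique within
   each catalog), standardize with training-species statistics, apply to
   fission yeast;
3. **within-species** — train and cross-validate on fission-yeast
   features alone;
4. method 3 plus the ortholog's budding-yeast feature block, zero-imputed
   for genes without an ortholog (the feature count exactly doubles);
5. method 3 plus the anchor-proximity propagation feature (one extra
   column).

Candidate ranking runs method 5's model (cross-validated logistic
regression with `class_weight="balanced"`, reflecting the heavy TLM /
non-TLM imbalance) in a leave-one-out loop: for each gene the full
pipeline is refitted on the remaining genes and the held-out TLM
probability recorded. Genes already labeled TLM are excluded from the
output. Precision/recall for method comparisons use a 0.5 probability
cut by default (configurable; no operating point is canonical for this
task). Top candidates are tested for gene-set overrepresentation with a
one-sided Fisher exact test over terms of at most 250 background genes,
Benjamini-Hochberg corrected, significant at q < 0.05.

## The synthetic benchmark world

Because the curated inputs (SGA scores, BioGRID interactions, KEGG,
complex catalogs, FYPO labels, PomBase orthologs) are external
databases, the package ships a generator that emulates their statistical
structure with known ground truth. Defaults (all probabilities; gene
counts dimensionless):

| parameter | default | role |
|---|---|---|
| `n_genes` | 400 | genes per species |
| `fraction_tlm` | 0.30 | TLM fraction per species |
| `p_short_tlm_cerevisiae` / `p_short_tlm_pombe` | 0.62 / 0.25 | short-majority in budding yeast, long-majority in fission yeast (the two species have opposite imbalances) |
| `gi_signal` / `gi_background` | 0.6 / 0.02 | P(non-zero GI) from a TLM gene to members of its phenotype's associated sets vs. anywhere else |
| `complex_purity` | 0.85 | majority-phenotype share among a biased complex's TLM members |
| `ppi_density` / `anchor_edge_prob` | 0.02 / 0.35 | background PPI density; extra TLM-to-anchor attachment |
| `ortholog_coverage` | 0.8 | fraction of fission-yeast genes with an ortholog |
| `tlm_conservation` / `phenotype_conservation` | 0.5 / 0.6 | P(TLM \| ortholog TLM); P(same phenotype \| both TLM) |
| `masked_tlm_fraction` | 0.15 | TLM genes whose labels are withheld from emitted files |
| `mutation_rate` / `decoy_mutation_rate` | 0.05 / 0.30 | divergence of true ortholog sequences from their common ancestor; decoy candidates get unrelated sequences |

Sampling is keyed by (seed, stage name) so adding a stage never perturbs
earlier draws and one seed reproduces every file byte-for-byte. The
scored GI file deliberately contains sub-threshold decoy rows and
duplicate measurements so the assembly rules (p < 0.05 filter, lowest-p
selection) are exercised on real input, and the GO term catalog includes
one term below and one above the 3–30 size window for the filter to
drop.

The generator reproduces only the statistics the pipeline's operators
consume: set-correlated GI enrichment, phenotype-biased complexes,
anchor-proximal TLM genes, conserved orthologs with alignment-resolvable
ambiguity. It does **not** mimic real SGA score distributions, degree
distributions of real interactomes, GO DAG structure, or proteome
composition. Passing the benchmark therefore demonstrates that the
machinery recovers planted structure of the assumed form at realistic
sizes — not that real data carries that much signal; on the curated
datasets the discriminative signal is substantially weaker and the
expected scores correspondingly lower.

Benchmark problem sizes were chosen as 400 genes per species (giving
≈120 TLM genes, ≈50 phenotype-task samples after complex-coverage
restriction, and ≈270 leave-one-out candidates), which keeps every stage
of the planted-recovery analysis comfortably reproducible on a single
CPU while leaving the class-size requirements of stratified 10-fold CV
satisfied.

## Known limitations

* The GI matrix is consumed as directed (query → array) pairs with no
  symmetrization, matching SGA semantics; symmetric sources simply list
  both directions.
* Enrichment treats gene sets as flat; no GO-DAG parent propagation.
* Method 2's evaluation scores a budding-yeast-trained model on the full
  fission-yeast gene set; with inverted class balance between species
  the precision/recall operating point is not directly comparable to the
  cross-validated methods.
* The binomial test behind the conservation significance and the 0.5
  ranking threshold are package choices where the underlying protocol is
  unspecified; both are parameterized.
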