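# Methods

viratlas resolves de novo viral taxonomy, host assignments, lifestyles and
community ecology for assembled gut-virome contigs.  This note documents
the models and procedures, their assumptions, the tunable parameters, and
what the synthetic cohort generator does and does not emulate.

## Aggregate protein similarity (APS) and the rank tree

Novel phages lack universal marker genes, so relatedness is measured on
whole proteomes.  For genomes A and B the APS similarity is

    s(A, B) = sum of bitscores of orthologous protein pairs
              / mean(self-score total of A, self-score total of B)

clamped to [0, 1], where a genome's self-score total is the summed
bitscore of all its proteins aligned to themselves.  Orthologous pairs are
reciprocal best hits between the two genomes (per query, the
highest-bitscore subject in the other genome, ties broken to the
lexicographically smallest subject id so results are independent of input
order).  Local alignment uses BLOSUM62 with affine gaps (open 11,
extend 1); raw Smith–Waterman scores are converted to bits with the
standard gapped Karlin–Altschul parameters for that scheme
(lambda = 0.267, K = 0.041).  Identical genomes score s = 1, genomes with
no shared orthologues s = 0.

The normaliser is the *mean* of the two self totals, making s symmetric; a
minimum- or maximum-based normaliser would respectively up- or down-weight
partial genomes.  Hits below a configurable bitscore floor are discarded
to suppress spurious short matches (operation default 50 bits; the
pipeline runs at 30 bits so that deeply diverged order-level orthologues —
roughly 25–30% amino-acid identity over 90-residue proteins — are
retained; at desk scale, random 90-residue protein pairs score well below
either floor).

The distance d = 1 − s feeds average-linkage (UPGMA) agglomeration.
UPGMA trees are rooted and ultrametric by construction, so taxonomic ranks
can be read off as *root distances* (path length from the root, the root
at 0, all tips at the tree height).  Merge ties break to the
lexicographically lowest pair of cluster labels.  Cutting the tree at a
level d keeps the maximal subtrees whose ancestor lies at root distance
>= d; a node exactly at the level falls below the cut, d = 0 yields one
clade and a level beyond the tree height yields singletons.  The default
cut distances are

| rank      | root distance | ~AAI/coverage |
|-----------|---------------|---------------|
| genus     | 0.250         | 70%           |
| subfamily | 0.125         | 50%           |
| family    | 0.04          | 28%           |
| order     | 0.025         | 22%           |

The AAI correspondences are carried as documentation metadata, never
recomputed.  Because the cut levels are nested, the resulting
genus/subfamily/family/order assignments nest by construction; clades are
named `VGC_*/VSF_*/VFC_*/VOC_*` in deterministic order, and clades in
which labelled reference genomes hold a majority inherit the reference
name.

## Viral orthologue gene clusters (VOGs)

Proteins are clustered by Markov clustering (MCL) of the
orthology-filtered hit graph, with edge weights equal to hit bitscores —
the same substrate as the APS tree.  The implementation is the canonical
iteration: add self-loops (each node's maximum incident weight),
column-normalise, then alternate expansion (matrix power, default 2) and
inflation (elementwise power, default 2.0, followed by renormalisation)
until the largest entry change falls below 1e-6 or an iteration cap is
hit (the current partition is then returned with a warning).  Clusters
are read off attractor rows; overlapping clusters merge transitively so
the result is a strict partition, deterministic for the canonical
(sorted) node order and invariant under input permutation.  On graphs
whose components are cliques the partition equals the connected
components for any inflation > 1.

VOGs are labelled by the majority functional annotation of their members
(ties to the lexicographically smallest label).  The curated integrase
set contains VOGs whose label matches "integrase" or "serine recombinase"
case-insensitively; structural flags use a standard keyword list (capsid,
portal, tail, ...).

## Curation

* **Species de-replication (95% ANI).**  Greedy longest-first: a contig
  joins the first representative whose identity over the aligned fraction
  of the shorter sequence reaches 95%.  Identity is estimated by infix
  alignment of the shorter sequence against the longer (edlib, both
  strands) after a k-mer containment prefilter (k = 15); infix mode
  aligns the entire shorter sequence, enforcing the aligned-fraction
  requirement structurally.  The operation is idempotent on its own
  representatives.
* **Completeness bounds.**  Per family, member sizes are histogrammed in
  5 kb bins; the peak is the right-most non-empty bin whose count is >=
  both neighbours, and the left edge of the preceding bin is the lower
  size bound for a complete or near-complete genome (0 when the peak is
  the first bin).  A vOTU is complete iff its length >= the family bound
  (inclusive).
* **Weak families.**  Families with fewer than 5 vOTUs or fewer than 2
  complete vOTUs are dropped.
* **Decontamination ranking.**  Clusters are ranked by distinct targeting
  CRISPR spacer count x sample prevalence (descending, ties by cluster
  id); "extent of targeting" is read as the distinct-spacer count, the
  simplest defensible measure.  The visual confirmation of the top-ranked
  clusters is a manual step outside the package; the rank table supports
  it.
* **Contamination estimate.**  Per marker gene (16S rRNA, cpn60), the
  virome/metagenome marker rate ratio, plus their mean.

## Host prediction

Three predictors per vOTU, merged by last common ancestor:

1. **Cohort MAG spacers** and 2. **database spacers**: every ungapped
   placement of a spacer in a genome with <= 2 mismatches (both strands,
   no indels) is found exactly via pigeonhole seeding — a spacer split
   into max_mismatches + 1 chunks must place one chunk exactly; candidate
   placements are then verified by Hamming count.  Spacers shorter than
   20 nt are skipped.  Per vOTU and source, the call is the deepest rank
   at which a strict majority of its distinct targeting spacers' host
   lineages agree; the score is the supporting spacer count.
3. **Composition model**: per host taxon, a k-order Markov model
   (default k = 4) of nucleotide transitions with additive smoothing,
   trained on host genomes grouped at genus level.  A phage is assigned
   the taxon with the highest mean log-likelihood per nucleotide; the
   score is the gap to the runner-up (ties break lexicographically).  The
   default order is 4 rather than the order-8 convention of larger
   composition tools because desk-scale genomes (tens of kb) cannot
   populate 4^8 contexts; the order is configurable.

**LCA merging.**  Every unordered pair of predictions is reduced to its
last common ancestor in the host taxonomy; the pair with the deepest LCA
wins (an error-correction step: two agreeing methods outvote one outlier).
Depth ties prefer higher-priority sources (MAG spacers > database spacers
> composition).  A single prediction passes through unchanged; if every
pairwise LCA is the root the vOTU stays unassigned.  Merging two
predictions is never shallower than the LCA of all three.

## Lifestyle

A family is **temperate** when >= 50% of all member vOTUs (complete and
incomplete) carry an integrase-VOG gene, and **virulent** when more than
95% (strict) of its *complete* vOTUs lack one.  Temperate takes
precedence when both rules fire: integrase presence is positive evidence,
absence may reflect fragmentation.  Families with fewer than 2 complete
vOTUs (matching the weak-family completeness floor) are
`mixed_or_unknown`.

## Ecology

* **Ambiguous-read redistribution.**  Totals start at unique counts; each
  ambiguous read group is split across its candidate contigs
  proportionally to current totals (uniformly if all are zero), iterating
  until the largest change is below 1e-8.  Mass is conserved; the fixed
  point for unique counts (30, 10) with 20 shared reads is (45, 15).
* **Relative abundance.**  a_i = (c_i / L_i) / sum_j (c_j / L_j) per
  sample (depth and length normalised); all-zero samples stay zero.
  Clade abundances are sums of member abundances, preserving row sums;
  vOTUs missing from the taxonomy aggregate under "unassigned".
* **Clade statistics.**  MRA (mean relative abundance over all samples,
  zeros included), prevalence (fraction of samples with abundance > 0),
  richness (member count).
* **Neutral community model.**  A clade with source mean relative
  abundance p is predicted present with probability
  1 − I_d(N m p, N m (1 − p)), with I the regularised incomplete beta
  function, N the local community (read) size, d = 1/N the one-read
  detection limit, and m the migration probability, fitted by bounded
  least squares on the prevalence scale.  Residuals are
  log10(observed) − log10(predicted) with prevalences clamped to
  [1/n_samples, 1] to keep them finite.  Degenerate fits (all prevalence
  1, or the optimum pinned at the (0,1) boundary) are flagged with
  warnings.
* **Diversity.**  Unique branch length of a family = summed pendant
  (tip-leading) branch lengths of the family's induced subtree, as a
  fraction of the subtree's total branch length; a star is 1.0, and a
  single tip is 1.0 by convention (flagged).  The alternative reading —
  branch length unshared with other families — was not adopted; pendant
  branches measure within-family private divergence directly.
* **Comparative statistics.**  Two-sided Wilcoxon rank-sum: exact
  enumeration when the smaller group has <= 8 values and there are no
  ties, normal approximation with tie correction otherwise; two constant
  identical groups give p = 1.  Phage–host co-abundance is Spearman's
  rank correlation on host-genus MRA pairs (ties mid-ranked, >= 3 shared
  genera required).

## The synthetic cohort generator

The generator plants the exact structure each stage assumes, with truth
tables for every assignment.

* **Taxonomy and proteomes.**  Default cohort: 3 orders x 2 families x
  3 genera x 5 vOTUs (90 genomes), 12 proteins of 90 aa per genome in
  three conservation tiers — 3 order-core proteins shared (with
  divergence) across each order, 3 family-core shared across each family,
  6 genus-core private to each genus.  Divergence is realised as per-site
  substitution (to a different residue) along order→family→genus→vOTU
  branches; the `rank_divergence` levels {genus 0.30, family 0.68,
  order 0.88} are the expected pairwise divergence between genomes
  related at each rank.  These levels were calibrated once so that the
  planted ranks separate at the *default* cut distances: measured on the
  built trees, planted genus ancestors sit at root distance ~0.31–0.34
  (above the 0.250 genus cut), family ancestors at ~0.08–0.10 (strictly
  between the 0.04 family and 0.125 subfamily cuts), order ancestors at
  ~0.029–0.037 (between 0.025 and 0.04), and different orders share no
  proteins at all, so inter-order merges happen at the root.
* **Lifestyle.**  Families alternate virulent/temperate; temperate
  genomes carry a recognisable integrase gene (descended from one
  reserved sequence, heavily diverged between families) with probability
  0.9, virulent genomes with probability 0.  The integrase annotation
  drives VOG labelling downstream, so the end-to-end test needs no
  external protein database.
* **Genomes and hosts.**  Each family is bound to a host genus
  (round-robin over a generated order/family/genus/species bacterial
  taxonomy).  Every host genus has its own order-1 nucleotide transition
  matrix (Dirichlet-drawn rows); host genomes (20 kb) and the genomes of
  that genus's phages are emitted by the corresponding chain, giving the
  composition-based predictor genuine signal.  Complete genome lengths
  are ~N(37.5 kb, 2 kb) truncated to +-1 sd, so every complete genome
  falls in the [35, 40) kb histogram bin and the derived family bound is
  30 kb; fragments (default 25% of genomes) are 25–55% of the family
  mean, always below the bound.  The 35–40 kb scale matches the typical
  complete phage genome size in gut viromes.
* **Spacers.**  Per vOTU, 4 spacers (25–45 nt substrings of the target
  genome, either strand, optional per-site mismatches) annotated with the
  planted host lineage and alternating between the two spacer sources;
  decoy spacers are random sequences verified not to match any genome at
  <= 2 mismatches.
* **Counts.**  Source abundances p are lognormal(0, 1.0), normalised.
  Each sample's composition is drawn from the neutral stationary
  distribution Dirichlet(N m p) and reads multinomially with
  N = 30 000 and m = 0.1 over 40 samples — the finite Hubbell/Sloan
  local community whose occupancy marginals are exactly the
  Beta(N m p, N m (1 − p)) curve the fit assumes.  A one-pass assembly
  urn (immigrate w.p. m else copy a resident) was evaluated and rejected:
  its early-copy reinforcement inflates compositional variance far beyond
  the stationary Beta, biasing fitted m several-fold low.  A fraction
  (default 0.1) of each vOTU's reads is flagged as multi-mapping to its
  genus siblings, exercising the redistribution step.

**Fidelity note.**  Fitting the continuous Sloan prevalence curve to
discrete count data leaves a small intrinsic upward bias in m (count >= 1
detection is more permissive than the model's f > 1/N threshold); at the
default N = 30 000 the recovered m is typically within 5–15% of truth,
inside the 20% recovery tolerance used by the tests.

**What the generator does not emulate.**  Raw reads, assembly error and
chimerism, MDA amplification bias, gene calling (protein sequences are
not encoded in the nucleotide genomes, and genomes of related vOTUs share
composition but not nucleotide homology — sufficient for every stage
tested here, but the ANI de-replication and spacer stages therefore see
cleaner inputs than real data), reference phage contamination of
families, and non-neutral abundance structure.  Passing tests show the
machinery is correct on data satisfying its assumptions, not that real
viromes satisfy them.

## Problem sizes and numerical choices

Recovery suites run on the 90-genome default cohort (protein all-vs-all
~600k alignments, a few minutes end to end on one CPU); neutral-model
recovery uses 300 taxa x 200 samples.  These sizes give the package's
statistical checks stable answers while keeping the default test run
short.  Determinism: every stochastic step takes a seed
(`numpy.random.default_rng`); alignment, tree, MCL and naming are
deterministic given canonical orderings.  Known degenerate inputs —
empty protein sets, zero-protein genomes, single-tip clades, all-zero
samples, constant statistics vectors — are either rejected with messages
or flagged with warnings, as documented per function.

## Limitations

The APS tree is built by UPGMA, which assumes a clock-like decay of
protein sharing; strongly rate-heterogeneous clades would distort root
distances (the original analysis rooted an unconstrained tree by
outgroup instead — unpublished code, so the rooted-by-construction
alternative was chosen here).  The orthology filter is plain
reciprocal-best-hit without synteny or many-to-many orthology.  The
composition host predictor reports no significance, only a
log-likelihood gap (threshold configurable, default always-predict).
Spacer matching ignores indels by design.  None of the components is
performance-tuned for millions of contigs.
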