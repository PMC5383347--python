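# Methods

## The recurrence model

`cisrec` measures how often a gene's *cis*-regulatory space is hit by
functional noncoding variants across a tumor cohort.  The unit of
evidence is the (gene, sample) pair, not the variant site: a gene's
combinatorial recurrence M(v) is the number of distinct samples carrying
at least one motif-disrupting variant anywhere in its regulatory space.
This deliberately aggregates variants that are scattered across a
promoter and several enhancers, which single-site recurrence tests would
treat as unrelated events.

The regulatory space of a gene is assembled from chromatin-interaction
evidence:

* **Promoter** — 2 kb upstream to 500 bp downstream of the TSS,
  strand-aware, clipped at the chromosome origin.
* **Enhancers** — the distal anchor of every surviving interaction whose
  other anchor overlaps the gene's promoter by at least 1 bp.  Four
  source types are supported (ChIA-PET, IM-PET, DHS correlation, CAGE
  correlation).  ChIA-PET records need PET count >= 3; correlation-based
  sources, which describe a universal (cell-type-agnostic) set, can be
  intersected with a cell-type DHS track; interactions whose two anchors
  both overlap promoters (of any genes) are discarded, as are
  interactions touching no promoter.  An anchor overlapping several
  promoters assigns its enhancer to every overlapped gene — a deliberate,
  logged inclusion, since the evidence does not distinguish the targets.
* CAGE-detected eRNA loci are reduced to candidate enhancer intervals of
  +/-100 bp around the eRNA center before linking.

Genes are categorized by M: none (M <= 1), low (2 <= M <= 4), high
(M >= 5); "recurrent" means M >= 2.

## Motif disruption calls

A substitution is scored against each PWM on both alleles.  The allele
score is the best log-odds hit max over the windows covering the variant
and both strands; windows containing N or truncated by a chromosome end
are skipped.  The score is converted to the p-value P(S >= s) of a single
random motif-length window under the background model, and the call is a
threshold crossing at cutoff 1e-5: gain when p_alt <= cutoff < p_ref,
loss in the mirror case, none otherwise.  Two p-values that are both
below (or both above) the cutoff never yield a call, however large their
difference — the rule is a binary site-presence change, and no minimum
p-value gap is imposed beyond the crossing itself.  A Bonferroni
correction over the number of scanned windows is available behind a flag
and off by default, matching per-position p-value semantics of standard
PWM scanners.

**Score null distribution.**  P(S >= s) is computed by dynamic
programming over motif positions.  The DP is sparse and exact: it tracks
the full set of attainable score sums with their background
probabilities, so for motifs up to ~9 bp (< 2^19 states) the tail equals
exhaustive enumeration over all 4^k words to floating-point precision.
Longer motifs switch to a quantized score support (about 2^21 quanta over
the attainable range) and the tail lookup then allows one quantum of
slack per motif position, which keeps the p-value monotone in the score
and never drops an attainable score from its own tail.  The p-value is
clamped to the probability of the best word, so it is always in (0, 1].
PWMs carry a pseudocount (default 1e-4 per cell, renormalized) so
zero cells stay finite.

**Genome disruption index.**  Simulation nulls re-pass randomized
variants through motif calling, so calling must be cheap.  The
`DisruptionIndex` precomputes, for every genomic position and every
possible base at that position, whether the best covering-window hit of
each PWM is below the cutoff.  A substitution is motif-changing exactly
when this significance bit differs between the reference and alternate
base for at least one PWM — provably the same answer as per-variant
calling (asserted by test on sampled variants), at O(1) lookup per
variant.  Building the index costs one linear scan per PWM, strand and
base.

## Simulation nulls

Three schemes generate the null distribution of a recurrence statistic;
built-in statistics are the number of recurrent genes, the mean M over
all genes, and the per-gene M vector for single-gene tests.

* **in-silico** — variants are redrawn uniformly over the genome, each
  sample keeping its exact variant count; the reference allele is read
  from the genome and the alternate drawn from the other three bases.
  Uniform placement over the whole genome is the default; restricting
  placement to regulatory space is a stricter variant the engine can
  express through a custom statistic but is not the default reading.
* **clinical** — each sample's count is drawn without replacement (within
  a replicate; with replacement across replicates) from a pool of
  variants from unrelated tumor samples and relabelled; a pool smaller
  than the cohort's total count is an error.
* **epigenome** — the real variants are kept, but the map is rebuilt from
  a control interactome sampled per source type to exactly the real
  per-source counts, from an unrelated cell type's data.

Empirical p-values use the add-one estimator
p = (1 + #{replicates >= observed}) / (1 + reps), upper tail, which is
never exactly zero at finite replicates.  Replicates draw child RNGs
spawned from one master seed, so a full 1,000-replicate run is
reproducible from a single integer.  Per-sample count conservation is
exact and asserted in tests; when data are themselves generated under the
in-silico null, the resulting p-values are uniform (KS-tested in the
acceptance suite at 200 datasets x 200 replicates).

## Network characterization

**Causal score** (directed acyclic regulatory network):
score(v) = (outdeg(v)/deg(v)) * (d(v->tail)/len(chain)), where deg is
total degree, and the chain is the extremal source-to-sink path through
v.  Both factors are computed by DP over a topological order; `shortest`
(default) and `longest` path modes are exposed and coincide on chains and
stars.  When several extremal chains exist only their lengths enter the
score, so no tie-break is needed beyond the extremum itself.  Sinks and
isolated nodes score 0; a pure source has relative outdegree 1; all
scores lie in [0, 1].  Reported scores are divided by the network mean,
so relative scores average to exactly 1 (an all-zero network has no
defined normalization and raises).  Cyclic graphs are rejected for causal
scoring only; association networks may be cyclic and are summarized by
degree relative to the network mean, per gene group, with a coverage
report for genes absent from the network.

**CD–TD interaction enrichment.**  Only direct edges between the coding-
driver set and the TD set are counted (a gene in both sets counts for
both sides; each qualifying edge counts once).  The expectation comes
from 1,000 permutations: node mode permutes node labels uniformly; link
mode rewires edges by degree-preserving double-edge swaps.  The rewiring
is vectorized: each round pairs up a random permutation of the edge list,
proposes one of the two swap orientations per pair, and applies every
proposal that creates neither a self-loop nor a duplicate edge (against
the current graph or a simultaneous proposal); the default budget is two
attempted swaps per edge.  Degree preservation is asserted on every
replicate.  The result is the observed-to-mean-expected ratio with an
add-one empirical p.

**Modular scores.**  With L(v) the neighbors of v and deg the neighbor
count:

* Score_average(v) = M(v) + (Σ_u M(u)) / deg(v)
* Score_max(v) = M(v) + max_u M(u)·W(v,u)
* Score_sum(v) = M(v) + Σ_u M(u) / deg(u)

The additive M(v) + aggregate form is used for all three scores (the
alternative (M(v)+Σ)/deg reading for the average is available via the
brute-force formulas in tests but not exposed; the additive form keeps
the three scores structurally parallel).  Edge weights are normalized to
[0, 1] by the network maximum and always enter Score_max; the average and
sum are unweighted by default, since weighting them does not change their
ranking behavior on the synthetic cohorts.  An isolated node's aggregate
over the empty neighborhood is 0, collapsing all scores to M(v).
Prediction of coding-driver status is evaluated by ROC; AUC uses the
rank-sum identity with midranks for ties.

**20/20 classification.**  From a coding-variant consequence table, the
recurrent-position fraction is the share of a gene's variants at
positions hit >= 2 times in that gene, and the truncating fraction the
share with nonsense/frameshift/splice consequences.  Oncogene if the
recurrent fraction exceeds 0.20 (strictly), TSG if the truncating
fraction does; when both exceed, the larger wins and exact ties go to
TSG.  Genes with fewer than 7 variants (configurable) are left
unclassified — the rule is meaningless on one or two variants.

## Variant complementarity

For a coding gene with variant-carrying sample set A and a regulatory
gene with sample set B, complementarity is |A xor B| / |A or B|: 1 for
disjoint nonempty sets (perfect mutual exclusivity), 0 for identical
sets, and unaffected by samples carrying neither variant.  The measure is
symmetric, bounded, and never increases when a sample is added to both
sets; it is passed as a function, so alternative exclusivity statistics
drop in.  Pairs are compared in three groups — CD–TD pairs adjacent in
the protein network, all CD x TD pairs, and all coding-x-regulatory gene
pairs as background (subsampled above 20,000 pairs) — with two-sided
rank-sum tests between groups, and the top-k most complementary partners
of a coding gene are rendered as a sample-by-gene occurrence matrix with
entries none/coding/regulatory/both.

## The synthetic cohort generator

The generator emulates the pipeline's real inputs at desk scale with
planted, machine-readable ground truth (`truth.json`); downstream tests
read the truth file rather than re-deriving it.

Default study conditions: 40 samples; 300 protein-coding genes on one
2 Mb synthetic chromosome (the larger validation runs use 1,000 genes on
6.8 Mb); Poisson per-sample variant loads with mean 100 (a negative-
binomial dispersion is available); 5 planted TDs at co-occurrence 6;
3 planted CDs (alternating oncogene/TSG style, 12 variants each); one
mutually exclusive CD–TD pair per planted CD.  Genes occupy disjoint
slots with enough clearance that promoters never overlap and the
intergenic eRNA zone of one slot cannot touch the 2 kb downstream reach
of the previous gene's minus-strand promoter.  The motif library is one
strong 10 bp "planted" PWM (consensus probability 0.994, so its consensus
word scores below the 1e-5 cutoff and any single-base consensus change
lifts the best p above it — a loss call by construction) plus two weaker
8 bp background PWMs; consensus instances are scattered over the genome
at ~4% coverage so background variants disrupt motifs at a realistic few-
percent rate, which gives the null statistics their spread.

Planted TDs receive one ChIA-PET link (PET >= 3) per needed enhancer from
an intergenic eRNA-derived enhancer to their promoter; the disrupting
variants sit at distinct sites (20 bp pitch) inside those enhancers, one
per planted sample, so recurrence is combinatorial rather than
single-site by construction.  Background interactions draw random
eRNA enhancers and random promoters across all four source types, with
configurable fractions of PET < 3 records, promoter–promoter pairs and
promoter-less (orphan) pairs to exercise the filters; planted enhancers
are excluded from the background anchor pool so planted variants cannot
leak recurrence into random genes.  The control interactome (for the
epigenome null) is generated by the same background process at twice the
size, without planted links; the clinical control pool is three cohorts'
worth of uniform background variants.  The protein network is
Erdős–Rényi (mean degree 4) plus direct CD–TD edges for the planted
pairs; the regulatory network is a random DAG (mean outdegree 2).

What the generator does **not** emulate: mutational signatures and
trinucleotide context, indels and structural variants, hotspot placement
(available but off by default), chromatin-state covariation between
tracks, multi-chromosome genomes (supported by the data model, not the
default), and realistic gene/enhancer length distributions.  Passing
tests therefore demonstrate correctness of the statistical machinery and
recovery of planted structure under idealized covariates, not performance
on real tumor genomes.

## Numerical and design choices

* Coordinates are 0-based half-open in memory; variant tables and GTF are
  1-based on disk and converted at the reader boundary.
* Ranking ties in recurrence tables break lexicographically by gene id;
  M = 0 genes are kept in all tables since they enter modular scores.
* Gene-set enrichment is an upper-tail hypergeometric with Bonferroni
  adjustment over the number of sets tested.
* The acceptance-scale problem sizes (200 calibration datasets at 200
  replicates; 1,000-gene planted cohort at 1,000 replicates; 100
  enrichment trials at 1,000 permutations) were chosen so the full suite
  completes in a few minutes on one CPU while keeping every statistical
  band comfortably away from its threshold.
* All randomness flows from integer seeds through `numpy` generators and
  `SeedSequence.spawn`; fixed seeds give byte-identical outputs,
  including serialized cohorts and full pipeline runs.

## Known limitations

* The complementarity measure is a documented choice satisfying the
  boundary behavior any exclusivity measure must have (1 when disjoint,
  0 when identical); other definitions with the same boundary behavior
  would rank intermediate pairs differently.
* The causal score uses one extremal chain per gene; averaging over all
  source/sink pairs through a gene is a plausible alternative reading and
  would smooth scores in dense DAGs.
* Per-gene empirical p-values at 1,000 replicates are floored at
  ~1e-3 by the add-one estimator; genome-wide multiple-testing control
  across genes is intentionally out of scope.
* Batched double-edge swaps approximate the uniform degree-preserving
  ensemble; the rejection of colliding proposals slightly biases short
  runs, which is immaterial for expected-count estimation (calibration is
  tested) but would matter for exact graph-ensemble sampling.
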