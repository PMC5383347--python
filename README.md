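# cisrec

Combinatorial *cis*-regulatory variant recurrence analysis for tumor
cohorts.

Most somatic variants in cancer genomes fall in noncoding DNA, where
single-site recurrence across patients is rare even for functional
variants.  `cisrec` implements a combinatorial recurrence model: a
gene's *cis*-regulatory space is its promoter plus every distal enhancer
linked to that promoter through a merged, filtered chromatin interactome
(ChIA-PET, IM-PET, DHS correlation and CAGE correlation evidence), and
its recurrence

    M(v) = #{ samples with >= 1 motif-disrupting variant anywhere in v's cis-regulatory space }

counts distinct tumor samples, not variant sites — four variants from four
patients in four different enhancers of the same gene give M = 4.  A
variant is motif-disrupting when the best position-weight-matrix hit
p-value crosses a cutoff (default 1e-5) between the reference and
alternate alleles (gain: p_alt <= cutoff < p_ref; loss: the reverse).
Genes are categorized none / low / high at M <= 1 / 2–4 / >= 5, and
recurrence significance is assessed with three simulation nulls (uniform
in-silico variants, clinical resampling from unrelated tumor variants,
and a size-matched control interactome from an unrelated cell type), each
preserving per-sample variant counts or per-source interaction counts
exactly.  Identified transcriptional drivers (TDs) are then characterized
in networks: causal scores in a regulatory DAG, relative degree in
association networks, protein-interaction enrichment with coding drivers
(CDs), modular driver scores

    Score_average(v) = M(v) + (sum_{u in L(v)} M(u)) / deg(v)
    Score_max(v)     = M(v) + max_{u in L(v)} M(u) * W(v, u)
    Score_sum(v)     = M(v) + sum_{u in L(v)} M(u) / deg(u)

and coding/regulatory variant complementarity |A xor B| / |A or B| across
samples.  A fully synthetic cohort generator with planted ground truth
(planted TDs, 20/20-rule CDs, mutually exclusive CD–TD pairs) makes every
stage testable without external data.

## Worked example

```python
import numpy as np
import cisrec
from cisrec.motif_disruption import build_disruption_index, encode_sequence

cfg = cisrec.SyntheticCohortConfig(
    n_samples=20, n_genes=100, genome_length=700_000,
    variants_per_sample_mean=60, n_planted_tds=3, planted_recurrence=5,
    seed=1)
cohort = cisrec.generate_cohort(cfg)

genome = {c: encode_sequence(s) for c, s in cohort.genome.items()}
index = build_disruption_index(genome, cohort.pwms)          # motif calls
variants = cohort.variants.copy()
alt = np.array([encode_sequence(a)[0] for a in variants["alt"]])
variants["changing"] = index.is_changing(
    cfg.chrom, variants["pos"].to_numpy(), alt)

assignments = cisrec.map_variant_targets(variants, cohort.ep_map)
rec = cisrec.compute_recurrence(
    assignments, cohort.truth["cohort"],
    genes=[g.gene_id for g in cohort.annotation.genes])
print(rec.head(4)[["M", "category"]])
```

prints

```
         M category
gene_id
G0000    5     high
G0049    5     high
G0084    5     high
G0002    1     none
```

The three genes at M = 5 are exactly the planted transcriptional drivers
(`cohort.truth["planted_tds"]`): five distinct samples hit motif sites in
their chromatin-linked enhancers, so each reaches high recurrence although
no two variants share a site.  Their in-silico empirical p-values at 200
replicates are ~0.005 (`RecurrenceNullEngine.run(..., statistic="per-gene")`).

The same analysis runs from the shell:

```bash
cisrec simulate --seed 1 --out cohort/
cisrec run --seed 1 --out results/
```

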