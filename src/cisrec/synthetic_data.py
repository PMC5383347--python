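"""Synthetic tumor-cohort generator with planted ground truth.

Emulates every input of the recurrence pipeline on a small synthetic
chromosome ("chrS1" by default): non-overlapping protein-coding gene
models, intergenic eRNA loci and DHS open-chromatin intervals, a
four-source chromatin interactome (plus a size-matched "irrelevant
cell type" control), a PWM library whose consensus words are scattered
through the genome, per-sample somatic variant loads, a coding-variant
consequence table, a control variant pool from "other tumor types", and
protein-interaction / regulatory networks.

Planted structure drives the acceptance of every downstream stage:

* **transcriptional drivers (TDs)** — genes whose chromatin-linked
  enhancers receive motif-disrupting variants from a configured number of
  distinct samples, at distinct sites, so their combinatorial recurrence is
  known by construction;
* **coding drivers (CDs)** — genes whose coding-variant tables satisfy the
  20/20 rule (oncogene-style recurrent positions or TSG-style truncating
  fractions), wired to planted TDs in the protein interactome;
* **mutual exclusivity** — configured CD–TD pairs whose coding and
  regulatory sample sets are disjoint.

The planted truth is emitted as a machine-readable dictionary (serialized
to JSON) which downstream tests read instead of re-deriving it.  All
randomness flows from one integer seed; a fixed seed yields byte-identical
output files.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from . import io as cio
from .interactome import (ChromatinInteraction, EnhancerPromoterMap, Gene,
                          GenomicInterval, define_promoters,
                          enhancers_from_ernas, filter_interactions,
                          merge_interactomes)
from .motif_disruption import BASES, PWM, encode_sequence

logger = logging.getLogger(__name__)

CHROM = "chrS1"
#: bp reserved upstream of each gene: room for the upstream neighbor's
#: promoter (a minus-strand promoter reaches 2 kb past its gene end), an
#: intergenic eRNA zone and this gene's own promoter
_GENE_MARGIN = 5400
#: motif sites planted per enhancer (200 bp holds 8 ten-bp sites at 20 bp pitch)
_SITES_PER_ENHANCER = 8
_SITE_PITCH = 20


@dataclass
class SyntheticCohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe a desk-scale tumor cohort: tens of samples with about
    a hundred somatic point variants each on a megabase-scale chromosome,
    a handful of planted transcriptional and coding drivers, and planted
    mutually exclusive CD–TD pairs.
    """
    n_samples: int = 40
    n_genes: int = 300
    genome_length: int = 2_000_000
    variants_per_sample_mean: float = 100.0
    variants_per_sample_dispersion: Optional[float] = None  # None = Poisson
    n_planted_tds: int = 5
    planted_recurrence: int = 6
    n_planted_cds: int = 3
    n_exclusivity_pairs: Optional[int] = None  # default min(CDs, TDs)
    coding_variants_per_gene: int = 12
    n_background_coding_genes: int = 10
    gene_span: int = 1200
    n_background_ernas: Optional[int] = None  # default n_genes
    erna_length_range: Tuple[int, int] = (200, 600)
    dhs_cover_fraction: float = 0.8
    interactions_per_source: Optional[int] = None  # default n_genes
    fraction_low_pet: float = 0.1
    promoter_promoter_fraction: float = 0.05
    orphan_fraction: float = 0.05
    n_background_pwms: int = 2
    planted_motif_length: int = 10
    background_motif_length: int = 8
    motif_instance_density: float = 0.04
    ppi_mean_degree: float = 4.0
    dag_mean_outdegree: float = 2.0
    control_pool_factor: float = 3.0
    hotspot_fraction: float = 0.0  # background variant hotspots, off by default
    chrom: str = CHROM
    seed: int = 0

    def validate(self) -> None:
        positive = ["n_samples", "n_genes", "genome_length",
                    "variants_per_sample_mean", "n_planted_tds",
                    "planted_recurrence", "n_planted_cds", "gene_span",
                    "coding_variants_per_gene"]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.planted_recurrence > self.n_samples:
            raise ValueError("planted_recurrence cannot exceed n_samples")
        if self.n_planted_tds + self.n_planted_cds > self.n_genes:
            raise ValueError("planted genes exceed n_genes")
        slot = self.genome_length // self.n_genes
        if slot < self.gene_span + _GENE_MARGIN + 1:
            raise ValueError(
                f"genome too small: need >= "
                f"{self.n_genes * (self.gene_span + _GENE_MARGIN + 1)} bp "
                f"for {self.n_genes} genes")
        n_excl = self.resolved_exclusivity_pairs()
        if n_excl > min(self.n_planted_cds, self.n_planted_tds):
            raise ValueError("more exclusivity pairs than planted CD/TD genes")
        n_enh = -(-self.planted_recurrence // _SITES_PER_ENHANCER)
        if self.n_planted_tds * n_enh >= self.n_genes:
            raise ValueError("too few genes to host planted enhancer zones")

    def resolved_exclusivity_pairs(self) -> int:
        if self.n_exclusivity_pairs is None:
            return min(self.n_planted_cds, self.n_planted_tds)
        return self.n_exclusivity_pairs

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class Annotation:
    """Gene models plus regulatory tracks on the synthetic chromosome."""
    genes: List[Gene]
    ernas: List[GenomicInterval]
    dhs: List[GenomicInterval]
    chrom_lengths: Dict[str, int]
    planted_td_ids: List[str]
    td_erna_indices: Dict[str, List[int]]  # planted TD -> its eRNA indices


@dataclass
class SyntheticCohort:
    """Full generated input bundle plus the planted-truth record."""
    config: SyntheticCohortConfig
    annotation: Annotation
    pwms: List[PWM]
    genome: Dict[str, str]
    interactions: List[ChromatinInteraction]
    control_interactions: List[ChromatinInteraction]
    ep_map: EnhancerPromoterMap
    variants: pd.DataFrame
    coding_variants: pd.DataFrame
    control_pool: pd.DataFrame
    ppi: nx.Graph
    regulatory_dag: nx.DiGraph
    truth: dict

    @property
    def cohort(self) -> List[str]:
        return [f"S{i:03d}" for i in range(self.config.n_samples)]


def _stage_rng(cfg: SyntheticCohortConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed % (2 ** 31), stage])


# -- stage 1: annotation ----------------------------------------------------


def generate_annotation(cfg: SyntheticCohortConfig) -> Annotation:
    """Place non-overlapping genes, intergenic eRNAs and a DHS track.

    Each gene occupies its own slot of the chromosome with enough clearance
    that promoters of adjacent genes never overlap; eRNAs are placed in the
    intergenic zone upstream of each slot's gene.
    """
    cfg.validate()
    rng = _stage_rng(cfg, 1)
    slot = cfg.genome_length // cfg.n_genes
    genes: List[Gene] = []
    zones: List[Tuple[int, int]] = []  # intergenic free zone per slot
    for i in range(cfg.n_genes):
        base = i * slot
        offset = int(rng.integers(_GENE_MARGIN, slot - cfg.gene_span + 1))
        start = base + offset
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(Gene(f"G{i:04d}", cfg.chrom, start, start + cfg.gene_span,
                          strand))
        zones.append((base + 2300, start - 2600))

    n_td = cfg.n_planted_tds
    td_idx = rng.choice(cfg.n_genes, size=n_td + cfg.n_planted_cds,
                        replace=False)
    planted_td_ids = [genes[i].gene_id for i in sorted(td_idx[:n_td])]

    ernas: List[GenomicInterval] = []
    td_erna_indices: Dict[str, List[int]] = {g: [] for g in planted_td_ids}
    n_enh = -(-cfg.planted_recurrence // _SITES_PER_ENHANCER)
    # planted TDs draw their enhancer eRNAs from distinct free zones
    zone_ids = rng.choice(cfg.n_genes, size=n_td * n_enh, replace=False)
    zi = 0
    for g in planted_td_ids:
        for _ in range(n_enh):
            z0, z1 = zones[zone_ids[zi]]
            zi += 1
            length = int(rng.integers(*cfg.erna_length_range))
            center = int(rng.integers(z0 + 200, z1 - 200))
            s = max(0, center - length // 2)
            td_erna_indices[g].append(len(ernas))
            ernas.append(GenomicInterval(cfg.chrom, s, s + length))
    n_bg = cfg.n_background_ernas if cfg.n_background_ernas is not None else cfg.n_genes
    free_zones = sorted(set(range(cfg.n_genes)) - set(int(z) for z in zone_ids))
    for _ in range(n_bg):
        z0, z1 = zones[free_zones[int(rng.integers(len(free_zones)))]]
        length = int(rng.integers(*cfg.erna_length_range))
        center = int(rng.integers(z0 + 200, z1 - 200))
        s = max(0, center - length // 2)
        ernas.append(GenomicInterval(cfg.chrom, s, s + length))

    dhs: List[GenomicInterval] = []
    for iv in ernas:
        if rng.random() < cfg.dhs_cover_fraction:
            c = (iv.start + iv.end) // 2
            dhs.append(GenomicInterval(cfg.chrom, max(0, c - 150), c + 150))
    for _ in range(50):
        p = int(rng.integers(0, cfg.genome_length - 300))
        dhs.append(GenomicInterval(cfg.chrom, p, p + 300))
    dhs.sort()

    return Annotation(genes, ernas, dhs, {cfg.chrom: cfg.genome_length},
                      planted_td_ids, td_erna_indices)


# -- stage 2: motif library and genome scaffold ------------------------------


def generate_motifs(cfg: SyntheticCohortConfig) -> List[PWM]:
    """One strong 'planted' PWM plus weaker background PWMs.

    The planted PWM is near-deterministic, so its consensus word is a hit at
    p ~ 0.25^k (below the 1e-5 cutoff for the default length of 10) and any
    single-base change to the consensus lifts the best p above the cutoff —
    a guaranteed loss call.
    """
    rng = _stage_rng(cfg, 2)
    pwms = []

    def _matrix(length, strength):
        cons = rng.integers(0, 4, size=length)
        mat = np.full((length, 4), (1 - strength) / 3)
        mat[np.arange(length), cons] = strength
        return mat

    pwms.append(PWM("PLANTED_TF", _matrix(cfg.planted_motif_length, 0.994)))
    for i in range(cfg.n_background_pwms):
        pwms.append(PWM(f"BG_TF{i}", _matrix(cfg.background_motif_length, 0.92)))
    return pwms


def generate_genome(cfg: SyntheticCohortConfig, annotation: Annotation,
                    pwms: Sequence[PWM]) -> Dict[str, np.ndarray]:
    """Random genome with PWM consensus instances scattered at a configured
    density, giving background variants a realistic motif-disruption rate."""
    rng = _stage_rng(cfg, 3)
    codes = rng.integers(0, 4, size=cfg.genome_length).astype(np.uint8)
    mean_len = float(np.mean([len(p) for p in pwms]))
    n_inst = int(cfg.genome_length * cfg.motif_instance_density / mean_len)
    for _ in range(n_inst):
        pwm = pwms[int(rng.integers(len(pwms)))]
        word = encode_sequence(pwm.consensus())
        if rng.random() < 0.5:
            word = 3 - word[::-1]  # reverse complement
        p = int(rng.integers(0, cfg.genome_length - len(word)))
        codes[p:p + len(word)] = word
    return {cfg.chrom: codes}


# -- stage 3: interactome ----------------------------------------------------


def _promoter_core(gene: Gene) -> GenomicInterval:
    t = gene.tss
    return GenomicInterval(gene.chrom, max(0, t - 100), t + 100)


def generate_interactome(cfg: SyntheticCohortConfig, annotation: Annotation,
                         control: bool = False) -> List[ChromatinInteraction]:
    """BEDPE-style interactions for the four source types.

    Every planted TD gets ChIA-PET links (PET >= 3) from its enhancer
    eRNA(s) to its promoter.  Background interactions connect random eRNA
    enhancers to random promoters; configured fractions carry PET < 3, join
    two promoters, or touch no promoter at all, to exercise the filters.
    With ``control=True`` an independent interactome of the same flavor but
    without the planted links is generated (the "irrelevant cell type").
    """
    if not annotation.genes:
        raise ValueError("annotation has no genes")
    rng = _stage_rng(cfg, 5 if control else 4)
    enhancers = enhancers_from_ernas(annotation.ernas)
    genes = annotation.genes
    out: List[ChromatinInteraction] = []

    if not control:
        by_id = {g.gene_id: g for g in genes}
        for gid in annotation.planted_td_ids:
            for ei in annotation.td_erna_indices[gid]:
                out.append(ChromatinInteraction(
                    enhancers[ei], _promoter_core(by_id[gid]), "ChIA-PET",
                    int(rng.integers(3, 11))))

    planted_eis = {ei for eis in annotation.td_erna_indices.values()
                   for ei in eis}
    bg_pool = [i for i in range(len(enhancers)) if i not in planted_eis]

    n_per = (cfg.interactions_per_source
             if cfg.interactions_per_source is not None else cfg.n_genes)
    scale = 2 if control else 1  # control pool must cover real counts
    for source in ("ChIA-PET", "IM-PET", "DHS-corr", "CAGE-corr"):
        for _ in range(n_per * scale):
            gi = int(rng.integers(len(genes)))
            prom = _promoter_core(genes[gi])
            u = rng.random()
            if u < cfg.promoter_promoter_fraction:
                gj = int(rng.integers(len(genes)))
                other = _promoter_core(genes[gj])
            elif u < cfg.promoter_promoter_fraction + cfg.orphan_fraction:
                # orphan: neither anchor in a promoter
                other = enhancers[bg_pool[int(rng.integers(len(bg_pool)))]]
                prom = enhancers[bg_pool[int(rng.integers(len(bg_pool)))]]
            else:
                other = enhancers[bg_pool[int(rng.integers(len(bg_pool)))]]
            if source == "ChIA-PET":
                if rng.random() < cfg.fraction_low_pet:
                    support = int(rng.integers(1, 3))
                else:
                    support = int(rng.integers(3, 11))
            else:
                support = round(float(rng.uniform(0.5, 1.0)), 4)
            out.append(ChromatinInteraction(other, prom, source, support))
    return out


def build_ep_map(cfg: SyntheticCohortConfig, annotation: Annotation,
                 interactions: Sequence[ChromatinInteraction],
                 min_pet: int = 3) -> EnhancerPromoterMap:
    """Default map construction: PET filter then promoter-aware merge."""
    promoters = define_promoters(annotation.genes)
    surviving = filter_interactions(interactions, min_pet=min_pet)
    return merge_interactomes(surviving, promoters)


# -- stage 4: variants -------------------------------------------------------


def _draw_counts(cfg: SyntheticCohortConfig, rng, n: int) -> np.ndarray:
    mean = cfg.variants_per_sample_mean
    disp = cfg.variants_per_sample_dispersion
    if disp is None:
        return rng.poisson(mean, size=n)
    p = disp / (disp + mean)
    return rng.negative_binomial(disp, p, size=n)


def generate_variants(cfg: SyntheticCohortConfig, annotation: Annotation,
                      ep_map: EnhancerPromoterMap,
                      genome: Dict[str, np.ndarray],
                      pwms: Sequence[PWM]):
    """Plant TD-disrupting variants, coding-driver tables and background load.

    Returns ``(genome, variants, coding_variants, control_pool, truth)``.
    The genome is finalized here: the planted PWM's consensus is written at
    each planted site before its disrupting substitution is recorded, so the
    loss call holds by construction.  Planted TDs receive variants at
    distinct sites inside their linked enhancers from exactly
    ``planted_recurrence`` distinct samples; planted exclusivity pairs have
    disjoint coding/regulatory sample sets; everything else is uniform
    background.
    """
    cfg.validate()
    rng = _stage_rng(cfg, 6)
    codes = genome[cfg.chrom].copy()
    samples = [f"S{i:03d}" for i in range(cfg.n_samples)]
    planted_pwm = pwms[0]
    cons = encode_sequence(planted_pwm.consensus())
    k = len(cons)
    j_mid = k // 2
    worst = int(np.argmin(planted_pwm.matrix[j_mid]))

    # --- planted regulatory variants at distinct enhancer sites
    truth_tds = []
    planted_rows = []
    enhancers = enhancers_from_ernas(annotation.ernas)
    for gid in annotation.planted_td_ids:
        td_samples = rng.choice(cfg.n_samples, size=cfg.planted_recurrence,
                                replace=False)
        sites = []
        slots = []
        for ei in annotation.td_erna_indices[gid]:
            e = enhancers[ei]
            for s in range(_SITES_PER_ENHANCER):
                slots.append(e.start + 10 + s * _SITE_PITCH)
        for si, sample_i in enumerate(td_samples):
            site = slots[si]
            codes[site:site + k] = cons
            pos = site + j_mid
            planted_rows.append((samples[sample_i], cfg.chrom, pos,
                                 BASES[cons[j_mid]], BASES[worst]))
            sites.append(int(pos))
        truth_tds.append(dict(gene=gid,
                              samples=sorted(samples[i] for i in td_samples),
                              recurrence=int(cfg.planted_recurrence),
                              sites=sites))

    # --- planted coding drivers and exclusivity pairs
    all_ids = [g.gene_id for g in annotation.genes]
    used = set(annotation.planted_td_ids)
    candidates = [g for g in all_ids if g not in used]
    cd_pick = rng.choice(len(candidates), size=cfg.n_planted_cds,
                         replace=False)
    cd_ids = [candidates[i] for i in sorted(cd_pick)]
    n_excl = cfg.resolved_exclusivity_pairs()
    excl_pairs = [(cd_ids[i], truth_tds[i]["gene"]) for i in range(n_excl)]
    td_sample_sets = {t["gene"]: set(t["samples"]) for t in truth_tds}

    coding_rows = []
    truth_cds = []
    for i, gid in enumerate(cd_ids):
        style = "oncogene" if i % 2 == 0 else "TSG"
        n_var = cfg.coding_variants_per_gene
        if i < n_excl:
            forbidden = td_sample_sets[excl_pairs[i][1]]
            pool = [s for s in samples if s not in forbidden]
        else:
            pool = samples
        chosen = rng.choice(len(pool), size=min(n_var, len(pool)),
                            replace=False)
        chosen_samples = [pool[j] for j in chosen]
        positions = rng.choice(1000, size=len(chosen_samples), replace=False)
        n_special = max(1, int(np.ceil(0.3 * len(chosen_samples))))
        for j, s in enumerate(chosen_samples):
            if style == "oncogene":
                pos = int(positions[0]) if j < n_special else int(positions[j])
                consequence = "missense"
            else:
                pos = int(positions[j])
                consequence = (str(rng.choice(["nonsense", "frameshift",
                                               "splice"]))
                               if j < n_special else "missense")
            coding_rows.append((gid, s, pos, consequence))
        truth_cds.append(dict(gene=gid, style=style,
                              samples=sorted(chosen_samples)))

    # background (non-driver) coding genes: scattered, non-truncating
    bg_candidates = [g for g in candidates if g not in set(cd_ids)]
    bg_pick = rng.choice(len(bg_candidates),
                         size=min(cfg.n_background_coding_genes,
                                  len(bg_candidates)), replace=False)
    for gi in sorted(bg_pick):
        gid = bg_candidates[gi]
        n_var = int(rng.integers(7, 13))
        chosen = rng.choice(cfg.n_samples, size=min(n_var, cfg.n_samples),
                            replace=False)
        positions = rng.choice(1000, size=len(chosen), replace=False)
        for j, si in enumerate(chosen):
            consequence = "missense" if rng.random() < 0.85 else "silent"
            coding_rows.append((gid, samples[si], int(positions[j]),
                                consequence))

    # --- background noncoding variants, preserving per-sample totals
    counts = _draw_counts(cfg, rng, cfg.n_samples)
    planted_per_sample = np.zeros(cfg.n_samples, dtype=int)
    for row in planted_rows:
        planted_per_sample[samples.index(row[0])] += 1
    bg_counts = np.maximum(counts - planted_per_sample, 0)
    total_bg = int(bg_counts.sum())
    pos = rng.integers(0, cfg.genome_length, size=total_bg)
    ref = codes[pos]
    alt = (ref + rng.integers(1, 4, size=total_bg)) % 4
    bg_rows = list(zip(np.repeat(samples, bg_counts),
                       [cfg.chrom] * total_bg, pos.tolist(),
                       (BASES[b] for b in ref), (BASES[b] for b in alt)))
    variants = pd.DataFrame(planted_rows + bg_rows,
                            columns=["sample", "chrom", "pos", "ref", "alt"])
    variants = variants.sort_values(["sample", "pos"],
                                    kind="mergesort").reset_index(drop=True)

    # --- control pool ("other tumor types") for the clinical simulation
    pool_size = int(cfg.control_pool_factor
                    * max(counts.sum(), cfg.n_samples
                          * cfg.variants_per_sample_mean))
    ppos = rng.integers(0, cfg.genome_length, size=pool_size)
    pref = codes[ppos]
    palt = (pref + rng.integers(1, 4, size=pool_size)) % 4
    control_pool = pd.DataFrame({
        "sample": [f"C{i:05d}" for i in range(pool_size)],
        "chrom": cfg.chrom,
        "pos": ppos,
        "ref": [BASES[b] for b in pref],
        "alt": [BASES[b] for b in palt],
    })

    truth = dict(
        planted_tds=truth_tds,
        planted_cds=truth_cds,
        exclusivity_pairs=[list(p) for p in excl_pairs],
        planted_pwm=planted_pwm.motif_id,
        cohort=samples,
        config=cfg.to_dict(),
    )
    return {cfg.chrom: codes}, variants, coding_rows_frame(coding_rows), \
        control_pool, truth


def coding_rows_frame(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["gene", "sample", "position",
                                       "consequence"])


# -- stage 5: networks -------------------------------------------------------


def generate_networks(cfg: SyntheticCohortConfig, annotation: Annotation,
                      truth: dict) -> Tuple[nx.Graph, nx.DiGraph]:
    """Protein interactome (undirected) and regulatory DAG over all genes.

    The protein network is Erdős–Rényi background plus direct edges between
    each planted CD and (up to) two planted TDs — the planted modular
    CD-centered structure.  The regulatory network is a random DAG.
    """
    rng = _stage_rng(cfg, 7)
    ids = [g.gene_id for g in annotation.genes]
    n = len(ids)
    ppi = nx.Graph()
    ppi.add_nodes_from(ids)
    p_edge = min(1.0, cfg.ppi_mean_degree / max(1, n - 1))
    iu = np.triu_indices(n, k=1)
    mask = rng.random(len(iu[0])) < p_edge
    ppi.add_edges_from((ids[a], ids[b])
                       for a, b in zip(iu[0][mask], iu[1][mask]))
    td_ids = [t["gene"] for t in truth["planted_tds"]]
    for i, cd in enumerate(t["gene"] for t in truth["planted_cds"]):
        for j in range(min(2, len(td_ids))):
            ppi.add_edge(cd, td_ids[(i + j) % len(td_ids)])

    dag = nx.DiGraph()
    order = [ids[i] for i in rng.permutation(n)]
    dag.add_nodes_from(order)
    p_dag = min(1.0, cfg.dag_mean_outdegree / max(1, n - 1))
    mask = rng.random(len(iu[0])) < p_dag
    dag.add_edges_from((order[a], order[b])
                       for a, b in zip(iu[0][mask], iu[1][mask]))
    return ppi, dag


# -- orchestration -----------------------------------------------------------


def generate_cohort(cfg: Optional[SyntheticCohortConfig] = None
                    ) -> SyntheticCohort:
    """Generate the full input bundle with planted truth for one cohort."""
    cfg = cfg or SyntheticCohortConfig()
    cfg.validate()
    annotation = generate_annotation(cfg)
    pwms = generate_motifs(cfg)
    genome0 = generate_genome(cfg, annotation, pwms)
    interactions = generate_interactome(cfg, annotation)
    control_interactions = generate_interactome(cfg, annotation, control=True)
    ep_map = build_ep_map(cfg, annotation, interactions)
    genome, variants, coding, control_pool, truth = generate_variants(
        cfg, annotation, ep_map, genome0, pwms)
    ppi, dag = generate_networks(cfg, annotation, truth)
    genome_str = {c: "".join("ACGT"[b] for b in v) for c, v in genome.items()}
    return SyntheticCohort(cfg, annotation, pwms, genome_str, interactions,
                           control_interactions, ep_map, variants, coding,
                           control_pool, ppi, dag, truth)


# -- serialization -----------------------------------------------------------

FILES = dict(variants="variants.tsv", coding="coding_variants.tsv",
             interactions="interactions.bedpe",
             control_interactions="control_interactions.bedpe",
             control_pool="control_pool.tsv", annotation="annotation.gtf",
             ernas="ernas.bed", dhs="dhs.bed", genome="genome.fa",
             motifs="motifs.meme", ppi="ppi.tsv", regulatory="regulatory.tsv",
             truth="truth.json")


def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    """Serialize the bundle to plain-text files (see ``FILES``)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cio.write_variants(cohort.variants, out / FILES["variants"])
    cio.write_coding_variants(cohort.coding_variants, out / FILES["coding"])
    cio.write_bedpe(cohort.interactions, out / FILES["interactions"])
    cio.write_bedpe(cohort.control_interactions,
                    out / FILES["control_interactions"])
    cio.write_variants(cohort.control_pool, out / FILES["control_pool"])
    cio.write_gtf_genes(cohort.annotation.genes, out / FILES["annotation"])
    cio.write_bed(cohort.annotation.ernas, out / FILES["ernas"])
    cio.write_bed(cohort.annotation.dhs, out / FILES["dhs"])
    cio.write_fasta(cohort.genome, out / FILES["genome"])
    cio.write_meme(cohort.pwms, out / FILES["motifs"])
    cio.write_edgelist(cohort.ppi, out / FILES["ppi"])
    cio.write_edgelist(cohort.regulatory_dag, out / FILES["regulatory"])
    cio.write_json(cohort.truth, out / FILES["truth"])


def read_cohort(indir) -> SyntheticCohort:
    """Round-trip loader for a serialized cohort directory."""
    d = Path(indir)
    truth = cio.read_json(d / FILES["truth"])
    cfg = SyntheticCohortConfig(**truth["config"])
    genes = cio.read_gtf_genes(d / FILES["annotation"])
    ernas = cio.read_bed(d / FILES["ernas"])
    dhs = cio.read_bed(d / FILES["dhs"])
    annotation = Annotation(genes, ernas, dhs,
                            {cfg.chrom: cfg.genome_length},
                            [t["gene"] for t in truth["planted_tds"]], {})
    interactions = cio.read_bedpe(d / FILES["interactions"])
    control_interactions = cio.read_bedpe(d / FILES["control_interactions"])
    ep_map = build_ep_map(cfg, annotation, interactions)
    return SyntheticCohort(
        cfg, annotation, cio.read_meme(d / FILES["motifs"]),
        cio.read_fasta(d / FILES["genome"]), interactions,
        control_interactions, ep_map,
        cio.read_variants(d / FILES["variants"]),
        cio.read_coding_variants(d / FILES["coding"]),
        cio.read_variants(d / FILES["control_pool"]),
        cio.read_edgelist(d / FILES["ppi"]),
        cio.read_edgelist(d / FILES["regulatory"], directed=True),
        truth)
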