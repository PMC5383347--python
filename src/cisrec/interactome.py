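"""Merged, filtered enhancer–promoter chromatin interactome.

Combines chromatin interaction evidence from four source types (ChIA-PET,
IM-PET, DHS correlation, CAGE correlation) into a per-gene map of
cis-regulatory intervals: the gene's own promoter plus every distal anchor
linked to that promoter by a surviving interaction.  Motif-changing variants
falling anywhere in a gene's map count toward that gene's combinatorial
recurrence, however scattered the individual variant sites are.

Coordinates are 0-based half-open throughout (BED/BEDPE convention);
1-based inputs are converted at the reader boundary in :mod:`cisrec.io`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

SOURCES = ("ChIA-PET", "IM-PET", "DHS-corr", "CAGE-corr")
#: sources providing a universal (cell-type agnostic) enhancer-promoter set
UNIVERSAL_SOURCES = ("DHS-corr", "CAGE-corr")

PROMOTER_UPSTREAM = 2000
PROMOTER_DOWNSTREAM = 500
ENHANCER_FLANK = 100
MIN_PET = 3


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open genomic interval."""
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}")

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (self.chrom == other.chrom
                and self.start < other.end and other.start < self.end)

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Gene:
    """Protein-coding gene model; ``start``/``end`` are 0-based half-open."""
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id} missing strand")

    @property
    def tss(self) -> int:
        """0-based coordinate of the transcription start site base."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class ChromatinInteraction:
    anchor1: GenomicInterval
    anchor2: GenomicInterval
    source: str
    support: float = 1.0

    def __post_init__(self):
        if self.source not in SOURCES:
            raise ValueError(f"unknown interaction source {self.source!r}")
        if self.source == "ChIA-PET":
            if self.support != int(self.support) or self.support <= 0:
                raise ValueError("ChIA-PET support must be a positive integer PET count")


@dataclass(frozen=True)
class RegulatoryRegion:
    interval: GenomicInterval
    role: str  # {"promoter", "enhancer"}
    sources: frozenset


def define_promoters(genes: Iterable[Gene],
                     upstream: int = PROMOTER_UPSTREAM,
                     downstream: int = PROMOTER_DOWNSTREAM,
                     ) -> Dict[str, GenomicInterval]:
    """Promoter per gene: ``upstream`` bp upstream to ``downstream`` bp
    downstream of the TSS, strand-aware and clipped at coordinate 0."""
    out = {}
    for g in genes:
        t = g.tss
        if g.strand == "+":
            start, end = t - upstream, t + downstream
        else:
            start, end = t - downstream, t + upstream
        out[g.gene_id] = GenomicInterval(g.chrom, max(0, start), end, g.strand)
    return out


def enhancers_from_ernas(erna_intervals: Iterable[GenomicInterval],
                         flank: int = ENHANCER_FLANK) -> List[GenomicInterval]:
    """Enhancer = ``flank`` bp up- and downstream of the eRNA center."""
    out = []
    for iv in erna_intervals:
        c = (iv.start + iv.end) // 2
        out.append(GenomicInterval(iv.chrom, max(0, c - flank), c + flank))
    return out


def _promoter_trees(promoters: Mapping[str, GenomicInterval]
                    ) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = {}
    for gid, iv in promoters.items():
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, gid)
    return trees


def _overlapping_genes(trees, iv: GenomicInterval) -> List[str]:
    tree = trees.get(iv.chrom)
    if tree is None:
        return []
    return sorted(hit.data for hit in tree.overlap(iv.start, iv.end))


def _track_trees(track: Iterable[GenomicInterval]) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = {}
    for iv in track:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def _overlaps_track(trees, iv: GenomicInterval) -> bool:
    tree = trees.get(iv.chrom)
    return tree is not None and bool(tree.overlap(iv.start, iv.end))


@dataclass
class AnchorFilter:
    """Require an anchor to overlap a track (e.g. H3K27ac, Pol II, p300).

    ``mode='enhancer'`` constrains the non-promoter anchor (needs promoters
    at filter time); ``mode='any'`` is satisfied by either anchor.
    """
    track: List[GenomicInterval]
    mode: str = "enhancer"
    name: str = "track"


def filter_interactions(interactions: Sequence[ChromatinInteraction],
                        min_pet: int = MIN_PET,
                        anchor_filters: Sequence[AnchorFilter] = (),
                        promoters: Optional[Mapping[str, GenomicInterval]] = None,
                        ) -> List[ChromatinInteraction]:
    """Drop low-support ChIA-PET records and apply optional anchor filters.

    ChIA-PET interactions with PET count < ``min_pet`` are removed; other
    sources are unaffected by the PET threshold.  Anchor filters compose
    conjunctively: every filter must be satisfied for a record to survive.
    """
    for ia in interactions:
        if ia.source not in SOURCES:  # defensive; dataclass validates too
            raise ValueError(f"unknown interaction source {ia.source!r}")
    ptrees = _promoter_trees(promoters) if promoters else {}
    ftrees = [(_track_trees(f.track), f) for f in anchor_filters]
    out = []
    for ia in interactions:
        if ia.source == "ChIA-PET" and ia.support < min_pet:
            continue
        ok = True
        for trees, f in ftrees:
            if f.mode == "any":
                ok = _overlaps_track(trees, ia.anchor1) or _overlaps_track(trees, ia.anchor2)
            elif f.mode == "enhancer":
                if not ptrees:
                    raise ValueError("anchor filter mode 'enhancer' requires promoters")
                anchors = [a for a in (ia.anchor1, ia.anchor2)
                           if not _overlapping_genes(ptrees, a)]
                if not anchors:  # no non-promoter anchor to test
                    anchors = [ia.anchor1, ia.anchor2]
                ok = any(_overlaps_track(trees, a) for a in anchors)
            else:
                raise ValueError(f"unknown anchor filter mode {f.mode!r}")
            if not ok:
                break
        if ok:
            out.append(ia)
    return out


def restrict_to_celltype(universal_interactions: Sequence[ChromatinInteraction],
                         dhs_track: Sequence[GenomicInterval],
                         promoters: Optional[Mapping[str, GenomicInterval]] = None,
                         ) -> List[ChromatinInteraction]:
    """Intersect universal-set sources with cell-type DHS open chromatin.

    DHS-corr and CAGE-corr interactions are retained only when their
    enhancer (non-promoter) anchor overlaps >= 1 DHS interval; ChIA-PET and
    IM-PET records pass through unchanged.
    """
    if not dhs_track:
        logger.warning("empty DHS track: universal-set interactions all removed")
    trees = _track_trees(dhs_track)
    ptrees = _promoter_trees(promoters) if promoters else {}
    out = []
    for ia in universal_interactions:
        if ia.source not in UNIVERSAL_SOURCES:
            out.append(ia)
            continue
        anchors = (ia.anchor1, ia.anchor2)
        if ptrees:
            non_prom = [a for a in anchors if not _overlapping_genes(ptrees, a)]
            anchors = tuple(non_prom) or anchors
        if any(_overlaps_track(trees, a) for a in anchors):
            out.append(ia)
    return out


class EnhancerPromoterMap:
    """Per-gene cis-regulatory intervals with evidence sources.

    ``assignments`` maps gene_id to a list of :class:`RegulatoryRegion`.
    Every gene carries its own promoter; enhancer intervals are linked only
    through a surviving interaction.
    """

    def __init__(self, assignments: Dict[str, List[RegulatoryRegion]]):
        self.assignments = assignments
        self._flat: Optional[dict] = None

    def genes(self) -> List[str]:
        return sorted(self.assignments)

    def intervals(self, gene_id: str) -> List[RegulatoryRegion]:
        return self.assignments[gene_id]

    def __eq__(self, other) -> bool:
        if not isinstance(other, EnhancerPromoterMap):
            return NotImplemented
        a = {g: sorted((r.interval, r.role, tuple(sorted(r.sources)))
                       for r in rs) for g, rs in self.assignments.items()}
        b = {g: sorted((r.interval, r.role, tuple(sorted(r.sources)))
                       for r in rs) for g, rs in other.assignments.items()}
        return a == b

    def n_enhancers(self) -> int:
        return sum(1 for rs in self.assignments.values()
                   for r in rs if r.role == "enhancer")

    # -- flattened segment index for vectorized position lookup ------------

    def _flat_index(self) -> dict:
        if self._flat is not None:
            return self._flat
        gene_ids = self.genes()
        gidx = {g: i for i, g in enumerate(gene_ids)}
        per_chrom = {}
        by_chrom: Dict[str, List[Tuple[int, int, int]]] = {}
        for g, regions in self.assignments.items():
            for r in regions:
                iv = r.interval
                by_chrom.setdefault(iv.chrom, []).append(
                    (iv.start, iv.end, gidx[g]))
        for chrom, ivs in by_chrom.items():
            starts = np.array([s for s, _, _ in ivs])
            ends = np.array([e for _, e, _ in ivs])
            bp = np.unique(np.concatenate([starts, ends]))
            seg_pairs: List[Tuple[int, int]] = []
            i0 = np.searchsorted(bp, starts)
            i1 = np.searchsorted(bp, ends)
            for (a, b, gi) in zip(i0, i1, (g for _, _, g in ivs)):
                for seg in range(a, b):
                    seg_pairs.append((seg, gi))
            seg_pairs = sorted(set(seg_pairs))
            seg_arr = np.array([s for s, _ in seg_pairs], dtype=np.intp)
            gene_arr = np.array([g for _, g in seg_pairs], dtype=np.intp)
            counts = np.bincount(seg_arr, minlength=len(bp))
            offsets = np.concatenate([[0], np.cumsum(counts)])
            per_chrom[chrom] = dict(bp=bp, offsets=offsets, genes=gene_arr)
        self._flat = dict(gene_ids=gene_ids, chroms=per_chrom)
        return self._flat

    def map_positions(self, chrom: str, pos: np.ndarray
                      ) -> Tuple[np.ndarray, np.ndarray]:
        """Vectorized lookup: (query_index, gene_index) pairs for positions
        falling inside any mapped interval.  Gene indices refer to
        ``self.genes()`` order."""
        flat = self._flat_index()
        entry = flat["chroms"].get(chrom)
        pos = np.asarray(pos)
        if entry is None:
            return (np.empty(0, np.intp), np.empty(0, np.intp))
        bp, offsets, genes = entry["bp"], entry["offsets"], entry["genes"]
        seg = np.searchsorted(bp, pos, side="right") - 1
        valid = (seg >= 0) & (seg < len(bp) - 1)
        qi = np.nonzero(valid)[0]
        seg = seg[valid]
        n_per = (offsets[seg + 1] - offsets[seg]).astype(np.intp)
        keep = n_per > 0
        qi, seg, n_per = qi[keep], seg[keep], n_per[keep]
        if len(qi) == 0:
            return (np.empty(0, np.intp), np.empty(0, np.intp))
        out_q = np.repeat(qi, n_per)
        # gather CSR slices
        idx = np.concatenate([np.arange(offsets[s], offsets[s + 1]) for s in seg])
        return out_q, genes[idx]


def merge_interactomes(interactions: Sequence[ChromatinInteraction],
                       promoters: Mapping[str, GenomicInterval],
                       ) -> EnhancerPromoterMap:
    """Merge filtered interactions from all sources into one map.

    Promoter–promoter interactions (both anchors overlapping >= 1 promoter,
    even of different genes) are discarded.  A surviving interaction with
    exactly one promoter-overlapping anchor assigns its other anchor as an
    enhancer of every gene whose promoter it overlaps; interactions touching
    no promoter are dropped.  Each gene's own promoter is always included.
    Duplicate intervals per gene are unioned with their source tags merged.
    """
    trees = _promoter_trees(promoters)
    acc: Dict[str, Dict[Tuple, Set[str]]] = {g: {} for g in promoters}
    for ia in interactions:
        g1 = _overlapping_genes(trees, ia.anchor1)
        g2 = _overlapping_genes(trees, ia.anchor2)
        if g1 and g2:
            continue  # promoter-promoter
        if not g1 and not g2:
            continue  # no promoter anchor
        genes, enhancer = (g1, ia.anchor2) if g1 else (g2, ia.anchor1)
        if len(genes) > 1:
            logger.info("anchor %s overlaps %d promoters; assigned to all",
                        enhancer, len(genes))
        key = (enhancer.chrom, enhancer.start, enhancer.end)
        for g in genes:
            acc[g].setdefault(key, set()).add(ia.source)
    assignments: Dict[str, List[RegulatoryRegion]] = {}
    for g, prom in promoters.items():
        regions = [RegulatoryRegion(prom, "promoter", frozenset({"promoter"}))]
        for (chrom, start, end), sources in sorted(acc[g].items()):
            regions.append(RegulatoryRegion(
                GenomicInterval(chrom, start, end), "enhancer",
                frozenset(sources)))
        assignments[g] = regions
    return EnhancerPromoterMap(assignments)


def map_variant_targets(variants, ep_map: EnhancerPromoterMap):
    """Assign motif-changing variants to target genes through the map.

    ``variants`` is a DataFrame with columns sample, chrom, pos and either a
    ``call`` column (rows with gain/loss are eligible) or a boolean
    ``changing`` column.  Returns a DataFrame of (gene, sample, chrom, pos)
    triples; a variant inside the maps of several genes yields several rows.
    """
    import pandas as pd

    v = variants
    if "call" in v.columns:
        v = v[v["call"].isin(("gain", "loss"))]
    elif "changing" in v.columns:
        v = v[v["changing"].astype(bool)]
    flat = ep_map._flat_index()
    gene_ids = np.array(flat["gene_ids"], dtype=object)
    frames = []
    for chrom, sub in v.groupby("chrom", sort=True):
        if chrom not in flat["chroms"]:
            logger.warning("variant chrom %s absent from map; %d variants skipped",
                           chrom, len(sub))
            continue
        qi, gi = ep_map.map_positions(chrom, sub["pos"].to_numpy())
        if len(qi) == 0:
            continue
        frames.append(pd.DataFrame({
            "gene_id": gene_ids[gi],
            "sample": sub["sample"].to_numpy()[qi],
            "chrom": chrom,
            "pos": sub["pos"].to_numpy()[qi],
        }))
    if not frames:
        return pd.DataFrame(columns=["gene_id", "sample", "chrom", "pos"])
    return pd.concat(frames, ignore_index=True)
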