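"""Simulation null models for combinatorial cis-regulatory recurrence.

Three schemes assess whether observed recurrence exceeds chance:

* **insilico** — random variants are generated uniformly over the genome,
  preserving each sample's variant count exactly.
* **clinical** — each sample's variant count is drawn (without replacement
  within a replicate) from a pool of real variants from unrelated tumor
  samples and reassigned to the target sample.
* **epigenome** — the real variants are kept but mapped through a control
  chromatin interactome assembled by sampling, per source type, exactly as
  many interactions from an unrelated cell type as the real map contains.

Randomized variant sets are re-passed through motif calling and target
mapping — recurrence is defined only for motif-changing mapped variants —
using the precomputed :class:`~cisrec.motif_disruption.DisruptionIndex` so
that a thousand replicates stay affordable.

Empirical p-values use the add-one estimator
``p = (1 + #{replicates >= observed}) / (1 + reps)`` (upper tail), which
cannot return zero at finite replicate counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .interactome import (ChromatinInteraction, EnhancerPromoterMap,
                          GenomicInterval, merge_interactomes)
from .motif_disruption import _BASE_CODE, DisruptionIndex
from .recurrence import LOW_THRESHOLD

logger = logging.getLogger(__name__)

BASES = "ACGT"


@dataclass
class NullDistribution:
    """Replicate statistic values, the observed value and its empirical p."""
    scheme: str
    replicate_values: np.ndarray  # (reps,) or (reps, n_genes)
    observed: np.ndarray | float
    empirical_p: np.ndarray | float
    reps: int

    def __post_init__(self):
        if len(self.replicate_values) != self.reps:
            raise ValueError("replicate_values length must equal reps")


def empirical_pvalue(replicate_values: np.ndarray, observed) -> np.ndarray | float:
    """Add-one upper-tail empirical p-value; never exactly zero."""
    rep = np.asarray(replicate_values)
    reps = rep.shape[0]
    p = (1.0 + np.sum(rep >= observed, axis=0)) / (1.0 + reps)
    return float(p) if np.ndim(p) == 0 else p


def empirical_null(statistic_fn: Callable, generator: Callable,
                   observed, reps: int = 1000, seed=None,
                   scheme: str = "custom") -> NullDistribution:
    """Generic empirical null: ``generator(rng)`` yields a replicate dataset,
    ``statistic_fn`` reduces it to a scalar (or vector for per-gene tests).

    Replicates use independent child RNGs spawned from ``seed`` so the full
    run is reproducible from one master seed.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    children = np.random.SeedSequence(seed).spawn(reps)
    values = [np.asarray(statistic_fn(generator(np.random.default_rng(c))))
              for c in children]
    rep = np.stack(values)
    return NullDistribution(scheme, rep, observed,
                            empirical_pvalue(rep, observed), reps)


# -- variant randomization schemes -----------------------------------------


def _genome_layout(genome: Mapping[str, np.ndarray]):
    chroms = sorted(genome)
    lengths = np.array([len(genome[c]) for c in chroms], dtype=np.int64)
    return chroms, lengths, np.concatenate([[0], np.cumsum(lengths)])


def simulate_insilico(variants: pd.DataFrame, genome: Mapping[str, np.ndarray],
                      rng: np.random.Generator) -> pd.DataFrame:
    """Uniform random variants preserving per-sample counts exactly.

    The reference allele is read from the genome at each drawn position and
    the alternate allele drawn uniformly among the three other bases.
    """
    chroms, lengths, offsets = _genome_layout(genome)
    counts = variants.groupby("sample", sort=True).size()
    total = int(counts.sum())
    flat = rng.integers(0, offsets[-1], size=total)
    ci = np.searchsorted(offsets, flat, side="right") - 1
    pos = flat - offsets[ci]
    ref_code = np.empty(total, dtype=np.uint8)
    for i, c in enumerate(chroms):
        m = ci == i
        ref_code[m] = genome[c][pos[m]]
    alt_code = (ref_code + rng.integers(1, 4, size=total)) % 4
    return pd.DataFrame({
        "sample": np.repeat(counts.index.to_numpy(), counts.to_numpy()),
        "chrom": np.array(chroms, dtype=object)[ci],
        "pos": pos,
        "ref": np.array(list(BASES))[ref_code],
        "alt": np.array(list(BASES))[alt_code],
    })


def simulate_clinical(variants: pd.DataFrame, control_pool: pd.DataFrame,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Resample each sample's variant count from a control variant pool.

    Draws are without replacement within a replicate (the pool must be at
    least as large as the cohort's total variant count); drawn records are
    relabelled with the target sample.
    """
    if len(control_pool) == 0:
        raise ValueError("control pool is empty")
    counts = variants.groupby("sample", sort=True).size()
    total = int(counts.sum())
    if len(control_pool) < total:
        raise ValueError(
            f"control pool ({len(control_pool)}) smaller than required draw ({total})")
    idx = rng.choice(len(control_pool), size=total, replace=False)
    out = control_pool.iloc[idx][["chrom", "pos", "ref", "alt"]].reset_index(drop=True)
    out.insert(0, "sample", np.repeat(counts.index.to_numpy(), counts.to_numpy()))
    return out


def sample_control_interactions(real_interactions: Sequence[ChromatinInteraction],
                                control_interactions: Sequence[ChromatinInteraction],
                                rng: np.random.Generator
                                ) -> List[ChromatinInteraction]:
    """Per source type, sample (without replacement) from the control set as
    many interactions as the real data contains."""
    by_source_real: Dict[str, int] = {}
    for ia in real_interactions:
        by_source_real[ia.source] = by_source_real.get(ia.source, 0) + 1
    by_source_ctrl: Dict[str, List[ChromatinInteraction]] = {}
    for ia in control_interactions:
        by_source_ctrl.setdefault(ia.source, []).append(ia)
    out: List[ChromatinInteraction] = []
    for source in sorted(by_source_real):
        need = by_source_real[source]
        pool = by_source_ctrl.get(source, [])
        if len(pool) < need:
            logger.warning("control %s has %d < %d interactions; using all",
                           source, len(pool), need)
            out.extend(pool)
            continue
        idx = rng.choice(len(pool), size=need, replace=False)
        out.extend(pool[i] for i in idx)
    return out


def simulate_epigenome(real_interactions: Sequence[ChromatinInteraction],
                       control_interactions: Sequence[ChromatinInteraction],
                       promoters: Mapping[str, GenomicInterval],
                       rng: np.random.Generator) -> EnhancerPromoterMap:
    """Control enhancer–promoter map built from a size-matched sample of an
    unrelated cell type's interactome."""
    sampled = sample_control_interactions(real_interactions,
                                          control_interactions, rng)
    return merge_interactomes(sampled, promoters)


# -- fast recurrence nulls ---------------------------------------------------


def stat_n_recurrent(M: np.ndarray, low: int = LOW_THRESHOLD) -> int:
    """Number of recurrently mutated genes (M >= low)."""
    return int(np.sum(M >= low))


def stat_mean_recurrence(M: np.ndarray) -> float:
    """Average recurrence over all genes of the map."""
    return float(np.mean(M))


STATISTICS: Dict[str, Callable] = {
    "n-recurrent": stat_n_recurrent,
    "mean-recurrence": stat_mean_recurrence,
    "per-gene": lambda M: M,
}


class RecurrenceNullEngine:
    """Vectorized observed/replicate recurrence computation.

    Holds the disruption index, the flattened enhancer–promoter map and the
    cohort layout so each replicate reduces to array lookups.
    """

    def __init__(self, index: DisruptionIndex, ep_map: EnhancerPromoterMap,
                 cohort: Sequence[str], genome: Mapping[str, np.ndarray]):
        self.index = index
        self.ep_map = ep_map
        self.cohort = list(cohort)
        self.sample_index = {s: i for i, s in enumerate(self.cohort)}
        self.gene_ids = ep_map.genes()
        self.genome = {c: np.asarray(v, np.uint8) for c, v in genome.items()}
        self.chroms, self.lengths, self.offsets = _genome_layout(self.genome)

    # arrays form: dict chrom -> (pos, alt_code, sample_idx)
    def arrays_from_frame(self, variants: pd.DataFrame) -> Dict[str, tuple]:
        out = {}
        for chrom, sub in variants.groupby("chrom", sort=True):
            pos = sub["pos"].to_numpy(np.int64)
            alt = np.array([_BASE_CODE[a] for a in sub["alt"]], dtype=np.intp)
            si = sub["sample"].map(self.sample_index).to_numpy(np.int64)
            out[chrom] = (pos, alt, si)
        return out

    def M_vector(self, arrays: Dict[str, tuple],
                 ep_map: Optional[EnhancerPromoterMap] = None) -> np.ndarray:
        """Per-gene distinct-sample count for one variant set."""
        ep = ep_map if ep_map is not None else self.ep_map
        gene_ids = ep.genes()
        n_s, n_g = len(self.cohort), len(gene_ids)
        keys = []
        for chrom, (pos, alt, si) in arrays.items():
            changing = self.index.is_changing(chrom, pos, alt)
            qi, gi = ep.map_positions(chrom, pos[changing])
            if len(qi):
                keys.append(gi.astype(np.int64) * n_s + si[changing][qi])
        if not keys:
            return np.zeros(n_g, dtype=np.int64)
        uniq = np.unique(np.concatenate(keys))
        return np.bincount(uniq // n_s, minlength=n_g)

    def _counts(self, arrays: Dict[str, tuple]) -> np.ndarray:
        all_si = np.concatenate([si for _, _, si in arrays.values()])
        return np.bincount(all_si, minlength=len(self.cohort))

    def _random_arrays(self, counts: np.ndarray,
                       rng: np.random.Generator) -> Dict[str, tuple]:
        total = int(counts.sum())
        flat = rng.integers(0, self.offsets[-1], size=total)
        ci = np.searchsorted(self.offsets, flat, side="right") - 1
        pos = flat - self.offsets[ci]
        si = np.repeat(np.arange(len(counts)), counts)
        out = {}
        for i, chrom in enumerate(self.chroms):
            m = ci == i
            p = pos[m]
            ref = self.genome[chrom][p]
            alt = (ref + rng.integers(1, 4, size=len(p))) % 4
            out[chrom] = (p, alt.astype(np.intp), si[m])
        return out

    def run(self, variants: pd.DataFrame, scheme: str,
            statistic: str | Callable = "n-recurrent",
            reps: int = 1000, seed=None,
            control_pool: Optional[pd.DataFrame] = None,
            real_interactions: Optional[Sequence[ChromatinInteraction]] = None,
            control_interactions: Optional[Sequence[ChromatinInteraction]] = None,
            promoters: Optional[Mapping[str, GenomicInterval]] = None,
            ) -> NullDistribution:
        """Observed statistic plus its ``reps``-replicate null distribution."""
        if reps < 1:
            raise ValueError("reps must be >= 1")
        if scheme not in ("insilico", "clinical", "epigenome"):
            raise ValueError(f"unknown scheme {scheme!r}")
        stat = STATISTICS[statistic] if isinstance(statistic, str) else statistic
        arrays = self.arrays_from_frame(variants)
        observed = np.asarray(stat(self.M_vector(arrays)))
        counts = self._counts(arrays)
        children = np.random.SeedSequence(seed).spawn(reps)

        if scheme == "clinical":
            if control_pool is None:
                raise ValueError("clinical scheme requires control_pool")
            total = int(counts.sum())
            if len(control_pool) < total:
                raise ValueError(
                    f"control pool ({len(control_pool)}) smaller than "
                    f"required draw ({total})")
            # pool positions are fixed: precompute motif-change flags once
            pool = control_pool.sort_values(["chrom", "pos"], kind="mergesort")
            pool_chrom = pool["chrom"].to_numpy()
            pool_pos = pool["pos"].to_numpy(np.int64)
            pool_alt = np.array([_BASE_CODE[a] for a in pool["alt"]], np.intp)
            si_template = np.repeat(np.arange(len(counts)), counts)
            chrom_order = {c: i for i, c in enumerate(self.chroms)}
            pool_ci = np.array([chrom_order[c] for c in pool_chrom])

        if scheme == "epigenome":
            if real_interactions is None or control_interactions is None or promoters is None:
                raise ValueError("epigenome scheme requires real_interactions, "
                                 "control_interactions and promoters")

        values = []
        for c in children:
            rng = np.random.default_rng(c)
            if scheme == "insilico":
                rep_arrays = self._random_arrays(counts, rng)
                values.append(np.asarray(stat(self.M_vector(rep_arrays))))
            elif scheme == "clinical":
                idx = rng.choice(len(pool_pos), size=len(si_template),
                                 replace=False)
                rep_arrays = {}
                for i, chrom in enumerate(self.chroms):
                    m = pool_ci[idx] == i
                    rep_arrays[chrom] = (pool_pos[idx[m]], pool_alt[idx[m]],
                                         si_template[m])
                values.append(np.asarray(stat(self.M_vector(rep_arrays))))
            else:  # epigenome
                ctrl_map = simulate_epigenome(real_interactions,
                                              control_interactions,
                                              promoters, rng)
                values.append(np.asarray(stat(self.M_vector(arrays, ctrl_map))))
        rep = np.stack(values)
        return NullDistribution(scheme, rep, observed,
                                empirical_pvalue(rep, observed), reps)
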