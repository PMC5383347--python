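"""Combinatorial cis-regulatory recurrence per gene.

The recurrence of a gene v, M(v), is the number of distinct tumor samples
carrying at least one motif-changing variant anywhere in v's cis-regulatory
map (promoter plus chromatin-linked enhancers).  Variants from different
samples scattered across different enhancers of the same gene all count:
four such samples give M = 4 even if no two variants share a site.

Genes are categorized by M: none (M <= 1), low (2 <= M <= 4), high (M >= 5);
a gene is called recurrent when M >= 2.
"""

from __future__ import annotations

from typing import Dict, Iterable, Mapping, Optional, Sequence, Set

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

LOW_THRESHOLD = 2
HIGH_THRESHOLD = 5


def categorize(M: int, low: int = LOW_THRESHOLD, high: int = HIGH_THRESHOLD) -> str:
    """Recurrence category for a sample co-occurrence count."""
    if M < 0:
        raise ValueError("M must be non-negative")
    if M >= high:
        return "high"
    if M >= low:
        return "low"
    return "none"


def is_recurrent(M: int, low: int = LOW_THRESHOLD) -> bool:
    return M >= low


def compute_recurrence(assignments: pd.DataFrame,
                       cohort: Sequence[str],
                       genes: Optional[Iterable[str]] = None,
                       low: int = LOW_THRESHOLD,
                       high: int = HIGH_THRESHOLD) -> pd.DataFrame:
    """Per-gene distinct-sample recurrence from variant-target assignments.

    Parameters
    ----------
    assignments : DataFrame with columns gene_id, sample
        Output of :func:`cisrec.interactome.map_variant_targets`.
    cohort : all sample identifiers of the cohort
    genes : gene universe; genes without assignments are reported with M=0.
        Defaults to the genes present in ``assignments``.

    Returns a DataFrame indexed by gene_id with columns M, samples
    (frozenset), category, recurrent — sorted by descending M with ties
    broken lexicographically by gene_id.
    """
    cohort_set = set(cohort)
    bad = set(assignments["sample"]) - cohort_set
    if bad:
        raise ValueError(f"samples in assignments absent from cohort: {sorted(bad)[:5]}")
    per_gene: Dict[str, Set[str]] = {}
    for g, sub in assignments.groupby("gene_id"):
        per_gene[g] = set(sub["sample"])
    universe = sorted(genes) if genes is not None else sorted(per_gene)
    rows = []
    for g in universe:
        samples = frozenset(per_gene.get(g, ()))
        M = len(samples)
        rows.append((g, M, samples, categorize(M, low, high), M >= low))
    df = pd.DataFrame(rows, columns=["gene_id", "M", "samples", "category",
                                     "recurrent"])
    df = df.sort_values(["M", "gene_id"], ascending=[False, True],
                        kind="mergesort").set_index("gene_id")
    return df


def recurrence_vector(assignments: pd.DataFrame, gene_ids: Sequence[str],
                      sample_index: Mapping[str, int]) -> np.ndarray:
    """Fast path: per-gene M as an int array aligned with ``gene_ids``.

    Used inside simulation nulls where building a full table per replicate
    would dominate the runtime.
    """
    gidx = {g: i for i, g in enumerate(gene_ids)}
    gi = assignments["gene_id"].map(gidx).to_numpy()
    si = assignments["sample"].map(sample_index).to_numpy()
    if len(gi) == 0:
        return np.zeros(len(gene_ids), dtype=np.int64)
    key = gi.astype(np.int64) * len(sample_index) + si
    uniq = np.unique(key)
    return np.bincount(uniq // len(sample_index), minlength=len(gene_ids))


def geneset_enrichment(query_genes: Iterable[str],
                       annotation_sets: Mapping[str, Iterable[str]],
                       universe: Iterable[str]) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query_genes`` in each set.

    The p-value is the upper tail P(X >= overlap) for drawing |query| genes
    from a universe of which |set| are annotated; the adjusted p is the
    Bonferroni correction over the number of sets tested.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query_genes)
    if not query <= universe:
        raise ValueError("query genes must be a subset of the universe")
    n_sets = len(annotation_sets)
    rows = []
    for name, members in annotation_sets.items():
        members = set(members) & universe
        k = len(query & members)
        p = float(hypergeom.sf(k - 1, len(universe), len(members), len(query)))
        rows.append((name, len(members), k, p, min(1.0, p * n_sets)))
    return pd.DataFrame(rows, columns=["set", "set_size", "overlap",
                                       "p_value", "p_adjusted"]
                        ).set_index("set")
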