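"""Mutual exclusivity of coding and cis-regulatory variants across samples.

For a coding-driver gene and an interacting transcriptional-driver gene,
variant complementarity measures how strongly the two genes' variant-
carrying sample sets avoid each other.  The implemented measure is the
normalized symmetric difference

    value(A, B) = |A xor B| / |A or B|

over the coding sample set A and the regulatory sample set B: 1 for perfect
mutual exclusivity (disjoint, nonempty sets), 0 for perfect co-occurrence
(identical sets).  Samples with neither variant cancel from numerator and
denominator and never influence the value.  The measure is pluggable so an
alternative exclusivity statistic can be dropped in.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Callable, Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

logger = logging.getLogger(__name__)

GROUPS = ("interacting-CD-TD", "all-CD-TD", "background")


def variant_complementarity(A: Iterable[str], B: Iterable[str]) -> float:
    """Symmetric-difference-over-union exclusivity of two sample sets."""
    A, B = set(A), set(B)
    union = A | B
    if not union:
        raise ValueError("A and B are both empty: complementarity undefined")
    return len(A ^ B) / len(union)


def _pair_records(pairs: Iterable[Tuple[str, str]], group: str,
                  coding_map: Mapping[str, Set[str]],
                  regulatory_map: Mapping[str, Set[str]],
                  measure: Callable) -> List[tuple]:
    rows = []
    for c, t in pairs:
        A = set(coding_map.get(c, ()))
        B = set(regulatory_map.get(t, ()))
        if not (A | B):
            logger.debug("pair (%s, %s) has no variant samples; skipped", c, t)
            continue
        rows.append((c, t, measure(A, B), group, len(A), len(B), len(A & B)))
    return rows


def group_comparison(coding_map: Mapping[str, Set[str]],
                     regulatory_map: Mapping[str, Set[str]],
                     ppi_network: nx.Graph,
                     cd_set: Iterable[str], td_set: Iterable[str],
                     measure: Callable = variant_complementarity,
                     max_background_pairs: Optional[int] = 20000,
                     seed=None):
    """Complementarity records in three comparison groups plus rank tests.

    * ``interacting-CD-TD`` — CD–TD pairs directly linked in the protein
      interaction network,
    * ``all-CD-TD`` — every CD x TD pair,
    * ``background`` — every gene pair with >= 1 coding and >= 1 regulatory
      variant (subsampled to ``max_background_pairs`` when larger).

    Returns ``(records, tests)``: a DataFrame of per-pair records and a
    DataFrame of two-sided rank-sum (Mann-Whitney) comparisons between the
    groups.
    """
    cd_set, td_set = sorted(set(cd_set)), sorted(set(td_set))
    all_pairs = [(c, t) for c in cd_set for t in td_set if c != t]
    interacting = [(c, t) for c, t in all_pairs
                   if ppi_network.has_edge(c, t)]
    coding_genes = sorted(g for g, s in coding_map.items() if s)
    reg_genes = sorted(g for g, s in regulatory_map.items() if s)
    background = [(c, t) for c in coding_genes for t in reg_genes if c != t]
    if max_background_pairs is not None and len(background) > max_background_pairs:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(background), size=max_background_pairs,
                         replace=False)
        background = [background[i] for i in sorted(idx)]
    rows = (_pair_records(interacting, "interacting-CD-TD", coding_map,
                          regulatory_map, measure)
            + _pair_records(all_pairs, "all-CD-TD", coding_map,
                            regulatory_map, measure)
            + _pair_records(background, "background", coding_map,
                            regulatory_map, measure))
    records = pd.DataFrame(rows, columns=["gene_coding", "gene_regulatory",
                                          "value", "group", "n_coding",
                                          "n_regulatory", "n_shared"])
    tests = []
    for g1, g2 in itertools.combinations(GROUPS, 2):
        x = records.loc[records["group"] == g1, "value"]
        y = records.loc[records["group"] == g2, "value"]
        if len(x) == 0 or len(y) == 0:
            logger.warning("group %s or %s empty; comparison skipped", g1, g2)
            continue
        stat, p = mannwhitneyu(x, y, alternative="two-sided")
        tests.append((g1, g2, float(x.median()), float(y.median()),
                      float(stat), float(p)))
    tests = pd.DataFrame(tests, columns=["group1", "group2", "median1",
                                         "median2", "U", "p_value"])
    return records, tests


def exclusivity_matrix(coding_gene: str,
                       regulatory_genes: Iterable[str],
                       coding_map: Mapping[str, Set[str]],
                       regulatory_map: Mapping[str, Set[str]],
                       cohort: Sequence[str],
                       k: int = 5,
                       measure: Callable = variant_complementarity
                       ) -> pd.DataFrame:
    """Sample-by-gene occurrence matrix for a coding gene and its top-k
    complementary regulatory partners.

    Rows: the coding gene first, then up to ``k`` regulatory genes ordered
    by descending complementarity with it.  Entries are ``none``, ``coding``,
    ``regulatory`` or ``both``; columns are the cohort samples.
    """
    A = set(coding_map.get(coding_gene, ()))
    scored = []
    for t in sorted(set(regulatory_genes)):
        if t == coding_gene:
            continue
        B = set(regulatory_map.get(t, ()))
        if not (A | B):
            continue
        scored.append((measure(A, B), t))
    scored.sort(key=lambda x: (-x[0], x[1]))
    chosen = [t for _, t in scored[:k]]
    genes = [coding_gene] + chosen

    def cell(g, s):
        has_c = s in coding_map.get(g, ())
        has_r = s in regulatory_map.get(g, ())
        if has_c and has_r:
            return "both"
        if has_c:
            return "coding"
        if has_r:
            return "regulatory"
        return "none"

    data = {s: [cell(g, s) for g in genes] for s in cohort}
    return pd.DataFrame(data, index=genes, columns=list(cohort))
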