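"""Coding-driver classification, CD–TD interaction enrichment, modular
recurrence scores and ROC evaluation.

Transcriptional drivers (TDs; genes recurrently hit by cis-regulatory
variants) tend to interact with coding drivers (CDs) in the protein
interactome.  This module quantifies that: the observed number of direct
CD–TD links is compared with expectations from node-label permutation or
degree-preserving link rewiring, and a gene's coding-driver status is
predicted from the cis-regulatory recurrence of its own network
neighborhood via three modular scores

* ``score_average(v) = M(v) + (sum_{u in L(v)} M(u)) / deg(v)``
* ``score_max(v)     = M(v) + max_{u in L(v)} M(u) * W(v, u)``
* ``score_sum(v)     = M(v) + sum_{u in L(v)} M(u) / deg(u)``

with L(v) the neighbors of v, deg the neighbor count and W normalized edge
weights (W = 1 when the network is unweighted).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .null_models import empirical_pvalue

logger = logging.getLogger(__name__)

TRUNCATING_CLASSES = frozenset({"nonsense", "frameshift", "splice"})
CONSEQUENCE_CLASSES = TRUNCATING_CLASSES | {"missense", "silent"}
MIN_VARIANTS_2020 = 7


# -- 20/20 rule --------------------------------------------------------------


def classify_2020(coding_variants: pd.DataFrame,
                  min_variants: int = MIN_VARIANTS_2020) -> pd.DataFrame:
    """Classify genes as oncogene / TSG / none by the 20/20 rule.

    A gene is an oncogene when more than 20% of its coding variants sit at
    recurrent positions (positions hit >= 2 times in that gene) and a tumor
    suppressor when more than 20% are truncating (nonsense, frameshift or
    splice); both thresholds are strict.  When both fractions exceed 20%,
    the larger wins and ties go to TSG.  Genes with fewer than
    ``min_variants`` variants are left unclassified.

    ``coding_variants`` columns: gene, sample, position, consequence.
    """
    bad = set(coding_variants["consequence"]) - CONSEQUENCE_CLASSES
    if bad:
        raise ValueError(f"unknown consequence classes: {sorted(bad)}")
    rows = []
    for gene, sub in coding_variants.groupby("gene"):
        n = len(sub)
        pos_counts = sub["position"].value_counts()
        recurrent = pos_counts[pos_counts >= 2].sum()
        f_rec = recurrent / n
        f_trunc = sub["consequence"].isin(TRUNCATING_CLASSES).sum() / n
        if n < min_variants:
            cls = "none"
        elif f_rec > 0.20 and (f_rec > f_trunc or f_trunc <= 0.20):
            cls = "oncogene"
        elif f_trunc > 0.20:
            cls = "TSG"
        else:
            cls = "none"
        rows.append((gene, n, f_rec, f_trunc, cls))
    df = pd.DataFrame(rows, columns=["gene", "n_variants", "recurrent_fraction",
                                     "truncating_fraction", "driver_class"])
    df["source"] = "rule2020"
    return df.set_index("gene").sort_index()


# -- CD-TD interaction enrichment -------------------------------------------


@dataclass
class EnrichmentResult:
    """Observed vs permutation-expected count of direct A–B links."""
    observed: int
    expected_values: np.ndarray
    ratio: float
    empirical_p: float
    mode: str
    reps: int


def _count_cross_edges(u: np.ndarray, v: np.ndarray,
                       in_a: np.ndarray, in_b: np.ndarray) -> int:
    # each qualifying edge counted once; genes in both sets count for both sides
    return int(np.sum((in_a[u] & in_b[v]) | (in_b[u] & in_a[v])))


def interaction_enrichment(network: nx.Graph, set_a: Iterable[str],
                           set_b: Iterable[str], mode: str = "link",
                           reps: int = 1000, seed=None,
                           n_swaps: Optional[int] = None) -> EnrichmentResult:
    """Enrichment of direct links between two gene sets in a network.

    ``mode='node'`` permutes node labels uniformly; ``mode='link'`` rewires
    edges with degree-preserving double-edge swaps (every node keeps its
    degree in every replicate).  Returns the observed count, the replicate
    expectations, the observed-to-mean-expected ratio and an add-one
    empirical p-value.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if mode not in ("node", "link"):
        raise ValueError("mode must be 'node' or 'link'")
    nodes = sorted(network.nodes)
    nidx = {g: i for i, g in enumerate(nodes)}
    set_a, set_b = set(set_a), set(set_b)
    if not (set_a & set(nodes)) or not (set_b & set(nodes)):
        raise ValueError("gene sets must intersect the network")
    in_a = np.zeros(len(nodes), bool)
    in_b = np.zeros(len(nodes), bool)
    in_a[[nidx[g] for g in set_a if g in nidx]] = True
    in_b[[nidx[g] for g in set_b if g in nidx]] = True
    edges = np.array([(nidx[x], nidx[y]) for x, y in network.edges],
                     dtype=np.intp)
    u, v = edges[:, 0], edges[:, 1]
    observed = _count_cross_edges(u, v, in_a, in_b)
    rng = np.random.default_rng(seed)

    if mode == "node":
        perms = np.argsort(rng.random((reps, len(nodes))), axis=1)
        pa, pb = in_a[perms], in_b[perms]  # (reps, n)
        au, av = pa[:, u], pa[:, v]
        bu, bv = pb[:, u], pb[:, v]
        expected = np.sum((au & bv) | (bu & av), axis=1)
    else:
        n = len(nodes)
        degrees = np.bincount(np.concatenate([u, v]), minlength=n)
        if n_swaps is None:
            n_swaps = max(1, 2 * len(u))
        expected = np.empty(reps, dtype=np.int64)
        for r in range(reps):
            ru, rv = rewire_degree_preserving(u, v, n, rng, n_swaps=n_swaps)
            if not np.array_equal(
                    np.bincount(np.concatenate([ru, rv]), minlength=n),
                    degrees):
                raise AssertionError("link permutation changed node degrees")
            expected[r] = _count_cross_edges(ru, rv, in_a, in_b)
    mean_exp = float(np.mean(expected))
    ratio = observed / mean_exp if mean_exp > 0 else np.inf
    return EnrichmentResult(observed, np.asarray(expected), ratio,
                            empirical_pvalue(expected, observed), mode, reps)


def rewire_degree_preserving(u: np.ndarray, v: np.ndarray, n_nodes: int,
                             rng: np.random.Generator,
                             n_swaps: Optional[int] = None
                             ) -> Tuple[np.ndarray, np.ndarray]:
    """Degree-preserving rewiring of a simple graph by double-edge swaps.

    Swap proposals are evaluated in vectorized batches: each round pairs up
    a random permutation of the edges, proposes one of the two swap
    orientations per pair, and applies every proposal that creates neither a
    self-loop nor a duplicate of an existing or simultaneously proposed
    edge.  The result is a uniform-degree-sequence null adequate for
    expected-count estimation; ``n_swaps`` is the number of attempted swaps
    (default twice the edge count).
    """
    u = np.asarray(u, np.int64).copy()
    v = np.asarray(v, np.int64).copy()
    m = len(u)
    if m < 2:
        return u, v
    if n_swaps is None:
        n_swaps = 2 * m
    half = m // 2
    rounds = max(1, -(-n_swaps // half))
    for _ in range(rounds):
        keys = np.sort(np.minimum(u, v) * n_nodes + np.maximum(u, v))
        perm = rng.permutation(m)
        i, j = perm[:half], perm[half:2 * half]
        a, b, c, d = u[i], v[i], u[j], v[j]
        flip = rng.random(half) < 0.5
        # option 1: (a,d),(c,b); option 2: (a,c),(d,b)
        n1u, n1v = a, np.where(flip, c, d)
        n2u, n2v = np.where(flip, d, c), b
        k1 = np.minimum(n1u, n1v) * n_nodes + np.maximum(n1u, n1v)
        k2 = np.minimum(n2u, n2v) * n_nodes + np.maximum(n2u, n2v)
        ok = (n1u != n1v) & (n2u != n2v) & (k1 != k2)
        ok &= keys[np.searchsorted(keys, k1).clip(0, m - 1)] != k1
        ok &= keys[np.searchsorted(keys, k2).clip(0, m - 1)] != k2
        # reject proposals whose new keys collide with another proposal
        cand = np.concatenate([k1[ok], k2[ok]])
        uniq, counts = np.unique(cand, return_counts=True)
        dup = set(uniq[counts > 1])
        if dup:
            ok &= ~(np.isin(k1, list(dup)) | np.isin(k2, list(dup)))
        u[i[ok]], v[i[ok]] = n1u[ok], n1v[ok]
        u[j[ok]], v[j[ok]] = n2u[ok], n2v[ok]
    return u, v


# -- modular recurrence scores ----------------------------------------------


def normalize_weights(network: nx.Graph) -> Dict[Tuple, float]:
    """Edge weights rescaled to [0, 1] by the network maximum; missing
    weights default to 1."""
    w = {tuple(sorted(e)): float(network.edges[e].get("weight", 1.0))
         for e in network.edges}
    if not w:
        return w
    m = max(w.values())
    if m <= 0:
        raise ValueError("non-positive edge weights")
    if m > 1:
        w = {e: x / m for e, x in w.items()}
    return w


def modular_scores(network: nx.Graph, M: Mapping[str, int],
                   use_weights: bool = False) -> pd.DataFrame:
    """The three modular recurrence scores for every network gene.

    Genes missing from ``M`` are treated as M = 0 (logged).  Isolated nodes
    have no neighborhood, so all three scores collapse to M(v).  By default
    the average and sum are unweighted; weights (edge attribute ``weight``,
    normalized to [0, 1]) always enter score_max and optionally the others.
    """
    missing = [g for g in network.nodes if g not in M]
    if missing:
        logger.info("%d network genes missing from M; treated as 0", len(missing))
    W = normalize_weights(network) if (use_weights or
                                       any("weight" in network.edges[e]
                                           for e in network.edges)) else {}

    def weight(v, u):
        return W.get(tuple(sorted((v, u))), 1.0)

    deg = dict(network.degree())
    rows = []
    for v in sorted(network.nodes):
        mv = M.get(v, 0)
        nbrs = list(network.neighbors(v))
        if not nbrs:
            avg = smax = ssum = float(mv)
        else:
            mu = np.array([M.get(u, 0) for u in nbrs], dtype=float)
            if use_weights:
                wv = np.array([weight(v, u) for u in nbrs])
                avg = mv + float(np.sum(mu * wv)) / deg[v]
                ssum = mv + float(np.sum(mu * wv / np.array([deg[u] for u in nbrs])))
            else:
                avg = mv + float(np.sum(mu)) / deg[v]
                ssum = mv + float(np.sum(mu / np.array([deg[u] for u in nbrs])))
            smax = mv + float(np.max(mu * np.array([weight(v, u) for u in nbrs])))
        rows.append((v, M.get(v, 0), avg, smax, ssum, deg[v]))
    return pd.DataFrame(rows, columns=["gene", "M", "score_average",
                                       "score_max", "score_sum",
                                       "neighborhood_size"]).set_index("gene")


# -- ROC evaluation ----------------------------------------------------------


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by the rank-sum (Mann–Whitney) identity with midranks for ties."""
    labels = np.asarray(labels, bool)
    n_pos, n_neg = labels.sum(), (~labels).sum()
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative gene")
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_curve(scores: np.ndarray, labels: np.ndarray):
    """(fpr, tpr, thresholds) by sweeping the score threshold downwards."""
    labels = np.asarray(labels, bool)
    order = np.argsort(-np.asarray(scores, float), kind="mergesort")
    s = np.asarray(scores, float)[order]
    y = labels[order]
    tps = np.cumsum(y)
    fps = np.cumsum(~y)
    # keep the last point of each tied-threshold block
    last = np.r_[s[1:] != s[:-1], True]
    tpr = np.r_[0.0, tps[last] / max(1, tps[-1])]
    fpr = np.r_[0.0, fps[last] / max(1, fps[-1])]
    thresholds = np.r_[np.inf, s[last]]
    return fpr, tpr, thresholds


def roc_evaluate(scores: Mapping[str, Mapping[str, float]],
                 positives: Set[str],
                 genes: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """AUC of one or more scorers against a positive gene set.

    ``scores`` maps scorer name -> {gene -> score}; genes defaults to the
    union of scored genes, with every non-positive gene a negative.
    """
    if genes is None:
        genes = sorted(set().union(*(set(s) for s in scores.values())))
    genes = list(genes)
    labels = np.array([g in positives for g in genes])
    rows = []
    for name, s in scores.items():
        vec = np.array([s.get(g, 0.0) for g in genes], dtype=float)
        rows.append((name, roc_auc(vec, labels)))
    return pd.DataFrame(rows, columns=["scorer", "auc"]).set_index("scorer")
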