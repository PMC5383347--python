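"""Gene scores in directed (causal) and undirected (association) networks.

The causal score of a gene v in an acyclic regulatory network combines its
relative outdegree, outdeg(v)/deg(v) with deg = indeg + outdeg, and its
relative position in a causal chain: the extremal (shortest or longest)
source-to-sink path through v.  The positional factor is the length of the
v-to-tail segment divided by the full chain length, so upstream regulators
score high and sinks score zero.  Scores are reported relative to the
network average (mean of relative scores is 1 by construction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Set

import networkx as nx
import numpy as np
import pandas as pd


def _extremal_depths(dag: nx.DiGraph, mode: str):
    """(din, dout): extremal path length in edges from any source to v and
    from v to any sink, computed by DP over a topological order."""
    pick = min if mode == "shortest" else max
    order = list(nx.topological_sort(dag))
    din = {}
    for v in order:
        preds = list(dag.predecessors(v))
        din[v] = 0 if not preds else pick(din[u] for u in preds) + 1
    dout = {}
    for v in reversed(order):
        succs = list(dag.successors(v))
        dout[v] = 0 if not succs else pick(dout[w] for w in succs) + 1
    return din, dout


def causal_scores(dag: nx.DiGraph, path_mode: str = "shortest"
                  ) -> Dict[str, float]:
    """Raw causal score for every node of an acyclic directed network.

    score(v) = (outdeg(v) / deg(v)) * (d(v -> tail) / chain length), where
    the chain is the extremal source-to-sink path through v per
    ``path_mode``.  Sinks and isolated nodes score 0; pure sources have
    relative outdegree 1.  Scores lie in [0, 1].
    """
    if path_mode not in ("shortest", "longest"):
        raise ValueError("path_mode must be 'shortest' or 'longest'")
    if not nx.is_directed_acyclic_graph(dag):
        raise ValueError("causal scoring requires an acyclic directed graph")
    din, dout = _extremal_depths(dag, path_mode)
    scores = {}
    for v in dag.nodes:
        deg = dag.in_degree(v) + dag.out_degree(v)
        chain = din[v] + dout[v]
        if deg == 0 or chain == 0 or dout[v] == 0:
            scores[v] = 0.0
        else:
            scores[v] = (dag.out_degree(v) / deg) * (dout[v] / chain)
    return scores


def causal_score(dag: nx.DiGraph, gene, path_mode: str = "shortest") -> float:
    """Raw causal score of a single gene (see :func:`causal_scores`)."""
    if gene not in dag:
        raise ValueError(f"gene {gene!r} not in network")
    return causal_scores(dag, path_mode)[gene]


@dataclass
class CausalScoreResult:
    """Raw and network-mean-normalized causal scores."""
    table: pd.DataFrame  # index gene_id, columns raw_score, relative_score

    @property
    def raw(self) -> pd.Series:
        return self.table["raw_score"]

    @property
    def relative(self) -> pd.Series:
        return self.table["relative_score"]


def relative_scores(raw_scores: Mapping[str, float]) -> CausalScoreResult:
    """Normalize raw scores by the mean over all network genes.

    The mean of the relative scores is exactly 1.  All-zero input has no
    defined normalization and raises.
    """
    s = pd.Series(raw_scores, dtype=float).sort_index()
    mean = s.mean()
    if not np.isfinite(mean) or mean == 0:
        raise ValueError("all-zero causal scores: normalization undefined")
    return CausalScoreResult(pd.DataFrame({
        "raw_score": s, "relative_score": s / mean}))


def relative_degree(network: nx.Graph,
                    gene_groups: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Per-group mean of (gene degree / network mean degree).

    Genes absent from the network are excluded and reported via the
    ``coverage`` column (fraction of the group present in the network).
    """
    if network.number_of_nodes() == 0:
        raise ValueError("empty network")
    degrees = dict(network.degree())
    mean_deg = np.mean(list(degrees.values()))
    rows = []
    for name, members in gene_groups.items():
        members = list(members)
        present = [g for g in members if g in degrees]
        ratios = [degrees[g] / mean_deg for g in present]
        rows.append((name,
                     float(np.mean(ratios)) if ratios else np.nan,
                     len(present),
                     len(present) / len(members) if members else 0.0))
    return pd.DataFrame(rows, columns=["group", "mean_relative_degree",
                                       "n_in_network", "coverage"]
                        ).set_index("group")
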