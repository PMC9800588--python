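"""Network hubness of DEGs in a directed signaling network.

Degree, betweenness, and PageRank centralities are computed on the curated
directed network, and each index is compared between the DEG nodes and the
remaining (background) nodes with a one-sided Wilcoxon rank-sum test, in
both directions: DEGs may sit above the background (hubs) or, as seen in
some tissues, significantly below it.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

log = logging.getLogger(__name__)

CENTRALITY_INDICES = ("degree", "betweenness", "pagerank")
#: exact rank-sum enumeration is used up to this pooled sample size
EXACT_LIMIT = 12


def read_edgelist(path) -> nx.DiGraph:
    """Read a 2- or 3-column TSV edge list into a directed graph.

    A third column (edge sign/annotation) is ignored here; self-loops are
    dropped and parallel edges collapse.
    """
    graph = nx.DiGraph()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[:2] == ["source", "target"]:
                continue  # optional header
            if len(fields) < 2:
                raise InputError(f"{path}:{lineno}: edge line needs source and target")
            source, target = fields[0], fields[1]
            if source != target:
                graph.add_edge(source, target)
    return graph


def compute_centralities(net: nx.DiGraph) -> pd.DataFrame:
    """Degree, betweenness and PageRank for every node.

    Degree is total (in + out) degree; betweenness uses unweighted shortest
    paths on the directed graph, normalised by (N-1)(N-2); PageRank uses
    damping 0.85 with uniform teleport and dangling-mass redistribution,
    iterated to a tight L1 tolerance.
    """
    if net.number_of_nodes() == 0:
        raise InputError("empty network")
    graph = net.copy()
    graph.remove_edges_from(nx.selfloop_edges(graph))
    degree = dict(graph.degree())
    betweenness = nx.betweenness_centrality(graph, normalized=True)
    n = graph.number_of_nodes()
    if n >= 3:
        pagerank = nx.pagerank(graph, alpha=0.85, tol=1e-12 / n, max_iter=1000)
    else:
        pagerank = {node: 1.0 / n for node in graph}
    table = pd.DataFrame(
        {
            "degree": pd.Series(degree, dtype=float),
            "betweenness": pd.Series(betweenness, dtype=float),
            "pagerank": pd.Series(pagerank, dtype=float),
        }
    )
    table.index.name = "node"
    return table.sort_index()


def hubness_test(deg_values, background_values, alternative: str = "greater") -> float:
    """One-sided Wilcoxon rank-sum p-value for DEG vs background centrality.

    Uses exact enumeration of the rank-sum distribution when the pooled
    sample is small (n + m <= 12) and tie-free, and otherwise the normal
    approximation with tie and continuity corrections.  A constant pooled
    sample carries no ordering information and returns p = 1 (logged as
    degenerate).
    """
    x = np.asarray(deg_values, dtype=float)
    y = np.asarray(background_values, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InputError("both samples must be non-empty")
    if alternative not in ("greater", "less"):
        raise InputError("alternative must be 'greater' or 'less'")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        log.warning("degenerate hubness test: constant pooled sample")
        return 1.0
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= EXACT_LIMIT and tie_free) else "asymptotic"
    result = stats.mannwhitneyu(x, y, alternative=alternative, method=method, use_continuity=True)
    return float(result.pvalue)


def hubness_report(
    centralities: pd.DataFrame,
    deg_ids: Iterable[str],
    indices: Sequence[str] = CENTRALITY_INDICES,
) -> pd.DataFrame:
    """Both one-sided hubness tests per centrality index for one DEG set.

    ``deg_ids`` not present in the network are logged and dropped; the
    background is every network node outside the DEG set.  Returns rows
    (index, alternative, n_deg, n_background, p); empty with a warning if
    no DEG maps onto the network or the background is empty.
    """
    nodes = set(centralities.index)
    degs = sorted(set(deg_ids))
    mapped = [g for g in degs if g in nodes]
    if len(mapped) < len(degs):
        log.info("%d of %d DEG ids not in the network; dropped", len(degs) - len(mapped), len(degs))
    columns = ["index", "alternative", "n_deg", "n_background", "p"]
    if not mapped:
        log.warning("no DEG maps onto the network; empty hubness report")
        return pd.DataFrame(columns=columns)
    background = sorted(nodes - set(mapped))
    if not background:
        log.warning("DEG set covers the whole network; no background to compare")
        return pd.DataFrame(columns=columns)
    rows = []
    for index in indices:
        x = centralities.loc[mapped, index].to_numpy()
        y = centralities.loc[background, index].to_numpy()
        for alternative in ("greater", "less"):
            rows.append(
                {
                    "index": index,
                    "alternative": alternative,
                    "n_deg": len(mapped),
                    "n_background": len(background),
                    "p": hubness_test(x, y, alternative=alternative),
                }
            )
    return pd.DataFrame(rows, columns=columns)
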