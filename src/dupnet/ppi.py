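"""Protein-protein interaction network distances.

Distances follow the node-count convention: the length of a shortest path
is the number of proteins on it, endpoints included, so directly
interacting proteins are at distance 2 and one intermediate gives 3.
(Shortest paths are found by breadth-first search, which computes exactly
this quantity on an unweighted graph.) Unreachable pairs are tallied
separately and excluded from percentage distributions and averages.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .errors import (InsufficientDataError, InsufficientPopulationError,
                     MissingGeneError, ParseError)
from .homology import HomologyNetwork
from .stats import Chi2Result, bin_correlation, pearson_chi2

__all__ = [
    "NO_PATH",
    "parse_ppi",
    "shortest_path_length",
    "sample_nonparalog_pairs",
    "DistanceDistribution",
    "distance_distribution",
    "compare_distributions",
    "avg_family_distance",
    "binned_k_vs_distance",
]

#: sentinel for a disconnected pair
NO_PATH = math.inf


def parse_ppi(path, format: str = "tsv2col") -> nx.Graph:
    """Read an interaction edge list into an undirected simple graph.

    ``tsv2col`` reads the first two tab-separated columns; ``psimitab``
    reads the two interactor-identifier columns of PSI-MITAB lines,
    stripping the ``db:`` prefix. Self-loops and duplicate edges are
    dropped.
    """
    if format not in ("tsv2col", "psimitab"):
        raise ValueError(f"unknown PPI format {format!r}")
    g = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise ParseError(path, lineno, "expected 2 interactor columns")
            a, b = fields[0], fields[1]
            if format == "psimitab":
                a = a.rsplit(":", 1)[-1]
                b = b.rsplit(":", 1)[-1]
            if a != b:
                g.add_edge(a, b)
    return g


def shortest_path_length(graph: nx.Graph, a: str, b: str) -> float:
    """Node-count shortest-path length between two distinct proteins.

    Returns 2 for a direct interaction, 3 for one intermediate, ...;
    :data:`NO_PATH` when the pair is disconnected.
    """
    if a == b:
        raise ValueError("distance is defined for distinct proteins only")
    for g in (a, b):
        if g not in graph:
            raise MissingGeneError(f"protein {g!r} not in interaction graph")
    try:
        hops = nx.shortest_path_length(graph, a, b)
    except nx.NetworkXNoPath:
        return NO_PATH
    return hops + 1


def sample_nonparalog_pairs(graph: nx.Graph,
                            paralog_pairs: Iterable[tuple[str, str]],
                            n: int, seed: int) -> list[tuple[str, str]]:
    """Draw n distinct unordered node pairs that are not paralog pairs.

    Uniform over all such pairs; deterministic under ``seed``. Raises
    :class:`InsufficientPopulationError` when fewer than n non-paralog
    pairs exist.
    """
    nodes = sorted(graph.nodes)
    if len(nodes) < 2:
        raise InsufficientPopulationError("graph has fewer than 2 nodes")
    forbidden = {tuple(sorted(p)) for p in paralog_pairs}
    total = len(nodes) * (len(nodes) - 1) // 2
    available = total - sum(1 for p in forbidden
                            if p[0] in graph and p[1] in graph and p[0] != p[1])
    if n > available:
        raise InsufficientPopulationError(
            f"requested {n} pairs but only {available} non-paralog pairs exist")
    rng = np.random.default_rng(seed)
    # dense request: enumerate; sparse request: rejection-sample
    if n > available // 2:
        pool = [p for p in itertools.combinations(nodes, 2) if p not in forbidden]
        idx = rng.choice(len(pool), size=n, replace=False)
        return [pool[i] for i in sorted(idx)]
    chosen: set[tuple[str, str]] = set()
    while len(chosen) < n:
        i, j = rng.integers(0, len(nodes), size=2)
        if i == j:
            continue
        pair = (nodes[min(i, j)], nodes[max(i, j)])
        if pair in forbidden or pair in chosen:
            continue
        chosen.add(pair)
    return sorted(chosen)


@dataclass
class DistanceDistribution:
    """Histogram of node-count distances over a pair set."""

    counts: dict[int, int] = field(default_factory=dict)
    unreachable: int = 0

    @property
    def n_reachable(self) -> int:
        return sum(self.counts.values())

    @property
    def n_pairs(self) -> int:
        return self.n_reachable + self.unreachable

    def percentages(self) -> dict[int, float]:
        """Percentage of *reachable* pairs at each distance (sums to 100)."""
        total = self.n_reachable
        if total == 0:
            return {}
        return {d: 100.0 * c / total for d, c in sorted(self.counts.items())}

    def mean(self) -> float | None:
        if self.n_reachable == 0:
            return None
        return sum(d * c for d, c in self.counts.items()) / self.n_reachable


def distance_distribution(graph: nx.Graph,
                          pairs: Sequence[tuple[str, str]]) -> DistanceDistribution:
    """Distance histogram over ``pairs``; disconnected pairs are tallied in
    ``unreachable`` and excluded from percentages."""
    dist = DistanceDistribution()
    for a, b in pairs:
        d = shortest_path_length(graph, a, b)
        if d is NO_PATH or math.isinf(d):
            dist.unreachable += 1
        else:
            d = int(d)
            dist.counts[d] = dist.counts.get(d, 0) + 1
    dist.counts = dict(sorted(dist.counts.items()))
    return dist


def _pooled_table(d1: DistanceDistribution, d2: DistanceDistribution,
                  min_expected: float = 5.0) -> list[list[int]]:
    """k x 2 count table over the union of distances, pooling tail rows so
    every expected count reaches ``min_expected``."""
    support = sorted(set(d1.counts) | set(d2.counts))
    rows = [[d1.counts.get(d, 0), d2.counts.get(d, 0)] for d in support]
    n1, n2 = d1.n_reachable, d2.n_reachable
    total = n1 + n2

    def ok(row):
        rt = row[0] + row[1]
        return min(rt * n1 / total, rt * n2 / total) >= min_expected

    pooled: list[list[int]] = []
    for row in rows:
        pooled.append(list(row))
    # pool from the tail (largest distances) upward
    while len(pooled) > 2 and not ok(pooled[-1]):
        last = pooled.pop()
        pooled[-1][0] += last[0]
        pooled[-1][1] += last[1]
    # pool from the head too, if the first bins are sparse
    while len(pooled) > 2 and not ok(pooled[0]):
        first = pooled.pop(0)
        pooled[0][0] += first[0]
        pooled[0][1] += first[1]
    return pooled


def compare_distributions(d1: DistanceDistribution, d2: DistanceDistribution,
                          boundary: float | None = None) -> Chi2Result:
    """Pearson chi-square comparison of two distance distributions.

    With ``boundary`` given (e.g. 3.5), counts are collapsed into
    (<= boundary, > boundary) and tested in a 2x2 table; otherwise a k x 2
    test over the union of observed distances, pooling sparse tail cells
    so expected counts reach 5.
    """
    if d1.n_reachable == 0 or d2.n_reachable == 0:
        raise InsufficientDataError("a distribution has no reachable pairs")
    if boundary is not None:
        table = []
        for d in (d1, d2):
            left = sum(c for dist, c in d.counts.items() if dist <= boundary)
            right = d.n_reachable - left
            table.append([left, right])
    else:
        table = _pooled_table(d1, d2)
        table = [list(r) for r in zip(*table)]  # orient as 2 rows x k cols
    return pearson_chi2(table)


def avg_family_distance(gene: str, network: HomologyNetwork,
                        graph: nx.Graph) -> float | None:
    """Mean pairwise network distance among a gene's duplicate family.

    The family is {gene} ∪ homology-neighbors(gene); only members present
    in the interaction graph and mutually reachable contribute. Returns
    None (no data) when fewer than one usable pair remains.
    """
    if gene not in network:
        raise MissingGeneError(f"gene {gene!r} not in homology network")
    members = sorted({gene} | set(network.neighbors(gene)))
    present = [m for m in members if m in graph]
    dists = []
    for a, b in itertools.combinations(present, 2):
        d = shortest_path_length(graph, a, b)
        if not math.isinf(d):
            dists.append(d)
    if not dists:
        return None
    return sum(dists) / len(dists)


def binned_k_vs_distance(genes: Sequence[str], network: HomologyNetwork,
                         graph: nx.Graph, bin_size: int = 1):
    """Average family distance binned by duplicability K.

    Genes are grouped by ``floor(K / bin_size)``; each bin reports the mean
    of :func:`avg_family_distance` over its genes (genes with no usable
    distance are skipped). Returns ``(bins, r, p)`` where bins is a list of
    ``(midpoint, mean_distance, n_genes)`` and (r, p) is the Pearson
    correlation between bin midpoints and bin means (None when undefined).
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    groups: dict[int, list[float]] = {}
    for gene in genes:
        k = network.K(gene)
        if k < 1:
            continue
        d = avg_family_distance(gene, network, graph)
        if d is None:
            continue
        groups.setdefault(k // bin_size, []).append(d)
    if len(groups) < 2:
        raise InsufficientDataError("need at least 2 non-empty K bins")
    bins = []
    for b in sorted(groups):
        mid = b * bin_size + (bin_size - 1) / 2.0
        vals = groups[b]
        bins.append((mid, sum(vals) / len(vals), len(vals)))
    corr = bin_correlation([b[0] for b in bins], [b[1] for b in bins])
    if corr is None:
        return bins, None, None
    return bins, corr[0], corr[1]
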