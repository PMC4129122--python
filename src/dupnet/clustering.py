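"""Homology-weighted clustering coefficient as a sequence-divergence metric.

For a gene i with duplicability K_i >= 2 in the weighted homology network,
the Barrat-form weighted clustering coefficient is

    C_i = 1 / (s_i (K_i - 1)) * sum_{(j,k)} (W_ij + W_ik)

where the sum runs over unordered pairs of neighbors of i that are
themselves adjacent, and the strength s_i = sum_j W_ij. C_i is the
probability that two immediate neighbors of i close a non-zero weighted
triangle with i, each closed triangle weighted by the strength of its two
edges at i. With all weights equal to 1 it reduces to
the unweighted clustering coefficient. Because weights are -log10 E-values
normalized per cluster, low C means the sequences around i have diverged.

An alternative geometric-mean (Onnela) form is available behind the
``scheme`` switch for auditability.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import networkx as nx

from .errors import InsufficientDataError
from .homology import HomologyNetwork
from .stats import bin_correlation

__all__ = [
    "ClusteringRecord",
    "weighted_clustering_coefficient",
    "clustering_records",
    "c_vs_k_analysis",
]


@dataclass(frozen=True)
class ClusteringRecord:
    gene: str
    k: int
    strength: float
    c: float


def weighted_clustering_coefficient(network: HomologyNetwork, gene: str,
                                    scheme: str = "barrat") -> float | None:
    """Weighted clustering coefficient of one gene; None when K < 2."""
    g = network.graph
    if gene not in g:
        raise KeyError(f"gene {gene!r} not in network")
    nbrs = sorted(g.neighbors(gene))
    k = len(nbrs)
    if k < 2:
        return None
    if scheme == "barrat":
        s = sum(g[gene][j]["weight"] for j in nbrs)
        acc = 0.0
        for j, l in itertools.combinations(nbrs, 2):
            if g.has_edge(j, l):
                acc += g[gene][j]["weight"] + g[gene][l]["weight"]
        return acc / (s * (k - 1))
    if scheme == "onnela":
        # geometric mean of the three (max-normalized) triangle weights
        wmax = max(d["weight"] for _, _, d in g.edges(data=True))
        acc = 0.0
        for j, l in itertools.combinations(nbrs, 2):
            if g.has_edge(j, l):
                acc += (g[gene][j]["weight"] * g[gene][l]["weight"]
                        * g[j][l]["weight"]) ** (1.0 / 3.0) / wmax
        return 2.0 * acc / (k * (k - 1))
    raise ValueError(f"unknown weighting scheme {scheme!r}")


def clustering_records(network: HomologyNetwork,
                       scheme: str = "barrat") -> list[ClusteringRecord]:
    """Per-gene (gene, K, strength, C) table over genes with K >= 2."""
    g = network.graph
    out = []
    for gene in sorted(g.nodes):
        c = weighted_clustering_coefficient(network, gene, scheme=scheme)
        if c is None:
            continue
        s = sum(g[gene][j]["weight"] for j in g.neighbors(gene))
        out.append(ClusteringRecord(gene=gene, k=g.degree(gene), strength=s, c=c))
    return out


def c_vs_k_analysis(network: HomologyNetwork, bin_size: int = 2,
                    scheme: str = "barrat"):
    """Binned log-log relationship between duplicability K and mean C.

    Genes (K >= 2) are grouped by ``floor(K / bin_size)``; each bin reports
    the mean C over its genes. The Pearson correlation is computed between
    log10(bin midpoint) and log10(mean C); bins whose mean C is 0 cannot
    enter a log-log plot and are excluded from the correlation (their
    count is reported).

    Returns ``(bins, r, p, n_zero_excluded)`` with bins as a list of
    ``(midpoint, mean_c, n_genes)``.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    records = clustering_records(network, scheme=scheme)
    groups: dict[int, list[float]] = {}
    for rec in records:
        groups.setdefault(rec.k // bin_size, []).append(rec.c)
    bins = []
    for b in sorted(groups):
        mid = b * bin_size + (bin_size - 1) / 2.0
        vals = groups[b]
        bins.append((mid, sum(vals) / len(vals), len(vals)))
    usable = [(m, c) for m, c, _ in bins if c > 0 and m > 0]
    n_zero = len(bins) - len(usable)
    if len(usable) < 2:
        raise InsufficientDataError("need at least 2 bins with positive mean C")
    corr = bin_correlation([math.log10(m) for m, _ in usable],
                           [math.log10(c) for _, c in usable])
    if corr is None:
        return bins, None, None, n_zero
    return bins, corr[0], corr[1], n_zero
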