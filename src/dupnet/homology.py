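"""Sequence-homology network construction.

All-against-all protein similarity hits (BLAST tabular dialect) are cast
into a weighted undirected network: nodes are genes, an edge joins two
genes whose pairwise E-value passes a stringent threshold (1e-30 by
default). The degree of a gene in this network is its duplicability K
(its BLAST hit count among distinct genes), connected components are the
duplicate "clusters", and edges carry a homology weight

    W = min(-log10 E, zero_cap) / max_neglog(cluster)

which is in (0, 1] and equals 1 for the strongest edge of each cluster.
E-values reported as exact zeros are capped at -log10 E = 300 before
weighting (300 exceeds any representable double exponent).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx

from .errors import ParseError

__all__ = [
    "HomologyHit",
    "HomologyNetwork",
    "parse_blast_tabular",
    "build_homology_network",
    "neglog10_evalue",
    "edge_weight",
    "pk_distribution",
    "write_network",
    "load_network",
    "DEFAULT_E_THRESHOLD",
    "ZERO_EVALUE_CAP",
]

DEFAULT_E_THRESHOLD = 1e-30
ZERO_EVALUE_CAP = 300.0


@dataclass(frozen=True)
class HomologyHit:
    """One similarity record: query gene, subject gene, E-value."""

    query: str
    subject: str
    evalue: float


def parse_blast_tabular(path) -> list[HomologyHit]:
    """Read BLAST tabular (outfmt 6) records.

    Only columns 1 (qseqid), 2 (sseqid) and 11 (evalue) are used; lines
    beginning with '#' are skipped. Malformed lines raise :class:`ParseError`
    naming the line number.
    """
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(path, lineno, f"expected >=12 columns, got {len(fields)}")
            try:
                evalue = float(fields[10])
            except ValueError:
                raise ParseError(path, lineno, f"non-numeric E-value {fields[10]!r}") from None
            if not math.isfinite(evalue) or evalue < 0:
                raise ParseError(path, lineno, f"E-value out of range: {fields[10]!r}")
            hits.append(HomologyHit(fields[0], fields[1], evalue))
    return hits


def neglog10_evalue(evalue: float, zero_cap: float = ZERO_EVALUE_CAP) -> float:
    """-log10 of an E-value, capped at ``zero_cap`` (handles exact zeros)."""
    if evalue <= 0:
        return zero_cap
    return min(-math.log10(evalue), zero_cap)


def edge_weight(evalue: float, cluster_max_neglog: float,
                zero_cap: float = ZERO_EVALUE_CAP) -> float:
    """Homology weight of a retained edge, normalized per cluster.

    ``cluster_max_neglog`` is the maximum capped -log10(E) over the edges of
    the edge's connected component, so the result lies in (0, 1] and the
    strongest edge of every cluster has weight exactly 1.
    """
    if cluster_max_neglog <= 0:
        raise ValueError("cluster_max_neglog must be positive")
    return neglog10_evalue(evalue, zero_cap) / cluster_max_neglog


class HomologyNetwork:
    """Thresholded weighted homology network.

    Wraps a :class:`networkx.Graph` whose edges carry ``evalue``, ``neglog``
    and ``weight`` attributes. Duplicability ``K`` is the node degree.
    """

    def __init__(self, graph: nx.Graph, e_threshold: float, zero_cap: float,
                 weight_scope: str):
        self.graph = graph
        self.e_threshold = e_threshold
        self.zero_cap = zero_cap
        self.weight_scope = weight_scope

    # -- basic views -------------------------------------------------
    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def K(self, gene: str) -> int:
        return self.graph.degree(gene)

    def degrees(self) -> dict[str, int]:
        return dict(self.graph.degree())

    def components(self) -> list[set]:
        return [set(c) for c in nx.connected_components(self.graph)]

    def component_id(self) -> dict[str, int]:
        """Gene -> component index (components sorted by smallest member)."""
        comps = sorted(nx.connected_components(self.graph), key=min)
        return {g: i for i, comp in enumerate(comps) for g in comp}

    def neighbors(self, gene: str):
        return self.graph.neighbors(gene)

    def duplicate_pairs(self) -> list[tuple[str, str]]:
        """All retained edges as sorted unordered pairs."""
        return [tuple(sorted(e)) for e in self.graph.edges]

    def __contains__(self, gene: str) -> bool:
        return gene in self.graph


def build_homology_network(hits: Iterable[HomologyHit],
                           e_threshold: float = DEFAULT_E_THRESHOLD,
                           inclusive: bool = True,
                           zero_cap: float = ZERO_EVALUE_CAP,
                           weight_scope: str = "component") -> HomologyNetwork:
    """Build the thresholded homology network from similarity hits.

    Self-hits are dropped; hits failing the E-value threshold are dropped
    (``inclusive=True`` retains E == threshold); reciprocal hits are merged
    into one undirected edge keeping the smaller E-value. Edge weights are
    normalized within each connected component (``weight_scope="component"``)
    or over the whole network (``"global"``).
    """
    g = nx.Graph()
    for hit in hits:
        if hit.query == hit.subject:
            continue
        keep = hit.evalue <= e_threshold if inclusive else hit.evalue < e_threshold
        if not keep:
            continue
        a, b = hit.query, hit.subject
        if g.has_edge(a, b):
            if hit.evalue < g[a][b]["evalue"]:
                g[a][b]["evalue"] = hit.evalue
        else:
            g.add_edge(a, b, evalue=hit.evalue)
    net = HomologyNetwork(g, e_threshold, zero_cap, weight_scope)
    _assign_weights(net)
    return net


def _assign_weights(net: HomologyNetwork) -> None:
    g = net.graph
    for a, b, data in g.edges(data=True):
        data["neglog"] = neglog10_evalue(data["evalue"], net.zero_cap)
    if net.weight_scope == "global":
        groups = [set(g.nodes)] if len(g) else []
    elif net.weight_scope == "component":
        groups = nx.connected_components(g)
    else:
        raise ValueError(f"unknown weight scope {net.weight_scope!r}")
    for comp in groups:
        sub = g.subgraph(comp)
        max_neglog = max(d["neglog"] for _, _, d in sub.edges(data=True))
        for a, b, data in sub.edges(data=True):
            data["weight"] = data["neglog"] / max_neglog


def pk_distribution(network: HomologyNetwork, normalize: bool = False) -> dict[int, float]:
    """Histogram of duplicability K over genes with K >= 1.

    With ``normalize=True`` values become percentages summing to 100.
    """
    counts: dict[int, float] = {}
    for _, k in network.graph.degree():
        if k >= 1:
            counts[k] = counts.get(k, 0) + 1
    if normalize and counts:
        total = sum(counts.values())
        counts = {k: 100.0 * v / total for k, v in counts.items()}
    return dict(sorted(counts.items()))


# -- TSV round-trip -------------------------------------------------

def write_network(network: HomologyNetwork, edges_path, genes_path) -> None:
    """Write the edge list (geneA, geneB, evalue, weight) and the per-gene
    table (gene, K, component id)."""
    with open(edges_path, "w") as fh:
        fh.write("geneA\tgeneB\tevalue\tweight\n")
        for a, b in sorted(tuple(sorted(e)) for e in network.graph.edges):
            d = network.graph[a][b]
            fh.write(f"{a}\t{b}\t{d['evalue']:.6e}\t{d['weight']:.6f}\n")
    comp = network.component_id()
    with open(genes_path, "w") as fh:
        fh.write("gene\tK\tcomponent\n")
        for g in sorted(network.graph.nodes):
            fh.write(f"{g}\t{network.graph.degree(g)}\t{comp[g]}\n")


def load_network(edges_path,
                 e_threshold: float = DEFAULT_E_THRESHOLD,
                 zero_cap: float = ZERO_EVALUE_CAP,
                 weight_scope: str = "component") -> HomologyNetwork:
    """Rebuild a network from the edge-list TSV written by :func:`write_network`.

    Weights are recomputed from the stored E-values so a reloaded network is
    identical to the one originally built.
    """
    hits = []
    with open(edges_path) as fh:
        header = fh.readline()
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ParseError(edges_path, lineno, "expected >=3 columns")
            hits.append(HomologyHit(fields[0], fields[1], float(fields[2])))
    return build_homology_network(hits, e_threshold=e_threshold, zero_cap=zero_cap,
                                  weight_scope=weight_scope)
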