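"""Genetic antagonism (GA) vs genetic complementation (GC) classification.

Duplicate gene pairs whose double knockout *rescues or alleviates* the
single-knockout defects are antagonizing (GA; SGD vocabulary "synthetic
rescue", "phenotypic suppression"); pairs whose double knockout is *more
severe* are complementing (GC; "synthetic lethality", "phenotypic
enhancement"). Only pairs that are also edges of the homology network
(i.e. actual duplicate pairs) are classified; a pair annotated on both
sides is flagged CONFLICT and excluded from downstream GA/GC analyses.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import InsufficientDataError, MissingGeneError, ParseError
from .homology import HomologyNetwork
from .powerlaw import normalize_distribution
from .stats import five_number_summary

__all__ = [
    "GA_TYPES",
    "GC_TYPES",
    "PairAnnotation",
    "parse_genetic_interactions",
    "classify_pair",
    "classify_duplicate_pairs",
    "cooccurrence_k_set",
    "group_k_distribution",
    "boxplot_summary",
]

GA_TYPES = frozenset({"synthetic rescue", "phenotypic suppression"})
GC_TYPES = frozenset({"synthetic lethality", "phenotypic enhancement"})


@dataclass(frozen=True)
class PairAnnotation:
    """A classified duplicate gene pair (unordered; gene_a < gene_b)."""

    gene_a: str
    gene_b: str
    pair_class: str  # GA | GC | UNCLASSIFIED | CONFLICT
    evalue: float

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


def parse_genetic_interactions(path) -> list[tuple[str, str, str]]:
    """Read a 3+ column TSV of (gene A, gene B, interaction type).

    The type string is preserved verbatim; matching against the GA/GC
    vocabularies is case-insensitive.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(path, lineno, f"expected >=3 columns, got {len(fields)}")
            records.append((fields[0], fields[1], fields[2]))
    return records


def classify_pair(types: Iterable[str]) -> str:
    """Map the set of annotation strings of one pair to its class."""
    folded = {t.strip().lower() for t in types}
    ga = bool(folded & GA_TYPES)
    gc = bool(folded & GC_TYPES)
    if ga and gc:
        return "CONFLICT"
    if ga:
        return "GA"
    if gc:
        return "GC"
    return "UNCLASSIFIED"


def classify_duplicate_pairs(records: Sequence[tuple[str, str, str]],
                             network: HomologyNetwork) -> list[PairAnnotation]:
    """Classify every annotated pair that is a homology-network edge.

    Interactions between non-duplicate genes (no retained homology edge)
    are ignored. Multiple annotations of the same pair are pooled before
    classification.
    """
    pooled: dict[tuple[str, str], set[str]] = defaultdict(set)
    for a, b, kind in records:
        if a == b:
            continue
        pair = tuple(sorted((a, b)))
        if network.graph.has_edge(*pair):
            pooled[pair].add(kind)
    out = []
    for pair in sorted(pooled):
        out.append(PairAnnotation(pair[0], pair[1],
                                  classify_pair(pooled[pair]),
                                  network.graph[pair[0]][pair[1]]["evalue"]))
    return out


def cooccurrence_k_set(pair: tuple[str, str], network: HomologyNetwork) -> list[int]:
    """K values of the genes whose hit lists enclose both members of ``pair``.

    A gene g (distinct from both members — there are no self-edges, so a
    member can never enclose itself) qualifies when both pair members are
    neighbors of g in the homology network.
    """
    a, b = pair
    for g in (a, b):
        if g not in network:
            raise MissingGeneError(f"gene {g!r} not in homology network")
    graph = network.graph
    ks = []
    for g in graph.neighbors(a):
        if g != b and graph.has_edge(g, b):
            ks.append(graph.degree(g))
    return sorted(ks)


def group_k_distribution(pairs: Sequence[PairAnnotation],
                         network: HomologyNetwork,
                         mode: str = "members") -> dict[int, float]:
    """P(K) distribution (percentages) of one group of duplicate pairs.

    ``members`` pools K over the distinct genes appearing in the group's
    pairs; ``cooccurrence`` pools :func:`cooccurrence_k_set` over the
    group's pairs (with multiplicity across pairs).
    """
    if not pairs:
        raise InsufficientDataError("empty pair group")
    ks: list[int] = []
    if mode == "members":
        genes = sorted({g for p in pairs for g in p.pair})
        ks = [network.K(g) for g in genes]
    elif mode == "cooccurrence":
        for p in pairs:
            ks.extend(cooccurrence_k_set(p.pair, network))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    counts: dict[int, float] = {}
    for k in ks:
        if k >= 1:
            counts[k] = counts.get(k, 0) + 1
    if not counts:
        raise InsufficientDataError("no genes with K >= 1 in group")
    return normalize_distribution(dict(sorted(counts.items())))


def boxplot_summary(values: Sequence[float]):
    """Five-number summary (min, Q1, median, Q3, max) of a K sample."""
    return five_number_summary(values)
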