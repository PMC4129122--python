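"""Seeded synthetic proteome generator.

Emulates the statistical structure of the real inputs (yeast/human style)
that the analysis consumes, so every downstream stage is testable without
any download:

* a proteome partitioned into duplicate families whose duplicate-count
  distribution follows a power law P(K) ∝ K^-alpha (within a family the
  homology relation is a complete graph, so K = family size - 1; family
  sizes are drawn with the size bias divided out so the *gene-level* K
  distribution carries the target exponent);
* pairwise E-values whose divergence (-log10 E decreasing) grows with
  family size;
* a connected protein-interaction graph in which paralog-pair distance
  grows with family size;
* genetic-interaction annotations whose antagonism (GA) fraction grows
  with pair divergence via a logistic link;
* a whole-genome-duplication (WGD) pair list drawn preferentially from
  the least-diverged pairs, each gene appearing at most once.

Every generator is deterministic under a fixed config seed; the four
stages draw from independent child streams of the same root seed so each
can also be called on its own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .errors import ConfigError
from .homology import HomologyHit

__all__ = [
    "SyntheticConfig",
    "SyntheticBundle",
    "generate_families",
    "generate_pair_evalues",
    "generate_homology_hits",
    "generate_ppi",
    "generate_genetic_annotations",
    "generate_wgd_list",
    "generate_bundle",
    "write_blast_tabular",
    "write_ppi_tsv",
    "write_genetic_tsv",
    "write_wgd_tsv",
]

# Fixed shape constants of the E-value model: the least-diverged pairs sit
# around -log10 E = 150 with spread 15, and -log10 E is floored at 30 so
# every within-family pair passes the 1e-30 retention threshold.
EVALUE_BASE_NEGLOG = 150.0
EVALUE_NEGLOG_SD = 15.0
EVALUE_NEGLOG_FLOOR = 30.0
EVALUE_NEGLOG_CAP = 300.0

#: edges attached by each new node during PPI growth (keeps the graph connected)
PPI_ATTACH_EDGES = 2
#: e-folding scale (in family-size units) of the paralog-attachment decay
PPI_FAMILY_DECAY_SCALE = 4.0

_STAGE_FAMILIES = 0
_STAGE_EVALUES = 1
_STAGE_PPI = 2
_STAGE_GENETIC = 3
_STAGE_WGD = 4


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic proteome.

    ``family_exponent`` is the target exponent of the gene-level power law
    P(K) ∝ K^-alpha. ``evalue_divergence_slope`` is the drop in mean
    -log10 E per extra family member; ``ppi_distance_slope`` controls how
    fast paralog placement in the interaction graph decouples as families
    grow (0 disables the coupling entirely); ``ga_logistic_slope`` is the
    logistic slope of the antagonism probability on standardized pair
    divergence; ``edge_dropout_slope`` makes large families lose a
    size-dependent fraction of their internal homology edges (0 keeps
    families complete).
    """

    n_genes: int = 3000
    family_exponent: float = 2.5
    max_family_size: int = 12
    evalue_divergence_slope: float = 6.0
    ppi_distance_slope: float = 1.2
    ga_logistic_slope: float = 3.0
    wgd_fraction: float = 0.12
    edge_dropout_slope: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_genes <= 0:
            raise ConfigError(f"n_genes must be positive, got {self.n_genes}")
        if self.family_exponent <= 1:
            raise ConfigError("family_exponent must be > 1")
        if self.max_family_size < 1:
            raise ConfigError("max_family_size must be >= 1")
        for name in ("evalue_divergence_slope", "ppi_distance_slope",
                     "edge_dropout_slope"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0 <= self.wgd_fraction <= 1:
            raise ConfigError("wgd_fraction must be in [0, 1]")


def _child_seed(seed: int, stage: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=seed, spawn_key=(stage,))


def _rng(config: SyntheticConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(_child_seed(config.seed, stage))


def _gene_ids(n: int) -> list[str]:
    width = len(str(n - 1)) if n > 1 else 1
    return [f"g{idx:0{width}d}" for idx in range(n)]


def generate_families(config: SyntheticConfig) -> list[list[str]]:
    """Partition the proteome into duplicate families.

    Family sizes s >= 2 are drawn by inverse CDF from the size-debiased law
    P(s) ∝ (s-1)^-alpha / s, truncated at ``max_family_size``, so that the
    gene-level duplicate count K = s - 1 follows K^-alpha. Leftover genes
    that cannot fill another family remain singletons.
    """
    genes = _gene_ids(config.n_genes)
    rng = _rng(config, _STAGE_FAMILIES)
    max_size = min(config.max_family_size, config.n_genes)
    families: list[list[str]] = []
    if max_size >= 2:
        sizes = np.arange(2, max_size + 1)
        probs = (sizes - 1.0) ** (-config.family_exponent) / sizes
        probs /= probs.sum()
        cdf = np.cumsum(probs)
        cursor = 0
        remaining = config.n_genes
        while remaining >= 2:
            u = rng.random()
            s = int(sizes[np.searchsorted(cdf, u)])
            s = min(s, remaining)
            families.append(genes[cursor:cursor + s])
            cursor += s
            remaining -= s
        for g in genes[cursor:]:
            families.append([g])
    else:
        families = [[g] for g in genes]
    return families


def _family_pairs(family: Sequence[str]) -> list[tuple[str, str]]:
    return [(family[i], family[j])
            for i in range(len(family)) for j in range(i + 1, len(family))]


def generate_pair_evalues(config: SyntheticConfig,
                          families: Sequence[Sequence[str]]) -> dict[tuple[str, str], float]:
    """E-values for every retained within-family pair.

    Mean -log10 E decreases linearly with family size at rate
    ``evalue_divergence_slope`` (floored at 30, so E <= 1e-30 always).
    With ``edge_dropout_slope > 0`` a pair in a family of size s is dropped
    with probability 1 - exp(-slope * (s - 2)); size-2 families are never
    broken, so every family contributes at least one duplicate pair.
    """
    if not families:
        raise ConfigError("family partition is empty")
    rng = _rng(config, _STAGE_EVALUES)
    evalues: dict[tuple[str, str], float] = {}
    for family in families:
        s = len(family)
        if s < 2:
            continue
        mu = EVALUE_BASE_NEGLOG - config.evalue_divergence_slope * (s - 2)
        p_drop = 1.0 - math.exp(-config.edge_dropout_slope * (s - 2))
        for a, b in _family_pairs(family):
            neglog = float(np.clip(rng.normal(mu, EVALUE_NEGLOG_SD),
                                   EVALUE_NEGLOG_FLOOR, EVALUE_NEGLOG_CAP))
            dropped = p_drop > 0 and rng.random() < p_drop
            if not dropped:
                evalues[(a, b)] = 10.0 ** (-neglog)
    return evalues


def generate_homology_hits(config: SyntheticConfig,
                           families: Sequence[Sequence[str]] | None = None
                           ) -> list[HomologyHit]:
    """All-against-all style hit records for the synthetic proteome.

    Every retained within-family pair emits two reciprocal records with the
    same E-value; there are no between-family hits.
    """
    if families is None:
        families = generate_families(config)
    evalues = generate_pair_evalues(config, families)
    hits: list[HomologyHit] = []
    for (a, b), e in evalues.items():
        hits.append(HomologyHit(a, b, e))
        hits.append(HomologyHit(b, a, e))
    return hits


def generate_ppi(config: SyntheticConfig,
                 families: Sequence[Sequence[str]]) -> nx.Graph:
    """Connected interaction graph with size-dependent paralog placement.

    The graph grows by random attachment (every new node links to
    ``PPI_ATTACH_EDGES`` existing nodes, guaranteeing one component). When a
    new node's family already has placed members, one of its links is
    redirected to a random placed family member with probability

        q(s) = (1 - exp(-ppi_distance_slope)) * exp(-ppi_distance_slope * (s-2) / 4)

    so with slope 0 paralogs are placed like any other node, while with a
    positive slope small families sit close together and large families
    drift toward the random background distance — expected within-family
    distance increases with family size.
    """
    if not families:
        raise ConfigError("family partition is empty")
    rng = _rng(config, _STAGE_PPI)
    genes = [g for fam in families for g in fam]
    fam_of = {g: i for i, fam in enumerate(families) for g in fam}
    fam_size = {i: len(fam) for i, fam in enumerate(families)}
    order = list(genes)
    rng.shuffle(order)

    slope = config.ppi_distance_slope
    q_base = 1.0 - math.exp(-slope)

    g = nx.Graph()
    g.add_node(order[0])
    placed_by_family: dict[int, list[str]] = {fam_of[order[0]]: [order[0]]}
    placed: list[str] = [order[0]]
    for node in order[1:]:
        n_links = min(PPI_ATTACH_EDGES, len(placed))
        targets: set[str] = set()
        fam = fam_of[node]
        kin = placed_by_family.get(fam, [])
        if kin and slope > 0:
            s = fam_size[fam]
            q = q_base * math.exp(-slope * (s - 2) / PPI_FAMILY_DECAY_SCALE)
            if rng.random() < q:
                targets.add(kin[int(rng.integers(len(kin)))])
        while len(targets) < n_links:
            targets.add(placed[int(rng.integers(len(placed)))])
        for t in targets:
            g.add_edge(node, t)
        placed.append(node)
        placed_by_family.setdefault(fam, []).append(node)
    return g


def _standardized_divergence(evalues: Mapping[tuple[str, str], float]) -> dict[tuple[str, str], float]:
    pairs = list(evalues)
    neglogs = np.array([-math.log10(evalues[p]) for p in pairs])
    sd = neglogs.std()
    if sd == 0:
        return {p: 0.0 for p in pairs}
    # higher divergence = weaker homology = smaller -log10 E
    z = (neglogs.mean() - neglogs) / sd
    return dict(zip(pairs, z.tolist()))


def generate_genetic_annotations(families: Sequence[Sequence[str]],
                                 evalues: Mapping[tuple[str, str], float],
                                 config: SyntheticConfig
                                 ) -> list[tuple[str, str, str]]:
    """Synthetic-knockout style annotations for every within-family pair.

    A pair is annotated "synthetic rescue" (the antagonism side) with
    probability expit(ga_logistic_slope * divergence), where divergence is
    the pair's standardized inverted -log10 E; otherwise "synthetic
    lethality" (the complementation side). Slope 0 degenerates to a fair
    coin.
    """
    if not families:
        return []
    rng = _rng(config, _STAGE_GENETIC)
    div = _standardized_divergence(evalues) if evalues else {}
    records = []
    for pair in evalues:
        z = div[pair]
        p_ga = 1.0 / (1.0 + math.exp(-config.ga_logistic_slope * z))
        kind = "synthetic rescue" if rng.random() < p_ga else "synthetic lethality"
        records.append((pair[0], pair[1], kind))
    return records


def generate_wgd_list(families: Sequence[Sequence[str]],
                      evalues: Mapping[tuple[str, str], float],
                      config: SyntheticConfig) -> list[tuple[str, str]]:
    """Whole-genome-duplication pair list.

    Selects ``wgd_fraction`` of the within-family pairs, preferring the
    least-diverged (smallest E-value) pairs, under the constraint that each
    gene appears at most once in the list (greedy matching in divergence
    order; with ``wgd_fraction=1`` this yields a maximal matching).
    """
    if config.wgd_fraction == 0 or not evalues:
        return []
    target = int(round(config.wgd_fraction * len(evalues)))
    if target == 0:
        return []
    by_strength = sorted(evalues, key=lambda p: (evalues[p], p))
    used: set[str] = set()
    chosen: list[tuple[str, str]] = []
    for a, b in by_strength:
        if a in used or b in used:
            continue
        chosen.append((a, b))
        used.update((a, b))
        if len(chosen) >= target:
            break
    return chosen


@dataclass
class SyntheticBundle:
    """Everything one synthetic study generates, ready for the pipeline."""

    config: SyntheticConfig
    families: list[list[str]]
    evalues: dict[tuple[str, str], float]
    hits: list[HomologyHit]
    ppi: nx.Graph
    genetic: list[tuple[str, str, str]]
    wgd: list[tuple[str, str]]


def generate_bundle(config: SyntheticConfig) -> SyntheticBundle:
    families = generate_families(config)
    evalues = generate_pair_evalues(config, families)
    hits = []
    for (a, b), e in evalues.items():
        hits.append(HomologyHit(a, b, e))
        hits.append(HomologyHit(b, a, e))
    return SyntheticBundle(
        config=config,
        families=families,
        evalues=evalues,
        hits=hits,
        ppi=generate_ppi(config, families),
        genetic=generate_genetic_annotations(families, evalues, config),
        wgd=generate_wgd_list(families, evalues, config),
    )


# -- writers (plain-text interchange formats) -----------------------

def write_blast_tabular(hits: Iterable[HomologyHit], path) -> None:
    """BLAST outfmt-6 style TSV; only qseqid/sseqid/evalue carry meaning,
    the remaining ten columns hold valid placeholders."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(f"{h.query}\t{h.subject}\t90.0\t100\t1\t0\t1\t100\t1\t100\t"
                     f"{h.evalue:.3e}\t200\n")


def write_ppi_tsv(graph: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{a}\t{b}\n")


def write_genetic_tsv(records: Iterable[tuple[str, str, str]], path) -> None:
    with open(path, "w") as fh:
        for a, b, kind in records:
            fh.write(f"{a}\t{b}\t{kind}\n")


def write_wgd_tsv(pairs: Iterable[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for a, b in pairs:
            fh.write(f"{a}\t{b}\n")
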