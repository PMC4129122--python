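"""Whole-genome-duplication (WGD) vs small-scale-duplication (SSD) analysis.

A duplicate pair is WGD when it appears in a synteny-derived ohnolog pair
list (Yeast Gene Order Browser style); every other duplicate pair is SSD.
Listed pairs that are not duplicate pairs (their E-value failed the
retention threshold) are dropped and counted. The module reproduces the
GC/GA contingency summary per class and the resampling null used to
locate a small focal group of pairs against random same-size groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats as sps

from .errors import InsufficientPopulationError, ParseError
from .ppi import distance_distribution
from .stats import empirical_p

__all__ = [
    "parse_wgd_list",
    "label_wgd_ssd",
    "ClassRow",
    "ContingencySummary",
    "contingency_row",
    "contingency_summary",
    "ResampleResult",
    "resample_group_null",
]


def parse_wgd_list(path) -> list[tuple[str, str]]:
    """Read a two-column TSV of WGD gene pairs."""
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(path, lineno, "expected 2 columns")
            pairs.append((fields[0], fields[1]))
    return pairs


def label_wgd_ssd(duplicate_pairs: Sequence[tuple[str, str]],
                  wgd_list: Sequence[tuple[str, str]]):
    """Label every duplicate pair WGD or SSD.

    Returns ``(labels, dropped)`` where labels maps each sorted duplicate
    pair to "WGD" or "SSD" and dropped lists the wgd_list entries that are
    not duplicate pairs (no retained homology edge).
    """
    dup = {tuple(sorted(p)) for p in duplicate_pairs}
    wgd = {tuple(sorted(p)) for p in wgd_list}
    dropped = sorted(wgd - dup)
    labels = {p: ("WGD" if p in wgd else "SSD") for p in sorted(dup)}
    return labels, dropped


@dataclass(frozen=True)
class ClassRow:
    """One row of the WGD/SSD contingency summary.

    Percentages and the GC/GA ratio are rounded to one decimal for
    display, matching how such tables are reported; the ratio is None
    when there are no GA pairs.
    """

    pair_count: int
    gc_count: int
    ga_count: int
    gc_pct: float
    ga_pct: float
    gc_ga_ratio: float | None


@dataclass(frozen=True)
class ContingencySummary:
    wgd: ClassRow
    ssd: ClassRow


def contingency_row(pair_count: int, gc_count: int, ga_count: int) -> ClassRow:
    if pair_count == 0:
        return ClassRow(0, gc_count, ga_count, 0.0, 0.0, None)
    gc_pct = round(100.0 * gc_count / pair_count, 1)
    ga_pct = round(100.0 * ga_count / pair_count, 1)
    ratio = round(gc_count / ga_count, 1) if ga_count > 0 else None
    return ClassRow(pair_count, gc_count, ga_count, gc_pct, ga_pct, ratio)


def contingency_summary(labels: Mapping[tuple[str, str], str],
                        pair_classes: Mapping[tuple[str, str], str]) -> ContingencySummary:
    """GC/GA counts, percentages and ratio per duplication class.

    ``labels`` maps duplicate pairs to WGD/SSD; ``pair_classes`` maps
    (a subset of) pairs to GA/GC/UNCLASSIFIED/CONFLICT.
    """
    rows = {}
    for cls in ("WGD", "SSD"):
        pairs = [p for p, lab in labels.items() if lab == cls]
        gc = sum(1 for p in pairs if pair_classes.get(tuple(sorted(p))) == "GC")
        ga = sum(1 for p in pairs if pair_classes.get(tuple(sorted(p))) == "GA")
        rows[cls] = contingency_row(len(pairs), gc, ga)
    return ContingencySummary(wgd=rows["WGD"], ssd=rows["SSD"])


@dataclass(frozen=True)
class ResampleResult:
    observed_mean: float
    null_means: tuple[float, ...]
    p_empirical: float   # add-one, one-sided (focal longer)
    p_normal: float      # upper tail of z-score against the null
    focal_unreachable: int


def resample_group_null(focal_pairs: Sequence[tuple[str, str]],
                        population: Sequence[tuple[str, str]],
                        graph: nx.Graph,
                        reps: int = 100,
                        seed: int = 0) -> ResampleResult:
    """Locate a focal group's mean pair distance against a resampling null.

    The null is built from ``reps`` random subsets of ``population``
    (without replacement within a subset, same size as the focal group);
    each subset's mean distance is computed over its reachable pairs. The
    one-sided question is whether the focal group's pairs are *longer*.
    """
    group_size = len(focal_pairs)
    if group_size == 0:
        raise InsufficientPopulationError("focal group is empty")
    if group_size > len(population):
        raise InsufficientPopulationError(
            f"group size {group_size} exceeds population {len(population)}")
    focal = distance_distribution(graph, focal_pairs)
    observed = focal.mean()
    if observed is None:
        raise InsufficientPopulationError("no reachable pair in the focal group")

    rng = np.random.default_rng(seed)
    population = sorted(tuple(sorted(p)) for p in population)
    null_means = []
    for _ in range(reps):
        idx = rng.choice(len(population), size=group_size, replace=False)
        sub = [population[i] for i in idx]
        m = distance_distribution(graph, sub).mean()
        if m is not None:
            null_means.append(m)
    null = np.asarray(null_means, dtype=float)
    p_emp = empirical_p(observed, null, direction="ge")
    sd = null.std(ddof=1) if null.size > 1 else 0.0
    if sd > 0:
        z = (observed - null.mean()) / sd
        p_norm = float(sps.norm.sf(z))
    else:
        p_norm = 1.0 if observed <= null.mean() else 0.0
    return ResampleResult(observed_mean=float(observed),
                          null_means=tuple(float(m) for m in null_means),
                          p_empirical=float(p_emp),
                          p_normal=p_norm,
                          focal_unreachable=focal.unreachable)
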