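"""End-to-end pipeline over the analysis stages.

Each stage reads and writes plain TSV files in the output directory, so a
stage can be re-run standalone on a previous stage's outputs with results
identical to the end-to-end run. ``run_pipeline`` sequences them:

    simulate (optional) -> build-network -> fit-powerlaw -> classify-pairs
        -> ppi-distance -> wgd-ssd -> clustering

and writes a JSON summary plus a log of every exclusion count. All
randomness (control-pair sampling, resampling null) is fanned out from the
single root seed, so identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import clustering as clu
from . import genetic as gen
from . import homology as hom
from . import powerlaw as pl
from . import ppi as ppim
from . import synthetic as syn
from . import wgd as wgdm
from .errors import ConfigError, InsufficientDataError

__all__ = ["PipelineConfig", "run_pipeline"]

# stage ids for seed fan-out (distinct from the generator's internal stages)
_SEED_CONTROL = 10
_SEED_RESAMPLE = 11


def _derived_seed(root_seed: int, stage: int) -> int:
    state = np.random.SeedSequence(entropy=root_seed, spawn_key=(stage,)).generate_state(1)
    return int(state[0] % (2**31))


@dataclass
class PipelineConfig:
    """Pipeline configuration: four input paths or a synthetic section."""

    blast: str | None = None
    ppi: str | None = None
    genetic: str | None = None
    wgd: str | None = None
    ppi_format: str = "tsv2col"
    synthetic: syn.SyntheticConfig | None = None
    e_threshold: float = hom.DEFAULT_E_THRESHOLD
    inclusive_threshold: bool = True
    boundary: float = 3.5
    bin_size_distance: int = 1
    bin_size_clustering: int = 2
    reps: int = 100
    group_size: int | None = None   # default: size of the GA-WGD focal group
    weight_scheme: str = "barrat"
    weight_scope: str = "component"
    seed: int = 0
    outdir: str = "dupnet_out"

    def validate_for_run(self) -> None:
        """A full run needs all four input paths or a synthetic section.

        Stage subcommands may run on partial configs (they read the previous
        stage's TSV outputs), so this is checked at run time, before any
        stage executes.
        """
        paths = (self.blast, self.ppi, self.genetic, self.wgd)
        if self.synthetic is None and not all(paths):
            raise ConfigError(
                "config needs either all four input paths (blast, ppi, genetic, wgd) "
                "or a synthetic section")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        synth = raw.pop("synthetic", None)
        raw.update(overrides)
        if synth is not None:
            seed = raw.get("seed", 0)
            synth.setdefault("seed", seed)
            raw["synthetic"] = syn.SyntheticConfig(**synth)
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class RunLog:
    """Counts of everything the analyses exclude, one line per event."""

    lines: list[str] = field(default_factory=list)

    def note(self, message: str) -> None:
        self.lines.append(message)

    def write(self, path) -> None:
        Path(path).write_text("".join(f"{ln}\n" for ln in self.lines))


# ------------------------------------------------------------------
# stages (file -> file)
# ------------------------------------------------------------------

def stage_simulate(config: PipelineConfig, outdir: Path) -> dict:
    bundle = syn.generate_bundle(config.synthetic)
    syn.write_blast_tabular(bundle.hits, outdir / "blast.tsv")
    syn.write_ppi_tsv(bundle.ppi, outdir / "ppi.tsv")
    syn.write_genetic_tsv(bundle.genetic, outdir / "genetic.tsv")
    syn.write_wgd_tsv(bundle.wgd, outdir / "wgd.tsv")
    return {
        "n_genes": config.synthetic.n_genes,
        "n_families": sum(1 for f in bundle.families if len(f) >= 2),
        "n_within_family_pairs": len(bundle.evalues),
        "n_ppi_edges": bundle.ppi.number_of_edges(),
        "n_wgd_pairs": len(bundle.wgd),
    }


def stage_network(blast_path, outdir: Path, config: PipelineConfig,
                  log: RunLog) -> dict:
    hits = hom.parse_blast_tabular(blast_path)
    net = hom.build_homology_network(
        hits, e_threshold=config.e_threshold, inclusive=config.inclusive_threshold,
        weight_scope=config.weight_scope)
    n_dropped = sum(1 for h in hits if h.query != h.subject and not (
        h.evalue <= config.e_threshold if config.inclusive_threshold
        else h.evalue < config.e_threshold))
    log.note(f"network: {n_dropped} hits above E-value threshold dropped")
    hom.write_network(net, outdir / "edges.tsv", outdir / "genes.tsv")
    return {
        "n_genes": net.graph.number_of_nodes(),
        "n_edges": net.graph.number_of_edges(),
        "n_components": len(net.components()),
    }


def _read_k_column(genes_path) -> list[int]:
    ks = []
    with open(genes_path) as fh:
        fh.readline()
        for line in fh:
            ks.append(int(line.split("\t")[1]))
    return ks


def stage_powerlaw(genes_path, outdir: Path) -> dict:
    ks = [k for k in _read_k_column(genes_path) if k >= 1]
    dist: dict[int, float] = {}
    for k in ks:
        dist[k] = dist.get(k, 0) + 1
    fit = pl.fit_power_law(dist)
    with open(outdir / "powerlaw.tsv", "w") as fh:
        fh.write("group\talpha\tintercept\tr_squared\tn_points\n")
        fh.write(f"all\t{fit.alpha:.6f}\t{fit.intercept:.6f}\t"
                 f"{fit.r_squared:.6f}\t{fit.n_points}\n")
    with open(outdir / "pk.tsv", "w") as fh:
        fh.write("K\tcount\n")
        for k, v in sorted(dist.items()):
            fh.write(f"{k}\t{int(v)}\n")
    return {"alpha": fit.alpha, "intercept": fit.intercept,
            "r_squared": fit.r_squared, "n_points": fit.n_points}


def stage_classify(edges_path, genetic_path, outdir: Path,
                   config: PipelineConfig, log: RunLog) -> dict:
    net = hom.load_network(edges_path, e_threshold=config.e_threshold,
                           weight_scope=config.weight_scope)
    records = gen.parse_genetic_interactions(genetic_path)
    pairs = gen.classify_duplicate_pairs(records, net)
    n_nondup = len({tuple(sorted((a, b))) for a, b, _ in records if a != b}) - len(pairs)
    log.note(f"classify: {n_nondup} annotated non-duplicate pairs ignored")
    n_conflict = sum(1 for p in pairs if p.pair_class == "CONFLICT")
    log.note(f"classify: {n_conflict} conflicting pairs excluded from GA/GC analyses")
    with open(outdir / "pairs.tsv", "w") as fh:
        fh.write("geneA\tgeneB\tclass\tevalue\n")
        for p in pairs:
            fh.write(f"{p.gene_a}\t{p.gene_b}\t{p.pair_class}\t{p.evalue:.6e}\n")

    summary: dict = {
        "n_pairs": len(pairs),
        "n_ga": sum(1 for p in pairs if p.pair_class == "GA"),
        "n_gc": sum(1 for p in pairs if p.pair_class == "GC"),
        "n_conflict": n_conflict,
        "n_unclassified": sum(1 for p in pairs if p.pair_class == "UNCLASSIFIED"),
    }
    fits_rows = []
    for cls in ("GA", "GC"):
        group = [p for p in pairs if p.pair_class == cls]
        if not group:
            continue
        member_ks = [net.K(g) for g in sorted({g for p in group for g in p.pair})]
        summary[f"{cls.lower()}_member_k_summary"] = gen.boxplot_summary(member_ks)
        for mode in ("members", "cooccurrence"):
            try:
                dist = gen.group_k_distribution(group, net, mode=mode)
                fit = pl.fit_power_law(dist)
            except InsufficientDataError:
                continue
            fits_rows.append((f"{cls}_{mode}", fit))
            summary[f"{cls.lower()}_{mode}_alpha"] = fit.alpha
            summary[f"{cls.lower()}_{mode}_r_squared"] = fit.r_squared
    with open(outdir / "genetic_fits.tsv", "w") as fh:
        fh.write("group\talpha\tintercept\tr_squared\tn_points\n")
        for name, fit in fits_rows:
            fh.write(f"{name}\t{fit.alpha:.6f}\t{fit.intercept:.6f}\t"
                     f"{fit.r_squared:.6f}\t{fit.n_points}\n")
    return summary


def _present_pairs(pairs, graph, log: RunLog, label: str):
    ok = [p for p in pairs if p[0] in graph and p[1] in graph]
    missing = len(pairs) - len(ok)
    if missing:
        log.note(f"{label}: {missing} pairs with a protein absent from the PPI graph skipped")
    return ok


def stage_ppi(edges_path, ppi_path, pairs_path, outdir: Path,
              config: PipelineConfig, log: RunLog) -> dict:
    net = hom.load_network(edges_path, e_threshold=config.e_threshold,
                           weight_scope=config.weight_scope)
    graph = ppim.parse_ppi(ppi_path, format=config.ppi_format)
    dup_pairs = net.duplicate_pairs()
    present = _present_pairs(dup_pairs, graph, log, "ppi-distance(paralog)")
    summary: dict = {}
    rows = []

    paralog_dist = ppim.distance_distribution(graph, present)
    log.note(f"ppi-distance: {paralog_dist.unreachable} unreachable paralog pairs "
             "excluded from percentages")
    control_pairs = ppim.sample_nonparalog_pairs(
        graph, dup_pairs, len(present), seed=_derived_seed(config.seed, _SEED_CONTROL))
    control_dist = ppim.distance_distribution(graph, control_pairs)
    log.note(f"ppi-distance: {control_dist.unreachable} unreachable control pairs "
             "excluded from percentages")
    rows.append(("paralog", paralog_dist))
    rows.append(("control", control_dist))
    chi_full = ppim.compare_distributions(paralog_dist, control_dist)
    chi_bound = ppim.compare_distributions(paralog_dist, control_dist,
                                           boundary=config.boundary)
    summary["paralog_mean_distance"] = paralog_dist.mean()
    summary["control_mean_distance"] = control_dist.mean()
    summary["paralog_vs_control_chi2"] = chi_full.statistic
    summary["paralog_vs_control_p"] = chi_full.p
    summary["paralog_vs_control_boundary_chi2"] = chi_bound.statistic
    summary["paralog_vs_control_boundary_p"] = chi_bound.p

    # GA vs GC distances
    classes: dict[tuple[str, str], str] = {}
    with open(pairs_path) as fh:
        fh.readline()
        for line in fh:
            a, b, cls, _ = line.rstrip("\n").split("\t")
            classes[(a, b)] = cls
    for cls in ("GA", "GC"):
        sel = [p for p, c in classes.items() if c == cls]
        sel = _present_pairs(sel, graph, log, f"ppi-distance({cls})")
        rows.append((cls, ppim.distance_distribution(graph, sel)))
    ga_dist = rows[2][1]
    gc_dist = rows[3][1]
    if ga_dist.n_reachable and gc_dist.n_reachable:
        chi_gagc = ppim.compare_distributions(ga_dist, gc_dist)
        summary["ga_mean_distance"] = ga_dist.mean()
        summary["gc_mean_distance"] = gc_dist.mean()
        summary["ga_vs_gc_chi2"] = chi_gagc.statistic
        summary["ga_vs_gc_p"] = chi_gagc.p

    with open(outdir / "distance_distributions.tsv", "w") as fh:
        fh.write("group\tdistance\tcount\tpercent\n")
        for name, dist in rows:
            pct = dist.percentages()
            for d, c in sorted(dist.counts.items()):
                fh.write(f"{name}\t{d}\t{c}\t{pct[d]:.4f}\n")
            fh.write(f"{name}\tunreachable\t{dist.unreachable}\t\n")

    # K vs average family distance
    genes = sorted(g for g in net.graph.nodes if net.K(g) >= 1)
    bins, r, p = ppim.binned_k_vs_distance(genes, net, graph,
                                           bin_size=config.bin_size_distance)
    with open(outdir / "distance_bins.tsv", "w") as fh:
        fh.write("k_bin_mid\tmean_distance\tn_genes\n")
        for mid, mean, n in bins:
            fh.write(f"{mid:.1f}\t{mean:.6f}\t{n}\n")
    summary["k_vs_distance_r"] = r
    summary["k_vs_distance_p"] = p
    return summary


def stage_wgd(edges_path, pairs_path, wgd_path, ppi_path, outdir: Path,
              config: PipelineConfig, log: RunLog) -> dict:
    net = hom.load_network(edges_path, e_threshold=config.e_threshold,
                           weight_scope=config.weight_scope)
    wgd_list = wgdm.parse_wgd_list(wgd_path)
    labels, dropped = wgdm.label_wgd_ssd(net.duplicate_pairs(), wgd_list)
    log.note(f"wgd-ssd: {len(dropped)} listed WGD pairs without a retained "
             "homology edge dropped")
    classes: dict[tuple[str, str], str] = {}
    with open(pairs_path) as fh:
        fh.readline()
        for line in fh:
            a, b, cls, _ = line.rstrip("\n").split("\t")
            classes[(a, b)] = cls
    table = wgdm.contingency_summary(labels, classes)
    with open(outdir / "wgd_table.tsv", "w") as fh:
        fh.write("class\tpair_count\tgc_count\tga_count\tgc_pct\tga_pct\tgc_ga_ratio\n")
        for name, row in (("WGD", table.wgd), ("SSD", table.ssd)):
            ratio = "NA" if row.gc_ga_ratio is None else f"{row.gc_ga_ratio}"
            fh.write(f"{name}\t{row.pair_count}\t{row.gc_count}\t{row.ga_count}\t"
                     f"{row.gc_pct}\t{row.ga_pct}\t{ratio}\n")
    summary: dict = {
        "wgd": {"pair_count": table.wgd.pair_count, "gc_count": table.wgd.gc_count,
                "ga_count": table.wgd.ga_count, "gc_pct": table.wgd.gc_pct,
                "ga_pct": table.wgd.ga_pct, "gc_ga_ratio": table.wgd.gc_ga_ratio},
        "ssd": {"pair_count": table.ssd.pair_count, "gc_count": table.ssd.gc_count,
                "ga_count": table.ssd.ga_count, "gc_pct": table.ssd.gc_pct,
                "ga_pct": table.ssd.ga_pct, "gc_ga_ratio": table.ssd.gc_ga_ratio},
    }

    graph = ppim.parse_ppi(ppi_path, format=config.ppi_format)
    wgd_pairs = sorted(p for p, lab in labels.items() if lab == "WGD")
    focal = [p for p in wgd_pairs if classes.get(p) == "GA"]
    focal = _present_pairs(focal, graph, log, "wgd-resample(focal)")
    population = _present_pairs(wgd_pairs, graph, log, "wgd-resample(population)")
    group_size = config.group_size or len(focal)
    if focal and group_size <= len(population):
        res = wgdm.resample_group_null(
            focal[:group_size] if config.group_size else focal,
            population, graph, reps=config.reps,
            seed=_derived_seed(config.seed, _SEED_RESAMPLE))
        null = np.asarray(res.null_means)
        with open(outdir / "wgd_resample.tsv", "w") as fh:
            fh.write("observed_mean\tnull_mean\tnull_sd\tp_empirical\tp_normal\treps\n")
            fh.write(f"{res.observed_mean:.6f}\t{null.mean():.6f}\t"
                     f"{null.std(ddof=1):.6f}\t{res.p_empirical:.6f}\t"
                     f"{res.p_normal:.6g}\t{len(null)}\n")
        summary["resample"] = {
            "observed_mean": res.observed_mean,
            "null_mean": float(null.mean()),
            "null_sd": float(null.std(ddof=1)),
            "p_empirical": res.p_empirical,
            "p_normal": res.p_normal,
            "group_size": len(focal) if not config.group_size else group_size,
        }
    else:
        log.note("wgd-ssd: resampling skipped (no usable GA-WGD focal group)")
        summary["resample"] = None

    # focal-vs-background K curves restricted to the focal K values
    focal_genes = sorted({g for p in focal for g in p})
    if focal_genes:
        focal_ks = [net.K(g) for g in focal_genes]
        focal_dist: dict[int, float] = {}
        for k in focal_ks:
            if k >= 1:
                focal_dist[k] = focal_dist.get(k, 0) + 1
        bg_genes = sorted({g for p in wgd_pairs for g in p})
        bg_dist: dict[int, float] = {}
        for g in bg_genes:
            k = net.K(g)
            if k >= 1:
                bg_dist[k] = bg_dist.get(k, 0) + 1
        try:
            bg_restricted = pl.restrict_to_k_values(bg_dist, set(focal_dist))
            focal_fit = pl.fit_power_law(focal_dist)
            bg_fit = pl.fit_power_law(bg_restricted)
            shifted = pl.overlay_shift(focal_dist, bg_restricted)
            summary["focal_alpha"] = focal_fit.alpha
            summary["background_alpha"] = bg_fit.alpha
            with open(outdir / "wgd_k_curves.tsv", "w") as fh:
                fh.write("group\tK\tvalue\n")
                for k, v in sorted(bg_restricted.items()):
                    fh.write(f"background\t{k}\t{v:.6f}\n")
                for k, v in sorted(shifted.items()):
                    fh.write(f"focal_shifted\t{k}\t{v:.6f}\n")
        except InsufficientDataError as exc:
            log.note(f"wgd-ssd: K-curve comparison skipped ({exc})")
    return summary


def stage_clustering(edges_path, outdir: Path, config: PipelineConfig,
                     log: RunLog) -> dict:
    net = hom.load_network(edges_path, e_threshold=config.e_threshold,
                           weight_scope=config.weight_scope)
    records = clu.clustering_records(net, scheme=config.weight_scheme)
    with open(outdir / "clustering.tsv", "w") as fh:
        fh.write("gene\tK\ts\tC\n")
        for rec in records:
            fh.write(f"{rec.gene}\t{rec.k}\t{rec.strength:.6f}\t{rec.c:.6f}\n")
    bins, r, p, n_zero = clu.c_vs_k_analysis(net, bin_size=config.bin_size_clustering,
                                             scheme=config.weight_scheme)
    log.note(f"clustering: {n_zero} zero-C bins excluded from the log-log correlation")
    with open(outdir / "clustering_bins.tsv", "w") as fh:
        fh.write("k_bin_mid\tmean_C\tn_genes\n")
        for mid, mean, n in bins:
            fh.write(f"{mid:.1f}\t{mean:.6f}\t{n}\n")
    return {"n_genes_with_c": len(records), "log_c_vs_log_k_r": r,
            "log_c_vs_log_k_p": p, "n_zero_c_bins": n_zero}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the JSON-ready summary dict."""
    config.validate_for_run()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = RunLog()
    summary: dict = {"seed": config.seed}

    if config.synthetic is not None:
        summary["simulate"] = stage_simulate(config, outdir)
        blast, ppi_path = outdir / "blast.tsv", outdir / "ppi.tsv"
        genetic_path, wgd_path = outdir / "genetic.tsv", outdir / "wgd.tsv"
    else:
        blast, ppi_path = config.blast, config.ppi
        genetic_path, wgd_path = config.genetic, config.wgd

    summary["network"] = stage_network(blast, outdir, config, log)
    summary["powerlaw"] = stage_powerlaw(outdir / "genes.tsv", outdir)
    summary["genetic"] = stage_classify(outdir / "edges.tsv", genetic_path,
                                        outdir, config, log)
    summary["ppi"] = stage_ppi(outdir / "edges.tsv", ppi_path,
                               outdir / "pairs.tsv", outdir, config, log)
    summary["wgd"] = stage_wgd(outdir / "edges.tsv", outdir / "pairs.tsv",
                               wgd_path, ppi_path, outdir, config, log)
    summary["clustering"] = stage_clustering(outdir / "edges.tsv", outdir, config, log)

    log.write(outdir / "run_log.txt")
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
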