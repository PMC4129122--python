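import numpy as np
import pytest
from scipy import stats as sps

from dupnet.errors import ConfigError
from dupnet.homology import build_homology_network
from dupnet.ppi import distance_distribution, sample_nonparalog_pairs
from dupnet.synthetic import (SyntheticConfig, generate_bundle,
                              generate_families, generate_genetic_annotations,
                              generate_homology_hits, generate_pair_evalues,
                              generate_ppi, generate_wgd_list)

import networkx as nx


def small_config(**kw):
    defaults = dict(n_genes=400, seed=11)
    defaults.update(kw)
    return SyntheticConfig(**defaults)


class TestConfig:
    def test_invalid_values_rejected(self):
        with pytest.raises(ConfigError):
            SyntheticConfig(n_genes=0)
        with pytest.raises(ConfigError):
            SyntheticConfig(family_exponent=1.0)
        with pytest.raises(ConfigError):
            SyntheticConfig(wgd_fraction=1.5)


class TestHomologyHits:
    def test_single_family_of_three_gives_six_records(self):
        cfg = SyntheticConfig(n_genes=3, max_family_size=3, seed=0)
        fams = [["g0", "g1", "g2"]]
        hits = generate_homology_hits(cfg, families=fams)
        assert len(hits) == 6
        pairs = {tuple(sorted((h.query, h.subject))) for h in hits}
        assert len(pairs) == 3

    def test_reciprocal_hits_share_evalue(self):
        hits = generate_homology_hits(small_config())
        by_pair = {}
        for h in hits:
            by_pair.setdefault(tuple(sorted((h.query, h.subject))), set()).add(h.evalue)
        assert all(len(v) == 1 for v in by_pair.values())

    def test_determinism(self):
        cfg = small_config()
        assert generate_homology_hits(cfg) == generate_homology_hits(cfg)

    def test_evalues_within_retention_threshold(self):
        hits = generate_homology_hits(small_config(evalue_divergence_slope=50))
        assert all(0 < h.evalue <= 1e-30 for h in hits)

    def test_gene_ids_unique(self):
        fams = generate_families(small_config())
        genes = [g for f in fams for g in f]
        assert len(genes) == len(set(genes)) == 400

    def test_complete_families_give_k_equals_size_minus_one(self):
        cfg = small_config()
        fams = generate_families(cfg)
        net = build_homology_network(generate_homology_hits(cfg, families=fams))
        for fam in fams:
            if len(fam) >= 2:
                for g in fam:
                    assert net.K(g) == len(fam) - 1

    def test_divergence_slope_weakly_decreases_mean_neglog(self):
        fams = [list(map(str, range(i * 8, i * 8 + 8))) for i in range(6)]
        flat = generate_pair_evalues(small_config(evalue_divergence_slope=0.0,
                                                  n_genes=48), fams)
        steep = generate_pair_evalues(small_config(evalue_divergence_slope=12.0,
                                                   n_genes=48), fams)
        mean_neglog = lambda ev: np.mean([-np.log10(e) for e in ev.values()])
        assert mean_neglog(steep) < mean_neglog(flat)


class TestPpi:
    def test_connected_single_component(self):
        cfg = small_config()
        g = generate_ppi(cfg, generate_families(cfg))
        assert nx.is_connected(g)
        assert g.number_of_nodes() == 400

    def test_empty_families_rejected(self):
        with pytest.raises(ConfigError):
            generate_ppi(small_config(), [])

    def test_no_coupling_matches_random_pairs(self):
        """With ppi_distance_slope=0 paralog placement is unbiased, so paralog
        distances should not differ from random non-paralog pairs."""
        diffs = []
        for seed in range(10):
            cfg = small_config(seed=seed, ppi_distance_slope=0.0)
            fams = generate_families(cfg)
            g = generate_ppi(cfg, fams)
            pairs = [(f[i], f[j]) for f in fams if len(f) >= 2
                     for i in range(len(f)) for j in range(i + 1, len(f))]
            para = distance_distribution(g, pairs).mean()
            ctrl_pairs = sample_nonparalog_pairs(g, pairs, len(pairs), seed=seed)
            ctrl = distance_distribution(g, ctrl_pairs).mean()
            diffs.append(para - ctrl)
        t = sps.ttest_1samp(diffs, 0.0)
        assert t.pvalue > 0.05

    def test_positive_coupling_correlates_size_with_distance(self):
        cfg = small_config(n_genes=1500, ppi_distance_slope=1.2, seed=4)
        fams = generate_families(cfg)
        g = generate_ppi(cfg, fams)
        sizes, means = [], []
        for fam in fams:
            if len(fam) < 2:
                continue
            pairs = [(fam[i], fam[j]) for i in range(len(fam))
                     for j in range(i + 1, len(fam))]
            m = distance_distribution(g, pairs).mean()
            if m is not None:
                sizes.append(len(fam))
                means.append(m)
        r = sps.pearsonr(sizes, means)[0]
        assert r > 0


class TestGeneticAnnotations:
    def test_degenerate_logistic_gives_half_ga(self):
        cfg = small_config(n_genes=2000, ga_logistic_slope=0.0)
        fams = generate_families(cfg)
        ev = generate_pair_evalues(cfg, fams)
        recs = generate_genetic_annotations(fams, ev, cfg)
        ga = sum(1 for *_, t in recs if t == "synthetic rescue")
        frac = ga / len(recs)
        # 3-sigma binomial band around 0.5
        tol = 3 * 0.5 / len(recs) ** 0.5
        assert abs(frac - 0.5) < tol

    def test_extreme_slope_orders_divergence_deciles(self):
        cfg = small_config(n_genes=2000, ga_logistic_slope=25.0,
                           evalue_divergence_slope=6.0)
        fams = generate_families(cfg)
        ev = generate_pair_evalues(cfg, fams)
        recs = generate_genetic_annotations(fams, ev, cfg)
        kinds = {(a, b): t for a, b, t in recs}
        ranked = sorted(ev, key=ev.get)  # ascending E = least diverged first
        n10 = len(ranked) // 10
        low_div = ranked[:n10]
        high_div = ranked[-n10:]
        frac = lambda pairs: np.mean([kinds[p] == "synthetic rescue" for p in pairs])
        assert frac(high_div) > frac(low_div)

    def test_empty_families_empty_annotations(self):
        assert generate_genetic_annotations([], {}, small_config()) == []

    def test_vocabulary_matches_classifier(self):
        from dupnet.genetic import GA_TYPES, GC_TYPES
        cfg = small_config()
        fams = generate_families(cfg)
        ev = generate_pair_evalues(cfg, fams)
        kinds = {t for *_, t in generate_genetic_annotations(fams, ev, cfg)}
        assert kinds <= (GA_TYPES | GC_TYPES)


class TestWgdList:
    def test_zero_fraction_empty(self):
        cfg = small_config(wgd_fraction=0.0)
        fams = generate_families(cfg)
        assert generate_wgd_list(fams, generate_pair_evalues(cfg, fams), cfg) == []

    def test_each_gene_appears_at_most_once(self):
        cfg = small_config(wgd_fraction=0.5)
        fams = generate_families(cfg)
        wgd = generate_wgd_list(fams, generate_pair_evalues(cfg, fams), cfg)
        genes = [g for p in wgd for g in p]
        assert len(genes) == len(set(genes))

    def test_full_fraction_is_maximal_matching(self):
        cfg = small_config(wgd_fraction=1.0)
        fams = generate_families(cfg)
        ev = generate_pair_evalues(cfg, fams)
        wgd = set(generate_wgd_list(fams, ev, cfg))
        used = {g for p in wgd for g in p}
        # maximality: no remaining pair has both genes unused
        for a, b in ev:
            assert a in used or b in used

    def test_prefers_least_diverged(self):
        cfg = small_config(wgd_fraction=0.2)
        fams = generate_families(cfg)
        ev = generate_pair_evalues(cfg, fams)
        wgd = generate_wgd_list(fams, ev, cfg)
        chosen = np.median([-np.log10(ev[p]) for p in wgd])
        rest = np.median([-np.log10(e) for p, e in ev.items() if p not in set(wgd)])
        assert chosen > rest


def test_bundle_determinism():
    cfg = small_config(edge_dropout_slope=0.05)
    b1, b2 = generate_bundle(cfg), generate_bundle(cfg)
    assert b1.hits == b2.hits
    assert b1.evalues == b2.evalues
    assert sorted(b1.ppi.edges) == sorted(b2.ppi.edges)
    assert b1.genetic == b2.genetic
    assert b1.wgd == b2.wgd
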