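"""The synthetic-data generator: determinism, planted fractions, tag shifts."""

import numpy as np
import pytest

from cistromekit.motifs import match_iupac, PRE_FULL_CONSENSUS
from cistromekit.regions import intersect
from cistromekit.simulate import (
    CELL_LINES,
    SimConfig,
    plant_binding_sites,
    sample_link_distances,
    simulate_expression,
    simulate_genome,
    simulate_tags,
    simulate_study,
)


def se3(p, n):
    return 3 * np.sqrt(p * (1 - p) / n)


class TestConfig:
    def test_probability_validation(self):
        with pytest.raises(ValueError):
            SimConfig(pre_plant_prob=1.5)

    def test_fragment_range_validation(self):
        with pytest.raises(ValueError):
            SimConfig(fragment_length_range=(10, 400))


class TestGenome:
    def test_deterministic_under_seed(self):
        cfg = SimConfig(seed=5, n_chroms=2, chrom_length=50_000, n_genes=20)
        g1, genes1 = simulate_genome(cfg)
        g2, genes2 = simulate_genome(cfg)
        assert g1.sequences == g2.sequences
        assert genes1 == genes2

    def test_no_genes(self):
        cfg = SimConfig(seed=1, n_chroms=1, chrom_length=50_000, n_genes=0)
        _, genes = simulate_genome(cfg)
        assert genes == []

    def test_uniform_base_frequencies(self):
        cfg = SimConfig(seed=2, n_chroms=1, chrom_length=10_000, n_genes=0)
        genome, _ = simulate_genome(cfg)
        seq = genome.sequences["chr1"]
        for base in "ACGT":
            freq = seq.count(base) / len(seq)
            assert abs(freq - 0.25) <= se3(0.25, len(seq))


class TestSitePlanting:
    def test_shared_fraction_one_gives_identical_sets(self):
        cfg = SimConfig(seed=3, n_chroms=2, chrom_length=500_000, n_genes=0,
                        n_sites=20, shared_site_fraction=1.0,
                        frac_regulated_genes=0.0, with_sequence=False)
        genome, genes = simulate_genome(cfg)
        truth = plant_binding_sites(genome, genes, cfg)
        coords = [
            sorted((s.interval.chrom, s.interval.start)
                   for s in truth.sites_for(ln))
            for ln in CELL_LINES
        ]
        assert coords[0] == coords[1] and len(coords[0]) == 20

    def test_pre_prob_zero_plants_nothing(self):
        cfg = SimConfig(seed=4, pre_plant_prob=0.0,
                        cofactor_plant_probs={ln: {"FOXA1": 0, "NF1": 0, "AP1": 0}
                                              for ln in CELL_LINES})
        genome, genes = simulate_genome(cfg)
        truth = plant_binding_sites(genome, genes, cfg)
        assert all(not s.motifs for s in truth.sites)
        # and no consensus word at any planted site centre
        for s in truth.sites[:20]:
            seq = genome.sequences[s.interval.chrom]
            window = seq[s.centre - 80:s.centre + 80]
            assert not any(abs(off + 7 - 80) < 10
                           for off, _ in match_iupac(PRE_FULL_CONSENSUS, window))

    def test_pre_fraction_binomial(self):
        cfg = SimConfig(seed=5, n_chroms=4, chrom_length=10_000_000,
                        with_sequence=False, n_genes=0, n_sites=500,
                        shared_site_fraction=0.0, frac_regulated_genes=0.0,
                        pre_plant_prob=0.6)
        genome, genes = simulate_genome(cfg)
        truth = plant_binding_sites(genome, genes, cfg)
        for ln in CELL_LINES:
            sites = truth.sites_for(ln)
            frac = np.mean([any(m[0] == "PRE" for m in s.motifs) for s in sites])
            assert abs(frac - 0.6) <= se3(0.6, len(sites))

    def test_cofactor_fractions_on_unique_sites(self):
        cfg = SimConfig(seed=6, n_chroms=4, chrom_length=10_000_000,
                        with_sequence=False, n_genes=0, n_sites=400,
                        shared_site_fraction=0.0, frac_regulated_genes=0.0)
        genome, genes = simulate_genome(cfg)
        truth = plant_binding_sites(genome, genes, cfg)
        for ln in CELL_LINES:
            sites = [s for s in truth.sites_for(ln) if not s.shared]
            for name, p in cfg.cofactor_plant_probs[ln].items():
                frac = np.mean([any(m[0] == name for m in s.motifs)
                                for s in sites])
                # motif placement can be skipped on rare overlap collisions
                assert abs(frac - p) <= se3(max(p, 0.02), len(sites)) + 0.02

    def test_shared_fraction_recovered_by_intersect(self):
        cfg = SimConfig(seed=7, n_chroms=4, chrom_length=10_000_000,
                        with_sequence=False, n_genes=0, n_sites=300,
                        shared_site_fraction=0.3, frac_regulated_genes=0.0)
        genome, genes = simulate_genome(cfg)
        truth = plant_binding_sites(genome, genes, cfg)
        a = [s.interval for s in truth.sites_for(CELL_LINES[0])]
        b = [s.interval for s in truth.sites_for(CELL_LINES[1])]
        parts = intersect(a, b)
        frac = len(parts["common_a"]) / len(a)
        assert abs(frac - 0.3) <= se3(0.3, len(a))

    def test_linked_sites_within_100kb(self, small_study):
        truth, genes = small_study.truth, small_study.genes
        gene_map = {g.gene_id: g for g in genes}
        for reg in truth.regulated:
            if reg.linked_site_index is None:
                continue
            site = truth.sites[reg.linked_site_index]
            gene = gene_map[reg.gene_id]
            assert site.interval.chrom == gene.chrom
            assert abs(site.centre - gene.tss) <= 100_000


class TestLinkDistances:
    def test_direction_means(self):
        rng = np.random.default_rng(0)
        cfg = SimConfig()
        up = sample_link_distances(cfg, "up", 2000, rng)
        down = sample_link_distances(cfg, "down", 2000, rng)
        assert up.min() >= cfg.min_link_distance
        assert up.max() <= cfg.max_link_distance
        assert np.median(up) < np.median(down)


class TestTags:
    def site_config(self, **kw):
        base = dict(seed=8, n_chroms=1, chrom_length=1_000_000,
                    with_sequence=False, n_genes=0, n_sites=1,
                    shared_site_fraction=0.0, frac_regulated_genes=0.0,
                    background_rate=0.0, n_chip_tags=10_000,
                    n_input_tags=1000, multiread_fraction=0.0)
        base.update(kw)
        return SimConfig(**base)

    def test_strand_asymmetry_single_site(self):
        cfg = self.site_config()
        genome, genes = simulate_genome(cfg)
        truth = plant_binding_sites(genome, genes, cfg)
        chip, _ = simulate_tags(genome, truth, cfg, "cellA")
        centre = truth.sites[0].centre
        plus = chip.tags.loc[chip.tags.strand == "+", "pos"]
        minus = chip.tags.loc[chip.tags.strand == "-", "pos"]
        assert plus.max() <= centre and minus.min() >= centre
        assert plus.median() < centre < minus.median()

    def test_strand_separation_matches_fragment_length(self):
        cfg = self.site_config(seed=9)
        genome, genes = simulate_genome(cfg)
        truth = plant_binding_sites(genome, genes, cfg)
        chip, _ = simulate_tags(genome, truth, cfg, "cellA")
        plus = chip.tags.loc[chip.tags.strand == "+", "pos"].mean()
        minus = chip.tags.loc[chip.tags.strand == "-", "pos"].mean()
        assert abs((minus - plus) - 300) <= 10

    def test_deterministic(self):
        cfg = self.site_config()
        genome, genes = simulate_genome(cfg)
        truth = plant_binding_sites(genome, genes, cfg)
        a, ai = simulate_tags(genome, truth, cfg, "cellA")
        b, bi = simulate_tags(genome, truth, cfg, "cellA")
        assert a.tags.equals(b.tags) and ai.tags.equals(bi.tags)

    def test_multiread_multiplicities(self):
        cfg = self.site_config(multiread_fraction=0.2)
        genome, genes = simulate_genome(cfg)
        truth = plant_binding_sites(genome, genes, cfg)
        chip, _ = simulate_tags(genome, truth, cfg, "cellA")
        mult = chip.tags["multiplicity"]
        frac = (mult > 1).mean()
        assert mult.max() <= cfg.multiread_max
        assert abs(frac - 0.2) <= se3(0.2, len(mult))


class TestExpression:
    def test_null_study_false_positive_rate(self):
        cfg = SimConfig(seed=10, frac_regulated_genes=0.0)
        genome, genes = simulate_genome(cfg)
        truth = plant_binding_sites(genome, genes, cfg)
        expr = simulate_expression(truth, genes, cfg, "cellA")
        from cistromekit.expression import call_regulated, regulated_directions
        reg = regulated_directions(call_regulated(expr))
        # p<0.01 alone bounds the false-call rate; the FC filter cuts further
        assert len(reg) <= 0.01 * len(expr) + se3(0.01, len(expr)) * len(expr)

    def test_deterministic_table(self, small_study):
        expr2 = simulate_expression(small_study.truth, small_study.genes,
                                    small_study.config, "cellA")
        assert small_study.expression["cellA"].equals(expr2)

    def test_regulated_genes_pass_thresholds(self, small_study):
        from cistromekit.expression import call_regulated, regulated_directions
        reg = regulated_directions(call_regulated(small_study.expression["cellA"]))
        truth_reg = {g.gene_id: g.direction
                     for g in small_study.truth.regulated_for("cellA")}
        assert set(truth_reg) <= set(reg)
        assert all(reg[g] == d for g, d in truth_reg.items())


class TestStudyBundle:
    def test_full_determinism(self):
        cfg = SimConfig(seed=12, n_chroms=2, chrom_length=1_000_000,
                        n_genes=40, n_sites=12, n_chip_tags=5_000,
                        n_input_tags=1_000)
        d1 = simulate_study(cfg)
        d2 = simulate_study(cfg)
        assert d1.genome.sequences == d2.genome.sequences
        for ln in CELL_LINES:
            assert d1.chip[ln].tags.equals(d2.chip[ln].tags)
            assert d1.expression[ln].equals(d2.expression[ln])
        assert [s.interval for s in d1.truth.sites] == \
               [s.interval for s in d2.truth.sites]
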