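"""DE calling thresholds, SOM clustering, regulation deltas and overlaps."""

import numpy as np
import pandas as pd
import pytest

from cistromekit.expression import (
    call_regulated,
    cluster_distance_test,
    delta_distance_analysis,
    nearest_region_distances,
    region_density_per_gene,
    regulated_directions,
    regulation_delta,
    som_cluster,
    transcriptome_overlap,
)
from cistromekit.regions import BindingRegion, GeneModel, GenomicInterval


def expr_table(rows):
    return pd.DataFrame(rows, columns=["transcript_id", "timepoint",
                                       "log2_fc", "diff_p"])


class TestCallRegulated:
    @pytest.mark.parametrize("fc,p,expected", [
        (1.6, 0.005, "up"),      # passes both thresholds
        (1.4, 0.001, "none"),    # fold change below 1.5
        (2.0, 0.02, "none"),     # p above 0.01
        (1 / 1.6, 0.005, "down"),
    ])
    def test_threshold_combinations(self, fc, p, expected):
        table = expr_table([("t1", 2, np.log2(fc), p)])
        assert call_regulated(table)[0].direction == expected

    def test_any_timepoint_suffices(self):
        table = expr_table([("t1", 2, 0.0, 0.9),
                            ("t1", 6, np.log2(1.8), 0.001),
                            ("t1", 24, 0.0, 0.5)])
        assert regulated_directions(call_regulated(table)) == {"t1": "up"}

    def test_monotone_in_fc_threshold(self):
        rng = np.random.default_rng(0)
        rows = [(f"t{i}", 2, float(rng.normal(0, 1)), float(rng.uniform(0, 0.02)))
                for i in range(200)]
        table = expr_table(rows)
        loose = set(regulated_directions(call_regulated(table, fc_threshold=1.2)))
        tight = set(regulated_directions(call_regulated(table, fc_threshold=1.8)))
        assert tight <= loose

    def test_missing_values_skipped(self):
        table = expr_table([("t1", 2, np.nan, 0.001), ("t2", 2, 1.0, 0.001)])
        calls = call_regulated(table)
        assert [c.transcript_id for c in calls] == ["t2"]


class TestSom:
    def test_identical_profiles_one_label(self):
        profiles = {f"t{i}": [1.0, 2.0, 3.0] for i in range(20)}
        res = som_cluster(profiles, grid=(1, 2), seed=0)
        assert len(set(res.labels.values())) == 1

    def test_grid_larger_than_sample_errors(self):
        with pytest.raises(ValueError):
            som_cluster({"a": [1, 2], "b": [2, 3]}, grid=(2, 2), seed=0)

    def test_recovers_two_planted_groups(self):
        rng = np.random.default_rng(1)
        profiles = {}
        for i in range(200):
            base = [2.0, 1.5, 1.0] if i < 100 else [-1.0, -1.5, -2.0]
            profiles[f"t{i}"] = list(np.array(base) + rng.normal(0, 0.3, 3))
        res = som_cluster(profiles, grid=(1, 2), seed=2)
        labels = np.array([res.labels[f"t{i}"] for i in range(200)])
        majority_first = np.bincount(labels[:100], minlength=2).argmax()
        agreement = ((labels[:100] == majority_first).sum()
                     + (labels[100:] != majority_first).sum()) / 200
        assert agreement >= 0.95

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        profiles = {f"t{i}": list(rng.normal(0, 1, 3)) for i in range(50)}
        a = som_cluster(profiles, grid=(3, 3), seed=7)
        b = som_cluster(profiles, grid=(3, 3), seed=7)
        assert a.labels == b.labels
        assert np.allclose(a.node_means, b.node_means)

    def test_quantization_error_decreases(self):
        rng = np.random.default_rng(4)
        profiles = {f"t{i}": list(rng.normal(0, 1, 3)) for i in range(100)}
        res = som_cluster(profiles, grid=(2, 2), seed=5)
        qe = res.quantization_errors
        assert qe[-1] <= qe[0]


class TestClusterDistanceTest:
    def test_hand_h_statistic(self):
        labels = {"a": 0, "b": 0, "c": 0, "d": 1, "e": 1, "f": 1}
        dists = dict(zip("abcdef", [1, 2, 3, 4, 5, 6]))
        res = cluster_distance_test(labels, dists)
        assert res.statistic == pytest.approx(3.857142857, abs=1e-6)

    def test_null_grouping_not_significant(self):
        rng = np.random.default_rng(5)
        labels = {f"t{i}": i % 3 for i in range(120)}
        dists = {f"t{i}": float(rng.exponential(50_000)) for i in range(120)}
        assert cluster_distance_test(labels, dists).pvalue > 0.01

    def test_degenerate_grouping_errors(self):
        with pytest.raises(ValueError):
            cluster_distance_test({"a": 0, "b": 1}, {"a": 1.0, "b": 2.0})


class TestRegulationDelta:
    def test_basic_partition(self):
        d = regulation_delta({"a", "b"}, {"b", "c"})
        assert (set(d.lost), set(d.gained), set(d.conserved)) == \
            ({"a"}, {"c"}, {"b"})

    def test_identical_sets(self):
        d = regulation_delta({"a", "b"}, {"a", "b"})
        assert not d.lost and not d.gained

    def test_partition_law_random(self, rng):
        universe = [f"t{i}" for i in range(100)]
        base = {t for t in universe if rng.random() < 0.4}
        cond = {t for t in universe if rng.random() < 0.4}
        d = regulation_delta(base, cond)
        assert d.lost | d.conserved == frozenset(base)
        assert d.gained & frozenset(base) == frozenset()
        assert not (d.lost & d.gained or d.lost & d.conserved
                    or d.gained & d.conserved)
        for t in universe:
            expected = ("lost" if t in base and t not in cond else
                        "gained" if t in cond and t not in base else
                        "conserved" if t in base else None)
            if expected:
                assert t in getattr(d, expected)


def synthetic_gene_layout(rng, n, chrom="chr1", spacing=250_000):
    return [GeneModel(f"g{i:03d}", chrom, "+", spacing * (i + 1),
                      spacing * (i + 1) + 10_000) for i in range(n)]


class TestDeltaDistanceAnalysis:
    def test_identical_distance_lists_p_one(self):
        rng = np.random.default_rng(6)
        genes = synthetic_gene_layout(rng, 20)
        regions = [BindingRegion(GenomicInterval("chr1", g.tss + 4900,
                                                 g.tss + 5100),
                                 g.tss + 5000, 1.0, 5.0, f"r{i}")
                   for i, g in enumerate(genes)]
        delta = regulation_delta({g.gene_id for g in genes[:10]},
                                 {g.gene_id for g in genes[:10]} |
                                 {g.gene_id for g in genes[10:]})
        out = delta_distance_analysis(delta, regions, genes)
        res = out["tests"][("gained", "conserved")]
        assert res.pvalue == pytest.approx(1.0)

    def test_planted_distance_offset_detected(self):
        rng = np.random.default_rng(7)
        genes = synthetic_gene_layout(rng, 400, spacing=200_000)
        regions = []
        conserved, gained = set(), set()
        for i, g in enumerate(genes):
            if i < 200:
                d = abs(rng.normal(20_000, 8_000))
                conserved.add(g.gene_id)
            else:
                d = abs(rng.normal(50_000, 8_000))   # +30 kb planted offset
                gained.add(g.gene_id)
            mid = int(g.tss + d)
            regions.append(BindingRegion(
                GenomicInterval(g.chrom, mid - 100, mid + 100), mid, 1.0, 5.0,
                f"r{i}"))
        delta = regulation_delta(conserved, conserved | gained)
        out = delta_distance_analysis(delta, regions, genes)
        res = out["tests"][("gained", "conserved")]
        assert res.pvalue < 0.01
        assert out["per_class"]["gained"]["mean_distance"] > \
            out["per_class"]["conserved"]["mean_distance"]

    def test_density_equals_brute_force(self, rng):
        genes = synthetic_gene_layout(rng, 30)
        regions = [BindingRegion(GenomicInterval("chr1", int(p), int(p) + 200),
                                 int(p) + 100, 1.0, 5.0, f"r{i}")
                   for i, p in enumerate(rng.integers(0, 8_000_000, 200))]
        dens = region_density_per_gene([g.gene_id for g in genes],
                                       regions, genes)
        for g in genes:
            brute = sum(1 for r in regions
                        if r.chrom == g.chrom
                        and abs(r.midpoint - g.tss) <= 100_000)
            assert dens[g.gene_id] == brute


class TestTranscriptomeOverlap:
    def test_disjoint(self):
        out = transcriptome_overlap({"a"}, {"b"})
        assert out["common"] == 0 and out["pct_of_union"] == 0

    def test_identical(self):
        out = transcriptome_overlap({"a", "b"}, {"a", "b"})
        assert out["pct_of_union"] == 100

    def test_both_empty_sentinel(self):
        out = transcriptome_overlap(set(), set())
        assert out["pct_of_union"] is None

    def test_consistency_invariants(self, rng):
        universe = [f"t{i}" for i in range(60)]
        a = {t for t in universe if rng.random() < 0.5}
        b = {t for t in universe if rng.random() < 0.5}
        if not a or not b:
            return
        out = transcriptome_overlap(a, b)
        assert out["common"] == len(a & b) <= min(len(a), len(b))
        assert out["pct_of_union"] <= min(out["pct_of_a"], out["pct_of_b"])
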