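"""PWM scoring, exact p-values, scanning, IUPAC matching and enrichment."""

import math
from itertools import product

import numpy as np
import pytest

from cistromekit.motifs import (
    PRE_FULL_CONSENSUS,
    PWM,
    build_matched_background,
    classify_strength,
    cooccurrence_table,
    enrichment_test,
    gc_content,
    match_iupac,
    positional_distribution,
    pwm_from_iupac,
    read_meme,
    revcomp,
    scan_regions,
    write_meme,
    MotifHit,
    IUPAC_SETS,
)
from cistromekit.regions import GenomicInterval
from conftest import random_dna


def deterministic_pwm(width=4):
    p = np.zeros((width, 4))
    p[np.arange(width), np.arange(width) % 4] = 1.0
    return PWM("det", p, pseudocount=0.0)


class TestScoring:
    def test_closed_form_perfect_match(self):
        pwm = deterministic_pwm(4)
        assert pwm.score("ACGT") == pytest.approx(4 * math.log2(4))

    def test_zero_score_at_background(self):
        pwm = PWM("flat", np.full((5, 4), 0.25), pseudocount=0.0)
        assert pwm.score("ACGTA") == pytest.approx(0.0)

    def test_per_position_resummation_oracle(self, rng):
        probs = rng.dirichlet(np.ones(4), size=6)
        pwm = PWM("r", probs)
        window = random_dna(rng, 6)
        lo = pwm.log_odds
        expected = sum(lo[j, "ACGT".index(window[j])] for j in range(6))
        assert pwm.score(window) == pytest.approx(expected, abs=1e-12)

    def test_ambiguous_base_is_nan(self):
        assert math.isnan(deterministic_pwm().score("ACGN"))


class TestPValues:
    def test_minimum_score_p_is_one(self):
        pwm = deterministic_pwm(4)
        assert pwm.score_pvalue(pwm.score("TTTA")) == 1.0

    def test_width_two_counting(self):
        p = np.zeros((4, 4))
        p[:, 0] = 1.0
        pwm = PWM("aa", p[:2], pseudocount=0.0)
        assert pwm.score_pvalue(pwm.score("AA")) == pytest.approx(1 / 16)

    def test_dp_equals_enumeration(self, rng):
        """DP tail mass equals brute-force enumeration over all 4^w words
        scored with the same quantized matrix (independent summation)."""
        for _ in range(5):
            width = int(rng.integers(4, 7))
            pwm = PWM("r", rng.dirichlet(np.ones(4) * 0.7, size=width))
            q, bg = pwm.qscores, pwm.background
            words = list(product(range(4), repeat=width))
            qsums = np.array([q[np.arange(width), list(wd)].sum() for wd in words])
            probs = np.array([np.prod(bg[list(wd)]) for wd in words])
            for target in rng.choice(qsums, size=5, replace=False):
                exact = probs[qsums >= target].sum()
                assert pwm.qscore_pvalue(int(target)) == pytest.approx(
                    exact, abs=1e-9)

    def test_monotone_nonincreasing(self, rng):
        pwm = PWM("r", rng.dirichlet(np.ones(4), size=8))
        scores = np.linspace(-20, 20, 200)
        pvals = [pwm.score_pvalue(s) for s in scores]
        assert all(a >= b - 1e-15 for a, b in zip(pvals, pvals[1:]))
        assert all(0 < p <= 1 for p in pvals)


class TestStrengthClasses:
    @pytest.mark.parametrize("p,expected", [
        (1e-6, "strong"),
        (1e-5, "moderate"),      # boundary belongs to moderate
        (1e-4, "moderate"),
        (1e-3, "moderate"),      # closed upper bound
        (0.01, "weak_absent"),
    ])
    def test_boundaries(self, p, expected):
        assert classify_strength(p) == expected

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            classify_strength(0.0)


class TestScan:
    def test_planted_consensus_single_hit(self, rng):
        pre = pwm_from_iupac(PRE_FULL_CONSENSUS, "PRE")
        seq = list(random_dna(rng, 200))
        seq[92:107] = list("AGTACAGGGTGTACT")
        hits = scan_regions(pre, {"r": "".join(seq)}, report_p=1e-5)
        assert len(hits) == 1
        h = hits[0]
        assert h.offset == 92 + 7 - 100 and h.is_best
        assert h.strength_class == "strong"

    def test_random_sequence_no_extreme_hits(self, rng):
        pwm = PWM("r", rng.dirichlet(np.ones(4), size=10))
        seqs = {f"r{i}": random_dna(rng, 400) for i in range(5)}
        assert scan_regions(pwm, seqs, report_p=1e-12) == []

    def test_reverse_complement_symmetry(self, rng):
        pwm = PWM("r", rng.dirichlet(np.ones(4) * 0.5, size=7))
        seq = random_dna(rng, 151)
        fwd = scan_regions(pwm, {"s": seq}, report_p=0.05)
        rev = scan_regions(pwm, {"s": revcomp(seq)}, report_p=0.05)
        # odd length, odd width: a window at offset o maps to -o
        fwd_set = {(-h.offset, {"+": "-", "-": "+"}[h.strand],
                    round(h.score, 9)) for h in fwd}
        rev_set = {(h.offset, h.strand, round(h.score, 9)) for h in rev}
        assert fwd_set == rev_set

    def test_short_region_skipped(self, rng):
        pwm = PWM("r", rng.dirichlet(np.ones(4), size=8))
        assert scan_regions(pwm, {"tiny": "ACG"}, report_p=1.0) == []


class TestIupac:
    def test_degenerate_match(self):
        assert (0, "+") in match_iupac("RG", "AG")

    def test_consensus_self_instantiation(self):
        hits = match_iupac(PRE_FULL_CONSENSUS, "AGTACAGGGTGTACT")
        assert (0, "+") in hits

    def test_brute_force_oracle(self, rng):
        pattern = "RGNAY"
        seq = random_dna(rng, 300)
        sets = [IUPAC_SETS[c] for c in pattern]
        fwd = [(i, "+") for i in range(len(seq) - 4)
               if all(seq[i + j] in sets[j] for j in range(5))]
        rc_sets = [IUPAC_SETS[c] for c in revcomp(pattern)]
        rev = [(i, "-") for i in range(len(seq) - 4)
               if all(seq[i + j] in rc_sets[j] for j in range(5))]
        assert match_iupac(pattern, seq) == sorted(fwd + rev)


class TestBackgroundAndEnrichment:
    def test_matched_background_geometry(self, rng):
        genome = {"chr1": random_dna(rng, 100_000)}
        fg = [GenomicInterval("chr1", i * 3000, i * 3000 + 350) for i in range(8)]
        bg = build_matched_background(fg, genome, n_per_region=2, rng=rng)
        assert sorted(iv.length for iv in bg) == sorted(
            [iv.length for iv in fg] * 2)
        for b in bg:
            assert not any(b.overlaps(f) for f in fg)
        diffs = []
        for i, f in enumerate(fg):
            for b in bg[2 * i:2 * i + 2]:
                diffs.append(abs(
                    gc_content(genome["chr1"][b.start:b.end])
                    - gc_content(genome["chr1"][f.start:f.end])))
        assert float(np.mean(diffs)) <= 0.05

    def test_enrichment_direct_count(self):
        assert enrichment_test(5, 5, 0, 5) == pytest.approx(1 / 252, rel=1e-9)

    def test_no_enrichment_at_equal_rates(self):
        for k, n in [(2, 10), (5, 20), (1, 4)]:
            assert enrichment_test(k, n, k, n) >= 0.5

    def test_monte_carlo_permutation_oracle(self, rng):
        fg_hit, fg_total, bg_hit, bg_total = 7, 20, 3, 20
        p = enrichment_test(fg_hit, fg_total, bg_hit, bg_total)
        labels = np.array([1] * (fg_hit + bg_hit) + [0] * (fg_total + bg_total
                                                           - fg_hit - bg_hit))
        n_perm, count = 100_000, 0
        for _ in range(n_perm):
            rng.shuffle(labels)
            if labels[:fg_total].sum() >= fg_hit:
                count += 1
        perm = count / n_perm
        se = math.sqrt(perm * (1 - perm) / n_perm)
        assert abs(p - perm) <= 3 * se + 1e-3


class TestCooccurrence:
    def test_pair_intersection(self):
        t = cooccurrence_table({"A": {"r1", "r2"}, "B": {"r2", "r3"}})
        assert t[("A", "B")] == 1 and t[("A",)] == 2

    def test_disjoint(self):
        t = cooccurrence_table({"A": {"r1"}, "B": {"r2"}})
        assert t[("A", "B")] == 0

    def test_brute_force_oracle(self, rng):
        universe = [f"r{i}" for i in range(40)]
        hits = {m: {r for r in universe if rng.random() < 0.4}
                for m in "XYZ"}
        t = cooccurrence_table(hits, universe=set(universe))
        for subset, count in t.items():
            brute = sum(1 for r in universe
                        if all(r in hits[m] for m in subset))
            assert count == brute


class TestPositionalDistribution:
    @staticmethod
    def hits_from_offsets(offsets):
        return [MotifHit("r%d" % i, int(o), "+", 5.0, 1e-4, "moderate",
                         is_best=True)
                for i, o in enumerate(offsets)]

    def test_accepts_planted_normal(self):
        rng = np.random.default_rng(0)
        res = positional_distribution(
            self.hits_from_offsets(rng.normal(0, 50, 500)))
        assert res.normality_p > 0.05

    def test_rejects_uniform(self):
        rng = np.random.default_rng(0)
        res = positional_distribution(
            self.hits_from_offsets(rng.uniform(-400, 400, 500)))
        assert res.normality_p < 0.05

    def test_degenerate_offsets(self):
        with pytest.raises(ValueError):
            positional_distribution(self.hits_from_offsets([5] * 20))

    def test_underpowered(self):
        with pytest.raises(ValueError):
            positional_distribution(self.hits_from_offsets([1, 2, 3]))


class TestMemeFormat:
    def test_roundtrip(self, rng):
        pwms = [pwm_from_iupac(PRE_FULL_CONSENSUS, "PRE"),
                PWM("rand", rng.dirichlet(np.ones(4), size=6))]
        text = write_meme(pwms)
        back = read_meme(text)
        assert [p.name for p in back] == ["PRE", "rand"]
        for orig, parsed in zip(pwms, back):
            assert np.allclose(orig.probs, parsed.probs, atol=1e-5)
            assert np.allclose(parsed.background, 0.25)
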