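"""Genotype container, VCF round trips, dataset-construction filters, HWE test."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rangexp.genotypes import (GenotypeMatrix, filter_individuals_by_call_rate,
                               filter_loci_by_maf, hwe_exact_test, read_vcf,
                               thin_loci_by_distance, write_vcf)

from conftest import make_gm


class TestVcfIO:
    def test_hand_written_vcf_transcribed(self, tmp_path):
        text = (
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\n"
            "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\n"
            "chr1\t200\t.\tC\tT\t.\tPASS\t.\tGT\t1/1\t0/0\n"
            "chr2\t50\t.\tG\tA\t.\tPASS\t.\tGT\t0/1\t./.\n"
        )
        p = tmp_path / "x.vcf"
        p.write_text(text)
        gm = read_vcf(p)
        assert gm.sample_ids == ["a", "b"]
        assert gm.n_loci == 3
        np.testing.assert_array_equal(gm.calls, [[0, 2, 1], [1, 0, -1]])
        assert gm.loci.pos.tolist() == [100, 200, 50]

    def test_multiallelic_and_indel_records_skipped(self, tmp_path):
        text = (
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\n"
            "chr1\t100\t.\tA\tG,T\t.\tPASS\t.\tGT\t0/1\n"
            "chr1\t200\t.\tAT\tA\t.\tPASS\t.\tGT\t0/1\n"
            "chr1\t300\t.\tA\tC\t.\tPASS\t.\tGT\t1/1\n"
        )
        p = tmp_path / "m.vcf"
        p.write_text(text)
        gm = read_vcf(p)
        assert gm.n_loci == 1
        assert gm.loci.pos.tolist() == [300]

    def test_round_trip_identity(self, tmp_path):
        rng = np.random.default_rng(3)
        calls = rng.choice([0, 1, 2, -1], size=(4, 6)).astype(np.int8)
        gm = make_gm(calls, chrom=["chr1"] * 3 + ["chr2"] * 3)
        p = tmp_path / "rt.vcf"
        write_vcf(gm, p)
        back = read_vcf(p)
        np.testing.assert_array_equal(back.calls, gm.calls)
        np.testing.assert_array_equal(back.loci.pos, gm.loci.pos)
        assert back.sample_ids == gm.sample_ids
        assert back.loci.ref.tolist() == gm.loci.ref.tolist()

    def test_invalid_calls_rejected(self):
        with pytest.raises(ValueError, match="calls must be"):
            make_gm([[0, 3]])

    def test_duplicate_positions_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            make_gm([[0, 1]], pos=[100, 100])


class TestFilters:
    def test_call_rate_threshold_inclusive(self):
        # call rates 0.80 (4/5), 0.74 impossible with 5 loci; use 20 loci
        calls = np.zeros((3, 20), dtype=np.int8)
        calls[0, :4] = -1   # rate 0.80
        calls[1, :6] = -1   # rate 0.70
        gm = make_gm(calls)
        out, rep = filter_individuals_by_call_rate(gm, 0.75)
        assert out.sample_ids == ["s0", "s2"]
        assert rep.removed == ["s1"]

    def test_call_rate_zero_keeps_everyone(self):
        calls = np.full((2, 4), -1, dtype=np.int8)
        calls[0, 0] = 1
        out, _ = filter_individuals_by_call_rate(make_gm(calls), 0.0)
        assert out.n_samples == 2

    def test_maf_boundary_inclusive(self):
        # 10 diploids, one heterozygote -> freq 1/20 = 0.05, kept at >= 0.05
        calls = np.zeros((10, 2), dtype=np.int8)
        calls[0, 0] = 1       # locus 0: maf 0.05
        calls[:, 1] = [1] + [0] * 9
        calls[0, 1] = 0       # locus 1 monomorphic
        calls[1, 1] = 1
        calls[1, 1] = 0       # make locus 1 truly monomorphic
        gm = make_gm(calls)
        out, rep = filter_loci_by_maf(gm, 0.05)
        assert out.n_loci == 1
        assert "chr1:200" in rep.removed

    def test_maf_uses_observed_copies(self):
        # 2 alt copies of 50 observed -> 0.04 < 0.05 -> removed
        calls = np.zeros((26, 1), dtype=np.int8)
        calls[0, 0] = 2
        calls[25, 0] = -1  # 25 genotyped diploids = 50 copies
        out, _ = filter_loci_by_maf(make_gm(calls), 0.05)
        assert out.n_loci == 0

    def test_all_missing_locus_reported(self):
        calls = np.array([[-1, 1], [-1, 1]], dtype=np.int8)
        out, rep = filter_loci_by_maf(make_gm(calls), 0.05)
        assert rep.reasons.get("chr1:100") == "all-missing"

    def test_thinning_constraint_and_determinism(self):
        gm = make_gm(
            np.ones((2, 3), dtype=np.int8),
            pos=[100, 5000, 10200],
        )
        out, _ = thin_loci_by_distance(gm, 10_000, seed=5)
        kept = sorted(out.loci.pos.tolist())
        assert kept in ([100, 10200], [5000], [10200], [100]) or all(
            abs(a - b) >= 10_000 for a, b in itertools.combinations(kept, 2)
        )
        out2, _ = thin_loci_by_distance(gm, 10_000, seed=5)
        assert out.loci.pos.tolist() == out2.loci.pos.tolist()

    def test_thinning_ignores_other_chromosomes(self):
        gm = make_gm(
            np.ones((1, 4), dtype=np.int8),
            chrom=["c1", "c2", "c3", "c4"],
            pos=[100, 150, 200, 250],
        )
        out, _ = thin_loci_by_distance(gm, 10_000, seed=0)
        assert out.n_loci == 4

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_filters_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        calls = rng.choice([0, 1, 2, -1], size=(6, 12), p=[0.4, 0.2, 0.2, 0.2]).astype(np.int8)
        gm = make_gm(calls, pos=rng.choice(10**6, size=12, replace=False) + 1)
        for filt in (
            lambda g: filter_individuals_by_call_rate(g, 0.75),
            lambda g: filter_loci_by_maf(g, 0.05),
            lambda g: thin_loci_by_distance(g, 10_000, seed=1),
        ):
            once, _ = filt(gm)
            twice, _ = filt(once)
            np.testing.assert_array_equal(once.calls, twice.calls)
            np.testing.assert_array_equal(once.loci.pos, twice.loci.pos)


def _levene_pmf(n, n_minor):
    """Independent oracle: Levene's conditional distribution of the
    heterozygote count, P(h) = n! nA! nB! 2^h / (n1! h! n2! (2n)!), exact."""
    n_major = 2 * n - n_minor
    out = {}
    for h in range(n_minor % 2, n_minor + 1, 2):
        n1 = (n_minor - h) // 2
        n2 = n - n1 - h
        num = (
            math.factorial(n) * math.factorial(n_minor) * math.factorial(n_major) * 2**h
        )
        den = (
            math.factorial(n1) * math.factorial(h) * math.factorial(n2)
            * math.factorial(2 * n)
        )
        out[h] = Fraction(num, den)
    return out


class TestHweExactTest:
    @pytest.mark.parametrize(
        "counts,expected",
        [((1, 0, 1), Fraction(1, 3)), ((0, 2, 0), Fraction(1, 1)), ((5, 0, 0), 1.0)],
    )
    def test_worked_examples(self, counts, expected):
        assert hwe_exact_test(*counts) == pytest.approx(float(expected), abs=1e-15)

    def test_all_zero_counts_error(self):
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)

    def test_matches_enumeration_oracle_all_configs(self):
        """Every configuration with n <= 30 agrees with the Levene-distribution
        oracle to 1e-12."""
        for n in range(1, 31):
            for n_minor in range(0, n + 1):
                pmf = _levene_pmf(n, n_minor)
                assert sum(pmf.values()) == 1
                for h_obs, p_obs in pmf.items():
                    n1 = (n_minor - h_obs) // 2
                    n2 = n - n1 - h_obs
                    expected = float(sum(p for p in pmf.values() if p <= p_obs))
                    got = hwe_exact_test(n2, h_obs, n1)
                    assert got == pytest.approx(expected, abs=1e-12)

    def test_literal_enumeration_small_n(self):
        """For n <= 5 the test also matches literal enumeration of every
        arrangement of allele copies into diploids."""
        for n in range(1, 6):
            for n_minor in range(0, 2 * n + 1):
                nm = min(n_minor, 2 * n - n_minor)
                counts_by_h = {}
                for minor_pos in itertools.combinations(range(2 * n), nm):
                    genome = np.zeros(2 * n, dtype=int)
                    genome[list(minor_pos)] = 1
                    h = int((genome.reshape(n, 2).sum(axis=1) == 1).sum())
                    counts_by_h[h] = counts_by_h.get(h, 0) + 1
                total = sum(counts_by_h.values())
                for h_obs, c_obs in counts_by_h.items():
                    expected = sum(c for c in counts_by_h.values() if c <= c_obs) / total
                    n1 = (nm - h_obs) // 2
                    n2 = n - n1 - h_obs
                    assert hwe_exact_test(n2, h_obs, n1) == pytest.approx(expected, abs=1e-12)

    def test_calibration_under_hardy_weinberg(self):
        """Rejection rate stays inside the 99% binomial envelope of alpha when
        genotypes really follow Hardy-Weinberg proportions.

        300 diploids per locus: the conditional exact test is conservative at
        small samples because the heterozygote-count distribution is discrete,
        so calibration is checked where the discreteness is mild.
        """
        rng = np.random.default_rng(11)
        n_loci, n_dip = 2000, 300
        pvals = []
        for _ in range(n_loci):
            p = rng.uniform(0.1, 0.9)
            g = rng.binomial(1, p, size=(n_dip, 2)).sum(axis=1)
            counts = [(g == k).sum() for k in (0, 1, 2)]
            pvals.append(hwe_exact_test(*counts))
        pvals = np.array(pvals)
        for alpha in (0.05, 0.01):
            frac = (pvals < alpha).mean()
            se = math.sqrt(alpha * (1 - alpha) / n_loci)
            assert alpha - 2.58 * se <= frac <= alpha + 2.58 * se
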