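"""Diversity, Tajima's D, Weir-Cockerham F_ST, psi, Evanno delta-K."""

import math

import numpy as np
import pytest

from rangexp.genotypes import PopulationMap
from rangexp.sfs import JointSFS
from rangexp.sumstats import (FstResult, UndefinedStatistic, diversity,
                              evanno_delta_k, fst_permutation_test, psi,
                              tajima_constants, tajimas_d, wc_fst)

from conftest import make_gm


class TestDiversity:
    def test_two_heterozygotes_single_locus(self):
        gm = make_gm([[1], [1]])
        pm = PopulationMap({"s0": "P", "s1": "P"})
        rep = diversity(gm, pm).iloc[0]
        assert rep.h_o == 1.0
        assert rep.pi == pytest.approx(4 / 3 * 0.5, abs=1e-12)

    def test_monomorphic_population(self):
        gm = make_gm([[0, 2], [0, 2]])
        pm = PopulationMap({"s0": "P", "s1": "P"})
        rep = diversity(gm, pm).iloc[0]
        assert rep.pi == 0.0
        assert rep.h_o == 0.0

    def test_het_hom_ratio(self):
        gm = make_gm([[1, 1, 1, 0]])
        pm = PopulationMap({"s0": "P"})
        assert diversity(gm, pm).iloc[0].het_hom == 3.0

    def test_all_missing_population_errors(self):
        gm = make_gm([[-1], [0]])
        pm = PopulationMap({"s0": "P", "s1": "Q"})
        with pytest.raises(ValueError, match="non-missing"):
            diversity(gm, pm)


def oracle_tajimas_d(xi, n):
    """Independent from-scratch implementation of the 1989 normalization."""
    s = xi[1:n].sum()
    pi = sum(xi[i] * i * (n - i) for i in range(1, n)) / (n * (n - 1) / 2)
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (pi - s / a1) / math.sqrt(e1 * s + e2 * s * (s - 1))


class TestTajimasD:
    def test_worked_example_n4(self):
        sfs = JointSFS(np.array([0.0, 2.0, 1.0, 0.0, 0.0]), ["p"])
        assert tajimas_d(sfs).d == pytest.approx(0.168, abs=5e-4)

    def test_a1_harmonic_sum_n10(self):
        assert tajima_constants(10)["a1"] == pytest.approx(2.828968, abs=1e-6)

    def test_no_segregating_sites_undefined(self):
        sfs = JointSFS(np.array([5.0, 0.0, 0.0]), ["p"])
        with pytest.raises(UndefinedStatistic):
            tajimas_d(sfs)

    def test_matches_oracle_on_random_spectra(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            n = int(rng.integers(4, 31))
            xi = np.zeros(n + 1)
            xi[1:n] = rng.integers(0, 20, size=n - 1)
            if xi[1:n].sum() == 0:
                xi[1] = 1
            got = tajimas_d(JointSFS(xi, ["p"])).d
            assert got == pytest.approx(oracle_tajimas_d(xi, n), abs=1e-10)

    def test_folded_spectrum_gives_same_value(self):
        from rangexp.sfs import fold

        xi = np.array([0.0, 5.0, 3.0, 2.0, 1.0, 0.5, 0.0])
        unfolded = JointSFS(xi, ["p"])
        assert tajimas_d(fold(unfolded)).d == pytest.approx(
            tajimas_d(unfolded).d, abs=1e-12
        )


def oracle_wc_theta(calls_a, calls_b):
    """Textbook variance-component estimator, written independently: per-locus
    a, b, c from sample sizes, allele frequencies and heterozygote frequencies
    of r=2 samples; theta = sum(a)/sum(a+b+c)."""
    num = den = 0.0
    r = 2
    for l in range(calls_a.shape[1]):
        ga = calls_a[:, l][calls_a[:, l] >= 0]
        gb = calls_b[:, l][calls_b[:, l] >= 0]
        if len(ga) < 2 or len(gb) < 2:
            continue
        ns = np.array([len(ga), len(gb)], float)
        ps = np.array([ga.mean() / 2, gb.mean() / 2])
        hs = np.array([(ga == 1).mean(), (gb == 1).mean()])
        nbar = ns.mean()
        nc = (r * nbar - (ns**2).sum() / (r * nbar)) / (r - 1)
        pbar = (ns * ps).sum() / (r * nbar)
        s2 = (ns * (ps - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (ns * hs).sum() / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        num += a
        den += a + b + c
    return num / den


class TestWcFst:
    def test_fixed_difference_is_one(self):
        gm = make_gm([[0], [0], [2], [2]])
        pm = PopulationMap({"s0": "A", "s1": "A", "s2": "B", "s3": "B"})
        assert wc_fst(gm, pm, "A", "B") == pytest.approx(1.0, abs=1e-12)

    def test_identical_population_copies_no_positive_signal(self):
        """Two populations that are exact copies of one sample set carry no
        among-population variance: the among component is non-positive (the
        1984 estimator is slightly negative on duplicated finite samples
        because it subtracts the within-sample expectation) and theta matches
        the independent oracle exactly."""
        rng = np.random.default_rng(10)
        half = rng.integers(0, 3, size=(4, 10)).astype(np.int8)
        gm = make_gm(np.vstack([half, half]))
        pm = PopulationMap({f"s{i}": ("A" if i < 4 else "B") for i in range(8)})
        theta = wc_fst(gm, pm, "A", "B", min_maf=0.0)
        assert theta <= 0.0
        assert theta == pytest.approx(oracle_wc_theta(half, half), abs=1e-12)

    def test_matches_variance_component_oracle(self, two_pop_gm):
        gm, pm = two_pop_gm
        got = wc_fst(gm, pm, "P1", "P2", min_maf=0.0)
        want = oracle_wc_theta(gm.calls[:5], gm.calls[5:])
        assert got == pytest.approx(want, abs=1e-12)

    def test_invariant_to_sample_and_locus_order(self, two_pop_gm):
        gm, pm = two_pop_gm
        base = wc_fst(gm, pm, "P1", "P2", min_maf=0.0)
        rng = np.random.default_rng(0)
        perm_s = rng.permutation(gm.n_samples)
        perm_l = rng.permutation(gm.n_loci)
        gm2 = gm.take_samples(perm_s).take_loci(perm_l)
        assert wc_fst(gm2, pm, "P1", "P2", min_maf=0.0) == pytest.approx(base, abs=1e-12)


class TestFstPermutation:
    def test_fixed_difference_minimal_p(self):
        """The observed theta = 1 is maximal, so p reaches the 1/(n_perm+1)
        floor (10v10 samples keep the chance of re-drawing the exact original
        split among 99 permutations negligible)."""
        gm = make_gm(np.array([[0, 0]] * 10 + [[2, 2]] * 10, dtype=np.int8))
        pm = PopulationMap({f"s{i}": ("A" if i < 10 else "B") for i in range(20)})
        res = fst_permutation_test(gm, pm, "A", "B", n_perm=99, seed=1)
        assert res.theta == pytest.approx(1.0, abs=1e-12)
        assert res.p_value == pytest.approx(1 / 100)

    def test_seeded_determinism(self, two_pop_gm):
        gm, pm = two_pop_gm
        r1 = fst_permutation_test(gm, pm, "P1", "P2", n_perm=50, seed=4, min_maf=0.0)
        r2 = fst_permutation_test(gm, pm, "P1", "P2", n_perm=50, seed=4, min_maf=0.0)
        assert (r1.theta, r1.p_value) == (r2.theta, r2.p_value)

    def test_n_perm_validation(self, two_pop_gm):
        gm, pm = two_pop_gm
        with pytest.raises(ValueError):
            fst_permutation_test(gm, pm, "P1", "P2", n_perm=0)


class TestPsi:
    def test_symmetric_spectrum_zero(self):
        f = np.array([[0, 1, 2], [1, 3, 1], [2, 1, 0]], float)
        res = psi(JointSFS(f, ["a", "b"]))
        assert res.psi == pytest.approx(0.0, abs=1e-15)

    def test_single_shared_site(self):
        f = np.zeros((3, 3))
        f[1, 2] = 1.0
        assert psi(JointSFS(f, ["a", "b"])).psi == pytest.approx(0.5)

    def test_antisymmetry_exact(self):
        rng = np.random.default_rng(12)
        f = rng.uniform(0, 4, size=(6, 6))
        fwd = psi(JointSFS(f, ["a", "b"])).psi
        rev = psi(JointSFS(f.T, ["b", "a"])).psi
        assert fwd == -rev

    def test_no_shared_sites_undefined(self):
        f = np.zeros((3, 3))
        f[1, 0] = 3.0
        f[0, 2] = 2.0
        with pytest.raises(UndefinedStatistic):
            psi(JointSFS(f, ["a", "b"]))

    def test_unequal_sizes_rejected(self):
        with pytest.raises(ValueError, match="equal"):
            psi(JointSFS(np.ones((3, 4)), ["a", "b"]))


class TestEvanno:
    def test_worked_example(self):
        table = {
            1: [-1000.0, -1000.0],
            2: [-905.0, -895.0],  # mean -900, sd ~7.07
            3: [-890.0, -890.0],
        }
        # fix sd(2) = 5 by construction
        table[2] = [-900 - 5 / math.sqrt(2), -900 + 5 / math.sqrt(2)]
        df = evanno_delta_k(table).set_index("k")
        assert df.loc[2, "delta_k"] == pytest.approx(18.0, abs=1e-9)

    def test_zero_variance_undefined(self):
        table = {1: [-10.0, -10.0], 2: [-8.0, -8.0], 3: [-7.0, -7.0]}
        df = evanno_delta_k(table).set_index("k")
        assert not df.loc[2, "defined"]
        assert np.isnan(df.loc[2, "delta_k"])

    def test_linear_trend_zero(self):
        table = {1: [-30.0, -31.0], 2: [-20.0, -21.0], 3: [-10.0, -11.0]}
        df = evanno_delta_k(table).set_index("k")
        assert df.loc[2, "delta_k"] == pytest.approx(0.0, abs=1e-12)

    def test_non_consecutive_grid_rejected(self):
        with pytest.raises(ValueError, match="consecutive"):
            evanno_delta_k({1: [0, 0], 3: [0, 0], 4: [0, 0]})
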