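"""Weir–Cockerham theta (pairwise/global), permutation test, AMOVA."""

import itertools

import numpy as np
import pytest

from breeddiv.differentiation import (
    amova,
    fst_matrix,
    fst_permutation_test,
    global_fst,
    pairwise_fst,
)
from breeddiv.simulate import SimConfig, balding_nichols
from conftest import make_matrix


class TestPairwiseTheta:
    def test_same_population_near_zero(self):
        G = balding_nichols(
            SimConfig(n_pops=2, samples_per_pop=100, n_loci=3000, fst_per_pop=0.0, seed=80)
        )
        assert pairwise_fst(G, "pop1", "pop2") == pytest.approx(0.0, abs=0.01)

    def test_fixed_opposite_alleles_is_one(self):
        calls = np.vstack([np.zeros((4, 10)), np.full((4, 10), 2)]).astype(np.int8)
        G = make_matrix(calls, populations=["A"] * 4 + ["B"] * 4)
        assert pairwise_fst(G, "A", "B") == pytest.approx(1.0)

    def test_balding_nichols_recovery(self):
        G = balding_nichols(
            SimConfig(n_pops=2, samples_per_pop=50, n_loci=5000, fst_per_pop=0.10, seed=81)
        )
        assert pairwise_fst(G, "pop1", "pop2") == pytest.approx(0.10, abs=0.015)

    def test_invariant_to_allele_relabeling(self):
        G = balding_nichols(
            SimConfig(n_pops=2, samples_per_pop=30, n_loci=400, fst_per_pop=0.05, seed=82)
        )
        theta = pairwise_fst(G, "pop1", "pop2")
        calls = G.calls.copy()
        flip = np.arange(0, 400, 3)
        m = calls[:, flip] != -1
        calls[:, flip] = np.where(m, 2 - calls[:, flip], calls[:, flip])
        G2 = make_matrix(calls, populations=[s.population for s in G.samples])
        assert pairwise_fst(G2, "pop1", "pop2") == pytest.approx(theta, abs=1e-12)

    def test_monotone_in_simulated_F(self):
        means = []
        for F in (0.02, 0.05, 0.1, 0.2):
            vals = [
                pairwise_fst(
                    balding_nichols(
                        SimConfig(n_pops=2, samples_per_pop=30, n_loci=600,
                                  fst_per_pop=F, seed=1000 + int(F * 1000) + r)
                    ),
                    "pop1", "pop2",
                )
                for r in range(20)
            ]
            means.append(np.mean(vals))
        assert means == sorted(means)
        assert means[0] < means[-1]


class TestGlobalTheta:
    def test_two_populations_reduces_to_pairwise(self):
        G = balding_nichols(
            SimConfig(n_pops=2, samples_per_pop=25, n_loci=500, fst_per_pop=0.08, seed=83)
        )
        assert global_fst(G) == pytest.approx(pairwise_fst(G, "pop1", "pop2"), abs=1e-12)

    def test_panmictic_near_zero(self):
        G = balding_nichols(
            SimConfig(n_pops=4, samples_per_pop=40, n_loci=2000, fst_per_pop=0.0, seed=84)
        )
        assert global_fst(G) == pytest.approx(0.0, abs=0.01)

    def test_five_population_recovery(self):
        G = balding_nichols(
            SimConfig(n_pops=5, samples_per_pop=40, n_loci=3000, fst_per_pop=0.1, seed=85)
        )
        assert global_fst(G) == pytest.approx(0.10, abs=0.015)


class TestFstPermutation:
    def test_seeded_determinism(self):
        G = balding_nichols(
            SimConfig(n_pops=2, samples_per_pop=15, n_loci=200, fst_per_pop=0.05, seed=86)
        )
        assert fst_permutation_test(G, "pop1", "pop2", n_perm=50, seed=3) == \
            fst_permutation_test(G, "pop1", "pop2", n_perm=50, seed=3)

    def test_power_under_differentiation(self):
        hits = 0
        for s in range(5):
            G = balding_nichols(
                SimConfig(n_pops=2, samples_per_pop=30, n_loci=2000,
                          fst_per_pop=0.05, seed=90 + s)
            )
            _, p = fst_permutation_test(G, "pop1", "pop2", n_perm=99, seed=s)
            hits += p < 0.05
        assert hits == 5

    def test_null_not_significant_mostly(self):
        ps = []
        for s in range(6):
            G = balding_nichols(
                SimConfig(n_pops=2, samples_per_pop=25, n_loci=400,
                          fst_per_pop=0.0, seed=96 + s)
            )
            _, p = fst_permutation_test(G, "pop1", "pop2", n_perm=99, seed=s)
            ps.append(p)
        assert np.mean(np.array(ps) < 0.05) <= 0.5  # loose sanity, not power


class TestFstMatrix:
    def test_symmetry_consistency_and_exclusion(self):
        G = balding_nichols(
            SimConfig(n_pops=3, samples_per_pop=12, n_loci=300, fst_per_pop=0.1, seed=87)
        )
        # shrink pop3 below the size floor
        keep = [s.id for s in G.samples if not (s.population == "pop3" and int(s.id.split("ind")[1]) > 5)]
        G2 = G.subset(sample_ids=keep)
        theta, _ = fst_matrix(G2, min_pop_size=8)
        assert list(theta.index) == ["pop1", "pop2"]  # pop3 (n=5) excluded
        assert theta.loc["pop1", "pop2"] == theta.loc["pop2", "pop1"]
        assert theta.loc["pop1", "pop1"] == 0.0
        assert theta.loc["pop1", "pop2"] == pytest.approx(
            pairwise_fst(G2, "pop1", "pop2"), abs=1e-12
        )


def brute_force_amova(calls_by_pop):
    """Direct-enumeration AMOVA oracle for complete diploid data.

    Computes sums of squares at each level from all pairwise 0/1 allele
    distances within groups, then solves the nested mean-square equations.
    Only valid with no missing genotypes.
    """
    def ss_group(copies):
        k = len(copies)
        return sum(
            (a != b) for a, b in itertools.combinations(copies, 2)
        ) / k

    L = calls_by_pop[0].shape[1]
    r = len(calls_by_pop)
    n_i = [b.shape[0] for b in calls_by_pop]
    N = sum(n_i)
    SSa = SSb = SSc = 0.0
    for l in range(L):
        pops = []
        for b in calls_by_pop:
            copies = []
            for g in b[:, l]:
                copies += [1, 1] if g == 2 else ([0, 1] if g == 1 else [0, 0])
            pops.append(copies)
        allc = [c for p in pops for c in p]
        ss_tot = ss_group(allc)
        ss_wp = sum(ss_group(p) for p in pops)
        ss_wi = sum(
            ss_group(p[2 * i : 2 * i + 2]) for p in pops for i in range(len(p) // 2)
        )
        SSa += ss_tot - ss_wp
        SSb += ss_wp - ss_wi
        SSc += ss_wi
    dfa, dfb, dfc = L * (r - 1), L * (N - r), L * N
    MSa, MSb, MSc = SSa / dfa, SSb / dfb, SSc / dfc
    copies_i = [2 * n for n in n_i]
    C = sum(copies_i)
    n_c = (C - sum(c**2 for c in copies_i) / C) / (r - 1)
    sc = MSc
    sb = (MSb - sc) / 2
    sa = (MSa - sc - 2 * sb) / n_c
    return sa, sb, sc


class TestAmova:
    def test_matches_brute_force_oracle_on_toy(self):
        rng = np.random.default_rng(88)
        blocks = [
            rng.integers(0, 3, size=(3, 2)).astype(np.int8),
            rng.integers(0, 3, size=(3, 2)).astype(np.int8),
        ]
        calls = np.vstack(blocks)
        G = make_matrix(calls, populations=["A"] * 3 + ["B"] * 3)
        res = amova(G)
        sa, sb, sc = brute_force_amova(blocks)
        tot = sa + sb + sc
        assert res.sigma2_among_pops == pytest.approx(sa, abs=1e-9)
        assert res.sigma2_among_ind_within == pytest.approx(sb, abs=1e-9)
        assert res.sigma2_within_ind == pytest.approx(sc, abs=1e-9)
        assert res.pct_among_pops == pytest.approx(100 * sa / tot, abs=1e-9)

    def test_fixed_differences_all_among_populations(self):
        calls = np.vstack([np.zeros((3, 5)), np.full((3, 5), 2)]).astype(np.int8)
        G = make_matrix(calls, populations=["A"] * 3 + ["B"] * 3)
        res = amova(G)
        assert res.pct_among_pops == pytest.approx(100.0)
        assert res.phi_ST == pytest.approx(1.0)

    def test_arbitrary_split_of_panmictic_population(self):
        G = balding_nichols(
            SimConfig(n_pops=1, samples_per_pop=100, n_loci=1000, fst_per_pop=0.0, seed=89)
        )
        pops = ["A"] * 50 + ["B"] * 50
        G2 = make_matrix(G.calls, populations=pops)
        res = amova(G2)
        assert abs(res.pct_among_pops) < 2.0

    def test_percentages_sum_and_phi_vs_global_fst(self):
        G = balding_nichols(
            SimConfig(n_pops=3, samples_per_pop=30, n_loci=1000, fst_per_pop=0.1, seed=90)
        )
        res = amova(G)
        assert res.pct_among_pops + res.pct_among_ind + res.pct_within_ind == pytest.approx(100, abs=1e-6)
        assert res.phi_ST == pytest.approx(global_fst(G), abs=0.01)

    def test_permutation_pvalues_detect_structure(self):
        G = balding_nichols(
            SimConfig(n_pops=2, samples_per_pop=20, n_loci=400, fst_per_pop=0.15, seed=91)
        )
        res = amova(G, n_perm=49, seed=2)
        assert res.p_among == pytest.approx(1 / 50)
        assert 0 < res.p_within_ind <= 1
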