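"""Call-rate/MAF filters, ascertainment-aware MAF, pi-hat, LD pruning."""

import itertools

import numpy as np
import pytest

from breeddiv.genotypes import MISSING, allele_frequencies
from breeddiv.qc import (
    ascertainment_aware_maf_filter,
    build_paper_snp_sets,
    filter_call_rate,
    filter_maf,
    ld_prune_pairwise,
    ld_prune_vif,
    pihat_matrix,
    prune_related,
)
from breeddiv.simulate import SimConfig, balding_nichols, population_frequencies, related_pair
from conftest import make_matrix


class TestCallRateAndMaf:
    def test_call_rate_boundaries(self):
        calls = np.zeros((100, 3), dtype=np.int8)
        calls[:, 1] = 1  # keep polymorphic-ish structure
        calls[:2, 0] = MISSING  # locus 1: rate 0.98 -> removed at 0.99
        G = make_matrix(calls)
        ss, kept = filter_call_rate(G, min_snp_rate=0.99, min_sample_rate=0.90)
        assert "m1" not in ss.locus_ids and {"m2", "m3"} <= set(ss.locus_ids)
        assert len(kept) == 100  # sample rates all >= 0.90

    def test_sample_rate_kept_at_095(self):
        calls = np.ones((2, 20), dtype=np.int8)
        calls[0, 0] = MISSING  # sample rate 0.95 at threshold 0.90 -> kept
        G = make_matrix(calls)
        _, kept = filter_call_rate(G, min_snp_rate=0.0, min_sample_rate=0.90)
        assert kept == ["s1", "s2"]

    def test_complete_matrix_unchanged(self):
        G = make_matrix(np.tile([0, 1, 2], (5, 1)).astype(np.int8))
        ss, kept = filter_call_rate(G)
        assert ss.locus_ids == G.locus_ids and kept == G.sample_ids

    def test_maf_boundary_inclusive_and_monomorphic(self):
        # locus 1: p = 0.05 exactly (2 of 40 copies) -> removed (<=)
        calls = np.zeros((20, 3), dtype=np.int8)
        calls[0, 0] = 2
        calls[:10, 1] = 1  # p = 0.25 -> kept
        G = make_matrix(calls)
        ss = filter_maf(G, min_maf=0.05)
        assert ss.locus_ids == ["m2"]  # m3 monomorphic -> removed

    def test_p_half_kept(self):
        calls = np.array([[1], [1]], dtype=np.int8)
        assert filter_maf(make_matrix(calls), min_maf=0.05).locus_ids == ["m1"]


class TestAscertainmentFilter:
    def _two_pop_toy(self):
        # locus m1: common in discovery pop (p=0.5), rare outside (1/40)
        # locus m2: rare in discovery pop only
        disc = np.zeros((10, 2), dtype=np.int8)
        disc[:, 0] = 1
        disc[0, 1] = 0
        rest = np.zeros((20, 2), dtype=np.int8)
        rest[0, 0] = 1  # p = 1/40 = 0.025 outside discovery
        rest[:, 1] = 1  # common outside
        calls = np.vstack([disc, rest])
        return make_matrix(calls, populations=["disc"] * 10 + ["other"] * 20)

    def test_removed_when_rare_outside_discovery(self):
        G = self._two_pop_toy()
        ss = ascertainment_aware_maf_filter(G, ["disc"], min_maf=0.05)
        assert "m1" not in ss.locus_ids and "m2" in ss.locus_ids

    def test_empty_discovery_reduces_to_pooled_maf(self):
        G = self._two_pop_toy()
        a = ascertainment_aware_maf_filter(G, [], min_maf=0.05)
        b = filter_maf(G, min_maf=0.05)
        assert a.locus_ids == b.locus_ids

    def test_all_populations_discovery_is_error(self):
        G = self._two_pop_toy()
        with pytest.raises(ValueError):
            ascertainment_aware_maf_filter(G, ["disc", "other"])


class TestPiHat:
    @pytest.mark.parametrize(
        "relationship,expected,tol",
        [
            ("duplicate", 1.0, 0.07),
            ("parent_offspring", 0.5, 0.07),
            ("full_sib", 0.5, 0.07),
            ("unrelated", 0.0, 0.07),
        ],
    )
    def test_relationship_classes(self, relationship, expected, tol):
        freqs = population_frequencies(
            SimConfig(n_pops=1, n_loci=2000, fst_per_pop=0.0, seed=21)
        )[0]
        # mean over a few independent pairs: single-pair pi-hat has sampling
        # noise of a few percent at 2,000 loci
        vals = []
        for seed in range(22, 27):
            G = related_pair(freqs, relationship, seed=seed)
            # the generating frequencies play the role of the cohort estimate
            k = pihat_matrix(G, freq_source=freqs)
            vals.append(k.loc[0, "pi_hat"])
        assert np.mean(vals) == pytest.approx(expected, abs=tol)

    def test_ibs_counts_partition_loci(self):
        G = balding_nichols(SimConfig(n_pops=1, samples_per_pop=4, n_loci=300, fst_per_pop=0.0, seed=23))
        k = pihat_matrix(G)
        # polymorphic loci only enter the comparison
        assert ((k.ibs0 + k.ibs1 + k.ibs2) > 200).all()
        assert k.pi_hat.between(-1e-9, 1 + 1e-9).all()

    def test_low_confidence_flag(self):
        G = balding_nichols(SimConfig(n_pops=1, samples_per_pop=2, n_loci=150, fst_per_pop=0.0, seed=24))
        assert not pihat_matrix(G, min_loci=100).low_confidence.any()
        assert pihat_matrix(G, min_loci=10_000).low_confidence.all()


class TestPruneRelated:
    def _kin(self, pairs):
        import pandas as pd

        rows = [
            {"sample_i": a, "sample_j": b, "pi_hat": v} for a, b, v in pairs
        ]
        return pd.DataFrame(rows)

    def test_no_pair_above_threshold_keeps_all(self):
        kin = self._kin([("A", "B", 0.1), ("A", "C", 0.2), ("B", "C", 0.0)])
        assert prune_related(kin) == ["A", "B", "C"]

    def test_triangle_removes_hub_only(self):
        kin = self._kin([("A", "B", 0.6), ("A", "C", 0.6), ("B", "C", 0.1)])
        kept = prune_related(kin)
        # brute force over removal sets of a 3-node graph: {A} is the unique
        # minimal vertex cover of edges {AB, AC}
        assert kept == ["B", "C"]

    def test_single_pair_removes_exactly_one(self):
        kin = self._kin([("A", "B", 0.9)])
        kept = prune_related(kin)
        assert len(kept) == 1 and kept[0] in {"A", "B"}


class TestLdPrunePairwise:
    def test_duplicate_pair_one_survives(self):
        rng = np.random.default_rng(31)
        col = rng.integers(0, 3, size=50).astype(np.int8)
        G = make_matrix(np.column_stack([col, col]))
        ss = ld_prune_pairwise(G, r2_max=0.2)
        assert len(ss) == 1

    def test_independent_loci_all_survive(self):
        G = balding_nichols(
            SimConfig(n_pops=1, samples_per_pop=200, n_loci=40, fst_per_pop=0.0, seed=32)
        )
        ss = ld_prune_pairwise(G, r2_max=0.4)
        assert len(ss) == 40

    def test_three_identical_loci_one_survives(self):
        rng = np.random.default_rng(33)
        col = rng.integers(0, 3, size=60).astype(np.int8)
        G = make_matrix(np.column_stack([col, col, col]))
        # brute force: any removal order on 3 mutually-r2=1 loci keeps 1
        ss = ld_prune_pairwise(G, r2_max=0.2)
        assert len(ss) == 1

    def test_no_retained_pair_exceeds_threshold(self):
        G = balding_nichols(
            SimConfig(n_pops=1, samples_per_pop=60, n_loci=30, fst_per_pop=0.0, seed=34)
        )
        # plant a few correlated columns
        calls = G.calls.copy()
        calls[:, 5] = calls[:, 4]
        calls[:, 11] = np.clip(calls[:, 10], 0, 1)
        G2 = make_matrix(calls)
        r2_max = 0.3
        ss = ld_prune_pairwise(G2, r2_max=r2_max)
        kept_idx = [G2.locus_ids.index(i) for i in ss.locus_ids]
        X = G2.calls[:, kept_idx].astype(float)
        C = np.corrcoef(X.T) ** 2
        np.fill_diagonal(C, 0)
        assert np.nanmax(C) <= r2_max + 1e-9

    def test_idempotent(self):
        G = balding_nichols(
            SimConfig(n_pops=1, samples_per_pop=50, n_loci=30, fst_per_pop=0.0, seed=35)
        )
        once = ld_prune_pairwise(G, r2_max=0.2)
        twice = ld_prune_pairwise(G, once, r2_max=0.2)
        assert once.locus_ids == twice.locus_ids


class TestLdPruneVif:
    def test_duplicate_removed_at_any_threshold(self):
        rng = np.random.default_rng(41)
        col = rng.integers(0, 3, size=50).astype(np.int8)
        G = make_matrix(np.column_stack([col, col]))
        assert len(ld_prune_vif(G, vif_max=100.0)) == 1

    def test_independent_loci_survive(self):
        # n large relative to window size so null R2 (~ (w-1)/n) stays well
        # below the 0.1 the VIF threshold encodes
        G = balding_nichols(
            SimConfig(n_pops=1, samples_per_pop=600, n_loci=15, fst_per_pop=0.0, seed=42)
        )
        assert len(ld_prune_vif(G, vif_max=1 / (1 - 0.1))) == 15

    def test_snp_predicted_by_sum_of_two_removed(self):
        rng = np.random.default_rng(43)
        a = rng.integers(0, 2, size=80).astype(np.int8)
        b = rng.integers(0, 2, size=80).astype(np.int8)
        c = np.clip(a + b, 0, 2).astype(np.int8)  # == a + b (each in {0,1})
        # regression oracle: R^2 of c on (a, b) is 1
        X = np.column_stack([a - a.mean(), b - b.mean()])
        coef, *_ = np.linalg.lstsq(X, c - c.mean(), rcond=None)
        resid = (c - c.mean()) - X @ coef
        assert resid @ resid == pytest.approx(0, abs=1e-18)
        G = make_matrix(np.column_stack([a, b, c]))
        ss = ld_prune_vif(G, vif_max=5.0)
        assert len(ss) == 2


class TestPaperSnpSets:
    def test_monotone_in_r2_threshold_and_provenance(self):
        G = balding_nichols(
            SimConfig(n_pops=3, samples_per_pop=25, n_loci=120, fst_per_pop=0.1,
                      missing_rate=0.002, seed=51)
        )
        sets = build_paper_snp_sets(G, discovery_pops=["pop1"])
        assert len(sets["primary"]) <= len(sets["r2_02"]) <= len(sets["r2_04"])
        for ss in sets.values():
            assert set(ss.locus_ids) <= set(G.locus_ids)
            assert ss.provenance[-1]["filter"].startswith("ld_prune")
        # determinism: rebuild gives identical sets
        again = build_paper_snp_sets(G, discovery_pops=["pop1"])
        assert again["primary"].locus_ids == sets["primary"].locus_ids

    def test_zero_ld_data_sets_equal(self):
        G = balding_nichols(
            SimConfig(n_pops=2, samples_per_pop=150, n_loci=40, fst_per_pop=0.02, seed=52)
        )
        sets = build_paper_snp_sets(G)
        assert (
            sets["primary"].locus_ids
            == sets["r2_02"].locus_ids
            == sets["r2_04"].locus_ids
        )
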