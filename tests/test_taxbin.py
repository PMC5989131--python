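"""LCA binning: complexity filter, score thresholds, min support, rank projection."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings, strategies as st

from benthos import synthio, taxbin
from benthos.taxbin import (NOHITS, UNASSIGNED, BinningParams, ReadHitSet,
                            TaxonomyTree, apply_min_support, lca_assign,
                            profile_at_rank, sequence_complexity)


class TestSequenceComplexity:
    @pytest.mark.parametrize("seq,expected", [
        ("AAAAAAAA", 0.0),                      # homopolymer
        ("ACGTACGT", 1.0),                      # uniform composition
        ("AACC", math.log(2) / math.log(4)),    # entropy of (1/2, 1/2) = log 2
    ])
    def test_known_values(self, seq, expected):
        assert sequence_complexity(seq) == pytest.approx(expected)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            sequence_complexity("")

    @given(st.text(alphabet="ACGT", min_size=1, max_size=60))
    @settings(deadline=None, max_examples=50)
    def test_bounded_in_unit_interval(self, seq):
        assert 0.0 <= sequence_complexity(seq) <= 1.0


class TestLcaAssign:
    def test_top_percent_band_coarsens_to_family(self, small_tree):
        # GenA at 50 and GenB at 48: 48 >= 0.9*50, so the LCA climbs to FamF
        read = ReadHitSet("r1", [(6, 50.0), (7, 48.0)])
        assert lca_assign(read, BinningParams(), small_tree) == 5

    def test_single_hit_is_its_own_assignment(self, small_tree):
        read = ReadHitSet("r1", [(8, 50.0)])
        assert lca_assign(read, BinningParams(), small_tree) == 8

    def test_all_hits_below_min_score_go_to_nohits(self, small_tree):
        read = ReadHitSet("r1", [(6, 20.0), (7, 34.9)])
        assert lca_assign(read, BinningParams(), small_tree) == NOHITS

    def test_weak_second_hit_outside_band_is_ignored(self, small_tree):
        read = ReadHitSet("r1", [(8, 50.0), (10, 40.0)])  # 40 < 0.9*50
        assert lca_assign(read, BinningParams(), small_tree) == 8

    def test_unknown_taxon_raises(self, small_tree):
        with pytest.raises(KeyError):
            lca_assign(ReadHitSet("r1", [(99, 50.0)]), BinningParams(), small_tree)

    def test_order_invariance(self, small_tree, rng):
        hits = [(8, 50.0), (9, 47.0), (10, 46.0), (6, 49.0)]
        base = lca_assign(ReadHitSet("r", hits), BinningParams(), small_tree)
        for perm in itertools.permutations(hits):
            assert lca_assign(ReadHitSet("r", list(perm)), BinningParams(),
                              small_tree) == base

    def test_result_never_below_any_retained_hit(self, small_tree, rng):
        params = BinningParams()
        nodes = list(small_tree.parents)
        for _ in range(200):
            k = rng.integers(1, 6)
            hits = [(int(rng.choice(nodes)), float(rng.uniform(30, 70)))
                    for _ in range(k)]
            res = lca_assign(ReadHitSet("r", hits), params, small_tree)
            if res == NOHITS:
                continue
            scored = [(t, s) for t, s in hits if s >= params.min_score]
            best = max(s for _, s in scored)
            retained = [t for t, s in scored if s >= 0.9 * best]
            for t in retained:
                assert res in small_tree.ancestors(t)

    def test_matches_bruteforce_ancestor_intersection(self, small_tree, rng):
        """Exhaustive oracle: LCA = deepest node in the intersection of the
        retained taxa's ancestor sets."""
        params = BinningParams()
        nodes = list(small_tree.parents)
        for _ in range(300):
            k = int(rng.integers(1, 7))
            hits = [(int(rng.choice(nodes)), float(rng.uniform(36, 70)))
                    for _ in range(k)]
            best = max(s for _, s in hits)
            retained = {t for t, s in hits if s >= 0.9 * best}
            common = set.intersection(*(set(small_tree.ancestors(t))
                                        for t in retained))
            depth = {n: len(small_tree.ancestors(n)) for n in common}
            oracle = max(common, key=lambda n: depth[n])
            assert lca_assign(ReadHitSet("r", hits), params, small_tree) == oracle

    def test_widening_top_percent_band_only_coarsens(self, small_tree, rng):
        """A wider top-percent band retains a superset of hits, so the LCA
        can only move toward the root (or stay put)."""
        nodes = list(small_tree.parents)
        for _ in range(100):
            hits = [(int(rng.choice(nodes)), float(rng.uniform(36, 70)))
                    for _ in range(int(rng.integers(1, 5)))]
            prev = None
            for tp in (0.0, 10.0, 30.0, 100.0):
                res = lca_assign(ReadHitSet("r", hits),
                                 BinningParams(top_percent=tp), small_tree)
                if prev is not None:
                    assert res in small_tree.ancestors(prev)
                prev = res


class TestMinSupport:
    def test_sparse_genus_moves_to_family(self, small_tree):
        # GenA holds 24 (< 25), FamF holds 10: after the pass FamF has 34
        adjusted = apply_min_support({6: 24, 5: 10}, 25, small_tree)
        assert adjusted == {5: 34}

    def test_min_support_one_is_identity(self, small_tree):
        counts = {6: 3, 7: 1, 5: 2}
        assert apply_min_support(counts, 1, small_tree) == counts

    def test_cascade_through_empty_ancestors(self, small_tree):
        # species counts individually below threshold accumulate at genus
        adjusted = apply_min_support({8: 13, 9: 13}, 25, small_tree)
        assert adjusted == {6: 26}

    @given(st.dictionaries(st.sampled_from(list(range(1, 11))),
                           st.integers(0, 40), max_size=10),
           st.integers(1, 30))
    @settings(deadline=None, max_examples=80,
              suppress_health_check=[HealthCheck.function_scoped_fixture])
    def test_total_count_conserved(self, small_tree, counts, min_support):
        before = sum(counts.values())
        after = apply_min_support(counts, min_support, small_tree)
        assert sum(after.values()) == before
        for node, c in after.items():
            if node != small_tree.root:
                assert c >= min_support

    def test_unassigned_variant_conserves_total(self, small_tree):
        after = apply_min_support({8: 5, 10: 40}, 25, small_tree,
                                  to_unassigned=True)
        assert after == {UNASSIGNED: 5, 10: 40}


class TestProfileAtRank:
    def test_species_assignments_aggregate_to_genus(self, small_tree):
        assigns = {"s1": {8: 5, 9: 7, 10: 3}}
        prof = profile_at_rank(assigns, "genus", small_tree)
        assert prof.loc["GenA", "s1"] == 12
        assert prof.loc["GenB", "s1"] == 3

    def test_family_level_read_lands_in_above_rank_audit(self, small_tree):
        prof = profile_at_rank({"s1": {5: 4, 8: 2}}, "genus", small_tree,
                               audit=True)
        assert prof.loc["__above_rank__", "s1"] == 4
        assert prof.loc["GenA", "s1"] == 2

    def test_unknown_rank_rejected(self, small_tree):
        with pytest.raises(ValueError):
            profile_at_rank({}, "tribe", small_tree)

    def test_zero_noise_simulation_roundtrip(self):
        """With no decoys/no-hits/low-complexity reads, binning at species
        rank reproduces the ground-truth count matrix exactly."""
        md = synthio.generate_metadata(1)
        params = synthio.SimulationParams(n_reps=1, n_taxa=25,
                                          library_sizes=400, seed=11)
        truth, hits, reads, tree = synthio.generate_profiles_and_hits(md, params)
        bp = BinningParams(min_support=1)
        assigns = {sid: taxbin.bin_reads(rs, bp, tree)
                   for sid, rs in synthio.hits_to_readsets(hits, reads)}
        for rank in ("species", "genus", "phylum"):
            prof = profile_at_rank(assigns, rank, tree).loc[:, md.index]
            spp = sorted(n for n in tree.parents if tree.rank_of(n) == "species")
            up = {tree.names[s]: tree.names[tree.ancestor_at_rank(s, rank)]
                  for s in spp}
            expected = truth.groupby(truth.index.map(up)).sum()
            expected = expected.loc[prof.index, md.index]
            assert (prof.values == expected.values).all()


def test_complexity_filter_diverts_reads_before_lca(small_tree):
    reads = [ReadHitSet("r1", [(8, 50.0)], complexity=0.2),
             ReadHitSet("r2", [(8, 50.0)], complexity=0.9)]
    counts = taxbin.bin_reads(reads, BinningParams(min_support=1), small_tree)
    assert counts == {UNASSIGNED: 1, 8: 1}


def test_taxonomy_table_roundtrip(small_tree):
    rebuilt = TaxonomyTree.from_table(small_tree.to_table())
    assert rebuilt.parents == small_tree.parents
    assert rebuilt.ranks == small_tree.ranks
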