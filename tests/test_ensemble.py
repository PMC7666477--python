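import io
import math
from dataclasses import replace

import numpy as np
import pytest

import pankov as pk
from pankov.ensemble import read_probabilities_tsv, write_probabilities_tsv
from pankov.structures import build_tree, pseudo_root

from helpers import enumeration_stats, random_rna


def seq(residues: str) -> pk.RnaSequence:
    return pk.RnaSequence("t", residues)


@pytest.fixture(scope="module")
def small_cohort(params):
    """Seeded sequences with full enumeration statistics and DP tables."""
    rng = np.random.default_rng(417)
    cohort = []
    for _ in range(6):
        s = random_rna(rng, int(rng.integers(10, 15)))
        cohort.append(
            (s, pk.compute_ensemble(s, params), enumeration_stats(s, params))
        )
    return cohort


class TestPartitionFunction:
    def test_unpairable_sequence_is_trivial(self, params):
        t = pk.compute_ensemble(seq("AAAA"), params)
        assert t.Z == 1.0
        assert t.P_pair == {} and t.candidates == ()
        assert t.ensemble_energy == 0.0

    def test_two_structure_closed_form(self, params):
        p0 = replace(params, min_hairpin=0)
        t = pk.compute_ensemble(seq("GC"), p0)
        w = math.exp(-p0.hairpin_penalty(0) / p0.rt)
        assert t.Z == pytest.approx(1 + w, rel=1e-14)
        assert t.P_pair[(1, 2)] == pytest.approx(w / (1 + w), rel=1e-14)

    def test_matches_enumeration_oracle(self, small_cohort):
        for _, t, stats in small_cohort:
            assert t.Z == pytest.approx(stats.Z, rel=1e-10)
            for c in t.candidates:
                assert t.P_pair[c] == pytest.approx(
                    stats.P_pair.get(c, 0.0), rel=1e-10, abs=1e-13
                )
                assert t.P_ext[c] == pytest.approx(
                    stats.P_ext.get(c, 0.0), rel=1e-10, abs=1e-13
                )
            for key, v in t.P_joint.items():
                assert v == pytest.approx(
                    stats.P_joint.get(key, 0.0), rel=1e-10, abs=1e-13
                )

    def test_parent_partition_identity(self, small_cohort):
        for _, t, _ in small_cohort:
            for c in t.candidates:
                total = t.P_ext[c] + sum(
                    v for (par, child), v in t.P_joint.items() if child == c
                )
                assert total == pytest.approx(t.P_pair[c], rel=1e-10, abs=1e-13)

    def test_ensemble_energy_is_minus_rt_log_z(self, small_cohort):
        for _, t, _ in small_cohort:
            assert t.ensemble_energy == pytest.approx(
                -t.params.rt * math.log(t.Z), rel=1e-12
            )

    def test_probabilities_lie_in_unit_interval(self, small_cohort):
        for _, t, _ in small_cohort:
            values = (
                list(t.P_pair.values())
                + list(t.P_ext.values())
                + list(t.P_joint.values())
                + list(t.P_cond.values())
            )
            assert all(-1e-15 <= v <= 1 + 1e-12 for v in values)

    def test_locality_when_appending_unpairable_tail(self, params):
        # no U residues, so appended A's cannot form any new pair
        base = "GGGCAAAGCCC"
        t1 = pk.compute_ensemble(seq(base), params)
        t2 = pk.compute_ensemble(seq(base + "AAAA"), params)
        for c in t1.candidates:
            assert t2.P_pair[c] == pytest.approx(t1.P_pair[c], rel=1e-12)


class TestConditionalLoopProbability:
    def test_trivial_external_loop(self, params):
        t = pk.compute_ensemble(seq("AAAA"), params)
        assert pk.conditional_loop_probability(t, pseudo_root(4), []) == 1.0

    def test_sole_content_hairpin(self, params):
        p0 = replace(params, min_hairpin=0)
        t = pk.compute_ensemble(seq("GC"), p0)
        assert pk.conditional_loop_probability(t, (1, 2), []) == pytest.approx(1.0)

    def test_matches_enumeration(self, small_cohort):
        for s, t, stats in small_cohort:
            # every loop realized in some structure, conditioned on its closing pair
            seen = set()
            for structure, p in zip(stats.structures, stats.probabilities):
                tree = build_tree(structure)
                for node in tree.nodes():
                    key = (node, tree.children[node])
                    if key in seen:
                        continue
                    seen.add(key)
                    num = sum(
                        q
                        for other, q in zip(stats.structures, stats.probabilities)
                        if _realizes(other, node, tree.children[node], len(s))
                    )
                    if node == pseudo_root(len(s)):
                        den = 1.0
                    else:
                        den = stats.P_pair[node.astuple()]
                    assert pk.conditional_loop_probability(
                        t, node, tree.children[node]
                    ) == pytest.approx(num / den, rel=1e-10)

    def test_inloop_conditional_overestimates_exact_loop(self, small_cohort):
        # the in-loop conditional also counts multiloop contexts
        for _, t, _ in small_cohort:
            for (parent, child), cond in t.P_cond.items():
                exact = pk.conditional_loop_probability(t, parent, [child])
                assert cond >= exact - 1e-12


def _realizes(structure, closing, children, n):
    tree = build_tree(structure)
    if closing == pseudo_root(n):
        return tree.children[tree.root] == children
    return closing in tree.parent and tree.children[closing] == children


class TestStructureProbability:
    def test_empty_structure_on_unpairable_sequence(self, params):
        s = seq("AAAA")
        t = pk.compute_ensemble(s, params)
        empty = pk.SecondaryStructure(s, frozenset())
        assert pk.structure_probability_exact(t, empty) == 1.0

    def test_factorization_equals_boltzmann_probability(self, small_cohort):
        for _, t, stats in small_cohort:
            for structure, e in zip(stats.structures, stats.energies):
                direct = math.exp(-e / t.params.rt) / t.Z
                assert pk.structure_probability_exact(t, structure) == pytest.approx(
                    direct, rel=1e-10
                )

    def test_probabilities_sum_to_one(self, small_cohort):
        for _, t, stats in small_cohort:
            total = sum(
                pk.structure_probability_exact(t, structure)
                for structure in stats.structures
            )
            assert total == pytest.approx(1.0, rel=1e-10)

    def test_unknown_pair_rejected(self, params):
        s = seq("GGGAAACCCC")
        t = pk.compute_ensemble(s, params)
        bogus = pk.SecondaryStructure(s, frozenset({pk.BasePair(1, 4)}))
        with pytest.raises(ValueError):
            pk.structure_probability_exact(t, bogus)


class TestTsvExport:
    def test_round_trip(self, params):
        s = seq("GGGCAAAGCCCAU")
        t = pk.compute_ensemble(s, params)
        buf = io.StringIO()
        write_probabilities_tsv(t, buf)
        buf.seek(0)
        parsed = read_probabilities_tsv(buf)
        assert parsed["pair"] == t.P_pair
        assert parsed["external"] == t.P_ext
        assert parsed["conditional"] == t.P_cond
        assert parsed["joint"] == t.P_joint
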