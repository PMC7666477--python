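import math
from dataclasses import replace

import numpy as np
import pytest

import pankov as pk
from pankov.aligner import build_candidates

from helpers import nw_score, oracle_alignment_score, random_rna


@pytest.fixture(scope="module")
def homolog(params):
    spec = pk.FixtureSpec(
        seed=31, length_range=(26, 32), mutation_rate=0.15, indel_rate=0.05,
        stem_length=5,
    )
    pair = pk.make_pair(spec, 1)
    t_a = pk.compute_ensemble(pair.seq_a, params)
    t_b = pk.compute_ensemble(pair.seq_b, params)
    return pair, t_a, t_b


class TestCandidates:
    def test_threshold_above_one_excludes_everything(self, params):
        s = pk.RnaSequence("s", "GGGCAAAGCCC")
        t = pk.compute_ensemble(s, params)
        c = build_candidates(t, 1.1, 1.1)
        assert c.pairs == ()
        assert c.children[c.root] == ()

    def test_zero_thresholds_admit_all_candidates(self, params):
        s = pk.RnaSequence("s", "GGGCAAAGCCC")
        t = pk.compute_ensemble(s, params)
        c = build_candidates(t, 0.0, 0.0)
        assert set(c.pairs) == set(t.candidates)

    def test_default_thresholds_sparsify(self, params, rng):
        s = random_rna(rng, 60)
        t = pk.compute_ensemble(s, params)
        c = build_candidates(t, 1e-3, 1e-4)
        n = len(s)
        assert 0 < len(c.pairs) < n * n / 2
        counts = [
            len(build_candidates(t, theta, 1e-4).pairs)
            for theta in (0.0, 1e-4, 1e-3, 1e-2, 1e-1)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_every_listed_pair_honours_its_threshold(self, params, rng):
        s = random_rna(rng, 40)
        t = pk.compute_ensemble(s, params)
        c = build_candidates(t, 1e-3, 1e-4)
        assert all(t.P_pair[p] >= 1e-3 for p in c.pairs)
        for parent, kids in c.children.items():
            for child in kids:
                if parent == c.root:
                    assert t.P_ext[child] >= 1e-4
                else:
                    assert t.P_joint[(parent, child)] >= 1e-4


class TestDegenerateAndSelfAlignment:
    def test_sequence_only_alignment_matches_needleman_wunsch(
        self, params, score_cfg, rng
    ):
        # A/C-only sequences admit no base pair at all
        for _ in range(4):
            a = random_rna(rng, int(rng.integers(8, 16)), letters="AC")
            b = random_rna(rng, int(rng.integers(8, 16)), letters="AC")
            t_a = pk.compute_ensemble(a, params)
            t_b = pk.compute_ensemble(b, params)
            r = pk.align(a, b, t_a, t_b, score_cfg)
            assert r.structure_a.pairs == frozenset() == r.structure_b.pairs
            assert r.total_score == pytest.approx(
                nw_score(a.residues, b.residues, score_cfg.sigma, score_cfg.gamma)
            )

    def test_self_alignment_is_gapless_with_shared_structure(
        self, params, score_cfg, rng
    ):
        s = random_rna(rng, 40)
        t = pk.compute_ensemble(s, params)
        r = pk.align(s, s, t, t, score_cfg)
        assert r.n_indel == 0
        assert [e[0] for e in r.edges] == [e[1] for e in r.edges]
        assert r.structure_a.pairs == r.structure_b.pairs
        expected = sum(
            score_cfg.sigma(c, c) for c in s.residues
        ) + 2 * pk.pankov_score(t, r.structure_a, score_cfg)
        assert r.total_score == pytest.approx(expected, abs=1e-9)


class TestOptimality:
    def test_matches_brute_force_over_all_triples(self, params, score_cfg):
        rng = np.random.default_rng(5150)
        for _ in range(6):
            a = random_rna(rng, int(rng.integers(8, 11)))
            b = random_rna(rng, int(rng.integers(8, 11)))
            t_a = pk.compute_ensemble(a, params)
            t_b = pk.compute_ensemble(b, params)
            r = pk.align(a, b, t_a, t_b, score_cfg, theta=0.0, theta_prime=0.0)
            best = oracle_alignment_score(
                a, b, t_a, t_b, score_cfg, params.min_hairpin
            )
            assert r.total_score == pytest.approx(best, abs=1e-9)


class TestRescore:
    def test_rescore_equals_total_score(self, homolog, score_cfg):
        pair, t_a, t_b = homolog
        for l_d in (0, 12):
            r = pk.align(pair.seq_a, pair.seq_b, t_a, t_b, score_cfg, l_d=l_d)
            assert pk.rescore(r, t_a, t_b, score_cfg) == pytest.approx(
                r.total_score, abs=1e-9
            )
            assert r.total_score == pytest.approx(
                r.sequence_score + r.structure_score + r.indel_score, abs=1e-9
            )

    def test_dropping_a_pair_changes_the_score(self, homolog, score_cfg):
        pair, t_a, t_b = homolog
        r = pk.align(pair.seq_a, pair.seq_b, t_a, t_b, score_cfg)
        assert len(r.structure_a) > 0
        smaller = pk.SecondaryStructure(
            pair.seq_a, frozenset(sorted(r.structure_a.pairs)[1:])
        )
        mutated = replace(r, structure_a=smaller)
        assert pk.rescore(mutated, t_a, t_b, score_cfg) != pytest.approx(
            r.total_score, abs=1e-9
        )

    def test_non_monotone_edges_rejected(self, homolog, score_cfg):
        pair, t_a, t_b = homolog
        r = pk.align(pair.seq_a, pair.seq_b, t_a, t_b, score_cfg)
        bad = replace(r, edges=((1, 2), (2, 1)) + r.edges[2:])
        with pytest.raises(ValueError):
            pk.rescore(bad, t_a, t_b, score_cfg)


class TestBehaviouralProperties:
    def test_score_symmetric_under_argument_swap(self, homolog, score_cfg):
        pair, t_a, t_b = homolog
        r_ab = pk.align(pair.seq_a, pair.seq_b, t_a, t_b, score_cfg)
        r_ba = pk.align(pair.seq_b, pair.seq_a, t_b, t_a, score_cfg)
        assert r_ab.total_score == pytest.approx(r_ba.total_score, abs=1e-9)
        # the mirrored solution realizes the same optimum
        mirrored = pk.AlignmentResult(
            seq_a=pair.seq_b,
            seq_b=pair.seq_a,
            edges=tuple(sorted((k, i) for i, k in r_ab.edges)),
            n_indel=r_ab.n_indel,
            structure_a=r_ab.structure_b,
            structure_b=r_ab.structure_a,
            total_score=r_ab.total_score,
            sequence_score=r_ab.sequence_score,
            structure_score=r_ab.structure_score,
            indel_score=r_ab.indel_score,
        )
        assert pk.rescore(mirrored, t_b, t_a, score_cfg) == pytest.approx(
            r_ba.total_score, abs=1e-9
        )

    def test_score_never_increases_with_thresholds(self, homolog, score_cfg):
        pair, t_a, t_b = homolog
        scores = [
            pk.align(
                pair.seq_a, pair.seq_b, t_a, t_b, score_cfg,
                theta=theta, theta_prime=tp,
            ).total_score
            for theta, tp in [(0.0, 0.0), (1e-3, 1e-4), (1e-2, 1e-3), (0.2, 0.1)]
        ]
        assert all(s1 >= s2 - 1e-12 for s1, s2 in zip(scores, scores[1:]))

    def test_domain_indels_off_reproduces_base_recursion(self, homolog, score_cfg):
        pair, t_a, t_b = homolog
        r0 = pk.align(pair.seq_a, pair.seq_b, t_a, t_b, score_cfg, l_d=0)
        r0_again = pk.align(pair.seq_a, pair.seq_b, t_a, t_b, score_cfg, l_d=0)
        assert r0.total_score == r0_again.total_score
        assert r0.edges == r0_again.edges
        for l_d in (5, 10, 20):
            r = pk.align(pair.seq_a, pair.seq_b, t_a, t_b, score_cfg, l_d=l_d)
            assert r.total_score >= r0.total_score - 1e-12

    def test_mismatched_parameterizations_rejected(self, params, score_cfg, rng):
        a = random_rna(rng, 12)
        b = random_rna(rng, 12)
        other = replace(params, multiloop_closing=9.9)
        t_a = pk.compute_ensemble(a, params)
        t_b = pk.compute_ensemble(b, other)
        with pytest.raises(ValueError):
            pk.align(a, b, t_a, t_b, score_cfg)

    def test_tables_must_match_sequences(self, params, score_cfg, rng):
        a = random_rna(rng, 12)
        b = random_rna(rng, 12)
        t_a = pk.compute_ensemble(a, params)
        with pytest.raises(ValueError):
            pk.align(a, b, t_a, t_a, score_cfg)
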