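"""Independent oracles shared by the test suite.

Everything here recomputes quantities by a route independent of the
implementation under test: exhaustive enumeration with Boltzmann weighting
for ensemble quantities, a counting recursion for structure counts, plain
Needleman-Wunsch for sequence-only alignment, and an enumerate-everything
search over (structure, structure, pair-matching) triples for the
alignment-and-folding optimum.
"""

from __future__ import annotations

import itertools
import math
from collections import defaultdict
from dataclasses import dataclass

import numpy as np

import pankov as pk
from pankov.structures import COMPLEMENTARY, build_tree, pseudo_root

NEG_INF = float("-inf")


def random_rna(rng: np.random.Generator, n: int, letters: str = "ACGU") -> pk.RnaSequence:
    return pk.RnaSequence(f"rand{n}", "".join(rng.choice(list(letters), size=n)))


def nussinov_count(seq: pk.RnaSequence, min_hairpin: int) -> int:
    """Count non-crossing structures by an independent counting recursion."""
    res = seq.residues
    n = len(res)
    memo: dict[tuple[int, int], int] = {}

    def count(i: int, j: int) -> int:
        if i > j:
            return 1
        if (i, j) in memo:
            return memo[(i, j)]
        total = count(i + 1, j)
        for k in range(i + min_hairpin + 1, j + 1):
            if (res[i - 1], res[k - 1]) in COMPLEMENTARY:
                total += count(i + 1, k - 1) * count(k + 1, j)
        memo[(i, j)] = total
        return total

    return count(1, n)


@dataclass
class EnumerationStats:
    """Exhaustive Boltzmann sums of one sequence."""

    structures: list
    energies: list[float]
    Z: float
    P_pair: dict
    P_joint: dict
    P_ext: dict
    probabilities: list[float]


def enumeration_stats(seq: pk.RnaSequence, params: pk.EnergyParameters) -> EnumerationStats:
    structures = pk.enumerate_structures(seq, params.min_hairpin)
    energies = [pk.structure_energy(params, s) for s in structures]
    weights = [math.exp(-e / params.rt) for e in energies]
    z = sum(weights)
    probs = [w / z for w in weights]
    pp: dict = defaultdict(float)
    pj: dict = defaultdict(float)
    pe: dict = defaultdict(float)
    root = pseudo_root(len(seq))
    for s, p in zip(structures, probs):
        tree = build_tree(s)
        for pair, parent in tree.parent.items():
            pp[pair.astuple()] += p
            if parent == root:
                pe[pair.astuple()] += p
            else:
                pj[(parent.astuple(), pair.astuple())] += p
    return EnumerationStats(structures, energies, z, dict(pp), dict(pj), dict(pe), probs)


def nw_score(xa: str, xb: str, sig, g: float) -> float:
    """Plain global alignment with linear gap costs."""
    la, lb = len(xa), len(xb)
    m = [[0.0] * (lb + 1) for _ in range(la + 1)]
    for i in range(1, la + 1):
        m[i][0] = i * g
    for k in range(1, lb + 1):
        m[0][k] = k * g
    for i in range(1, la + 1):
        for k in range(1, lb + 1):
            m[i][k] = max(
                m[i - 1][k - 1] + sig(xa[i - 1], xb[k - 1]),
                m[i - 1][k] + g,
                m[i][k - 1] + g,
            )
    return m[la][lb]


def oracle_alignment_score(
    seq_a: pk.RnaSequence,
    seq_b: pk.RnaSequence,
    t_a: pk.EnsembleTables,
    t_b: pk.EnsembleTables,
    cfg: pk.ScoreConfig,
    min_hairpin: int,
) -> float:
    """Exhaustive optimum over (structure_A, structure_B, pair matching).

    For each structure pair and each injective matching between their base
    pairs, the matching is realized recursively over the two loop trees: a
    loop pair either matches its children one-to-one in order (unpaired
    segments aligned by Needleman-Wunsch), or deletes a sole unmatched
    child (its flank and both endpoints charged as gaps) and descends.
    In-loop Phi terms are charged for every pair of both structures.
    Matchings that cannot be realized score minus infinity.
    """
    g = cfg.gamma
    sig = cfg.sigma
    ra, rb = seq_a.residues, seq_b.residues
    best = NEG_INF
    structures_a = pk.enumerate_structures(seq_a, min_hairpin)
    structures_b = pk.enumerate_structures(seq_b, min_hairpin)
    for sa in structures_a:
        tree_a = build_tree(sa)
        phi_a = sum(
            math.log(t_a.inloop_conditional(par, p)) + cfg.beta
            for p, par in tree_a.parent.items()
        )
        pairs_a = sorted(sa.pairs)
        for sb in structures_b:
            tree_b = build_tree(sb)
            phi_b = sum(
                math.log(t_b.inloop_conditional(par, p)) + cfg.beta
                for p, par in tree_b.parent.items()
            )
            pairs_b = sorted(sb.pairs)
            for k in range(0, min(len(pairs_a), len(pairs_b)) + 1):
                for subset in itertools.combinations(pairs_a, k):
                    for image in itertools.permutations(pairs_b, k):
                        matching = dict(zip(subset, image))
                        matched_b = set(image)

                        def realize(a, b):
                            ch_a = tree_a.children[a]
                            ch_b = tree_b.children[b]
                            opts = []
                            if len(ch_a) == 1 and ch_a[0] not in matching:
                                u = ch_a[0]
                                cost = (
                                    u.left - a.left + 1 + (a.right - 1 - u.right)
                                ) * g
                                opts.append(cost + realize(u, b))
                            if len(ch_b) == 1 and ch_b[0] not in matched_b:
                                u = ch_b[0]
                                cost = (
                                    u.left - b.left + 1 + (b.right - 1 - u.right)
                                ) * g
                                opts.append(cost + realize(a, u))
                            if all(c in matching for c in ch_a):
                                img = [matching[c] for c in ch_a]
                                if img == list(ch_b):
                                    sc = 0.0
                                    prev_a, prev_b = a.left, b.left
                                    for c, d in zip(ch_a, ch_b):
                                        sc += nw_score(
                                            ra[prev_a : c.left - 1],
                                            rb[prev_b : d.left - 1],
                                            sig,
                                            g,
                                        )
                                        sc += sig(ra[c.left - 1], rb[d.left - 1])
                                        sc += sig(ra[c.right - 1], rb[d.right - 1])
                                        sc += realize(c, d)
                                        prev_a, prev_b = c.right, d.right
                                    sc += nw_score(
                                        ra[prev_a : a.right - 1],
                                        rb[prev_b : b.right - 1],
                                        sig,
                                        g,
                                    )
                                    opts.append(sc)
                            return max(opts) if opts else NEG_INF

                        v = realize(pseudo_root(len(seq_a)), pseudo_root(len(seq_b)))
                        if v > NEG_INF:
                            best = max(best, phi_a + phi_b + v)
    return best
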