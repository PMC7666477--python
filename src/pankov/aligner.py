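"""Sparsified simultaneous alignment and folding of two RNA sequences.

The dynamic program matches candidate base pairs of the two sequences and
aligns the loops they enclose.  For every pair of candidate pairs ``(a, b)``
a matrix ``M`` holds the best score of aligning the loop contents, with
four cases: residue match (sigma), gap in either sequence (gamma), and
closing a matched child pair pair, which adds the child's ``D`` entry, the
similarity of the child's ends and the in-loop scores ``Phi(a, a1)`` and
``Phi(b, b1)``.  The ``I_A`` / ``I_B`` vectors delete (insert) a base pair
in one sequence only: the deleted pair's ends and left flank are charged as
gaps while its loop is aligned against the partner loop.  With ``l_d > 0``
two extra ``M`` cases delete an entire structural branch (span bounded by
``l_d``) against a gap.

Sparsification: only pairs with ``P(pair) >= theta`` participate, and a
child is considered under a parent only if their joint in-loop probability
reaches ``theta_prime`` (external pairs: ``P_ext >= theta_prime`` under the
pseudo root).  The pseudo roots of both sequences are treated like ordinary
closing pairs, so the recursion is uniform from the external loop down.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from .ensemble import EnsembleTables
from .scoring import ScoreConfig
from .structures import BasePair, RnaSequence, SecondaryStructure, build_tree

Pair = tuple[int, int]
NEG_INF = float("-inf")

#: Sparsification defaults: minimal significant pair probability and minimal
#: joint in-loop probability.
DEFAULT_THETA = 1e-3
DEFAULT_THETA_PRIME = 1e-4


@dataclass(frozen=True)
class SparseCandidates:
    """Threshold-filtered candidate pairs and parent-child lists of one sequence."""

    n: int
    theta: float
    theta_prime: float
    pairs: tuple[Pair, ...]
    by_right: Mapping[int, tuple[Pair, ...]]
    children: Mapping[Pair, tuple[Pair, ...]]
    cond: Mapping[tuple[Pair, Pair], float]

    @property
    def root(self) -> Pair:
        return (0, self.n + 1)


def build_candidates(
    t: EnsembleTables, theta: float, theta_prime: float
) -> SparseCandidates:
    """Filter the ensemble of one sequence by ``theta`` / ``theta_prime``.

    The pseudo root is always a valid parent; its children are the
    candidates whose external probability reaches ``theta_prime``.
    """
    n = len(t.sequence)
    root = (0, n + 1)
    pairs = tuple(
        sorted(
            (p for p in t.candidates if t.P_pair[p] >= theta),
            key=lambda p: (p[1] - p[0], p),
        )
    )
    by_right: dict[int, list[Pair]] = {}
    for p in sorted(pairs):
        by_right.setdefault(p[1], []).append(p)
    children: dict[Pair, tuple[Pair, ...]] = {}
    cond: dict[tuple[Pair, Pair], float] = {}
    ext_kids = tuple(sorted(p for p in pairs if t.P_ext[p] >= theta_prime))
    children[root] = ext_kids
    for c in ext_kids:
        cond[(root, c)] = t.P_ext[c]
    for parent in pairs:
        kids = []
        for c in pairs:
            if parent[0] < c[0] and c[1] < parent[1]:
                if t.P_joint[(parent, c)] >= theta_prime:
                    kids.append(c)
                    cond[(parent, c)] = t.P_cond[(parent, c)]
        children[parent] = tuple(sorted(kids))
    return SparseCandidates(
        n=n,
        theta=theta,
        theta_prime=theta_prime,
        pairs=pairs,
        by_right={k: tuple(v) for k, v in by_right.items()},
        children=children,
        cond=cond,
    )


@dataclass(frozen=True)
class AlignmentResult:
    """Joint alignment and per-sequence structure prediction.

    ``edges`` are matched position pairs (1-based, strictly increasing in
    both coordinates); ``n_indel`` counts gapped positions of both
    sequences.  ``total_score`` is the DP optimum; the three components
    (sequence similarity, structure Phi terms, gap cost) are recomputed
    from the explicit result and sum to it.
    """

    seq_a: RnaSequence
    seq_b: RnaSequence
    edges: tuple[tuple[int, int], ...]
    n_indel: int
    structure_a: SecondaryStructure
    structure_b: SecondaryStructure
    total_score: float
    sequence_score: float
    structure_score: float
    indel_score: float


class _Dp:
    """Shared state of one alignment run (forward fill + traceback)."""

    def __init__(self, seq_a, seq_b, ca, cb, cfg, l_d):
        self.res_a = seq_a.residues
        self.res_b = seq_b.residues
        self.ca = ca
        self.cb = cb
        self.sig = cfg.sigma
        self.g = cfg.gamma
        self.l_d = l_d
        beta = cfg.beta
        self.phi_a = {
            k: math.log(v) + beta for k, v in ca.cond.items()
        }
        self.phi_b = {
            k: math.log(v) + beta for k, v in cb.cond.items()
        }
        # per parent: children grouped by right end, ordered by left end
        self.kids_a = self._group(ca)
        self.kids_b = self._group(cb)
        self.D: dict[tuple[Pair, Pair], float] = {}

    @staticmethod
    def _group(c: SparseCandidates) -> dict[Pair, dict[int, tuple[Pair, ...]]]:
        out: dict[Pair, dict[int, tuple[Pair, ...]]] = {}
        for parent, kids in c.children.items():
            g: dict[int, list[Pair]] = {}
            for k in kids:
                g.setdefault(k[1], []).append(k)
            out[parent] = {r: tuple(v) for r, v in g.items()}
        return out

    # -- forward -----------------------------------------------------------

    def fill(self, a: Pair, b: Pair):
        """Compute the M / I_A / I_B tables of the loop pair ``(a, b)``."""
        aL, aR = a
        bL, bR = b
        wa, wb = aR - aL, bR - bL
        sig, g, D = self.sig, self.g, self.D
        res_a, res_b = self.res_a, self.res_b
        ch_a = self.kids_a.get(a, {})
        ch_b = self.kids_b.get(b, {})
        phi_a, phi_b = self.phi_a, self.phi_b
        l_d = self.l_d

        M = [[0.0] * wb for _ in range(wa)]
        row0 = M[0]
        for ki in range(1, wb):
            row0[ki] = ki * g
        for ii in range(1, wa):
            i = aL + ii
            row = M[ii]
            prev = M[ii - 1]
            row[0] = ii * g
            xa = res_a[i - 1]
            a_kids = ch_a.get(i)
            for ki in range(1, wb):
                k = bL + ki
                xb = res_b[k - 1]
                best = prev[ki - 1] + sig(xa, xb)
                v = prev[ki] + g
                if v > best:
                    best = v
                v = row[ki - 1] + g
                if v > best:
                    best = v
                if a_kids:
                    b_kids = ch_b.get(k)
                    if b_kids:
                        end_sig = sig(xa, xb)
                        for a1 in a_kids:
                            pa = phi_a[(a, a1)]
                            ma = M[a1[0] - 1 - aL]
                            left_a = res_a[a1[0] - 1]
                            for b1 in b_kids:
                                v = (
                                    ma[b1[0] - 1 - bL]
                                    + D[(a1, b1)]
                                    + sig(left_a, res_b[b1[0] - 1])
                                    + end_sig
                                    + pa
                                    + phi_b[(b, b1)]
                                )
                                if v > best:
                                    best = v
                if l_d > 0:
                    if a_kids:
                        for a1 in a_kids:
                            span = a1[1] - a1[0]
                            if span < l_d:
                                v = (
                                    M[a1[0] - 1 - aL][ki]
                                    + (span + 1) * g
                                    + phi_a[(a, a1)]
                                )
                                if v > best:
                                    best = v
                    b_kids = ch_b.get(k)
                    if b_kids:
                        for b1 in b_kids:
                            span = b1[1] - b1[0]
                            if span < l_d:
                                v = (
                                    row[b1[0] - 1 - bL]
                                    + (span + 1) * g
                                    + phi_b[(b, b1)]
                                )
                                if v > best:
                                    best = v
                row[ki] = best

        IA = [NEG_INF] * wa
        for ii in range(1, wa):
            i = aL + ii
            v = IA[ii - 1] + g
            for a1 in ch_a.get(i, ()):
                w = (a1[0] - aL + 1) * g + D[(a1, b)] + phi_a[(a, a1)]
                if w > v:
                    v = w
            IA[ii] = v
        IB = [NEG_INF] * wb
        for ki in range(1, wb):
            k = bL + ki
            v = IB[ki - 1] + g
            for b1 in ch_b.get(k, ()):
                w = (b1[0] - bL + 1) * g + D[(a, b1)] + phi_b[(b, b1)]
                if w > v:
                    v = w
            IB[ki] = v
        return M, IA, IB

    def run(self):
        """Fill D bottom-up over candidate-pair pairs ordered by span."""
        list_a = list(self.ca.pairs) + [self.ca.root]
        list_b = list(self.cb.pairs) + [self.cb.root]
        for a in list_a:
            for b in list_b:
                M, IA, IB = self.fill(a, b)
                self.D[(a, b)] = max(M[-1][-1], IA[-1], IB[-1])
        return self.D[(self.ca.root, self.cb.root)]

    # -- traceback ---------------------------------------------------------

    def traceback(self):
        self.edges: list[tuple[int, int]] = []
        self.gaps = 0
        self.pairs_a: set[Pair] = set()
        self.pairs_b: set[Pair] = set()
        self._trace_d(self.ca.root, self.cb.root)
        return sorted(self.edges), self.gaps, self.pairs_a, self.pairs_b

    def _trace_d(self, a: Pair, b: Pair) -> None:
        M, IA, IB = self.fill(a, b)
        d = self.D[(a, b)]
        if d == M[-1][-1]:
            self._trace_m(a, b, M, len(M) - 1, len(M[0]) - 1)
        elif d == IA[-1]:
            self._trace_i(a, b, IA, len(IA) - 1, which="A")
        elif d == IB[-1]:
            self._trace_i(a, b, IB, len(IB) - 1, which="B")
        else:  # pragma: no cover - internal consistency
            raise RuntimeError(f"traceback failed at D{(a, b)}")

    def _trace_m(self, a: Pair, b: Pair, M, ii: int, ki: int) -> None:
        aL = a[0]
        bL = b[0]
        sig, g = self.sig, self.g
        res_a, res_b = self.res_a, self.res_b
        ch_a = self.kids_a.get(a, {})
        ch_b = self.kids_b.get(b, {})
        while ii > 0 or ki > 0:
            i = aL + ii
            k = bL + ki
            cur = M[ii][ki]
            if (
                ii > 0
                and ki > 0
                and cur == M[ii - 1][ki - 1] + sig(res_a[i - 1], res_b[k - 1])
            ):
                self.edges.append((i, k))
                ii -= 1
                ki -= 1
                continue
            if ii > 0 and cur == M[ii - 1][ki] + g:  # gap character in B
                self.gaps += 1
                ii -= 1
                continue
            if ki > 0 and cur == M[ii][ki - 1] + g:  # gap character in A
                self.gaps += 1
                ki -= 1
                continue
            hit = self._trace_pair_match(a, b, M, ii, ki, ch_a, ch_b)
            if hit is None:  # pragma: no cover - internal consistency
                raise RuntimeError(f"traceback failed in M{(a, b)} at {(ii, ki)}")
            ii, ki = hit

    def _trace_pair_match(self, a, b, M, ii, ki, ch_a, ch_b):
        aL = a[0]
        bL = b[0]
        i = aL + ii
        k = bL + ki
        sig = self.sig
        res_a, res_b = self.res_a, self.res_b
        cur = M[ii][ki]
        end_sig = sig(res_a[i - 1], res_b[k - 1])
        for a1 in ch_a.get(i, ()):
            pa = self.phi_a[(a, a1)]
            for b1 in ch_b.get(k, ()):
                v = (
                    M[a1[0] - 1 - aL][b1[0] - 1 - bL]
                    + self.D[(a1, b1)]
                    + sig(res_a[a1[0] - 1], res_b[b1[0] - 1])
                    + end_sig
                    + pa
                    + self.phi_b[(b, b1)]
                )
                if cur == v:
                    self.pairs_a.add(a1)
                    self.pairs_b.add(b1)
                    self.edges.append((a1[0], b1[0]))
                    self.edges.append((i, k))
                    self._trace_d(a1, b1)
                    return a1[0] - 1 - aL, b1[0] - 1 - bL
        if self.l_d > 0:
            g = self.g
            for a1 in ch_a.get(i, ()):
                span = a1[1] - a1[0]
                if span < self.l_d and cur == (
                    M[a1[0] - 1 - aL][ki] + (span + 1) * g + self.phi_a[(a, a1)]
                ):
                    self.pairs_a.add(a1)
                    self.gaps += span + 1
                    return a1[0] - 1 - aL, ki
            for b1 in ch_b.get(k, ()):
                span = b1[1] - b1[0]
                if span < self.l_d and cur == (
                    M[ii][b1[0] - 1 - bL] + (span + 1) * g + self.phi_b[(b, b1)]
                ):
                    self.pairs_b.add(b1)
                    self.gaps += span + 1
                    return ii, b1[0] - 1 - bL
        return None

    def _trace_i(self, a: Pair, b: Pair, I, idx: int, which: str) -> None:
        own = a if which == "A" else b
        ch = (self.kids_a if which == "A" else self.kids_b).get(own, {})
        phi = self.phi_a if which == "A" else self.phi_b
        g = self.g
        while True:
            pos = own[0] + idx
            cur = I[idx]
            if idx > 0 and cur == I[idx - 1] + g:
                self.gaps += 1
                idx -= 1
                continue
            for c1 in ch.get(pos, ()):
                cost = (c1[0] - own[0] + 1) * g
                dkey = (c1, b) if which == "A" else (a, c1)
                if cur == cost + self.D[dkey] + phi[(own, c1)]:
                    # left flank plus both ends of the deleted pair are gaps
                    self.gaps += c1[0] - own[0] + 1
                    if which == "A":
                        self.pairs_a.add(c1)
                        self._trace_d(c1, b)
                    else:
                        self.pairs_b.add(c1)
                        self._trace_d(a, c1)
                    return
            raise RuntimeError(  # pragma: no cover - internal consistency
                f"traceback failed in I_{which}{(a, b)} at {idx}"
            )


def align(
    seq_a: RnaSequence,
    seq_b: RnaSequence,
    t_a: EnsembleTables,
    t_b: EnsembleTables,
    cfg: ScoreConfig | None = None,
    theta: float = DEFAULT_THETA,
    theta_prime: float = DEFAULT_THETA_PRIME,
    l_d: int = 0,
) -> AlignmentResult:
    """Simultaneously align and fold ``seq_a`` and ``seq_b``.

    Parameters
    ----------
    t_a, t_b : EnsembleTables
        Ensembles of the two sequences; must be computed with identical
        energy parameters.
    cfg : ScoreConfig, optional
        Score weights (sigma, gamma, beta); defaults apply.
    theta, theta_prime : float
        Sparsification thresholds on pair and joint in-loop probabilities.
    l_d : int
        Maximal span of a deletable/insertable structural branch; 0 turns
        the domain-indel feature off.

    Returns
    -------
    AlignmentResult
        Optimal edges, predicted structure per sequence, indel count and
        the decomposed score.
    """
    if t_a.sequence != seq_a or t_b.sequence != seq_b:
        raise ValueError("ensemble tables do not belong to the given sequences")
    if t_a.params != t_b.params:
        raise ValueError("ensembles were computed with different energy parameters")
    if l_d < 0:
        raise ValueError("l_d must be non-negative")
    cfg = cfg or ScoreConfig()
    ca = build_candidates(t_a, theta, theta_prime)
    cb = build_candidates(t_b, theta, theta_prime)
    dp = _Dp(seq_a, seq_b, ca, cb, cfg, l_d)
    total = dp.run()
    edges, gaps, pairs_a, pairs_b = dp.traceback()
    n_indel = len(seq_a) + len(seq_b) - 2 * len(edges)
    if n_indel != gaps:  # pragma: no cover - internal consistency
        raise RuntimeError("traceback gap accounting is inconsistent")
    structure_a = SecondaryStructure(
        seq_a, frozenset(BasePair(*p) for p in pairs_a)
    )
    structure_b = SecondaryStructure(
        seq_b, frozenset(BasePair(*p) for p in pairs_b)
    )
    seq_score = sum(
        cfg.sigma(seq_a.base(i), seq_b.base(k)) for i, k in edges
    )
    struct_score = _structure_component(
        structure_a, t_a, cfg
    ) + _structure_component(structure_b, t_b, cfg)
    return AlignmentResult(
        seq_a=seq_a,
        seq_b=seq_b,
        edges=tuple(edges),
        n_indel=n_indel,
        structure_a=structure_a,
        structure_b=structure_b,
        total_score=total,
        sequence_score=seq_score,
        structure_score=struct_score,
        indel_score=n_indel * cfg.gamma,
    )


def _structure_component(
    s: SecondaryStructure, t: EnsembleTables, cfg: ScoreConfig
) -> float:
    """Sum of Phi(child, parent) over the loop tree of ``s``."""
    tree = build_tree(s)
    total = 0.0
    for pair, parent in tree.parent.items():
        cond = t.inloop_conditional(parent, pair)
        total += math.log(cond) + cfg.beta
    return total


def rescore(
    result: AlignmentResult,
    t_a: EnsembleTables,
    t_b: EnsembleTables,
    cfg: ScoreConfig,
) -> float:
    """Recompute the total score of a result from its explicit edges/structures.

    Independent of the DP: sums sigma over edges, gamma per unaligned
    position, and Phi over the parent-child relations of both predicted
    structures.  Must equal ``result.total_score``.
    """
    edges = sorted(result.edges)
    for (i1, k1), (i2, k2) in zip(edges, edges[1:]):
        if i2 <= i1 or k2 <= k1:
            raise ValueError("alignment edges are not strictly increasing")
    seq_score = sum(
        cfg.sigma(result.seq_a.base(i), result.seq_b.base(k)) for i, k in edges
    )
    n_indel = len(result.seq_a) + len(result.seq_b) - 2 * len(edges)
    struct = _structure_component(result.structure_a, t_a, cfg)
    struct += _structure_component(result.structure_b, t_b, cfg)
    return seq_score + n_indel * cfg.gamma + struct
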