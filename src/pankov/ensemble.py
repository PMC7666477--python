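"""Partition function and in-loop probabilities over the energy model.

Inside/outside dynamic programs compute, for a single sequence:

* the partition function ``Z`` and per-pair inside partition functions
  ``Z_in[a]`` (all structures enclosed by pair ``a``),
* base-pair probabilities ``P_pair[a]``,
* joint pair-in-loop probabilities ``P_joint[a, a'] = P(a and a' in chi(a))``
  together with the conditional form ``P_cond[a' || a]``,
* external-pair probabilities ``P_ext[a']`` (``a'`` a child of the pseudo
  root),
* and the ensemble free energy ``-RT log Z``.

The joint accumulation is stratified by loop context — ``a'`` as the sole
child of ``a`` (stack/bulge/interior) versus one branch of a multiloop —
so that the overestimation property of in-loop conditionals relative to
exact single-child loop conditionals is directly inspectable.

Everything is stored sparsely, keyed by candidate pairs ``(i, j)`` (all
complementary pairs honouring the hairpin constraint).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, TextIO

from .energy import (
    EnergyParameters,
    _one_child_energy,
    candidate_pairs,
    loop_energy,
)
from .structures import (
    BasePair,
    RnaSequence,
    SecondaryStructure,
    build_tree,
)

Pair = tuple[int, int]


def _as_tuple(p) -> Pair:
    if isinstance(p, BasePair):
        return p.astuple()
    return (int(p[0]), int(p[1]))


@dataclass
class EnsembleTables:
    """Sparse ensemble quantities of one sequence under one parameter set."""

    sequence: RnaSequence
    params: EnergyParameters
    Z: float
    Z_in: dict[Pair, float]
    P_pair: dict[Pair, float]
    P_joint: dict[tuple[Pair, Pair], float]
    P_cond: dict[tuple[Pair, Pair], float]
    P_joint_nonbranching: dict[tuple[Pair, Pair], float]
    P_joint_multiloop: dict[tuple[Pair, Pair], float]
    P_ext: dict[Pair, float]
    ensemble_energy: float
    candidates: tuple[Pair, ...] = field(default=())

    # -- convenience accessors ---------------------------------------------

    def pair_probability(self, a) -> float:
        return self.P_pair[_as_tuple(a)]

    def ext_probability(self, a) -> float:
        return self.P_ext[_as_tuple(a)]

    def joint_probability(self, parent, child) -> float:
        return self.P_joint[(_as_tuple(parent), _as_tuple(child))]

    def inloop_conditional(self, parent, child) -> float:
        """``P(child || parent)``; the pseudo root conditions via ``P_ext``."""
        pt = _as_tuple(parent)
        ct = _as_tuple(child)
        if pt == (0, len(self.sequence) + 1):
            return self.P_ext[ct]
        try:
            return self.P_cond[(pt, ct)]
        except KeyError:
            raise KeyError(
                f"no in-loop entry for child {ct} under parent {pt}"
            ) from None


def compute_ensemble(seq: RnaSequence, params: EnergyParameters) -> EnsembleTables:
    """Run the inside/outside dynamic programs for ``seq``.

    The inside pass fills ``Z_in`` over candidate pairs by loop type
    (hairpin; single child; multiloop via a ``>=1 branch`` region table),
    plus external prefix/suffix partition functions.  The outside pass
    distributes each parent's probability over its possible direct children,
    accumulating ``P_joint`` stratified by loop context; ``P_pair`` of a
    pair is the sum of its external mass and its in-loop mass under every
    candidate parent, so every occurrence has exactly one parent.
    """
    n = len(seq)
    res = seq.residues
    rt = params.rt
    mh = params.min_hairpin
    wu = math.exp(-params.multiloop_unpaired / rt)
    wb = math.exp(-params.multiloop_branch / rt)
    wa = math.exp(-params.multiloop_closing / rt)
    wext = math.exp(-params.external_contribution / rt)

    cands = candidate_pairs(seq, mh)
    cand_set = set(cands)
    by_left: list[list[int]] = [[] for _ in range(n + 2)]
    by_right: list[list[int]] = [[] for _ in range(n + 2)]
    for i, j in cands:
        by_left[i].append(j)
        by_right[j].append(i)

    # inside pass: Z_in over candidate pairs; Qm1[x][y] = partition function
    # of the region x..y inside a multiloop with >= 1 branch (branch weight
    # wb * Z_in, unpaired weight wu per position).
    Zb: dict[Pair, float] = {}
    Qm1 = [[0.0] * (n + 2) for _ in range(n + 3)]
    for w in range(1, n + 1):
        for x in range(1, n - w + 2):
            y = x + w - 1
            if (x, y) in cand_set:
                z = math.exp(-params.hairpin_penalty(y - x - 1) / rt)
                ml = 0.0
                for k in range(x + 1, y):
                    for l in by_left[k]:
                        if l >= y:
                            break
                        zkl = Zb[(k, l)]
                        z += (
                            math.exp(-_one_child_energy(params, res, x, y, k, l) / rt)
                            * zkl
                        )
                        tail = Qm1[l + 1][y - 1] if l + 1 <= y - 1 else 0.0
                        if tail:
                            # (k,l) is the first of >= 2 multiloop branches
                            ml += wu ** (k - x - 1) * wb * zkl * tail
                Zb[(x, y)] = z + wa * ml
            q = wu * Qm1[x + 1][y] if w > 1 else 0.0
            for l in by_left[x]:
                if l > y:
                    break
                rest = wu ** (y - l)
                if l + 1 <= y:
                    rest += Qm1[l + 1][y]
                q += wb * Zb[(x, l)] * rest
            Qm1[x][y] = q

    # external prefix/suffix partition functions (external loop is a single
    # constant contribution, applied once at the end)
    Ze = [1.0] * (n + 1)
    for j in range(1, n + 1):
        t = Ze[j - 1]
        for i in by_right[j]:
            t += Ze[i - 1] * Zb[(i, j)]
        Ze[j] = t
    Zhat = [1.0] * (n + 3)
    for i in range(n, 0, -1):
        t = Zhat[i + 1]
        for j in by_left[i]:
            t += Zb[(i, j)] * Zhat[j + 1]
        Zhat[i] = t

    Z = Ze[n] * wext
    ensemble_energy = -rt * math.log(Z)

    P_ext = {
        (i, j): Ze[i - 1] * Zb[(i, j)] * Zhat[j + 1] / Ze[n] for (i, j) in cands
    }

    def qany(x: int, y: int) -> float:
        # region with >= 0 multiloop branches
        if x > y:
            return 1.0
        return wu ** (y - x + 1) + Qm1[x][y]

    # outside pass: parents before children (strictly larger span)
    order = sorted(cands, key=lambda p: p[1] - p[0], reverse=True)
    P_pair: dict[Pair, float] = {}
    P_joint: dict[tuple[Pair, Pair], float] = {}
    P_cond: dict[tuple[Pair, Pair], float] = {}
    P_joint_nb: dict[tuple[Pair, Pair], float] = {}
    P_joint_ml: dict[tuple[Pair, Pair], float] = {}
    for (i, j) in order:
        zb_child = Zb[(i, j)]
        p = P_ext[(i, j)]
        for (k, l) in cands:
            if not (k < i and j < l):
                continue
            zb_par = Zb[(k, l)]
            mass_int = (
                math.exp(-_one_child_energy(params, res, k, l, i, j) / rt) * zb_child
            )
            mass_ml = (
                wa
                * wb
                * zb_child
                * (
                    qany(k + 1, i - 1) * qany(j + 1, l - 1)
                    - wu ** (i - k - 1) * wu ** (l - j - 1)
                )
            )
            key = ((k, l), (i, j))
            cond_nb = mass_int / zb_par
            cond_ml = mass_ml / zb_par
            P_cond[key] = cond_nb + cond_ml
            pp = P_pair[(k, l)]
            P_joint_nb[key] = pp * cond_nb
            P_joint_ml[key] = pp * cond_ml
            P_joint[key] = P_joint_nb[key] + P_joint_ml[key]
            p += P_joint[key]
        P_pair[(i, j)] = p

    return EnsembleTables(
        sequence=seq,
        params=params,
        Z=Z,
        Z_in=Zb,
        P_pair=P_pair,
        P_joint=P_joint,
        P_cond=P_cond,
        P_joint_nonbranching=P_joint_nb,
        P_joint_multiloop=P_joint_ml,
        P_ext=P_ext,
        ensemble_energy=ensemble_energy,
        candidates=tuple(cands),
    )


def conditional_loop_probability(
    t: EnsembleTables,
    closing: BasePair | Pair,
    children: Iterable[BasePair | Pair],
) -> float:
    """Exact ``P(loop(closing, children) | closing)``.

    Computed as ``(prod Z_in[child]) * exp(-E_loop/RT) / Z_in[closing]``
    with ``Z_in[pseudo root] := Z``.
    """
    n = len(t.sequence)
    ct = _as_tuple(closing)
    kids = sorted(_as_tuple(c) for c in children)
    if ct == (0, n + 1):
        z_close = t.Z
    else:
        try:
            z_close = t.Z_in[ct]
        except KeyError:
            raise ValueError(f"closing pair {ct} is not a candidate pair") from None
        if z_close <= 0.0:
            raise ValueError(f"closing pair {ct} has zero inside partition function")
    e = loop_energy(
        t.params,
        t.sequence,
        BasePair(*ct),
        [BasePair(*c) for c in kids],
    )
    num = math.exp(-e / t.params.rt)
    for c in kids:
        try:
            num *= t.Z_in[c]
        except KeyError:
            raise ValueError(f"child pair {c} is not a candidate pair") from None
    return num / z_close


def structure_probability_exact(t: EnsembleTables, s: SecondaryStructure) -> float:
    """Exact equilibrium probability of ``s`` as a product of loop conditionals.

    Equals ``exp(-E(S)/RT) / Z``; every pair of ``s`` must be a candidate
    pair of the ensemble.
    """
    tree = build_tree(s)
    prob = 1.0
    for node in tree.nodes():
        prob *= conditional_loop_probability(t, node, tree.children[node])
    return prob


# -- tab-separated export ---------------------------------------------------

_TSV_HEADER = "kind\ti\tj\tparent_i\tparent_j\tprobability"


def write_probabilities_tsv(t: EnsembleTables, fh: TextIO) -> None:
    """Write pair/external/conditional/joint probabilities as TSV.

    Columns: ``kind`` (pair | external | conditional | joint), the pair
    ``i, j``, the parent pair (empty for pair/external rows) and the
    probability.
    """
    fh.write(_TSV_HEADER + "\n")
    for (i, j), p in sorted(t.P_pair.items()):
        fh.write(f"pair\t{i}\t{j}\t\t\t{p!r}\n")
    for (i, j), p in sorted(t.P_ext.items()):
        fh.write(f"external\t{i}\t{j}\t\t\t{p!r}\n")
    for ((k, l), (i, j)), p in sorted(t.P_cond.items()):
        fh.write(f"conditional\t{i}\t{j}\t{k}\t{l}\t{p!r}\n")
    for ((k, l), (i, j)), p in sorted(t.P_joint.items()):
        fh.write(f"joint\t{i}\t{j}\t{k}\t{l}\t{p!r}\n")


def read_probabilities_tsv(fh: TextIO) -> dict[str, dict]:
    """Parse the TSV written by :func:`write_probabilities_tsv`.

    Returns a dict with keys ``pair``, ``external`` (pair -> probability)
    and ``conditional``, ``joint`` ((parent, pair) -> probability).
    """
    header = fh.readline().rstrip("\n")
    if header != _TSV_HEADER:
        raise ValueError(f"unexpected TSV header: {header!r}")
    out: dict[str, dict] = {
        "pair": {},
        "external": {},
        "conditional": {},
        "joint": {},
    }
    for raw in fh:
        line = raw.rstrip("\n")
        if not line:
            continue
        kind, i, j, pi, pj, prob = line.split("\t")
        if kind in ("pair", "external"):
            out[kind][(int(i), int(j))] = float(prob)
        elif kind in ("conditional", "joint"):
            out[kind][((int(pi), int(pj)), (int(i), int(j)))] = float(prob)
        else:
            raise ValueError(f"unknown row kind {kind!r}")
    return out
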