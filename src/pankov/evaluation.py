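"""Model-agreement evaluation against the reference energy model.

The procedure mirrors the standard way probabilistic structure-scoring
models are benchmarked: (i) generate the suboptimal structure ensemble of a
sequence within an energy window above the minimum free energy, (ii) score
every suboptimal under each model variant, (iii) transform the values to
the energy scale and compute Spearman rank correlations against the
reference free energies.

Suboptimal generation is a best-first branch-and-bound over the same loop
grammar as the partition function (a Wuchty-style enumeration): minimum
free energy tables provide admissible bounds, partial structures are
expanded in bound order, and completed structures therefore emerge sorted
by energy — so the enumeration stops exactly at ``max_count`` structures or
at the window edge, whichever comes first, at any sequence length.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .energy import (
    EnergyParameters,
    _one_child_energy,
    candidate_pairs,
    structure_energy,
)
from .ensemble import (
    EnsembleTables,
    compute_ensemble,
    structure_probability_exact,
)
from .scoring import (
    ScoreConfig,
    pankov_probability,
    pankov_score,
    pmcomp_probability,
    pmcomp_score,
    probability_to_energy,
)
from .structures import (
    BasePair,
    RnaSequence,
    SecondaryStructure,
    write_dotbracket,
)

INF = float("inf")


# -- minimum free energy tables (bounds for the enumeration) ----------------


@dataclass
class _FoldingTables:
    n: int
    cand_by_left: list[list[int]]
    Vb: dict[tuple[int, int], float]
    Mmin1: list[list[float]]
    We: list[float]
    e_min: float


def _folding_tables(seq: RnaSequence, params: EnergyParameters) -> _FoldingTables:
    """Min-plus analogue of the inside partition recursions."""
    n = len(seq)
    res = seq.residues
    mh = params.min_hairpin
    c_un = params.multiloop_unpaired
    c_br = params.multiloop_branch
    c_cl = params.multiloop_closing

    cands = candidate_pairs(seq, mh)
    cand_set = set(cands)
    by_left: list[list[int]] = [[] for _ in range(n + 2)]
    for i, j in cands:
        by_left[i].append(j)

    Vb: dict[tuple[int, int], float] = {}
    Mmin1 = [[INF] * (n + 2) for _ in range(n + 3)]
    for w in range(1, n + 1):
        for x in range(1, n - w + 2):
            y = x + w - 1
            if (x, y) in cand_set:
                e = params.hairpin_penalty(y - x - 1)
                for k in range(x + 1, y):
                    for l in by_left[k]:
                        if l >= y:
                            break
                        vkl = Vb[(k, l)]
                        e = min(
                            e,
                            _one_child_energy(params, res, x, y, k, l) + vkl,
                        )
                        tail = Mmin1[l + 1][y - 1] if l + 1 <= y - 1 else INF
                        if tail < INF:
                            e = min(
                                e,
                                c_cl
                                + (k - x - 1) * c_un
                                + c_br
                                + vkl
                                + tail,
                            )
                Vb[(x, y)] = e
            q = c_un + Mmin1[x + 1][y] if w > 1 else INF
            for l in by_left[x]:
                if l > y:
                    break
                rest = (y - l) * c_un
                if l + 1 <= y:
                    rest = min(rest, Mmin1[l + 1][y])
                q = min(q, c_br + Vb[(x, l)] + rest)
            Mmin1[x][y] = q

    We = [0.0] * (n + 3)
    for i in range(n, 0, -1):
        e = We[i + 1]
        for j in by_left[i]:
            e = min(e, Vb[(i, j)] + We[j + 1])
        We[i] = e
    e_min = We[1] + params.external_contribution
    return _FoldingTables(n, by_left, Vb, Mmin1, We, e_min)


def suboptimal_ensemble(
    seq: RnaSequence,
    params: EnergyParameters,
    e_window: float = 5.0,
    max_count: int | float = 500,
) -> list[SecondaryStructure]:
    """All structures with ``E(S) <= E_min + e_window``, energy ascending.

    Truncated to ``max_count`` structures (counting from the minimum free
    energy up); ``e_window=inf, max_count=inf`` yields the complete,
    energy-sorted ensemble.  Each open subproblem of a partial structure is
    bounded by its minimum free energy, so states are expanded best-first
    and structures complete in non-decreasing energy order.
    """
    if e_window < 0:
        raise ValueError("e_window must be non-negative")
    ft = _folding_tables(seq, params)
    n = ft.n
    by_left = ft.cand_by_left
    Vb, Mmin1, We = ft.Vb, ft.Mmin1, ft.We
    c_un = params.multiloop_unpaired
    c_br = params.multiloop_branch
    c_cl = params.multiloop_closing
    limit = ft.e_min + e_window + 1e-9

    def bound(item) -> float:
        kind = item[0]
        if kind == "E":
            return We[item[1]]
        if kind == "B":
            return Vb[(item[1], item[2])]
        return Mmin1[item[1]][item[2]]

    # state: (bound, tie, accumulated energy, pairs, open items)
    counter = itertools.count()
    start = (
        ft.e_min,
        next(counter),
        params.external_contribution,
        (),
        (("E", 1),),
    )
    heap = [start]
    results: list[SecondaryStructure] = []
    while heap and len(results) < max_count:
        bnd, _, acc, pairs, open_ = heapq.heappop(heap)
        if bnd > limit:
            break
        if not open_:
            results.append(
                SecondaryStructure(seq, frozenset(BasePair(*p) for p in pairs))
            )
            continue
        item, rest = open_[0], open_[1:]
        rest_bound = sum(bound(it) for it in rest)

        def push(cost: float, new_pairs, new_items) -> None:
            new_acc = acc + cost
            b = new_acc + sum(bound(it) for it in new_items) + rest_bound
            if b <= limit:
                heapq.heappush(
                    heap,
                    (b, next(counter), new_acc, new_pairs, new_items + rest),
                )

        kind = item[0]
        if kind == "E":
            i = item[1]
            if i > n:
                push(0.0, pairs, ())
            else:
                push(0.0, pairs, (("E", i + 1),))
                for j in by_left[i]:
                    push(0.0, pairs + ((i, j),), (("B", i, j), ("E", j + 1)))
        elif kind == "B":
            i, j = item[1], item[2]
            push(params.hairpin_penalty(j - i - 1), pairs, ())
            for k in range(i + 1, j):
                for l in by_left[k]:
                    if l >= j:
                        break
                    push(
                        _one_child_energy(params, seq.residues, i, j, k, l),
                        pairs + ((k, l),),
                        (("B", k, l),),
                    )
                    if l + 1 <= j - 1 and Mmin1[l + 1][j - 1] < INF:
                        push(
                            c_cl + (k - i - 1) * c_un + c_br,
                            pairs + ((k, l),),
                            (("B", k, l), ("M1", l + 1, j - 1)),
                        )
        else:  # M1 region x..y with >= 1 branch
            x, y = item[1], item[2]
            if x < y:
                push(c_un, pairs, (("M1", x + 1, y),))
            for l in by_left[x]:
                if l > y:
                    break
                push(
                    c_br + (y - l) * c_un,
                    pairs + ((x, l),),
                    (("B", x, l),),
                )
                if l + 1 <= y and Mmin1[l + 1][y] < INF:
                    push(
                        c_br,
                        pairs + ((x, l),),
                        (("B", x, l), ("M1", l + 1, y)),
                    )
    return results


# -- rank correlation -------------------------------------------------------


def spearman_correlation(x, y) -> float:
    """Spearman rank correlation with average ranks for ties.

    Invariant under strictly monotone transforms of either argument, hence
    the energy-scale transformation of model outputs does not change it.
    """
    x = list(x)
    y = list(y)
    if len(x) != len(y):
        raise ValueError("inputs must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if len(set(x)) < 2 or len(set(y)) < 2:
        raise ValueError("degenerate constant input")
    return float(stats.spearmanr(x, y).statistic)


# -- the evaluation procedure ----------------------------------------------

MODEL_NAMES = (
    "pmcomp_probability",
    "pmcomp_score",
    "pankov_ml_min",
    "pankov_ml_prod",
    "pankov_score",
)


def evaluate_models(
    seq: RnaSequence,
    params: EnergyParameters,
    cfg: ScoreConfig | None = None,
    e_window: float = 5.0,
    max_count: int | float = 500,
    include_exact: bool = False,
    tables: EnsembleTables | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Score the suboptimal ensemble under every model variant.

    Returns the per-structure table (reference energy, raw model values and
    their energy-scaled transforms) and the per-model Spearman correlation
    against the reference energies.  Probabilities are energy-scaled via
    ``-RT log(p) + E_ens``; log-scale scores via the monotone affine map
    ``-RT * score + E_ens``, which preserves each score's own ranking.

    ``include_exact`` adds the exact structure probability as an oracle
    model (its energy-scaled values reproduce the reference energies).
    """
    cfg = cfg or ScoreConfig()
    if tables is None:
        tables = compute_ensemble(seq, params)
    subs = suboptimal_ensemble(seq, params, e_window=e_window, max_count=max_count)
    if len(subs) < 3:
        raise ValueError(f"only {len(subs)} suboptimal structures; need >= 3")
    rt = params.rt
    e_ens = tables.ensemble_energy
    rows = []
    for s in subs:
        ref = structure_energy(params, s)
        p_pm = pmcomp_probability(tables, s)
        sc_pm = pmcomp_score(tables, s, cfg)
        p_min = pankov_probability(tables, s, "ml_min")
        p_prod = pankov_probability(tables, s, "ml_prod")
        sc_pk = pankov_score(tables, s, cfg)
        row = {
            "structure": write_dotbracket(s),
            "n_pairs": len(s),
            "ref_energy": ref,
            "pmcomp_probability": p_pm,
            "pmcomp_score": sc_pm,
            "pankov_ml_min": p_min,
            "pankov_ml_prod": p_prod,
            "pankov_score": sc_pk,
            "pmcomp_probability_energy": probability_to_energy(p_pm, tables),
            "pmcomp_score_energy": -rt * sc_pm + e_ens,
            "pankov_ml_min_energy": probability_to_energy(p_min, tables),
            "pankov_ml_prod_energy": probability_to_energy(p_prod, tables),
            "pankov_score_energy": -rt * sc_pk + e_ens,
        }
        if include_exact:
            p_exact = structure_probability_exact(tables, s)
            row["exact_probability"] = p_exact
            row["exact_probability_energy"] = probability_to_energy(p_exact, tables)
        rows.append(row)
    table = pd.DataFrame(rows)
    names = MODEL_NAMES + (("exact_probability",) if include_exact else ())
    correlations: dict[str, float] = {}
    ref = table["ref_energy"].tolist()
    for name in names:
        correlations[name] = spearman_correlation(
            ref, table[f"{name}_energy"].tolist()
        )
    return table, correlations
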