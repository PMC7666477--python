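"""Structure scoring models: PMcomp, exact, ML-min/ML-prod and the Phi score.

PMcomp scores a structure from unconditional base-pair probabilities,
implicitly assuming independence between pairing events.  The loop-aware
alternative multiplies conditional pair-in-loop probabilities along the
loop tree, with two multiloop approximations: the minimum over branch
conditionals (ML-min, an upper bound on the exact loop conditional) and the
product over branch conditionals (ML-prod, a branch-independence
assumption).  Children of the pseudo root condition through the
external-pair probability.  ``probability_to_energy`` maps any
probability-like value back to the free-energy scale through the ensemble
energy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable

from .ensemble import EnsembleTables
from .structures import SecondaryStructure, build_tree


def default_sigma(x: str, y: str) -> float:
    """Base similarity: +2.0 for identical residues, -1.0 otherwise."""
    return 2.0 if x == y else -1.0


@dataclass(frozen=True)
class ScoreConfig:
    """Weights of the alignment-and-folding score.

    Parameters
    ----------
    p_min : float or None
        Minimal probability of a significant base pair.  ``None`` resolves
        to ``1 / (2 * sequence_length)`` at the point of use.
    beta : float
        Structure bonus added per scored child pair, balancing structure
        against sequence contributions.
    sigma : callable (residue, residue) -> float
        Base similarity for matched positions; must be symmetric.
    gamma : float
        Gap penalty per inserted/deleted position (non-positive).
    """

    p_min: float | None = None
    beta: float = 1.5
    sigma: Callable[[str, str], float] = default_sigma
    gamma: float = -2.0

    def __post_init__(self) -> None:
        if self.p_min is not None and not 0.0 < self.p_min < 1.0:
            raise ValueError("p_min must lie strictly between 0 and 1")
        if self.gamma > 0:
            raise ValueError("gamma must be non-positive")

    def resolved_p_min(self, n: int) -> float:
        """``p_min`` if set, else the default ``1 / (2 n)``."""
        return self.p_min if self.p_min is not None else 1.0 / (2 * n)


# -- PMcomp -----------------------------------------------------------------


def pmcomp_probability(t: EnsembleTables, s: SecondaryStructure) -> float:
    """Product of unconditional pair probabilities (independence model)."""
    prob = 1.0
    for p in s.sorted_pairs:
        prob *= t.P_pair[p.astuple()]
    return prob


def pmcomp_score(
    t: EnsembleTables, s: SecondaryStructure, cfg: ScoreConfig
) -> float:
    """Sum of normalized log pair probabilities, ``sum log(P(a)/P_min)``."""
    p_min = cfg.resolved_p_min(len(t.sequence))
    score = 0.0
    for p in s.sorted_pairs:
        pp = t.P_pair[p.astuple()]
        if pp <= 0.0:
            raise ValueError(f"pair {p} has zero probability")
        score += math.log(pp / p_min)
    return score


# -- loop-probability approximations ---------------------------------------


def ml_min_loop_probability(
    t: EnsembleTables, closing, children: Iterable
) -> float:
    """Least probable branch assigned to the whole loop; 1 for hairpins."""
    conds = [t.inloop_conditional(closing, c) for c in children]
    return min(conds) if conds else 1.0


def ml_prod_loop_probability(
    t: EnsembleTables, closing, children: Iterable
) -> float:
    """Branch-independence approximation: product over branch conditionals."""
    prob = 1.0
    for c in children:
        prob *= t.inloop_conditional(closing, c)
    return prob


_LOOP_VARIANTS = {
    "ml_min": ml_min_loop_probability,
    "ml_prod": ml_prod_loop_probability,
}


def pankov_probability(
    t: EnsembleTables, s: SecondaryStructure, variant: str = "ml_prod"
) -> float:
    """Loop-aware structure probability from in-loop conditionals.

    ``ml_prod`` multiplies the branch conditionals of every loop; ``ml_min``
    replaces each loop's inner product by the minimum branch conditional.
    Children of the pseudo root use the external-pair probability as their
    conditional.
    """
    try:
        per_loop = _LOOP_VARIANTS[variant]
    except KeyError:
        raise ValueError(f"unknown variant {variant!r}; use 'ml_min' or 'ml_prod'")
    tree = build_tree(s)
    prob = 1.0
    for node in tree.nodes():
        prob *= per_loop(t, node, tree.children[node])
    return prob


def pankov_score(
    t: EnsembleTables, s: SecondaryStructure, cfg: ScoreConfig
) -> float:
    """Sum of ``Phi(a', a) = log P(a' || a) + beta`` over parent-child pairs.

    Equals ``log(pankov_probability(ml_prod)) + |S| * beta`` since every
    real pair is scored exactly once, as a child.
    """
    tree = build_tree(s)
    score = 0.0
    for node in tree.nodes():
        for child in tree.children[node]:
            cond = t.inloop_conditional(node, child)
            if cond <= 0.0:
                raise ValueError(f"zero in-loop conditional for {child} under {node}")
            score += math.log(cond) + cfg.beta
    return score


def phi(
    t: EnsembleTables, parent, child, beta: float
) -> float:
    """``Phi(child, parent) = log P(child || parent) + beta``."""
    cond = t.inloop_conditional(parent, child)
    if cond <= 0.0:
        raise ValueError(f"zero in-loop conditional for {child} under {parent}")
    return math.log(cond) + beta


def probability_to_energy(p: float, t: EnsembleTables) -> float:
    """Transform a structure probability back to the energy scale.

    ``E = -RT log(p) + E_ens``; inverts the Boltzmann relation so the exact
    structure probability maps back to the structure's free energy.
    """
    if p <= 0.0:
        raise ValueError("probability must be positive")
    return -t.params.rt * math.log(p) + t.ensemble_energy
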