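"""A loop-decomposable nearest-neighbor-style energy model.

The free energy of a structure is the sum of independent loop contributions
``E_loop(a, chi(a))`` over its loop tree (including the external loop closed
by the pseudo pair), which is exactly the precondition under which structure
probabilities factor into conditional loop probabilities.

The built-in parameterization is deliberately simple — a stacking table over
the six complementary pair types, tabulated hairpin/interior size penalties
with logarithmic extrapolation, and an affine multiloop — because every
result downstream holds for *any* loop-decomposable model.  All values are
configuration: they are serialized to and from a flat key-value text format.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from .structures import (
    BasePair,
    COMPLEMENTARY,
    RnaSequence,
    SecondaryStructure,
    build_tree,
    pseudo_root,
)

#: Thermal energy RT at 37 degrees Celsius, kcal/mol.
RT_37 = 0.6163

#: Jacobson-Stockmayer-style loop-size extrapolation prefactor (units of RT).
LOOP_EXTRAPOLATION_RT = 1.75

# Relative stacking strength per pair type; stack energies are derived from
# these so the canonical GC > AU > GU hierarchy is respected.
_PAIR_STRENGTH = {"GC": 2.1, "CG": 2.1, "AU": 1.1, "UA": 1.1, "GU": 0.7, "UG": 0.7}


def _default_stack_table() -> dict[tuple[str, str], float]:
    table = {}
    for p, sp in _PAIR_STRENGTH.items():
        for q, sq in _PAIR_STRENGTH.items():
            table[(p, q)] = round(-(sp + sq) / 1.3, 3)
    return table


@dataclass(frozen=True)
class EnergyParameters:
    """Loop contribution tables defining ``E_loop`` and RT.

    Parameters
    ----------
    stack : mapping (closing pair type, inner pair type) -> kcal/mol
        Stacking energy when the single child is directly adjacent on both
        sides.  Pair types are two-letter strings like ``"GC"`` read 5'->3'
        on the closing side.
    hairpin : tuple of float
        Hairpin penalties for loop sizes ``hairpin_base_size, ...``; sizes
        beyond the table extrapolate logarithmically, sizes below clamp to
        the first entry (only reachable with ``min_hairpin < hairpin_base_size``).
    interior : tuple of float
        Bulge/interior penalties indexed by the total number of unpaired
        loop positions (1, 2, ...), with logarithmic extrapolation.
    multiloop_closing, multiloop_branch, multiloop_unpaired : float
        Affine multiloop model: closing + #branches * branch + #unpaired * unpaired.
    external_contribution : float
        Constant energy of the external loop (default 0).
    rt : float
        Thermal energy in kcal/mol; must be positive.
    min_hairpin : int
        Minimal number of unpaired positions inside a hairpin; defines the
        candidate-pair universe shared by enumeration, ensemble and aligner.
    """

    stack: Mapping[tuple[str, str], float] = field(
        default_factory=_default_stack_table
    )
    hairpin: tuple[float, ...] = (5.0, 5.1, 5.2, 5.4, 5.6, 5.8, 6.0)
    hairpin_base_size: int = 3
    interior: tuple[float, ...] = (3.6, 2.9, 3.2, 3.6, 4.0, 4.3)
    multiloop_closing: float = 3.4
    multiloop_branch: float = 0.4
    multiloop_unpaired: float = 0.0
    external_contribution: float = 0.0
    rt: float = RT_37
    min_hairpin: int = 3

    def __post_init__(self) -> None:
        if self.rt <= 0:
            raise ValueError("RT must be positive")
        if self.min_hairpin < 0:
            raise ValueError("min_hairpin must be non-negative")
        vals = list(self.stack.values()) + list(self.hairpin) + list(self.interior)
        vals += [
            self.multiloop_closing,
            self.multiloop_branch,
            self.multiloop_unpaired,
            self.external_contribution,
        ]
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("all energy contributions must be finite")

    # -- size-dependent penalties ------------------------------------------

    def hairpin_penalty(self, size: int) -> float:
        """Hairpin penalty for ``size`` unpaired loop positions (kcal/mol)."""
        if size < 0:
            raise ValueError("hairpin size must be non-negative")
        base = self.hairpin_base_size
        if size < base:
            return self.hairpin[0]
        if size - base < len(self.hairpin):
            return self.hairpin[size - base]
        last_size = base + len(self.hairpin) - 1
        return self.hairpin[-1] + LOOP_EXTRAPOLATION_RT * self.rt * math.log(
            size / last_size
        )

    def interior_penalty(self, size: int) -> float:
        """Bulge/interior penalty for ``size`` total unpaired positions."""
        if size < 1:
            raise ValueError("interior/bulge loop needs >= 1 unpaired position")
        if size <= len(self.interior):
            return self.interior[size - 1]
        return self.interior[-1] + LOOP_EXTRAPOLATION_RT * self.rt * math.log(
            size / len(self.interior)
        )

    def stack_energy(self, closing_type: str, inner_type: str) -> float:
        try:
            return self.stack[(closing_type, inner_type)]
        except KeyError:
            raise ValueError(
                f"no stacking entry for {closing_type} over {inner_type}"
            ) from None

    # -- serialization ------------------------------------------------------

    def to_config_text(self) -> str:
        """Serialize as a flat ``key = value`` config (documented schema).

        Keys: ``stack.<closing>.<inner>``, ``hairpin.<size>``,
        ``interior.<size>``, ``multiloop.closing|branch|unpaired``,
        ``external``, ``rt``, ``min_hairpin``, ``hairpin_base_size``.
        """
        lines = ["# pankov energy parameters"]
        for (p, q), v in sorted(self.stack.items()):
            lines.append(f"stack.{p}.{q} = {v!r}")
        for k, v in enumerate(self.hairpin):
            lines.append(f"hairpin.{self.hairpin_base_size + k} = {v!r}")
        for k, v in enumerate(self.interior):
            lines.append(f"interior.{k + 1} = {v!r}")
        lines.append(f"multiloop.closing = {self.multiloop_closing!r}")
        lines.append(f"multiloop.branch = {self.multiloop_branch!r}")
        lines.append(f"multiloop.unpaired = {self.multiloop_unpaired!r}")
        lines.append(f"external = {self.external_contribution!r}")
        lines.append(f"rt = {self.rt!r}")
        lines.append(f"min_hairpin = {self.min_hairpin}")
        lines.append(f"hairpin_base_size = {self.hairpin_base_size}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_config_text(cls, text: str) -> "EnergyParameters":
        stack: dict[tuple[str, str], float] = {}
        hairpin: dict[int, float] = {}
        interior: dict[int, float] = {}
        scalars: dict[str, float] = {}
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line {lineno}: {raw!r}")
            key, val = (part.strip() for part in line.split("=", 1))
            parts = key.split(".")
            if parts[0] == "stack" and len(parts) == 3:
                stack[(parts[1], parts[2])] = float(val)
            elif parts[0] == "hairpin" and len(parts) == 2:
                hairpin[int(parts[1])] = float(val)
            elif parts[0] == "interior" and len(parts) == 2:
                interior[int(parts[1])] = float(val)
            elif parts[0] == "multiloop" and len(parts) == 2:
                scalars[f"multiloop_{parts[1]}"] = float(val)
            elif key in ("external", "rt", "min_hairpin", "hairpin_base_size"):
                scalars[key] = float(val)
            else:
                raise ValueError(f"unknown config key {key!r} (line {lineno})")
        if not stack or not hairpin or not interior:
            raise ValueError("config must define stack, hairpin and interior tables")
        hp_sizes = sorted(hairpin)
        base = int(scalars.pop("hairpin_base_size", hp_sizes[0]))
        if hp_sizes != list(range(base, base + len(hp_sizes))):
            raise ValueError("hairpin sizes must be contiguous")
        int_sizes = sorted(interior)
        if int_sizes != list(range(1, len(int_sizes) + 1)):
            raise ValueError("interior sizes must be 1..k")
        return cls(
            stack=stack,
            hairpin=tuple(hairpin[s] for s in hp_sizes),
            hairpin_base_size=base,
            interior=tuple(interior[s] for s in int_sizes),
            multiloop_closing=scalars.get("multiloop_closing", 3.4),
            multiloop_branch=scalars.get("multiloop_branch", 0.4),
            multiloop_unpaired=scalars.get("multiloop_unpaired", 0.0),
            external_contribution=scalars.get("external", 0.0),
            rt=scalars.get("rt", RT_37),
            min_hairpin=int(scalars.get("min_hairpin", 3)),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_config_text())

    @classmethod
    def load(cls, path) -> "EnergyParameters":
        with open(path) as fh:
            return cls.from_config_text(fh.read())


def default_parameters() -> EnergyParameters:
    """The energy parameter set shipped with the package."""
    return EnergyParameters()


# -- loop energies ----------------------------------------------------------


def _one_child_energy(
    params: EnergyParameters,
    res: str,
    ci: int,
    cj: int,
    ki: int,
    kj: int,
) -> float:
    """Energy of the loop closed by (ci,cj) with single child (ki,kj).

    Zero unpaired positions -> stack table; otherwise a bulge/interior
    penalty depending only on the total unpaired count.  ``res`` is the raw
    residue string (0-based access via position-1).
    """
    unpaired = (ki - ci - 1) + (cj - kj - 1)
    if unpaired == 0:
        return params.stack_energy(
            res[ci - 1] + res[cj - 1], res[ki - 1] + res[kj - 1]
        )
    return params.interior_penalty(unpaired)


def loop_energy(
    params: EnergyParameters,
    seq: RnaSequence,
    closing: BasePair,
    children: tuple[BasePair, ...] | list[BasePair],
) -> float:
    """Contribution ``E_loop(closing, children)`` in kcal/mol.

    Dispatches on loop type: external (closing is the pseudo pair), hairpin
    (no children), stack/bulge/interior (one child), multiloop (two or
    more).  The value depends only on the closing pair, the children and the
    residues they delimit.
    """
    n = len(seq)
    children = sorted(children)
    prev_right = closing.left
    for c in children:
        if not (closing.left < c.left and c.right < closing.right):
            raise ValueError(f"child {c} not strictly inside {closing}")
        if c.left <= prev_right:
            raise ValueError(f"children overlap at {c}")
        prev_right = c.right
    if closing == pseudo_root(n):
        return params.external_contribution
    k = len(children)
    if k == 0:
        return params.hairpin_penalty(closing.right - closing.left - 1)
    if k == 1:
        c = children[0]
        return _one_child_energy(
            params, seq.residues, closing.left, closing.right, c.left, c.right
        )
    unpaired = (closing.right - closing.left - 1) - sum(
        c.right - c.left + 1 for c in children
    )
    return (
        params.multiloop_closing
        + k * params.multiloop_branch
        + unpaired * params.multiloop_unpaired
    )


def structure_energy(params: EnergyParameters, s: SecondaryStructure) -> float:
    """Total free energy ``E(S)``: the sum of loop energies over the loop tree."""
    tree = build_tree(s)
    return sum(
        loop_energy(params, s.sequence, node, tree.children[node])
        for node in tree.nodes()
    )


def boltzmann_weight(params: EnergyParameters, e: float) -> float:
    """``exp(-e / RT)`` for a finite energy ``e``."""
    if not math.isfinite(e):
        raise ValueError("energy must be finite")
    return math.exp(-e / params.rt)


def candidate_pairs(seq: RnaSequence, min_hairpin: int) -> list[tuple[int, int]]:
    """All complementary (i, j) with ``j - i - 1 >= min_hairpin``, sorted."""
    res = seq.residues
    n = len(res)
    out = []
    for i in range(1, n + 1):
        xi = res[i - 1]
        for j in range(i + min_hairpin + 1, n + 1):
            if (xi, res[j - 1]) in COMPLEMENTARY:
                out.append((i, j))
    return out
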