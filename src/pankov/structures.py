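"""Sequences, base pairs, non-crossing secondary structures and loop trees.

An RNA secondary structure is modelled as a set of complementary (AU, GC,
GU), non-crossing base pairs over a sequence in ``{A, C, G, U}``.  Sequence
positions are 1-based throughout the public API.  A *pseudo base pair*
``(0, n+1)`` closes the external loop and acts as the root of the loop tree,
in which every base pair is a node and its parent is the minimal enclosing
base pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping

ALPHABET = frozenset("ACGU")

#: Allowed pairings: Watson-Crick plus the GU wobble, either orientation.
COMPLEMENTARY = frozenset(
    {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
)

#: Hard guard for exhaustive structure enumeration.
MAX_ENUMERATION_LENGTH = 30


@dataclass(frozen=True)
class RnaSequence:
    """A validated RNA sequence with a text identifier.

    Parameters
    ----------
    id : str
        Sequence label (e.g. a FASTA header token).
    residues : str
        Residue string over ``{A, C, G, U}``; length must be at least 1.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-RNA letters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def base(self, i: int) -> str:
        """Residue at 1-based position ``i``."""
        if not 1 <= i <= len(self.residues):
            raise IndexError(f"position {i} outside 1..{len(self.residues)}")
        return self.residues[i - 1]


@dataclass(frozen=True, order=True)
class BasePair:
    """A base pair ``(left, right)`` with ``1 <= left < right <= n``.

    The pseudo base pair is ``(0, n+1)``; use :func:`pseudo_root`.
    """

    left: int
    right: int

    def __post_init__(self) -> None:
        if self.left >= self.right:
            raise ValueError(f"base pair ends must satisfy left < right: {self}")

    @property
    def span(self) -> int:
        """Number of enclosed positions plus one, ``right - left``."""
        return self.right - self.left

    def encloses(self, other: "BasePair") -> bool:
        """True if ``other`` lies strictly inside this pair."""
        return self.left < other.left and other.right < self.right

    def astuple(self) -> tuple[int, int]:
        return (self.left, self.right)


def pseudo_root(n: int) -> BasePair:
    """The pseudo base pair ``(0, n+1)`` enclosing all pairs of a length-n sequence."""
    return BasePair(0, n + 1)


def is_complementary(x: str, y: str) -> bool:
    return (x, y) in COMPLEMENTARY


@dataclass(frozen=True)
class SecondaryStructure:
    """A non-crossing secondary structure of a sequence.

    Invariants enforced at construction: all pairs within 1..n, pairwise
    distinct ends, and non-crossing.  Complementarity is checked by the
    producers (:func:`parse_dotbracket`, :func:`enumerate_structures`); the
    pseudo base pair is never stored in ``pairs``.
    """

    sequence: RnaSequence
    pairs: frozenset[BasePair]

    def __post_init__(self) -> None:
        n = len(self.sequence)
        ends: set[int] = set()
        for p in self.pairs:
            if not (1 <= p.left < p.right <= n):
                raise ValueError(f"pair {p} outside sequence bounds 1..{n}")
            if p.left in ends or p.right in ends:
                raise ValueError(f"pair {p} shares an end with another pair")
            ends.update((p.left, p.right))
        sp = self.sorted_pairs
        # sorted by left end: a crossing shows up as left < left' < right < right'
        for a, b in zip(sp, sp[1:]):
            if a.left < b.left < a.right < b.right:
                raise ValueError(f"pairs {a} and {b} cross")

    @property
    def sorted_pairs(self) -> tuple[BasePair, ...]:
        return tuple(sorted(self.pairs))

    def __len__(self) -> int:
        return len(self.pairs)


def parse_dotbracket(
    text: str, seq: RnaSequence, on_noncomplementary: str = "raise"
) -> SecondaryStructure:
    """Parse a Vienna dot-bracket string into a :class:`SecondaryStructure`.

    Only ``(``, ``)`` and ``.`` are accepted; pseudoknot bracket layers are
    rejected (the model is non-crossing by definition).

    Parameters
    ----------
    on_noncomplementary : {"raise", "warn"}
        Whether a bracket pair over non-complementary residues is an error
        or merely a warning.
    """
    if len(text) != len(seq):
        raise ValueError(
            f"dot-bracket length {len(text)} != sequence length {len(seq)}"
        )
    if on_noncomplementary not in ("raise", "warn"):
        raise ValueError("on_noncomplementary must be 'raise' or 'warn'")
    pairs: set[BasePair] = set()
    stack: list[int] = []
    for pos, ch in enumerate(text, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {pos}")
            left = stack.pop()
            if not is_complementary(seq.base(left), seq.base(pos)):
                msg = (
                    f"non-complementary pair ({left},{pos}) "
                    f"{seq.base(left)}-{seq.base(pos)} in {seq.id!r}"
                )
                if on_noncomplementary == "raise":
                    raise ValueError(msg)
                warnings.warn(msg, stacklevel=2)
            pairs.add(BasePair(left, pos))
        elif ch != ".":
            raise ValueError(f"unsupported dot-bracket character {ch!r} at {pos}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return SecondaryStructure(seq, frozenset(pairs))


def write_dotbracket(s: SecondaryStructure) -> str:
    """Serialize a structure as a Vienna dot-bracket string."""
    out = ["."] * len(s.sequence)
    for p in s.pairs:
        out[p.left - 1] = "("
        out[p.right - 1] = ")"
    return "".join(out)


@dataclass(frozen=True)
class StructureTree:
    """The rooted loop tree of a structure.

    ``children`` maps every node (including the pseudo root) to its directly
    enclosed pairs, ordered by left end; ``parent`` maps every real pair to
    its minimal enclosing pair (the pseudo root for external pairs).
    """

    root: BasePair
    children: Mapping[BasePair, tuple[BasePair, ...]]
    parent: Mapping[BasePair, BasePair]

    def nodes(self) -> Iterable[BasePair]:
        """All tree nodes: the pseudo root followed by the real pairs."""
        yield self.root
        yield from self.parent


def build_tree(s: SecondaryStructure) -> StructureTree:
    """Build the loop tree of ``s`` (parent = minimal enclosing pair)."""
    root = pseudo_root(len(s.sequence))
    children: dict[BasePair, list[BasePair]] = {root: []}
    parent: dict[BasePair, BasePair] = {}
    stack = [root]
    for p in s.sorted_pairs:  # left ends ascending
        while stack[-1].right < p.left:
            stack.pop()
        par = stack[-1]
        parent[p] = par
        children[par].append(p)
        children[p] = []
        stack.append(p)
    return StructureTree(
        root, {k: tuple(v) for k, v in children.items()}, parent
    )


def enumerate_structures(
    seq: RnaSequence, min_hairpin: int = 3
) -> list[SecondaryStructure]:
    """Exhaustively enumerate every structure of ``seq``.

    Yields all non-crossing sets of complementary pairs whose hairpin loops
    contain at least ``min_hairpin`` unpaired positions, including the empty
    structure, with no duplicates.  Guarded to sequences of length at most
    :data:`MAX_ENUMERATION_LENGTH`; longer inputs raise ``ValueError``.
    """
    n = len(seq)
    if n > MAX_ENUMERATION_LENGTH:
        raise ValueError(
            f"exhaustive enumeration guarded to n <= {MAX_ENUMERATION_LENGTH}, got {n}"
        )
    res = seq.residues

    @lru_cache(maxsize=None)
    def structs(i: int, j: int) -> tuple[tuple[tuple[int, int], ...], ...]:
        # all pair sets over positions i..j; unique decomposition on the
        # leftmost position (unpaired, or paired to each admissible k)
        if i > j:
            return ((),)
        out = list(structs(i + 1, j))
        for k in range(i + min_hairpin + 1, j + 1):
            if (res[i - 1], res[k - 1]) in COMPLEMENTARY:
                for inner in structs(i + 1, k - 1):
                    for outer in structs(k + 1, j):
                        out.append(((i, k),) + inner + outer)
        return tuple(out)

    result = [
        SecondaryStructure(seq, frozenset(BasePair(a, b) for a, b in ps))
        for ps in structs(1, n)
    ]
    structs.cache_clear()
    return result
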