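"""Seeded synthetic RNA fixtures: singleton sequences and homolog pairs.

The generator stands in for curated ncRNA collections: random sequences
with a controllable GC fraction, optionally with a planted hairpin stem
(a strict Watson-Crick helix), and homolog pairs derived from a common
ancestor by per-site substitutions and indels.  Substitutions inside a
planted stem are compensated on the partner strand, so the stem — and with
it a known true alignment — survives mutation.  All output is a pure
function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .structures import BasePair, RnaSequence

_WC = {"A": "U", "U": "A", "G": "C", "C": "G"}
_LETTERS = ("A", "C", "G", "U")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one deterministic fixture batch.

    ``stem_length > 0`` plants a Watson-Crick hairpin stem of that many
    pairs (loop of ``stem_loop`` unpaired bases) at a random position of
    every sequence.
    """

    seed: int
    n_sequences: int = 20
    length_range: tuple[int, int] = (40, 60)
    gc_bias: float = 0.5
    mutation_rate: float = 0.1
    indel_rate: float = 0.02
    stem_length: int = 0
    stem_loop: int = 4

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_bias <= 1.0:
            raise ValueError("gc_bias must lie in [0, 1]")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must lie in [0, 1]")
        if not 0.0 <= self.indel_rate <= 1.0:
            raise ValueError("indel_rate must lie in [0, 1]")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid length_range")
        need = 2 * self.stem_length + self.stem_loop
        if self.stem_length and need > lo:
            raise ValueError("planted stem does not fit the minimal length")


def _probs(gc_bias: float) -> np.ndarray:
    au = (1.0 - gc_bias) / 2.0
    gc = gc_bias / 2.0
    return np.array([au, gc, gc, au])  # A C G U


def random_sequence(
    rng: np.random.Generator,
    length: int,
    gc_bias: float = 0.5,
    stem_length: int = 0,
    stem_loop: int = 4,
    seq_id: str = "random",
) -> tuple[RnaSequence, tuple[BasePair, ...]]:
    """A random sequence, optionally with a planted hairpin stem.

    Returns the sequence and the planted base pairs (empty when no stem is
    requested).
    """
    letters = rng.choice(_LETTERS, size=length, p=_probs(gc_bias))
    residues = list(letters)
    planted: list[BasePair] = []
    if stem_length > 0:
        width = 2 * stem_length + stem_loop
        if width > length:
            raise ValueError("planted stem does not fit the sequence")
        start = int(rng.integers(1, length - width + 2))  # 1-based left end
        for t in range(stem_length):
            left = start + t
            right = start + width - 1 - t
            base = str(rng.choice(("A", "C", "G", "U"), p=_probs(gc_bias)))
            residues[left - 1] = base
            residues[right - 1] = _WC[base]
            planted.append(BasePair(left, right))
    return RnaSequence(seq_id, "".join(residues)), tuple(sorted(planted))


def mutate_homolog(
    rng: np.random.Generator,
    ancestor: RnaSequence,
    mutation_rate: float,
    indel_rate: float,
    planted: tuple[BasePair, ...] = (),
    seq_id: str = "homolog",
) -> tuple[RnaSequence, tuple[tuple[int, int], ...]]:
    """Derive a homolog by substitutions and indels.

    Substitutions at a planted-stem position mutate the partner position
    compensatorily so the stem stays complementary.  Returns the derived
    sequence and the true alignment edges (ancestor position, homolog
    position) for all conserved sites.
    """
    residues = list(ancestor.residues)
    partner: dict[int, int] = {}
    for p in planted:
        partner[p.left] = p.right
        partner[p.right] = p.left
    # substitutions (each site considered once; compensation may overwrite)
    for pos in range(1, len(residues) + 1):
        if rng.random() < mutation_rate:
            old = residues[pos - 1]
            new = str(rng.choice([x for x in _LETTERS if x != old]))
            residues[pos - 1] = new
            if pos in partner:
                residues[partner[pos] - 1] = _WC[new]
    # indels: per-site deletion or insertion-after, planted stem untouched
    out: list[str] = []
    edges: list[tuple[int, int]] = []
    for pos in range(1, len(residues) + 1):
        protected = pos in partner
        if not protected and rng.random() < indel_rate / 2.0:
            continue  # deletion
        out.append(residues[pos - 1])
        edges.append((pos, len(out)))
        if not protected and rng.random() < indel_rate / 2.0:
            out.append(str(rng.choice(_LETTERS, p=_probs(0.5))))
    if not out:
        out = [residues[0]]
        edges = [(1, 1)]
    return RnaSequence(seq_id, "".join(out)), tuple(edges)


@dataclass(frozen=True)
class HomologPair:
    """A seeded homolog pair with its ground truth."""

    seq_a: RnaSequence
    seq_b: RnaSequence
    true_edges: tuple[tuple[int, int], ...]
    planted_a: tuple[BasePair, ...]


def make_pair(spec: FixtureSpec, index: int) -> HomologPair:
    """Deterministically generate homolog pair number ``index`` of a spec."""
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, index)))
    lo, hi = spec.length_range
    length = int(rng.integers(lo, hi + 1))
    anc, planted = random_sequence(
        rng,
        length,
        spec.gc_bias,
        spec.stem_length,
        spec.stem_loop,
        seq_id=f"pair{index}_a",
    )
    hom, edges = mutate_homolog(
        rng,
        anc,
        spec.mutation_rate,
        spec.indel_rate,
        planted,
        seq_id=f"pair{index}_b",
    )
    return HomologPair(anc, hom, edges, planted)


def make_sequence(spec: FixtureSpec, index: int) -> tuple[RnaSequence, tuple[BasePair, ...]]:
    """Deterministically generate singleton sequence number ``index``."""
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 10_000 + index)))
    lo, hi = spec.length_range
    length = int(rng.integers(lo, hi + 1))
    return random_sequence(
        rng,
        length,
        spec.gc_bias,
        spec.stem_length,
        spec.stem_loop,
        seq_id=f"seq{index}",
    )


def generate_fixtures(spec: FixtureSpec, outdir: str | Path) -> list[Path]:
    """Write singleton and homolog-pair FASTA files; byte-identical per seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    singles = outdir / "singletons.fa"
    with open(singles, "w") as fh:
        for idx in range(spec.n_sequences):
            seq, _ = make_sequence(spec, idx)
            fh.write(f">{seq.id}\n{seq.residues}\n")
    paths.append(singles)
    for idx in range(spec.n_sequences):
        pair = make_pair(spec, idx)
        path = outdir / f"pair_{idx:03d}.fa"
        with open(path, "w") as fh:
            fh.write(f">{pair.seq_a.id}\n{pair.seq_a.residues}\n")
            fh.write(f">{pair.seq_b.id}\n{pair.seq_b.residues}\n")
        paths.append(path)
    return paths
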