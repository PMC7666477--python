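"""FASTA input, alignment text output and the JSON result sidecar."""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from .aligner import AlignmentResult
from .structures import RnaSequence, write_dotbracket

logger = logging.getLogger("pankov")


def read_fasta(path: str | Path) -> list[RnaSequence]:
    """Read RNA sequences from FASTA; DNA T residues transliterate to U."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    out: list[RnaSequence] = []
    for record in SeqIO.parse(str(path), "fasta"):
        raw = str(record.seq).upper()
        if "T" in raw:
            logger.warning(
                "sequence %s contains T residues; transliterating to U", record.id
            )
            raw = raw.replace("T", "U")
        out.append(RnaSequence(record.id, raw))
    if not out:
        raise ValueError(f"no FASTA records in {path}")
    return out


def write_fasta(seqs: Iterable[RnaSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n{s.residues}\n")


def _gapped(result: AlignmentResult) -> tuple[str, str, str, str]:
    """Gapped sequence and structure lines in alignment coordinates."""
    a = result.seq_a.residues
    b = result.seq_b.residues
    db_a = write_dotbracket(result.structure_a)
    db_b = write_dotbracket(result.structure_b)
    ga: list[str] = []
    gb: list[str] = []
    sa: list[str] = []
    sb: list[str] = []
    ia = ib = 1

    def emit(ca, cb, xa, xb):
        ga.append(ca)
        gb.append(cb)
        sa.append(xa)
        sb.append(xb)

    for ea, eb in result.edges:
        while ia < ea:
            emit(a[ia - 1], "-", db_a[ia - 1], "-")
            ia += 1
        while ib < eb:
            emit("-", b[ib - 1], "-", db_b[ib - 1])
            ib += 1
        emit(a[ea - 1], b[eb - 1], db_a[ea - 1], db_b[eb - 1])
        ia, ib = ea + 1, eb + 1
    while ia <= len(a):
        emit(a[ia - 1], "-", db_a[ia - 1], "-")
        ia += 1
    while ib <= len(b):
        emit("-", b[ib - 1], "-", db_b[ib - 1])
        ib += 1
    return "".join(ga), "".join(gb), "".join(sa), "".join(sb)


def format_alignment(result: AlignmentResult, width: int = 60) -> str:
    """Clustal-like pairwise block with per-sequence dot-bracket lines."""
    ga, gb, sa, sb = _gapped(result)
    name_w = max(len(result.seq_a.id), len(result.seq_b.id), 9)
    lines = [
        f"# pankov alignment  score={result.total_score:.4f} "
        f"(sequence={result.sequence_score:.4f} "
        f"structure={result.structure_score:.4f} "
        f"gaps={result.indel_score:.4f} n_indel={result.n_indel})"
    ]
    for off in range(0, len(ga), width):
        sl = slice(off, off + width)
        lines.append(f"{result.seq_a.id:<{name_w}} {ga[sl]}")
        lines.append(f"{'':<{name_w}} {sa[sl]}")
        lines.append(f"{result.seq_b.id:<{name_w}} {gb[sl]}")
        lines.append(f"{'':<{name_w}} {sb[sl]}")
        lines.append("")
    return "\n".join(lines)


def result_to_json(result: AlignmentResult) -> dict:
    """Machine-readable form of an alignment result."""
    return {
        "seq_a": {"id": result.seq_a.id, "residues": result.seq_a.residues},
        "seq_b": {"id": result.seq_b.id, "residues": result.seq_b.residues},
        "edges": [list(e) for e in result.edges],
        "n_indel": result.n_indel,
        "structure_a": write_dotbracket(result.structure_a),
        "structure_b": write_dotbracket(result.structure_b),
        "total_score": result.total_score,
        "components": {
            "sequence": result.sequence_score,
            "structure": result.structure_score,
            "indel": result.indel_score,
        },
    }


def write_result_json(result: AlignmentResult, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(result_to_json(result), fh, indent=2)
        fh.write("\n")
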