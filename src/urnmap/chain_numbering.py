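"""Transfer of prototype chain numbering by global sequence alignment.

The groove alpha and beta chains form a homologous family, so a target chain
is put into the prototype's position numbering with a single Needleman-Wunsch
global alignment (BLOSUM62, affine gaps 10/1 by default).  Matched target
residues inherit the prototype position number; unmatched residues are
explicit gaps.  An identity floor (default 40%) guards against aligning a
misassigned chain.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .errors import HomologyError

DEFAULT_IDENTITY_FLOOR = 0.4


@dataclass
class PositionMapping:
    """target residue index -> prototype position number (strictly increasing)."""

    mapping: dict[int, int]
    score: float
    identity: float

    def get(self, index: int) -> int | None:
        return self.mapping.get(index)


@lru_cache(maxsize=8)
def _aligner(open_gap: float, extend_gap: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -open_gap
    aligner.extend_gap_score = -extend_gap
    return aligner


def _sanitize(seq: str) -> str:
    alphabet = set("ARNDCQEGHILKMFPSTWYVBZX")
    return "".join(c if c in alphabet else "X" for c in seq.upper())


def alignment_score(seq_a: str, seq_b: str,
                    open_gap: float = 10.0, extend_gap: float = 1.0) -> float:
    """Global alignment score, normalized by the shorter sequence length."""
    if not seq_a or not seq_b:
        return float("-inf")
    score = _aligner(open_gap, extend_gap).score(_sanitize(seq_a), _sanitize(seq_b))
    return score / min(len(seq_a), len(seq_b))


def align_to_prototype(
    target_seq: str,
    prototype_seq: str,
    prototype_positions: Sequence[int] | None = None,
    identity_floor: float = DEFAULT_IDENTITY_FLOOR,
    open_gap: float = 10.0,
    extend_gap: float = 1.0,
) -> PositionMapping:
    """Map target residue indices to prototype position numbers.

    ``prototype_positions`` gives the position number of each prototype
    residue (defaults to 1..n, the convention when the prototype numbering is
    sequential).  Raises :class:`HomologyError` if the fraction of identical
    residues over aligned columns falls below ``identity_floor``.
    """
    if not target_seq or not prototype_seq:
        raise ValueError("sequences must be non-empty")
    if prototype_positions is None:
        prototype_positions = list(range(1, len(prototype_seq) + 1))
    if len(prototype_positions) != len(prototype_seq):
        raise ValueError("prototype_positions length mismatch")

    aligner = _aligner(open_gap, extend_gap)
    alignment = aligner.align(_sanitize(target_seq), _sanitize(prototype_seq))[0]
    mapping: dict[int, int] = {}
    matches = aligned_cols = 0
    for (t0, t1), (p0, p1) in zip(*alignment.aligned):
        for k in range(t1 - t0):
            ti, pi = t0 + k, p0 + k
            mapping[ti] = int(prototype_positions[pi])
            aligned_cols += 1
            if target_seq[ti].upper() == prototype_seq[pi].upper():
                matches += 1
    identity = matches / aligned_cols if aligned_cols else 0.0
    if identity < identity_floor:
        raise HomologyError(
            f"identity {identity:.2f} below floor {identity_floor:.2f}; "
            "the chain is probably misassigned")
    return PositionMapping(mapping=mapping, score=float(alignment.score),
                           identity=identity)


def mapping_to_tsv(mapping: PositionMapping) -> str:
    lines = ["target_index\tprototype_position"]
    for idx in sorted(mapping.mapping):
        lines.append(f"{idx}\t{mapping.mapping[idx]}")
    return "\n".join(lines) + "\n"
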