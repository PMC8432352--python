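"""Pairwise sequence identity primitive.

Every similarity decision in the pipeline — anchoring on *vriC*, typing a
tail spike protein (TSP) by its N-terminus, the 75 % subtype cut-off and the
detection of shared receptor-binding modules — reduces to one of two
operations: optimal *global* alignment identity or best *local* alignment
block. Both are computed with Biopython's :class:`Bio.Align.PairwiseAligner`
under a single parameter set (BLOSUM62, affine gap cost 10 + 1 per position,
end gaps penalized like internal gaps).

Percent identity is, by default, the number of identical columns divided by
the *total* number of alignment columns, end gaps included.  This is the
conservative denominator: it can only lower identity relative to counting
aligned columns only, so a pair passing a 75 % threshold under it passes
under any common convention.  The alternative denominator ("aligned": columns
where both sequences have a residue) is available via
``AlignmentParams.denominator`` for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Optional

from Bio import Align
from Bio.Align import substitution_matrices

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

__all__ = [
    "AlignmentParams",
    "IdentityResult",
    "global_identity",
    "local_identity",
    "PROTEIN_ALPHABET",
]


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring parameters shared by all protein alignments in the pipeline.

    ``gap_open_cost`` is the cost of opening a gap and ``gap_extend_cost`` the
    cost of each gapped position, so a gap of length L costs
    ``gap_open_cost + L * gap_extend_cost``.  With ``end_gaps_penalized`` set
    (the default) terminal gaps are charged exactly like internal ones.
    """

    substitution_model: str = "BLOSUM62"
    gap_open_cost: float = 10.0
    gap_extend_cost: float = 1.0
    end_gaps_penalized: bool = True
    denominator: str = "alignment"  # "alignment" | "aligned"

    def __post_init__(self) -> None:
        if self.gap_open_cost <= 0 or self.gap_extend_cost <= 0:
            raise ValueError("gap costs must be positive")
        if self.denominator not in ("alignment", "aligned"):
            raise ValueError("denominator must be 'alignment' or 'aligned'")


@dataclass
class IdentityResult:
    """Outcome of one pairwise alignment.

    ``identity`` = ``matches / alignment_length`` (or over aligned columns,
    depending on the params' denominator).  ``aligned_pairs`` holds 1-based
    (pos_a, pos_b) for every column where both sequences contribute a
    residue.  For local alignments ``start_*``/``end_*`` are the 1-based
    first/last aligned residues in each input.
    """

    identity: float
    alignment_length: int
    matches: int
    score: float
    aligned_pairs: list[tuple[int, int]] = field(default_factory=list, repr=False)
    start_a: int = 1
    start_b: int = 1
    end_a: int = 0
    end_b: int = 0


def _validate_protein(seq: str, name: str) -> None:
    if not seq:
        raise ValueError(f"sequence {name!r} is empty")
    bad = set(seq) - PROTEIN_ALPHABET
    if bad:
        raise ValueError(
            f"sequence {name!r} contains residues outside the 20-letter "
            f"alphabet plus X: {sorted(bad)}"
        )


@lru_cache(maxsize=8)
def _matrix(name: str):
    return substitution_matrices.load(name)


@lru_cache(maxsize=32)
def _aligner(params: AlignmentParams, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = _matrix(params.substitution_model)
    aligner.open_gap_score = -(params.gap_open_cost + params.gap_extend_cost)
    aligner.extend_gap_score = -params.gap_extend_cost
    if mode == "global" and not params.end_gaps_penalized:
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    aligner.mode = mode
    return aligner


def _collect(a: str, b: str, alignment) -> tuple[int, list[tuple[int, int]]]:
    """Identical-column count and 1-based aligned pairs of an alignment."""
    matches = 0
    pairs: list[tuple[int, int]] = []
    blocks_a, blocks_b = alignment.aligned
    for (sa, ea), (sb, _eb) in zip(blocks_a, blocks_b):
        for offset in range(ea - sa):
            ia, ib = sa + offset, sb + offset
            pairs.append((ia + 1, ib + 1))
            if a[ia] == b[ib]:
                matches += 1
    return matches, pairs


def global_identity(
    a: str, b: str, params: AlignmentParams | None = None
) -> IdentityResult:
    """Percent identity of the optimal global alignment of ``a`` and ``b``.

    Symmetric in its arguments (identity(a, b) == identity(b, a)); equals 1.0
    iff the sequences are equal (under the default all-columns denominator).
    """
    params = params or AlignmentParams()
    _validate_protein(a, "a")
    _validate_protein(b, "b")
    alignment = _aligner(params, "global").align(a, b)[0]
    matches, pairs = _collect(a, b, alignment)
    length = alignment.length
    denom = length if params.denominator == "alignment" else max(len(pairs), 1)
    return IdentityResult(
        identity=matches / denom,
        alignment_length=length,
        matches=matches,
        score=alignment.score,
        aligned_pairs=pairs,
        start_a=1,
        start_b=1,
        end_a=len(a),
        end_b=len(b),
    )


def local_identity(
    a: str,
    b: str,
    params: AlignmentParams | None = None,
    min_block: int = 100,
) -> Optional[IdentityResult]:
    """Best-scoring local alignment block, or None if shorter than ``min_block``.

    Start/end positions are the 1-based coordinates of the first/last aligned
    residue in each sequence.
    """
    params = params or AlignmentParams()
    _validate_protein(a, "a")
    _validate_protein(b, "b")
    alignments = _aligner(params, "local").align(a, b)
    if alignments.score <= 0:
        return None
    alignment = alignments[0]
    if alignment.length < min_block:
        return None
    matches, pairs = _collect(a, b, alignment)
    if not pairs:
        return None
    denom = (
        alignment.length if params.denominator == "alignment" else len(pairs)
    )
    return IdentityResult(
        identity=matches / denom,
        alignment_length=alignment.length,
        matches=matches,
        score=alignment.score,
        aligned_pairs=pairs,
        start_a=pairs[0][0],
        start_b=pairs[0][1],
        end_a=pairs[-1][0],
        end_b=pairs[-1][1],
    )
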