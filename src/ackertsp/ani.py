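"""Fragment-based average nucleotide identity (ANI) between phage genomes.

Genome ``a`` is cut into non-overlapping fragments (default 500 nt).  Each
fragment is placed in genome ``b`` by exact seed words (default 15-mers):
seed hits vote by diagonal, the best diagonal defines a candidate window,
and the fragment is locally aligned against that window (match +1, mismatch
−2; a gap of length L costs 4 + 2L).  Blocks shorter than the minimum block
length (default 100 nt) are dropped.  The directional ANI is the
length-weighted mean block identity over kept blocks; the reported ANI is
the mean of the two directions, on the 0–100 scale.  A pair with no
qualifying block in either direction has no ANI (None), which is itself the
informative negative: unrelated genomes do not share seeded blocks.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import numpy as np
from Bio import Align

from .genome_io import PhageGenome

__all__ = ["AniParams", "AniMatrix", "genome_ani", "ani_matrix", "genus_ani_summary"]


@dataclass(frozen=True)
class AniParams:
    seed_length: int = 15
    min_block_length: int = 100
    fragment_length: int = 500
    window_margin: int = 50

    def __post_init__(self) -> None:
        if self.seed_length < 8:
            raise ValueError("seed_length must be >= 8")
        if self.min_block_length <= self.seed_length:
            raise ValueError("min_block_length must exceed seed_length")


@dataclass
class AniMatrix:
    ids: list[str]
    ani: np.ndarray  # percentages; NaN where no qualifying blocks
    aligned_fraction: np.ndarray


@lru_cache(maxsize=1)
def _dna_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.match_score = 1.0
    aligner.mismatch_score = -2.0
    aligner.open_gap_score = -6.0  # gap open 4 + first position 2
    aligner.extend_gap_score = -2.0
    aligner.mode = "local"
    return aligner


def _seed_index(sequence: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(sequence) - k + 1):
        index.setdefault(sequence[i : i + k], []).append(i)
    return index


def _block_stats(fragment: str, window: str) -> tuple[int, int, float]:
    """(block columns, matches, score) of the best local alignment."""
    alignments = _dna_aligner().align(fragment, window)
    if alignments.score <= 0:
        return 0, 0, 0.0
    alignment = alignments[0]
    matches = 0
    blocks_a, blocks_b = alignment.aligned
    for (sa, ea), (sb, _eb) in zip(blocks_a, blocks_b):
        for off in range(ea - sa):
            if fragment[sa + off] == window[sb + off]:
                matches += 1
    return alignment.length, matches, alignment.score


def _directional(a: str, b: str, params: AniParams) -> tuple[Optional[float], float]:
    """Length-weighted mean block identity of a's fragments placed in b."""
    index = _seed_index(b, params.seed_length)
    k = params.seed_length
    total_cols = 0
    total_matches = 0
    covered = 0
    for frag_start in range(0, len(a) - params.fragment_length + 1, params.fragment_length):
        fragment = a[frag_start : frag_start + params.fragment_length]
        diagonals: dict[int, int] = {}
        for i in range(0, len(fragment) - k + 1):
            for bpos in index.get(fragment[i : i + k], ()):
                diag = bpos - i
                diagonals[diag] = diagonals.get(diag, 0) + 1
        if not diagonals:
            continue
        diag = max(diagonals, key=lambda d: (diagonals[d], -abs(d - frag_start)))
        w_start = max(0, diag - params.window_margin)
        w_end = min(len(b), diag + len(fragment) + params.window_margin)
        cols, matches, _score = _block_stats(fragment, b[w_start:w_end])
        if cols < params.min_block_length:
            continue
        total_cols += cols
        total_matches += matches
        covered += cols
    if total_cols == 0:
        return None, 0.0
    return 100.0 * total_matches / total_cols, covered / len(a)


def genome_ani(
    a: PhageGenome, b: PhageGenome, params: AniParams | None = None
) -> tuple[Optional[float], float]:
    """Symmetrized ANI percentage and mean aligned fraction for one pair."""
    params = params or AniParams()
    if len(a.sequence) < params.fragment_length or len(b.sequence) < params.fragment_length:
        raise ValueError("both genomes must be at least one fragment long")
    ani_ab, frac_ab = _directional(a.sequence, b.sequence, params)
    ani_ba, frac_ba = _directional(b.sequence, a.sequence, params)
    values = [v for v in (ani_ab, ani_ba) if v is not None]
    if not values:
        return None, 0.0
    return float(np.mean(values)), float((frac_ab + frac_ba) / 2)


def ani_matrix(genomes: list[PhageGenome], params: AniParams | None = None) -> AniMatrix:
    """All unordered pairs; diagonal 100, NaN where nothing qualifies."""
    if len(genomes) < 2:
        raise ValueError("need at least two genomes")
    params = params or AniParams()
    n = len(genomes)
    ani = np.full((n, n), np.nan)
    frac = np.zeros((n, n))
    np.fill_diagonal(ani, 100.0)
    np.fill_diagonal(frac, 1.0)
    for i in range(n):
        for j in range(i + 1, n):
            value, fraction = genome_ani(genomes[i], genomes[j], params)
            if value is not None:
                ani[i, j] = ani[j, i] = value
            frac[i, j] = frac[j, i] = fraction
    return AniMatrix(ids=[g.identifier for g in genomes], ani=ani, aligned_fraction=frac)


def genus_ani_summary(
    matrix: AniMatrix, genus_of: dict[str, str]
) -> dict[str, tuple[float, float]]:
    """Per genus, (min, max) within-genus ANI over pairs with a defined value."""
    summary: dict[str, tuple[float, float]] = {}
    by_genus: dict[str, list[int]] = {}
    for idx, gid in enumerate(matrix.ids):
        by_genus.setdefault(genus_of.get(gid, "unknown"), []).append(idx)
    for genus, indices in by_genus.items():
        values = [
            matrix.ani[i, j]
            for ii, i in enumerate(indices)
            for j in indices[ii + 1 :]
            if not np.isnan(matrix.ani[i, j])
        ]
        if values:
            summary[genus] = (float(min(values)), float(max(values)))
    return summary
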