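"""Shared receptor-binding modules and the conserved TD1-boundary motif.

Within the Kuttervirus genus, some TSP1/TSP3 proteins are near-identical to
TSP4 proteins everywhere except the type-specific N-terminus: the shared
region starts at residue 65 in TSP1/TSP3 and residue 391 in TSP4 and runs to
the C-terminus — evidence that the C-terminal receptor-binding module is
exchanged between TSP scaffolds.  :func:`detect_module_share` formalises
this as a C-terminally anchored local-alignment detector with explicit
thresholds (identity >= 0.75 over >= 300 residues, both block ends within a
tolerance of their protein's C-terminus).

The module boundary coincides with the distal part of the TD1 domain, where
a conserved 7-residue motif (GTTAVSL) marks a putative recombination site.
:func:`find_conserved_motif` recovers such motifs by exhaustive exact k-mer
support counting over pooled TD1 slices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .identity import AlignmentParams, local_identity
from .tsp_typing import TspProtein

# 1-based inclusive TD1 regions per TSP type
TD1_REGIONS = {1: (1, 96), 2: (157, 257), 3: (1, 96), 4: (344, 421)}

__all__ = [
    "ModuleShareHit",
    "MotifHit",
    "detect_module_share",
    "extract_td1",
    "find_conserved_motif",
    "TD1_REGIONS",
]


@dataclass
class ModuleShareHit:
    """A shared C-terminal module between a type-1/3 and a type-4 TSP."""

    protein_a: str  # type 1 or 3
    protein_b: str  # type 4
    start_a: int  # 1-based first identical aligned residue in a
    start_b: int
    block_identity: float
    block_length: int


@dataclass
class MotifHit:
    motif: str
    support: float
    positions: dict[int, int] = field(default_factory=dict)  # region index -> 1-based pos


def detect_module_share(
    a: TspProtein,
    b: TspProtein,
    min_identity: float = 0.75,
    min_block: int = 300,
    cterm_tolerance: int = 10,
    params: AlignmentParams | None = None,
) -> Optional[ModuleShareHit]:
    """Detect a shared C-terminal receptor-binding module between ``a`` and ``b``.

    ``a`` must be type 1 or 3 and ``b`` type 4 (the roles may be given
    swapped; the hit is reported in canonical orientation either way).  The
    best local alignment is accepted only if it is long enough, identical
    enough, and reaches within ``cterm_tolerance`` residues of *both*
    C-termini — internal similarity without C-terminal anchoring is not a
    module swap.  Start positions are the first identical aligned column of
    the accepted block, the convention that pins the junction at the
    conserved-motif boundary.
    """
    if a.tsp_type == 4 and b.tsp_type in (1, 3):
        mirrored = detect_module_share(b, a, min_identity, min_block, cterm_tolerance, params)
        return mirrored
    if a.tsp_type not in (1, 3) or b.tsp_type != 4:
        raise ValueError("detect_module_share expects one type-1/3 and one type-4 TSP")
    result = local_identity(a.sequence, b.sequence, params, min_block=min_block)
    if result is None:
        return None
    if result.end_a < len(a.sequence) - cterm_tolerance:
        return None
    if result.end_b < len(b.sequence) - cterm_tolerance:
        return None
    trimmed = _trim_weak_prefix(a.sequence, b.sequence, result.aligned_pairs, min_identity)
    if trimmed is None:
        return None
    pairs, block_length, block_identity = trimmed
    if block_length < min_block or block_identity < min_identity:
        return None
    return ModuleShareHit(
        protein_a=a.protein_id,
        protein_b=b.protein_id,
        start_a=pairs[0][0],
        start_b=pairs[0][1],
        block_identity=block_identity,
        block_length=block_length,
    )


_ANCHOR_RUN = 5


def _trim_weak_prefix(
    seq_a: str, seq_b: str, pairs: list[tuple[int, int]], min_identity: float
):
    """Refine the block start to the onset of sustained identity.

    Under cheap gap extension the optimal local alignment can drag a weak,
    chance-similarity prefix along with a genuinely shared block, so the
    first aligned (or even first identical) column is an unstable junction
    estimate.  The start is instead the first run of ``_ANCHOR_RUN``
    consecutive identical columns (consecutive in both sequences): a chance
    run of 5 exact residues between unrelated scaffolds has probability
    ~20^-5 per position, while a real module junction opens with the
    conserved 7-residue motif.  Returns (trimmed pairs, columns, identity).
    """
    is_match = [seq_a[pa - 1] == seq_b[pb - 1] for pa, pb in pairs]
    start_index = None
    for i in range(len(pairs) - _ANCHOR_RUN + 1):
        if not all(is_match[i : i + _ANCHOR_RUN]):
            continue
        consecutive = all(
            pairs[i + k + 1][0] == pairs[i + k][0] + 1
            and pairs[i + k + 1][1] == pairs[i + k][1] + 1
            for k in range(_ANCHOR_RUN - 1)
        )
        if consecutive:
            start_index = i
            break
    if start_index is None:
        return None
    kept = pairs[start_index:]
    matches = sum(is_match[start_index:])
    span_a = kept[-1][0] - kept[0][0] + 1
    span_b = kept[-1][1] - kept[0][1] + 1
    # columns = every advance in a or b; both advance together on a pair
    block_length = span_a + span_b - len(kept)
    return kept, block_length, matches / block_length


def extract_td1(p: TspProtein) -> str:
    """Type-specific TD1 slice (1-based inclusive region per type)."""
    if p.tsp_type not in TD1_REGIONS:
        raise ValueError(f"protein {p.protein_id} has no assigned TSP type")
    start, end = TD1_REGIONS[p.tsp_type]
    if len(p.sequence) < end:
        raise ValueError(
            f"protein {p.protein_id} (length {len(p.sequence)}) shorter than "
            f"TD1 region end {end} for type {p.tsp_type}"
        )
    return p.sequence[start - 1 : end]


def find_conserved_motif(
    regions: list[str],
    k_min: int = 5,
    k_max: int = 10,
    min_support: float = 0.8,
) -> list[MotifHit]:
    """Exact k-mers of the first region with high support across all regions.

    All k-mers (k_min <= k <= k_max) of ``regions[0]`` are scored by the
    fraction of regions containing them as exact substrings.  Hits with
    support >= ``min_support`` are returned longest first; a hit contained in
    an already-reported longer hit with equal support is suppressed.
    """
    if len(regions) < 2:
        raise ValueError("need at least two regions")
    hits: list[MotifHit] = []
    n = len(regions)
    for k in range(k_max, k_min - 1, -1):
        seen: set[str] = set()
        for i in range(len(regions[0]) - k + 1):
            kmer = regions[0][i : i + k]
            if kmer in seen:
                continue
            seen.add(kmer)
            containing = [idx for idx, r in enumerate(regions) if kmer in r]
            support = len(containing) / n
            if support < min_support:
                continue
            suppressed = any(
                kmer in kept.motif and abs(kept.support - support) < 1e-12
                for kept in hits
            )
            if suppressed:
                continue
            hits.append(
                MotifHit(
                    motif=kmer,
                    support=support,
                    positions={idx: regions[idx].index(kmer) + 1 for idx in containing},
                )
            )
    hits.sort(key=lambda h: (-len(h.motif), -h.support, h.motif))
    return hits
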