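"""Typing of tail spike proteins by N-terminal similarity.

The four TSPs of an *Ackermannviridae* phage assemble into one branched
receptor-binding complex through their N-termini, which are type-specific
and conserved family-wide while the C-terminal receptor-binding modules are
free to vary.  A candidate is therefore typed by aligning its N-terminal
window against each of four reference N-termini (modelled on the four TSPs
of the reference Kuttervirus) and taking the argmax, provided the best
identity clears a floor (default 0.30 — comfortably above the 5–30 %
background between unrelated receptor-binding modules, far below within-type
N-terminal conservation).

A phage carries at most one TSP of each type; :func:`resolve_phage_types`
enforces this by letting the higher-identity candidate keep a contested
type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .cluster_extraction import TspCandidate
from .identity import AlignmentParams, global_identity
from .references import TYPING_WINDOW, reference_tsps

DEFAULT_TYPING_THRESHOLD = 0.30
_TIE_EPS = 1e-9

__all__ = [
    "TspProtein",
    "TypingReference",
    "assign_type",
    "resolve_phage_types",
    "default_typing_reference",
    "DEFAULT_TYPING_THRESHOLD",
]


@dataclass
class TspProtein:
    """A typed tail spike protein with phage provenance."""

    phage_id: str
    cluster_index: int
    sequence: str
    tsp_type: int | None = None  # 1..4, None = unassigned
    type_identity: float = 0.0
    ambiguous: bool = False
    subtype: str | None = None

    @property
    def protein_id(self) -> str:
        return f"{self.phage_id}/tsp{self.cluster_index}"


@dataclass
class TypingReference:
    """Four named N-terminal reference segments, one per TSP type."""

    segments: dict[int, str]
    windows: dict[int, int] = field(default_factory=lambda: dict(TYPING_WINDOW))

    def __post_init__(self) -> None:
        if set(self.segments) != {1, 2, 3, 4}:
            raise ValueError("typing reference needs segments for types 1..4")
        if len(set(self.segments.values())) != 4:
            raise ValueError("reference segments must be pairwise distinct")
        for t, w in self.windows.items():
            if w <= 0:
                raise ValueError(f"window for type {t} must be positive")
        # clip each segment to its own window
        self.segments = {t: s[: self.windows[t]] for t, s in self.segments.items()}


def default_typing_reference() -> TypingReference:
    """Typing reference built from the packaged synthetic reference TSPs."""
    return TypingReference(segments=reference_tsps())


def assign_type(
    candidate: TspCandidate,
    ref: TypingReference | None = None,
    threshold: float = DEFAULT_TYPING_THRESHOLD,
    params: AlignmentParams | None = None,
) -> TspProtein:
    """Assign TSP type 1–4 by best N-terminal identity, or leave unassigned.

    The candidate's first W_t residues are globally aligned against the
    type-t reference segment.  A tie at the maximum (within 1e-9) leaves the
    protein unassigned with the ``ambiguous`` flag set.
    """
    params = params or AlignmentParams()
    ref = ref or default_typing_reference()
    scores: dict[int, float] = {}
    for t, segment in ref.segments.items():
        window = ref.windows[t]
        prefix = candidate.protein[:window]
        scores[t] = global_identity(prefix, segment, params).identity
    best_type = max(scores, key=lambda t: scores[t])
    best = scores[best_type]
    runner_up = max(v for t, v in scores.items() if t != best_type)
    protein = TspProtein(
        phage_id=candidate.phage_id,
        cluster_index=candidate.cluster_index,
        sequence=candidate.protein,
    )
    if best - runner_up <= _TIE_EPS and best >= threshold:
        protein.ambiguous = True
        protein.type_identity = best
    elif best >= threshold:
        protein.tsp_type = best_type
        protein.type_identity = best
    else:
        protein.type_identity = best
    return protein


def resolve_phage_types(proteins: list[TspProtein]) -> list[TspProtein]:
    """Enforce at most one TSP per type within a phage.

    When several candidates claim the same type, the one with the highest
    type identity keeps it (ties: lowest cluster index) and the others become
    unassigned.  Missing types are simply absent.
    """
    if len({p.phage_id for p in proteins}) > 1:
        raise ValueError("resolve_phage_types expects proteins of a single phage")
    by_type: dict[int, list[TspProtein]] = {}
    for protein in proteins:
        if protein.tsp_type is not None:
            by_type.setdefault(protein.tsp_type, []).append(protein)
    for tsp_type, claimants in by_type.items():
        claimants.sort(key=lambda p: (-p.type_identity, p.cluster_index))
        for loser in claimants[1:]:
            loser.tsp_type = None
    return proteins
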