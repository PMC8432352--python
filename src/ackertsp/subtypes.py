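"""Subtype clustering of same-type tail spike proteins.

TSPs of one type are partitioned into subtypes at a pairwise-identity
threshold (default 75 %, threshold inclusive).  The partition is the set of
connected components of the graph with an edge wherever identity >= the
threshold — single-linkage semantics, the parameter-free closure of
">= 75 % identical to something in the group".  On family-shaped data the
linkage choice is immaterial because within-subtype members are typically
>95 % identical while cross-subtype identity stays below ~30 %.

Labels are ``TSP{t}-{k}`` with k ordered by descending component size (ties:
lexicographically smallest member id), so the labelling is invariant to
input order.  Label *numbers* are a property of the cohort, not of the
published tables; correspondence with published subtype names is established
by membership, via the packaged knowledge tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .identity import AlignmentParams, global_identity
from .tsp_typing import TspProtein

DEFAULT_SUBTYPE_THRESHOLD = 0.75

__all__ = [
    "IdentityMatrix",
    "SubtypeAssignment",
    "identity_matrix",
    "cluster_subtypes",
    "genus_association",
    "DEFAULT_SUBTYPE_THRESHOLD",
]


@dataclass
class IdentityMatrix:
    ids: list[str]
    values: np.ndarray  # symmetric, unit diagonal, fractions in [0, 1]
    tsp_type: int | None = None

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("identity matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 1.0):
            raise ValueError("identity matrix must have unit diagonal")


@dataclass
class SubtypeAssignment:
    tsp_type: int
    labels: dict[str, str]  # protein id -> "TSP{t}-{k}"
    members: dict[str, list[str]] = field(default_factory=dict)
    threshold: float = DEFAULT_SUBTYPE_THRESHOLD


def identity_matrix(
    proteins: list[TspProtein], params: AlignmentParams | None = None
) -> IdentityMatrix:
    """All-vs-all global identity of same-type TSPs (computed once per pair)."""
    if not proteins:
        raise ValueError("need at least one protein")
    types = {p.tsp_type for p in proteins}
    if len(types) != 1:
        raise ValueError(f"identity_matrix requires a single TSP type, got {types}")
    params = params or AlignmentParams()
    ids = [p.protein_id for p in proteins]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate protein ids")
    n = len(proteins)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            ident = global_identity(proteins[i].sequence, proteins[j].sequence, params).identity
            values[i, j] = values[j, i] = ident
    return IdentityMatrix(ids=ids, values=values, tsp_type=types.pop())


def cluster_subtypes(
    matrix: IdentityMatrix, threshold: float = DEFAULT_SUBTYPE_THRESHOLD
) -> SubtypeAssignment:
    """Connected components at identity >= threshold, canonically labelled."""
    if matrix.tsp_type is None:
        raise ValueError("matrix must carry its TSP type")
    graph = nx.Graph()
    graph.add_nodes_from(matrix.ids)
    n = len(matrix.ids)
    for i in range(n):
        for j in range(i + 1, n):
            if matrix.values[i, j] >= threshold:
                graph.add_edge(matrix.ids[i], matrix.ids[j])
    components = [sorted(c) for c in nx.connected_components(graph)]
    components.sort(key=lambda c: (-len(c), c[0]))
    labels: dict[str, str] = {}
    members: dict[str, list[str]] = {}
    for k, component in enumerate(components, start=1):
        label = f"TSP{matrix.tsp_type}-{k}"
        members[label] = component
        for pid in component:
            labels[pid] = label
    return SubtypeAssignment(
        tsp_type=matrix.tsp_type, labels=labels, members=members, threshold=threshold
    )


def _phage_of(protein_id: str) -> str:
    return protein_id.rsplit("/", 1)[0]


def genus_association(
    assignment: SubtypeAssignment, genus_of: dict[str, str]
) -> dict[str, dict]:
    """Per subtype, the set of member genera; flags subtypes spanning > 1.

    ``genus_of`` maps phage id -> genus; every member phage must be present.
    """
    table: dict[str, dict] = {}
    for label, member_ids in assignment.members.items():
        genera = set()
        for pid in member_ids:
            phage = _phage_of(pid)
            if phage not in genus_of:
                raise ValueError(f"no genus recorded for phage {phage!r}")
            genera.add(genus_of[phage])
        table[label] = {
            "genera": sorted(genera),
            "cross_genus": len(genera) > 1,
            "n_members": len(member_ids),
        }
    return table
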