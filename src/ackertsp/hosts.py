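"""Host-range prediction by subtype label transfer.

The biological premise: TSPs of one subtype (>= 75 % identity, typically
>95 %) carry near-identical receptor-binding modules and therefore recognise
the same O-antigen.  Once a subtype's receptor has been determined
experimentally for one member, the label transfers to every phage carrying
that subtype — and, through module-equivalence links (subtypes shown to
share their C-terminal module across TSP types), to module-equivalent
subtypes as well, at a downgraded evidence tier.

The packaged knowledge base transcribes the published subtype → receptor
table with its phage membership lists and the three shared-module links
(TSP1-1~TSP4-7, TSP3-3~TSP4-2, TSP3-1~TSP4-8).  Predictions always carry a
full provenance chain (phage → TSP → subtype → [equivalence] → knowledge
entry); a phage with no characterised subtype gets an empty prediction,
never a guess.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .references import data_path
from .subtypes import SubtypeAssignment, _phage_of

EVIDENCE_LEVELS = ("experimental", "inferred")

__all__ = [
    "KnowledgeEntry",
    "EquivalenceLink",
    "KnowledgeBase",
    "HostPrediction",
    "load_knowledge",
    "load_packaged_knowledge",
    "predict_hosts",
    "summarize_predictions",
]


@dataclass
class KnowledgeEntry:
    subtype: str
    receptor: str
    host_taxa: list[str]
    evidence: str  # experimental | inferred
    evidence_phage: str = ""
    printed_total: Optional[int] = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.evidence not in EVIDENCE_LEVELS:
            raise ValueError(f"unknown evidence level {self.evidence!r}")
        if not self.receptor:
            raise ValueError(f"entry for {self.subtype}: receptor must be non-empty")
        if self.evidence == "experimental" and not self.evidence_phage:
            raise ValueError(
                f"experimental entry for {self.subtype} must name an evidence phage"
            )


@dataclass(frozen=True)
class EquivalenceLink:
    subtype_a: str
    subtype_b: str
    basis: str  # shared_module | literature

    def __post_init__(self) -> None:
        if self.subtype_a == self.subtype_b:
            raise ValueError("equivalence links are irreflexive")
        if self.basis not in ("shared_module", "literature"):
            raise ValueError(f"unknown equivalence basis {self.basis!r}")


@dataclass
class KnowledgeBase:
    entries: list[KnowledgeEntry] = field(default_factory=list)
    links: list[EquivalenceLink] = field(default_factory=list)
    memberships: dict[str, list[str]] = field(default_factory=dict)  # subtype -> phages
    count_mismatches: dict[str, tuple[int, int]] = field(default_factory=dict)

    def entries_for(self, subtype: str) -> list[KnowledgeEntry]:
        return [e for e in self.entries if e.subtype == subtype]

    def equivalents_of(self, subtype: str) -> list[tuple[str, EquivalenceLink]]:
        out = []
        for link in self.links:
            if link.subtype_a == subtype:
                out.append((link.subtype_b, link))
            elif link.subtype_b == subtype:
                out.append((link.subtype_a, link))
        return out


@dataclass
class HostPrediction:
    phage_id: str
    # receptor -> list of provenance chains; each chain is a list of steps
    receptors: dict[str, list[dict]] = field(default_factory=dict)

    @property
    def is_empty(self) -> bool:
        return not self.receptors


def load_knowledge(
    table, memberships=None, links=None
) -> KnowledgeBase:
    """Build a KnowledgeBase from TSV streams/paths.

    ``table`` needs columns subtype, receptor, host_taxa, evidence; optional
    evidence_phage, printed_total, source.  Duplicate (subtype, receptor)
    rows collapse to one entry.  When a subtype's printed total disagrees
    with its membership-list length, the mismatch is recorded in
    ``count_mismatches`` — flagged, not silently resolved.
    """
    try:
        frame = pd.read_csv(table, sep="\t", dtype=str).fillna("")
    except Exception as exc:
        raise ValueError(f"malformed knowledge table: {exc}") from exc
    required = {"subtype", "receptor", "host_taxa", "evidence"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"knowledge table missing columns: {sorted(missing)}")
    entries: list[KnowledgeEntry] = []
    seen: set[tuple[str, str]] = set()
    for line, row in frame.iterrows():
        key = (row["subtype"], row["receptor"])
        if key in seen:
            continue
        seen.add(key)
        try:
            entries.append(
                KnowledgeEntry(
                    subtype=row["subtype"],
                    receptor=row["receptor"],
                    host_taxa=[h for h in row["host_taxa"].split(";") if h],
                    evidence=row["evidence"],
                    evidence_phage=row.get("evidence_phage", ""),
                    printed_total=int(row["printed_total"])
                    if row.get("printed_total", "")
                    else None,
                    source=row.get("source", ""),
                )
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"knowledge table row {line + 2}: {exc}") from exc

    membership_map: dict[str, list[str]] = {}
    if memberships is not None:
        mframe = pd.read_csv(memberships, sep="\t", dtype=str)
        if {"subtype", "phage"} - set(mframe.columns):
            raise ValueError("membership table needs columns subtype, phage")
        for _, row in mframe.iterrows():
            membership_map.setdefault(row["subtype"], []).append(row["phage"])

    link_list: list[EquivalenceLink] = []
    if links is not None:
        lframe = pd.read_csv(links, sep="\t", dtype=str)
        for _, row in lframe.iterrows():
            link_list.append(
                EquivalenceLink(row["subtype_a"], row["subtype_b"], row["basis"])
            )

    mismatches = {}
    for entry in entries:
        if entry.printed_total is not None and entry.subtype in membership_map:
            listed = len(set(membership_map[entry.subtype]))
            if listed != entry.printed_total:
                mismatches[entry.subtype] = (entry.printed_total, listed)
    return KnowledgeBase(
        entries=entries,
        links=link_list,
        memberships=membership_map,
        count_mismatches=mismatches,
    )


def load_packaged_knowledge() -> KnowledgeBase:
    """The packaged transcription of the published host-prediction table."""
    with data_path("knowledge_table.tsv").open() as t, data_path(
        "table3_memberships.tsv"
    ).open() as m, data_path("equivalence_links.tsv").open() as l:
        return load_knowledge(t, m, l)


def _chains_for_subtype(
    kb: KnowledgeBase, subtype: str, protein_id: str
) -> Iterable[tuple[str, dict]]:
    """(receptor, provenance) pairs reachable from a subtype label."""
    for entry in kb.entries_for(subtype):
        yield entry.receptor, {
            "protein": protein_id,
            "subtype": subtype,
            "via": None,
            "entry_subtype": entry.subtype,
            "hosts": entry.host_taxa,
            "evidence": entry.evidence,
        }
    for other, link in kb.equivalents_of(subtype):
        for entry in kb.entries_for(other):
            yield entry.receptor, {
                "protein": protein_id,
                "subtype": subtype,
                "via": f"{link.basis}:{other}",
                "entry_subtype": entry.subtype,
                "hosts": entry.host_taxa,
                # any equivalence hop downgrades the tier
                "evidence": "inferred",
            }


def predict_hosts(
    assignments: list[SubtypeAssignment], kb: KnowledgeBase
) -> list[HostPrediction]:
    """Per phage, the union of receptors over its TSPs' subtypes.

    Assignments and knowledge base must share a label space (published
    labels via the packaged membership lists, or a user-supplied mapping).
    Every receptor carries at least one provenance chain.
    """
    per_phage: dict[str, HostPrediction] = {}
    for assignment in assignments:
        for protein_id, label in sorted(assignment.labels.items()):
            phage = _phage_of(protein_id)
            prediction = per_phage.setdefault(phage, HostPrediction(phage_id=phage))
            for receptor, chain in _chains_for_subtype(kb, label, protein_id):
                prediction.receptors.setdefault(receptor, []).append(chain)
    return sorted(per_phage.values(), key=lambda p: p.phage_id)


def summarize_predictions(kb: KnowledgeBase) -> pd.DataFrame:
    """Per knowledge entry, the distinct-phage count of its membership list.

    Mirrors the published table's row structure (equivalent subtypes keep
    separate rows); ``count_mismatch`` flags rows whose printed total and
    listed membership disagree.
    """
    rows = []
    for entry in kb.entries:
        members = sorted(set(kb.memberships.get(entry.subtype, [])))
        rows.append(
            {
                "subtype": entry.subtype,
                "receptor": entry.receptor,
                "n_phages": len(members),
                "printed_total": entry.printed_total,
                "count_mismatch": entry.subtype in kb.count_mismatches,
                "phages": ";".join(members),
            }
        )
    return pd.DataFrame(rows)
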