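"""Loaders for the packaged reference data.

Two kinds of data ship with the package:

* ``synthetic_reference_proteins.faa`` — synthetic stand-in reference
  proteins (a vriC anchor, a baseplate wedge, and four full-length
  type-defining TSPs).  They have the statistical shape of the real
  references (lengths matching the reported TSP gene lengths, the conserved
  GTTAVSL motif at the receptor-binding-module junction of types 1, 3 and 4)
  but are randomly generated, so no download is needed; for real genomes,
  users point the pipeline at their own FASTA of e.g. CBA120 references.
* the knowledge tables (``knowledge_table.tsv``, ``table3_memberships.tsv``,
  ``equivalence_links.tsv``) — a transcription of the published
  subtype → receptor/host table with its phage membership lists and
  module-equivalence links.

The TSP scaffold/module junctions (residue 64 for types 1 and 3, 260 for
type 2, 390 for type 4) are the package-wide convention: the shared-module
boundary reported for the family sits at residue 65 in TSP1/TSP3 and 391 in
TSP4.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

from .genome_io import read_protein_fasta

# 0-based scaffold length per TSP type == junction position - 1 (1-based)
SCAFFOLD_LENGTH = {1: 64, 2: 260, 3: 64, 4: 390}
# default N-terminal typing windows (residues) per TSP type
TYPING_WINDOW = {1: 150, 2: 250, 3: 150, 4: 450}
MOTIF = "GTTAVSL"

__all__ = [
    "SCAFFOLD_LENGTH",
    "TYPING_WINDOW",
    "MOTIF",
    "reference_proteins",
    "anchor_references",
    "wedge_references",
    "reference_tsps",
    "data_path",
]


def data_path(name: str):
    return resources.files("ackertsp.data").joinpath(name)


@lru_cache(maxsize=1)
def reference_proteins() -> dict[str, str]:
    with data_path("synthetic_reference_proteins.faa").open() as fh:
        return {header: seq for header, seq in read_protein_fasta(fh)}


def anchor_references() -> list[str]:
    """vriC anchor reference proteins."""
    return [reference_proteins()["synthetic_vriC"]]


def wedge_references() -> list[str]:
    """Baseplate-wedge (cluster stop) reference proteins."""
    return [reference_proteins()["synthetic_wedge"]]


def reference_tsps() -> dict[int, str]:
    """Full-length type-defining TSP reference proteins, keyed 1..4."""
    refs = reference_proteins()
    return {t: refs[f"synthetic_TSP{t}"] for t in (1, 2, 3, 4)}
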