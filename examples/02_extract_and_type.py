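"""Locate the vriC anchor, walk the cluster, and type the tail spikes.

Typing aligns each candidate's N-terminal window against the four
type-defining reference N-termini; the receptor-binding C-terminus plays no
role, so a protein keeps its type even when its module was swapped.
"""

from ackertsp import CohortConfig, generate_cohort
from ackertsp.cluster_extraction import extract_from_genome
from ackertsp.references import anchor_references, wedge_references
from ackertsp.tsp_typing import assign_type, resolve_phage_types

genomes, truth = generate_cohort(CohortConfig(seed=7))
genome = genomes[0]

report = extract_from_genome(genome, anchor_references(), wedge_references())
print(f"{genome.identifier}: anchor found={report.anchor_found}, "
      f"{len(report.candidates)} full-length TSP candidates")

proteins = resolve_phage_types([assign_type(c) for c in report.candidates])
for protein in proteins:
    print(
        f"  cluster position {protein.cluster_index}: type {protein.tsp_type} "
        f"(N-terminal identity {protein.type_identity:.2f}, {len(protein.sequence)} aa)"
    )
# The N-terminal identity is the similarity of the candidate's leading
# window to the winning reference segment; values near ~0.25 would mean
# "unassigned" (background between unrelated sequences).
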