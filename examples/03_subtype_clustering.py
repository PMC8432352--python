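"""Partition same-type tail spikes into subtypes at 75 % identity.

Subtypes are connected components of the >=75 %-identity graph.  On
family-shaped data the within-subtype identities sit above 0.9 and the
between-subtype identities below 0.35, so the threshold cuts cleanly; each
subtype is then checked for genus exclusivity.
"""

from ackertsp import CohortConfig, generate_cohort
from ackertsp.cluster_extraction import extract_from_genome
from ackertsp.references import anchor_references, wedge_references
from ackertsp.subtypes import cluster_subtypes, genus_association, identity_matrix
from ackertsp.tsp_typing import assign_type, resolve_phage_types

genomes, truth = generate_cohort(CohortConfig(seed=7))
proteins = []
for genome in genomes:
    report = extract_from_genome(genome, anchor_references(), wedge_references())
    proteins.extend(resolve_phage_types([assign_type(c) for c in report.candidates]))

type1 = [p for p in proteins if p.tsp_type == 1]
matrix = identity_matrix(type1)
assignment = cluster_subtypes(matrix)
print(f"{len(type1)} TSP1 proteins -> {len(assignment.members)} subtypes")
for label, members in assignment.members.items():
    print(f"  {label}: {len(members)} members, e.g. {members[0]}")

table = genus_association(assignment, truth.genus_of())
cross = [label for label, info in table.items() if info["cross_genus"]]
print(f"subtypes spanning more than one genus: {cross or 'none'}")
# With genus-private module pools every subtype maps to a single genus,
# mirroring the family-wide genus association of real subtypes.
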