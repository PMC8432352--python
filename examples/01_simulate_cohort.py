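"""Generate a synthetic Ackermannviridae-like cohort with ground truth.

Each genome carries a random genus backbone plus one co-oriented gene
cluster: vriC, 3-4 tail spike genes and a baseplate-wedge gene.  The truth
tables record everything that was planted (types, subtypes, swaps, motif
positions), which is what makes every later stage testable offline.
"""

from ackertsp import CohortConfig, generate_cohort

config = CohortConfig(seed=7)
genomes, truth = generate_cohort(config)

print(f"cohort of {len(genomes)} phages, genome length ~{len(genomes[0].sequence)} nt")
for genome in genomes[:4]:
    record = truth.phages[genome.identifier]
    types = sorted(t["tsp_type"] for t in record["tsps"])
    print(
        f"  {genome.identifier:<20} {record['genus']:<15} "
        f"TSP types {types}  vriC at {record['vric'][0]}..{record['vric'][1]}"
    )
# Types {1,2,4} means the phage lacks TSP3 — the one type that is absent in
# a fifth of real genomes; vriC coordinates anchor the downstream cluster.
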