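"""Transfer O-antigen/host labels from characterised subtypes.

The packaged knowledge base transcribes the published subtype → receptor
table.  A phage inherits a receptor when one of its TSPs falls in a
characterised subtype — or in a subtype linked to one by a shared
C-terminal module, in which case the evidence tier is downgraded to
"inferred".
"""

from ackertsp.hosts import load_packaged_knowledge, predict_hosts, summarize_predictions
from ackertsp.subtypes import SubtypeAssignment


def assignment(tsp_type, mapping):
    members = {}
    for pid, label in mapping.items():
        members.setdefault(label, []).append(pid)
    return SubtypeAssignment(tsp_type=tsp_type, labels=mapping, members=members)


kb = load_packaged_knowledge()
print("knowledge base:", len(kb.entries), "entries,", len(kb.links), "module-equivalence links")
print("flagged count mismatches:", kb.count_mismatches)

# an S117-like phage: TSP1-1 / TSP2-1 / TSP3-1, plus a TSP4-7 phage
predictions = predict_hosts(
    [
        assignment(1, {"S117_like/tsp1": "TSP1-1"}),
        assignment(2, {"S117_like/tsp2": "TSP2-1"}),
        assignment(3, {"S117_like/tsp3": "TSP3-1"}),
        assignment(4, {"other_phage/tsp4": "TSP4-7"}),
    ],
    kb,
)
for prediction in predictions:
    print(f"\n{prediction.phage_id}:")
    for receptor, chains in sorted(prediction.receptors.items()):
        tiers = {c["evidence"] for c in chains}
        via = {c["via"] for c in chains if c["via"]}
        note = f" via {sorted(via)}" if via else ""
        print(f"  {receptor:<10} [{'/'.join(sorted(tiers))}]{note}")

table = summarize_predictions(kb).set_index("subtype")
print("\nper-subtype member counts (published lists):")
for subtype in ("TSP3-1", "TSP1-26", "TSP1-1", "TSP3-2", "TSP4-7"):
    print(f"  {subtype}: {table.loc[subtype, 'n_phages']} phages")
# other_phage carries no directly characterised subtype but inherits O:21
# through the TSP1-1 ~ TSP4-7 shared-module link, at inferred evidence.
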