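"""Synthetic *Ackermannviridae*-like cohorts with ground truth.

A generated phage genome is a genus-specific random backbone carrying one
co-oriented gene cluster: a conserved vriC gene, three or four full-length
TSP genes (optionally interleaved with a small decoy ORF), and a baseplate
wedge gene.  Each TSP protein is a family-conserved type scaffold (mutated
per phage at ``scaffold_sub_rate``) followed by a C-terminal receptor-binding
module drawn from the genus/type subtype pool and mutated at
``within_subtype_sub_rate`` — reproducing the statistical signature the
analysis assumes: within-subtype identity near 1, cross-subtype module
identity near random background, and clean separation around the 75 %
subtype threshold.  Modules of types 1, 3 and 4 begin with the conserved
GTTAVSL motif, so the motif sits at the scaffold/module junction (residue 65
in types 1/3, 391 in type 4), and with probability ``p_swap`` a phage's TSP4
carries the module of its own TSP1 or TSP3 subtype — a planted module swap.

Ancestral proteins (scaffolds, modules, vriC, wedge) are back-translated
once per cohort with uniformly random synonymous codons; each phage's gene
then inherits the ancestral codon choice, with protein-level substitutions
mirrored by a random codon of the new residue.  Synonymous choices are
thereby conserved along lineages — as in real genomes — so nucleotide-level
similarity tracks protein-level relatedness and ANI reflects backbone
divergence plus conserved-gene divergence.  The GTTAVSL junction motif is
exempt from module mutation (it is conserved family-wide).  Everything is a
deterministic function of ``CohortConfig.seed``.

Default condition choices: genus sizes (6/3/4/2) mirror the family's skew
toward Kuttervirus at desk scale; backbone divergences (1.5–5 %) bracket the
published within-genus ANI ranges; 20 % of phages lack TSP3, the one type
reported absent in a fifth of real genomes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .genome_io import GeneFeature, PhageGenome, write_genome_genbank
from .references import MOTIF, SCAFFOLD_LENGTH, reference_tsps, reference_proteins

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
NUCLEOTIDES = "ACGT"

__all__ = ["CohortConfig", "SyntheticTruth", "generate_cohort", "mutate", "write_cohort"]


@dataclass(frozen=True)
class CohortConfig:
    seed: int = 0
    # (genus name, number of phages, backbone divergence from genus ancestor)
    genera: tuple = (
        ("Kuttervirus", 6, 0.03),
        ("Agtrevirus", 3, 0.04),
        ("Limestonevirus", 4, 0.015),
        ("Taipeivirus", 2, 0.05),
    )
    module_library_size: int = 3  # ancestral modules per genus per TSP type
    within_subtype_sub_rate: float = 0.02
    scaffold_sub_rate: float = 0.05
    conserved_gene_sub_rate: float = 0.02  # vriC / wedge per phage ("well-conserved")
    p_three_tsp: float = 0.2  # probability a phage lacks TSP3
    p_swap: float = 0.05  # probability TSP4 carries a TSP1/TSP3 module
    motif: str = MOTIF
    genome_length: int = 20000  # backbone length (desk scale)
    n_cross_genus_subtypes: int = 0  # shared TSP4 subtypes between first two genera
    include_decoy: bool = True

    def __post_init__(self) -> None:
        for rate in (
            self.within_subtype_sub_rate,
            self.scaffold_sub_rate,
            self.conserved_gene_sub_rate,
            self.p_three_tsp,
            self.p_swap,
        ):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.module_library_size < 1:
            raise ValueError("module_library_size must be >= 1")


@dataclass
class SyntheticTruth:
    """Planted structure of a generated cohort, keyed by phage id."""

    phages: dict[str, dict] = field(default_factory=dict)
    seed: int = 0

    def genus_of(self) -> dict[str, str]:
        return {pid: rec["genus"] for pid, rec in self.phages.items()}

    def type_partition(self, tsp_type: int) -> dict[str, str]:
        """protein id -> planted subtype key, for one TSP type."""
        partition = {}
        for pid, rec in self.phages.items():
            for tsp in rec["tsps"]:
                if tsp["tsp_type"] == tsp_type:
                    partition[f"{pid}/tsp{tsp['cluster_index']}"] = tsp["subtype_key"]
        return partition

    def planted_types(self, phage_id: str) -> set[int]:
        return {t["tsp_type"] for t in self.phages[phage_id]["tsps"]}

    def to_json(self) -> str:
        return json.dumps({"seed": self.seed, "phages": self.phages}, indent=1, sort_keys=True)


def mutate(seq: str, rate: float, rng, alphabet: str | None = None) -> str:
    """Substitute exactly round(rate·len) distinct positions to different symbols.

    ``rng`` is a numpy Generator or an integer seed.  The alphabet is
    inferred (nucleotide if the sequence is over {A,C,G,T,N}) unless given.
    """
    if not 0 <= rate <= 1:
        raise ValueError("rate must lie in [0, 1]")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if alphabet is None:
        alphabet = NUCLEOTIDES if set(seq) <= set("ACGTN") else AMINO_ACIDS
    n_sub = int(round(rate * len(seq)))
    if n_sub == 0:
        return seq
    positions = rng.choice(len(seq), size=n_sub, replace=False)
    out = list(seq)
    for pos in positions:
        alternatives = [c for c in alphabet if c != out[pos]]
        out[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


_CODON_TABLE = unambiguous_dna_by_id[1]
_CODONS_FOR = {}
for _codon, _aa in _CODON_TABLE.forward_table.items():
    _CODONS_FOR.setdefault(_aa, []).append(_codon)
for _aa in _CODONS_FOR:
    _CODONS_FOR[_aa].sort()


def back_translate(protein: str, rng) -> list[str]:
    """Codon list with uniformly random synonymous codons (no stop)."""
    return [_CODONS_FOR[aa][rng.integers(len(_CODONS_FOR[aa]))] for aa in protein]


def _random_seq(rng, n: int, alphabet: str) -> str:
    return "".join(np.asarray(list(alphabet))[rng.integers(len(alphabet), size=n)])


@dataclass
class _Gene:
    """An ancestral protein with its one-time back-translation."""

    protein: str
    codons: list[str]

    def mutated(self, rate: float, rng, frozen_prefix: int = 0) -> "_Gene":
        """Substitute residues outside the frozen prefix, mirrored in codons."""
        n = len(self.protein)
        mutable = n - frozen_prefix
        n_sub = int(round(rate * mutable))
        prot = list(self.protein)
        codons = list(self.codons)
        if n_sub:
            positions = rng.choice(np.arange(frozen_prefix, n), size=n_sub, replace=False)
            for pos in positions:
                alternatives = [c for c in AMINO_ACIDS if c != prot[pos]]
                new_aa = alternatives[rng.integers(len(alternatives))]
                prot[pos] = new_aa
                codons[pos] = _CODONS_FOR[new_aa][rng.integers(len(_CODONS_FOR[new_aa]))]
        return _Gene("".join(prot), codons)

    def __add__(self, other: "_Gene") -> "_Gene":
        return _Gene(self.protein + other.protein, self.codons + other.codons)

    @property
    def cds(self) -> str:
        return "".join(self.codons) + "TAA"


def _module_pools(config: CohortConfig, rng) -> dict:
    """(genus, type) -> list of (subtype_key, ancestral module gene)."""
    refs = reference_tsps()
    module_len = {t: len(refs[t]) - SCAFFOLD_LENGTH[t] for t in (1, 2, 3, 4)}
    pools: dict = {}
    genus_names = [g for g, _, _ in config.genera]
    for genus in genus_names:
        for t in (1, 2, 3, 4):
            pool = []
            for k in range(config.module_library_size):
                body_len = module_len[t] - (len(config.motif) if t != 2 else 0)
                body = _random_seq(rng, body_len, AMINO_ACIDS)
                module = body if t == 2 else config.motif + body
                pool.append((f"{genus}:T{t}:{k}", _Gene(module, back_translate(module, rng))))
            pools[(genus, t)] = pool
    # optionally share TSP4 subtypes between the first two genera (the
    # cross-genus-subtype situation observed once in the real family)
    for k in range(min(config.n_cross_genus_subtypes, config.module_library_size)):
        if len(genus_names) >= 2:
            pools[(genus_names[1], 4)][k] = pools[(genus_names[0], 4)][k]
    return pools


def generate_cohort(config: CohortConfig) -> tuple[list[PhageGenome], SyntheticTruth]:
    """Deterministically generate a cohort and its ground-truth tables."""
    rng = np.random.default_rng(config.seed)
    refs = reference_tsps()
    vric_ref = reference_proteins()["synthetic_vriC"]
    wedge_ref = reference_proteins()["synthetic_wedge"]
    vric_gene = _Gene(vric_ref, back_translate(vric_ref, rng))
    wedge_gene = _Gene(wedge_ref, back_translate(wedge_ref, rng))
    scaffolds = {
        t: _Gene(refs[t][: SCAFFOLD_LENGTH[t]], back_translate(refs[t][: SCAFFOLD_LENGTH[t]], rng))
        for t in (1, 2, 3, 4)
    }
    pools = _module_pools(config, rng)
    ancestors = {
        genus: _random_seq(rng, config.genome_length, NUCLEOTIDES)
        for genus, _, _ in config.genera
    }
    genomes: list[PhageGenome] = []
    truth = SyntheticTruth(seed=config.seed)

    for genus, n_phages, divergence in config.genera:
        for i in range(n_phages):
            phage_id = f"{genus}_{i + 1:02d}"
            backbone = mutate(ancestors[genus], divergence, rng)
            types_present = [1, 2, 4] if rng.random() < config.p_three_tsp else [1, 2, 3, 4]

            tsp_plan = []
            swap_record = None
            for t in types_present:
                key, ancestral = pools[(genus, t)][rng.integers(config.module_library_size)]
                tsp_plan.append({"tsp_type": t, "subtype_key": key, "ancestral": ancestral})
            if 4 in types_present and rng.random() < config.p_swap:
                donors = [p for p in tsp_plan if p["tsp_type"] in (1, 3)]
                if donors:
                    donor = donors[rng.integers(len(donors))]
                    for plan in tsp_plan:
                        if plan["tsp_type"] == 4:
                            plan["ancestral"] = donor["ancestral"]
                            plan["subtype_key"] = donor["subtype_key"] + ":on4"
                            plan["donor"] = {
                                "tsp_type": donor["tsp_type"],
                                "subtype_key": donor["subtype_key"],
                            }
                            swap_record = {
                                "donor_type": donor["tsp_type"],
                                "donor_subtype": donor["subtype_key"],
                                "junction_donor": SCAFFOLD_LENGTH[donor["tsp_type"]] + 1,
                                "junction_tsp4": SCAFFOLD_LENGTH[4] + 1,
                            }

            # build genes: per-phage mutation of scaffold and module, with the
            # conserved junction motif exempt (types 1/3/4)
            for plan in tsp_plan:
                t = plan["tsp_type"]
                # initial Met frozen so the CDS keeps its ATG start codon
                scaffold = scaffolds[t].mutated(config.scaffold_sub_rate, rng, frozen_prefix=1)
                frozen = 0 if plan["ancestral"].protein[: len(config.motif)] != config.motif else len(config.motif)
                module = plan["ancestral"].mutated(
                    config.within_subtype_sub_rate, rng, frozen_prefix=frozen
                )
                plan["gene"] = scaffold + module
                plan["protein"] = plan["gene"].protein
                plan["junction"] = SCAFFOLD_LENGTH[t] + 1
                plan["motif_position"] = None if t == 2 else SCAFFOLD_LENGTH[t] + 1

            vric = vric_gene.mutated(config.conserved_gene_sub_rate, rng, frozen_prefix=1)
            wedge = wedge_gene.mutated(config.conserved_gene_sub_rate, rng, frozen_prefix=1)

            # assemble the genome: backbone with the cluster spliced in
            insert_at = min(2000, len(backbone) // 2)
            segments: list[tuple[str, _Gene, str]] = [("vriC", vric, "virulence-associated protein VriC")]
            for order, plan in enumerate(tsp_plan):
                segments.append((f"tsp{order}", plan["gene"], "tail spike protein"))
                if config.include_decoy and order == 1:
                    decoy = _random_seq(rng, 120, AMINO_ACIDS)
                    segments.append(("decoy", _Gene(decoy, back_translate(decoy, rng)), "hypothetical protein"))
            segments.append(("wedge", wedge, "baseplate wedge protein"))

            sequence_parts = [backbone[:insert_at]]
            position = insert_at  # 0-based length so far
            features: list[GeneFeature] = []
            coords: dict[str, tuple[int, int]] = {}
            locus_n = 0
            for name, gene, product in segments:
                spacer = _random_seq(rng, int(rng.integers(20, 41)), NUCLEOTIDES)
                sequence_parts.append(spacer)
                position += len(spacer)
                cds = gene.cds
                start = position + 1  # 1-based inclusive
                end = position + len(cds)
                locus_n += 1
                features.append(
                    GeneFeature(
                        locus_tag=f"{phage_id}_{locus_n:03d}",
                        product=product,
                        start=start,
                        end=end,
                        strand="+",
                        translation=gene.protein,
                    )
                )
                coords[name] = (start, end)
                sequence_parts.append(cds)
                position += len(cds)
            sequence_parts.append(backbone[insert_at:])
            sequence = "".join(sequence_parts)

            genomes.append(
                PhageGenome(
                    identifier=phage_id,
                    sequence=sequence,
                    features=features,
                    taxonomy=genus,
                )
            )
            truth.phages[phage_id] = {
                "genus": genus,
                "vric": coords["vriC"],
                "wedge": coords["wedge"],
                "tsps": [
                    {
                        "cluster_index": order + 1,
                        "tsp_type": plan["tsp_type"],
                        "subtype_key": plan["subtype_key"],
                        "cds": coords[f"tsp{order}"],
                        "protein": plan["protein"],
                        "junction": plan["junction"],
                        "motif_position": plan["motif_position"],
                        "donor": plan.get("donor"),
                    }
                    for order, plan in enumerate(tsp_plan)
                ],
                "swap": swap_record,
            }
    return genomes, truth


def write_cohort(
    genomes: list[PhageGenome], truth: SyntheticTruth, directory: str | Path
) -> None:
    """Write GenBank files, a cohort metadata TSV and the truth JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lines = ["phage_id\tgenus\tsource_accession"]
    for genome in genomes:
        write_genome_genbank(genome, directory / f"{genome.identifier}.gbk")
        lines.append(f"{genome.identifier}\t{genome.taxonomy}\tsynthetic")
    (directory / "metadata.tsv").write_text("\n".join(lines) + "\n")
    (directory / "truth.json").write_text(truth.to_json() + "\n")
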