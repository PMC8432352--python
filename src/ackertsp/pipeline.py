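"""End-to-end pipeline: extract → type → subtype → modules → ANI → predict.

Each stage is a pure function of its inputs plus one :class:`RunConfig`;
all randomness flows from the config seed, so two runs on identical inputs
produce byte-identical output files.  Every stage writes machine-readable
TSV/JSON into the run directory and the run ends with a manifest recording
parameters, stages and output files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .ani import AniMatrix, AniParams, ani_matrix, genus_ani_summary
from .cluster_extraction import extract_from_genome
from .genome_io import PhageGenome, load_cohort_metadata, read_genome
from .hosts import load_knowledge, load_packaged_knowledge, predict_hosts
from .identity import AlignmentParams
from .modules import detect_module_share, extract_td1, find_conserved_motif
from .references import anchor_references, wedge_references
from .simulate import CohortConfig, generate_cohort, write_cohort
from .subtypes import cluster_subtypes, genus_association, identity_matrix
from .tsp_typing import assign_type, default_typing_reference, resolve_phage_types

__all__ = ["RunConfig", "run_pipeline", "load_run_config"]


@dataclass
class RunConfig:
    input_dir: str = "."  # directory of .gbk files + metadata.tsv
    output_dir: str = "run_out"
    seed: int = 0
    anchor_min_identity: float = 0.5
    min_protein_len: int = 500
    typing_threshold: float = 0.30
    subtype_threshold: float = 0.75
    module_min_identity: float = 0.75
    module_min_block: int = 300
    cterm_tolerance: int = 10
    motif_min_support: float = 0.8
    ani_seed_length: int = 15
    ani_min_block_length: int = 100
    ani_fragment_length: int = 500
    gap_open_cost: float = 10.0
    gap_extend_cost: float = 1.0
    knowledge_table: str | None = None  # None -> packaged tables
    memberships_table: str | None = None
    links_table: str | None = None

    def alignment_params(self) -> AlignmentParams:
        return AlignmentParams(
            gap_open_cost=self.gap_open_cost, gap_extend_cost=self.gap_extend_cost
        )

    def ani_params(self) -> AniParams:
        return AniParams(
            seed_length=self.ani_seed_length,
            min_block_length=self.ani_min_block_length,
            fragment_length=self.ani_fragment_length,
        )


def load_run_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def _load_cohort(input_dir: Path) -> tuple[list[PhageGenome], dict[str, str]]:
    paths = sorted(input_dir.glob("*.gbk")) + sorted(input_dir.glob("*.gb"))
    if not paths:
        raise FileNotFoundError(f"no GenBank files found in {input_dir}")
    genomes = [read_genome(p, "genbank") for p in paths]
    metadata_path = input_dir / "metadata.tsv"
    genus_of = load_cohort_metadata(metadata_path) if metadata_path.exists() else {}
    for genome in genomes:
        genome.taxonomy = genus_of.get(genome.identifier, genome.taxonomy)
    return genomes, genus_of


def stage_extract(genomes, config: RunConfig):
    params = config.alignment_params()
    reports = [
        extract_from_genome(
            genome,
            anchor_references(),
            wedge_references(),
            min_identity=config.anchor_min_identity,
            min_protein_len=config.min_protein_len,
            params=params,
        )
        for genome in genomes
    ]
    return reports


def stage_type(reports, config: RunConfig):
    params = config.alignment_params()
    reference = default_typing_reference()
    proteins = []
    for report in reports:
        phage_proteins = [
            assign_type(c, reference, config.typing_threshold, params)
            for c in report.candidates
        ]
        proteins.extend(resolve_phage_types(phage_proteins))
    return proteins


def stage_subtype(proteins, config: RunConfig):
    params = config.alignment_params()
    assignments, matrices = [], []
    for t in (1, 2, 3, 4):
        of_type = [p for p in proteins if p.tsp_type == t]
        if not of_type:
            continue
        matrix = identity_matrix(of_type, params)
        assignment = cluster_subtypes(matrix, config.subtype_threshold)
        for protein in of_type:
            protein.subtype = assignment.labels[protein.protein_id]
        assignments.append(assignment)
        matrices.append(matrix)
    return assignments, matrices


def stage_modules(proteins, config: RunConfig, genus_of: dict[str, str] | None = None):
    params = config.alignment_params()
    donors = [p for p in proteins if p.tsp_type in (1, 3)]
    acceptors = [p for p in proteins if p.tsp_type == 4]
    hits = []
    for a in donors:
        for b in acceptors:
            hit = detect_module_share(
                a,
                b,
                min_identity=config.module_min_identity,
                min_block=config.module_min_block,
                cterm_tolerance=config.cterm_tolerance,
                params=params,
            )
            if hit is not None:
                hits.append(hit)
    # motif discovery on pooled TD1 slices of types 1/3/4, per genus
    motif_hits = {}
    by_genus: dict[str, list] = {}
    for protein in proteins:
        if protein.tsp_type in (1, 3, 4):
            genus = (genus_of or {}).get(protein.phage_id, "cohort")
            by_genus.setdefault(genus, []).append(protein)
    for genus, members in sorted(by_genus.items()):
        regions = [extract_td1(p) for p in members]
        if len(regions) >= 2:
            motif_hits[genus] = find_conserved_motif(
                regions, min_support=config.motif_min_support
            )
    return hits, motif_hits


def stage_ani(genomes, genus_of, config: RunConfig):
    matrix = ani_matrix(genomes, config.ani_params())
    summary = genus_ani_summary(matrix, genus_of)
    return matrix, summary


def stage_predict(assignments, config: RunConfig):
    if config.knowledge_table:
        kb = load_knowledge(
            config.knowledge_table, config.memberships_table, config.links_table
        )
    else:
        kb = load_packaged_knowledge()
    return predict_hosts(assignments, kb), kb


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def _fmt(x: float) -> str:
    return f"{x:.6f}"


def run_pipeline(config: RunConfig) -> dict:
    """Execute all six stages and write the report bundle + manifest."""
    input_dir = Path(config.input_dir)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    genomes, genus_of = _load_cohort(input_dir)
    stages_done = []

    reports = stage_extract(genomes, config)
    _write_tsv(
        out / "extraction.tsv",
        ["phage_id", "anchor_found", "n_candidates", "discard_reason"],
        [
            [r.phage_id, r.anchor_found, len(r.candidates), r.discard_reason or ""]
            for r in reports
        ],
    )
    stages_done.append("extract")

    proteins = stage_type(reports, config)
    _write_tsv(
        out / "typing.tsv",
        ["phage_id", "cluster_index", "tsp_type", "type_identity"],
        [
            [p.phage_id, p.cluster_index, p.tsp_type or "unassigned", _fmt(p.type_identity)]
            for p in proteins
        ],
    )
    stages_done.append("type")

    assignments, matrices = stage_subtype(proteins, config)
    rows = []
    for assignment in assignments:
        for pid in sorted(assignment.labels):
            rows.append([pid, pid.rsplit("/", 1)[0], assignment.tsp_type, assignment.labels[pid]])
    _write_tsv(out / "subtypes.tsv", ["protein_id", "phage_id", "tsp_type", "subtype"], rows)
    for matrix in matrices:
        lines = ["\t".join([""] + matrix.ids)]
        for pid, row in zip(matrix.ids, matrix.values):
            lines.append("\t".join([pid] + [_fmt(v) for v in row]))
        (out / f"identity_matrix_tsp{matrix.tsp_type}.tsv").write_text(
            "\n".join(lines) + "\n"
        )
    if genus_of:
        rows = []
        for assignment in assignments:
            table = genus_association(assignment, genus_of)
            for label in sorted(table):
                info = table[label]
                rows.append(
                    [label, ";".join(info["genera"]), info["cross_genus"], info["n_members"]]
                )
        _write_tsv(
            out / "genus_association.tsv",
            ["subtype", "genera", "cross_genus", "n_members"],
            rows,
        )
    stages_done.append("subtype")

    hits, motif_hits = stage_modules(proteins, config, genus_of)
    _write_tsv(
        out / "module_shares.tsv",
        ["protein_a", "protein_b", "start_a", "start_b", "block_identity", "block_length"],
        [
            [h.protein_a, h.protein_b, h.start_a, h.start_b, _fmt(h.block_identity), h.block_length]
            for h in sorted(hits, key=lambda h: (h.protein_a, h.protein_b))
        ],
    )
    _write_tsv(
        out / "motifs.tsv",
        ["genus", "motif", "support"],
        [
            [genus, hit.motif, _fmt(hit.support)]
            for genus, hit_list in motif_hits.items()
            for hit in hit_list[:5]
        ],
    )
    stages_done.append("modules")

    matrix, summary = stage_ani(genomes, genus_of, config)
    lines = ["\t".join([""] + matrix.ids)]
    for gid, row in zip(matrix.ids, matrix.ani):
        lines.append(
            "\t".join([gid] + ["" if np.isnan(v) else f"{v:.3f}" for v in row])
        )
    (out / "ani_matrix.tsv").write_text("\n".join(lines) + "\n")
    _write_tsv(
        out / "ani_genus_summary.tsv",
        ["genus", "min_ani", "max_ani"],
        [[g, f"{lo:.3f}", f"{hi:.3f}"] for g, (lo, hi) in sorted(summary.items())],
    )
    stages_done.append("ani")

    predictions, kb = stage_predict(assignments, config)
    payload = [
        {"phage_id": p.phage_id, "receptors": p.receptors} for p in predictions
    ]
    (out / "predictions.json").write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    _write_tsv(
        out / "predictions.tsv",
        ["phage_id", "receptor", "evidence"],
        [
            [p.phage_id, receptor, ";".join(sorted({c["evidence"] for c in chains}))]
            for p in predictions
            for receptor, chains in sorted(p.receptors.items())
        ],
    )
    stages_done.append("predict")

    manifest = {
        "package": "ackertsp",
        "version": __version__,
        "config": asdict(config),
        "n_genomes": len(genomes),
        "stages": stages_done,
        "outputs": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest


def simulate_to_dir(cohort: CohortConfig, directory: str | Path) -> None:
    genomes, truth = generate_cohort(cohort)
    write_cohort(genomes, truth, directory)
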