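"""Reading and writing phage genomes, proteins and cohort metadata.

The in-memory model is deliberately small: a :class:`PhageGenome` is a
nucleotide string over {A, C, G, T, N} plus an ordered list of
:class:`GeneFeature` coding features with 1-based inclusive coordinates —
the convention used everywhere in this package.  GenBank flat files are the
primary input (CDS features carry the annotation the cluster walk needs);
bare FASTA genomes are accepted and gain features later through the ORF
fallback caller in :mod:`ackertsp.cluster_extraction`.

Genus labels are never guessed from GenBank taxonomy strings; they come from
an explicit cohort metadata TSV (columns: phage_id, genus, source_accession),
because ICTV genus assignment is curation, not parsing.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TextIO, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

GENUS_LABELS = ("Kuttervirus", "Agtrevirus", "Limestonevirus", "Taipeivirus", "unknown")
NUCLEOTIDE_ALPHABET = frozenset("ACGTN")

Source = Union[str, Path, TextIO]

__all__ = [
    "GeneFeature",
    "PhageGenome",
    "read_genome",
    "write_genome_genbank",
    "write_protein_fasta",
    "read_protein_fasta",
    "load_cohort_metadata",
    "translate_cds",
    "GENUS_LABELS",
]


@dataclass
class GeneFeature:
    """One coding feature; ``start``/``end`` are 1-based inclusive."""

    locus_tag: str
    product: str
    start: int
    end: int
    strand: str  # "+" or "-"
    translation: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"feature {self.locus_tag}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.locus_tag}: strand must be + or -")

    @property
    def nt_length(self) -> int:
        return self.end - self.start + 1


@dataclass
class PhageGenome:
    identifier: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)
    taxonomy: str = "unknown"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"genome {self.identifier}: empty sequence")
        bad = set(self.sequence) - NUCLEOTIDE_ALPHABET
        if bad:
            raise ValueError(
                f"genome {self.identifier}: ambiguity codes other than N are "
                f"rejected: {sorted(bad)}"
            )
        for feat in self.features:
            if feat.start < 1 or feat.end > len(self.sequence):
                raise ValueError(
                    f"genome {self.identifier}: feature {feat.locus_tag} "
                    f"[{feat.start},{feat.end}] outside [1,{len(self.sequence)}]"
                )


def translate_cds(genome: PhageGenome, feature: GeneFeature) -> str:
    """Translate a CDS with the standard code; trailing stop stripped.

    Codons containing N translate to X; an internal stop is *kept* (as '*')
    so that downstream stages can reject the candidate — dirty annotation is
    not an I/O error.
    """
    nt = genome.sequence[feature.start - 1 : feature.end]
    seq = Seq(nt)
    if feature.strand == "-":
        seq = seq.reverse_complement()
    aa = str(seq.translate())
    return aa[:-1] if aa.endswith("*") else aa


def ensure_translation(genome: PhageGenome, feature: GeneFeature) -> str:
    if feature.translation is None:
        feature.translation = translate_cds(genome, feature)
    return feature.translation


def _open(source: Source, mode: str = "r"):
    if isinstance(source, (str, Path)):
        return open(source, mode), True
    return source, False


def read_genome(source: Source, format: str = "genbank") -> PhageGenome:
    """Parse a single-genome GenBank or FASTA stream into a PhageGenome.

    GenBank CDS features populate ``features`` (1-based inclusive
    coordinates); FASTA yields an empty feature list.  A stream holding more
    than one sequence is rejected: one file, one genome.
    """
    if format not in ("genbank", "fasta"):
        raise ValueError(f"unsupported format {format!r}")
    handle, opened = _open(source)
    try:
        try:
            records = list(SeqIO.parse(handle, format))
        except Exception as exc:  # malformed record
            raise ValueError(f"malformed {format} record: {exc}") from exc
    finally:
        if opened:
            handle.close()
    if not records:
        raise ValueError(f"no {format} record found in input")
    if len(records) > 1:
        raise ValueError("multiple sequences; expected one genome")
    record = records[0]
    sequence = str(record.seq).upper()
    features: list[GeneFeature] = []
    if format == "genbank":
        n = 0
        for feat in record.features:
            if feat.type != "CDS":
                continue
            if len(feat.location.parts) > 1:
                # joined/compound CDS (rare in phages) are not modelled
                continue
            n += 1
            quals = feat.qualifiers
            translation = quals.get("translation", [None])[0]
            features.append(
                GeneFeature(
                    locus_tag=quals.get("locus_tag", [f"cds_{n:04d}"])[0],
                    product=quals.get("product", ["unknown"])[0],
                    start=int(feat.location.start) + 1,
                    end=int(feat.location.end),
                    strand="+" if feat.location.strand >= 0 else "-",
                    translation=translation,
                )
            )
        features.sort(key=lambda f: (f.start, f.end))
    genome = PhageGenome(
        identifier=record.id or record.name, sequence=sequence, features=features
    )
    for feat in genome.features:
        if feat.translation is None:
            ensure_translation(genome, feat)
    return genome


def write_genome_genbank(genome: PhageGenome, sink: Source) -> None:
    """Write a PhageGenome as a GenBank flat file (round-trips read_genome)."""
    record = SeqRecord(
        Seq(genome.sequence),
        id=genome.identifier,
        name=genome.identifier[:16].replace(" ", "_"),
        description=f"{genome.taxonomy} phage {genome.identifier}",
    )
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = "linear"
    record.annotations["date"] = "01-JAN-2021"  # fixed: outputs stay byte-identical
    for feat in genome.features:
        location = FeatureLocation(
            feat.start - 1, feat.end, strand=1 if feat.strand == "+" else -1
        )
        qualifiers = {
            "locus_tag": [feat.locus_tag],
            "product": [feat.product],
        }
        if feat.translation is not None:
            qualifiers["translation"] = [feat.translation]
        record.features.append(SeqFeature(location, type="CDS", qualifiers=qualifiers))
    handle, opened = _open(sink, "w")
    try:
        SeqIO.write([record], handle, "genbank")
    finally:
        if opened:
            handle.close()


def _protein_header(protein) -> str:
    tsp = protein.tsp_type if protein.tsp_type is not None else "NA"
    subtype = getattr(protein, "subtype", None) or "NA"
    return f"{protein.phage_id}|tsp{tsp}|{subtype}|idx{protein.cluster_index}"


def write_protein_fasta(proteins: Iterable, sink: Source) -> None:
    """Write TSP proteins as FASTA; headers encode phage, type and subtype.

    Duplicate headers (same phage, type, subtype and cluster index twice) are
    an error, so that re-reading always reproduces the exact input set.
    """
    records = []
    seen: set[str] = set()
    for protein in proteins:
        if not protein.sequence:
            raise ValueError(f"protein for phage {protein.phage_id} has empty sequence")
        header = _protein_header(protein)
        if header in seen:
            raise ValueError(f"duplicate protein header: {header}")
        seen.add(header)
        records.append(SeqRecord(Seq(protein.sequence), id=header, description=""))
    handle, opened = _open(sink, "w")
    try:
        SeqIO.write(records, handle, "fasta")
    finally:
        if opened:
            handle.close()


def read_protein_fasta(source: Source) -> list[tuple[str, str]]:
    """Read a protein FASTA as (header, sequence) pairs."""
    handle, opened = _open(source)
    try:
        return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(handle, "fasta")]
    finally:
        if opened:
            handle.close()


def load_cohort_metadata(source: Source) -> dict[str, str]:
    """Cohort metadata TSV (phage_id, genus, source_accession) -> phage→genus."""
    table = pd.read_csv(source, sep="\t", dtype=str)
    required = {"phage_id", "genus"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"cohort metadata missing columns: {sorted(missing)}")
    genus_of: dict[str, str] = {}
    for _, row in table.iterrows():
        genus = row["genus"]
        if genus not in GENUS_LABELS:
            raise ValueError(
                f"unknown genus {genus!r} for phage {row['phage_id']!r}; "
                f"expected one of {GENUS_LABELS}"
            )
        genus_of[row["phage_id"]] = genus
    return genus_of
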