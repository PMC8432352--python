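"""Anchored extraction of the TSP gene cluster.

In *Ackermannviridae* genomes the tail spike genes sit in one co-oriented
cluster flanked upstream by the well-conserved virulence-associated gene
*vriC* and downstream by a baseplate-wedge gene.  Extraction therefore
anchors on *vriC* (best global identity to a reference set, default floor
0.5), then walks coding features downstream on the anchor's strand —
increasing coordinates for a ``+`` anchor, decreasing for ``-`` — collecting
full-length TSP candidates until the wedge gene or a feature cap is reached.

Features shorter than the full-length floor (default 500 residues; the
shortest reported TSP gene, 2097 bp, encodes ~698 residues) are skipped
without terminating the walk, which tolerates small interleaved ORFs inside
the cluster.  Candidates whose translation contains an internal stop are
rejected.  For genomes without annotation, a plain ORF caller (ATG/GTG
starts, standard stops, both strands, >=900 nt) provides features first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from Bio.Seq import Seq

from .genome_io import GeneFeature, PhageGenome, ensure_translation
from .identity import AlignmentParams, global_identity

DEFAULT_MIN_PROTEIN_LEN = 500
DEFAULT_MAX_WALK = 6
DEFAULT_ANCHOR_MIN_IDENTITY = 0.5

__all__ = [
    "TspCandidate",
    "ExtractionReport",
    "locate_anchor",
    "extract_cluster",
    "extract_from_genome",
    "call_orfs",
]


@dataclass
class TspCandidate:
    phage_id: str
    feature: GeneFeature
    protein: str
    cluster_index: int  # ordinal position downstream of vriC, from 1


@dataclass
class ExtractionReport:
    phage_id: str
    anchor_found: bool
    candidates: list[TspCandidate]
    discard_reason: Optional[str] = None  # no_vriC | no_full_length_tsps
    anchor: Optional[GeneFeature] = None

    def __post_init__(self) -> None:
        if not self.anchor_found and (self.candidates or self.discard_reason != "no_vriC"):
            raise ValueError("no anchor implies empty candidates and reason no_vriC")


def _plausible_length(candidate: str, reference: str) -> bool:
    # global identity over full alignment length cannot reach 0.5 when one
    # sequence is more than twice as long as the other
    ratio = len(candidate) / len(reference)
    return 0.5 <= ratio <= 2.0


def _best_identity(protein: str, refs: list[str], params: AlignmentParams) -> float:
    best = 0.0
    for ref in refs:
        if not _plausible_length(protein, ref):
            continue
        best = max(best, global_identity(protein, ref, params).identity)
    return best


def locate_anchor(
    genome: PhageGenome,
    anchor_refs: list[str],
    min_identity: float = DEFAULT_ANCHOR_MIN_IDENTITY,
    params: AlignmentParams | None = None,
) -> Optional[GeneFeature]:
    """Feature with maximum global identity to any vriC reference, if >= floor."""
    if not anchor_refs:
        raise ValueError("anchor_refs must be non-empty")
    if not 0 < min_identity <= 1:
        raise ValueError("min_identity must lie in (0, 1]")
    if not genome.features:
        raise ValueError(f"genome {genome.identifier}: no coding features")
    params = params or AlignmentParams()
    best_feature, best_identity = None, 0.0
    for feature in genome.features:
        protein = ensure_translation(genome, feature)
        if "*" in protein:
            continue
        score = _best_identity(protein, anchor_refs, params)
        if score > best_identity:
            best_feature, best_identity = feature, score
    if best_feature is not None and best_identity >= min_identity:
        return best_feature
    return None


def _downstream_features(genome: PhageGenome, anchor: GeneFeature) -> list[GeneFeature]:
    """Coding features downstream of the anchor, in transcription order.

    Only features on the anchor's strand take part in the walk; the cluster
    is co-oriented with *vriC*.
    """
    same_strand = [f for f in genome.features if f.strand == anchor.strand]
    if anchor.strand == "+":
        downstream = [f for f in same_strand if f.start > anchor.end]
        downstream.sort(key=lambda f: f.start)
    else:
        downstream = [f for f in same_strand if f.end < anchor.start]
        downstream.sort(key=lambda f: -f.end)
    return downstream


def extract_cluster(
    genome: PhageGenome,
    anchor: GeneFeature,
    stop_refs: list[str],
    min_protein_len: int = DEFAULT_MIN_PROTEIN_LEN,
    max_walk: int = DEFAULT_MAX_WALK,
    stop_min_identity: float = DEFAULT_ANCHOR_MIN_IDENTITY,
    params: AlignmentParams | None = None,
) -> ExtractionReport:
    """Walk downstream of the anchor and collect full-length TSP candidates.

    The walk terminates at the first feature matching a baseplate-wedge
    reference (identity >= ``stop_min_identity``) or after ``max_walk``
    inspected features, whichever comes first.
    """
    if anchor not in genome.features:
        raise ValueError("anchor does not belong to the genome")
    params = params or AlignmentParams()
    candidates: list[TspCandidate] = []
    inspected = 0
    for feature in _downstream_features(genome, anchor):
        if inspected >= max_walk:
            break
        inspected += 1
        protein = ensure_translation(genome, feature)
        if "*" not in protein and _best_identity(protein, stop_refs, params) >= stop_min_identity:
            break  # baseplate wedge: cluster ends here
        if len(protein) < min_protein_len or "*" in protein:
            continue  # small interleaved ORF or broken CDS: skip, keep walking
        candidates.append(
            TspCandidate(
                phage_id=genome.identifier,
                feature=feature,
                protein=protein,
                cluster_index=len(candidates) + 1,
            )
        )
    return ExtractionReport(
        phage_id=genome.identifier,
        anchor_found=True,
        candidates=candidates,
        discard_reason=None if candidates else "no_full_length_tsps",
        anchor=anchor,
    )


def extract_from_genome(
    genome: PhageGenome,
    anchor_refs: list[str],
    stop_refs: list[str],
    min_identity: float = DEFAULT_ANCHOR_MIN_IDENTITY,
    min_protein_len: int = DEFAULT_MIN_PROTEIN_LEN,
    max_walk: int = DEFAULT_MAX_WALK,
    params: AlignmentParams | None = None,
) -> ExtractionReport:
    """Anchor + walk in one call; ORF fallback for unannotated genomes."""
    if not genome.features:
        genome.features.extend(call_orfs(genome.sequence))
    anchor = locate_anchor(genome, anchor_refs, min_identity, params)
    if anchor is None:
        return ExtractionReport(
            genome.identifier, anchor_found=False, candidates=[], discard_reason="no_vriC"
        )
    return extract_cluster(
        genome, anchor, stop_refs, min_protein_len, max_walk, min_identity, params
    )


_STOPS = {"TAA", "TAG", "TGA"}
_STARTS = {"ATG", "GTG"}


def call_orfs(sequence: str, min_nt: int = 900) -> list[GeneFeature]:
    """Naive ORF caller: ATG/GTG .. stop, both strands, >= ``min_nt``.

    Per stop-bounded segment the longest ORF (first start codon) is emitted.
    Coordinates are 1-based inclusive on the forward strand and include the
    stop codon, matching annotated CDS convention.
    """
    features: list[GeneFeature] = []
    n = len(sequence)
    revcomp = str(Seq(sequence).reverse_complement())
    for strand, seq in (("+", sequence), ("-", revcomp)):
        for frame in range(3):
            start_candidate = None
            for pos in range(frame, n - 2, 3):
                codon = seq[pos : pos + 3]
                if codon in _STARTS and start_candidate is None:
                    start_candidate = pos
                elif codon in _STOPS:
                    if start_candidate is not None:
                        length = pos + 3 - start_candidate
                        if length >= min_nt:
                            if strand == "+":
                                start, end = start_candidate + 1, pos + 3
                            else:
                                start, end = n - (pos + 3) + 1, n - start_candidate
                            aa = str(Seq(seq[start_candidate : pos + 3]).translate())
                            features.append(
                                GeneFeature(
                                    locus_tag=f"orf_{len(features) + 1:04d}",
                                    product="predicted ORF",
                                    start=start,
                                    end=end,
                                    strand=strand,
                                    translation=aa[:-1] if aa.endswith("*") else aa,
                                )
                            )
                    start_candidate = None
    features.sort(key=lambda f: (f.start, f.end))
    return features
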