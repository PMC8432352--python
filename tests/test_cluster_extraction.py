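"""Anchoring on vriC and extraction of the TSP gene cluster."""

import numpy as np
import pytest

from ackertsp.cluster_extraction import (
    call_orfs,
    extract_cluster,
    extract_from_genome,
    locate_anchor,
)
from ackertsp.genome_io import GeneFeature, PhageGenome
from ackertsp.references import anchor_references, wedge_references
from ackertsp.simulate import CohortConfig, generate_cohort, mutate

from conftest import random_dna, random_protein, small_config


def _genome_with_proteins(proteins, rng, strand="+"):
    """A genome whose CDS features encode the given proteins (stubs: the
    nucleotide content is irrelevant when translations are provided)."""
    spacer = 30
    position = 100
    features = []
    for i, protein in enumerate(proteins):
        nt_len = 3 * len(protein) + 3
        features.append(
            GeneFeature(f"g_{i:03d}", "cds", position + 1, position + nt_len, strand, protein)
        )
        position += nt_len + spacer
    sequence = random_dna(rng, position + 200)
    return PhageGenome("manual", sequence, features)


class TestLocateAnchor:
    def test_verbatim_reference_found_at_identity_one(self):
        rng = np.random.default_rng(0)
        vric = anchor_references()[0]
        genome = _genome_with_proteins([random_protein(rng, 300), vric], rng)
        anchor = locate_anchor(genome, [vric])
        assert anchor is genome.features[1]

    def test_no_feature_above_floor_gives_none(self):
        rng = np.random.default_rng(1)
        genome = _genome_with_proteins([random_protein(rng, 330), random_protein(rng, 600)], rng)
        assert locate_anchor(genome, anchor_references()) is None

    def test_mutated_anchor_still_found(self):
        rng = np.random.default_rng(2)
        vric = mutate(anchor_references()[0], 0.10, rng, "ACDEFGHIKLMNPQRSTVWY")
        genome = _genome_with_proteins([random_protein(rng, 330), vric], rng)
        anchor = locate_anchor(genome, anchor_references())
        assert anchor is genome.features[1]

    def test_no_coding_features_is_an_error(self):
        genome = PhageGenome("bare", "ACGT" * 100)
        with pytest.raises(ValueError, match="no coding features"):
            locate_anchor(genome, anchor_references())


class TestExtractCluster:
    def test_planted_clusters_recovered(self, small_cohort):
        """Candidate count equals planted TSP count, and anchors land on the
        planted vriC locus, for every genome of the cohort."""
        genomes, truth = small_cohort
        for genome in genomes:
            record = truth.phages[genome.identifier]
            report = extract_from_genome(genome, anchor_references(), wedge_references())
            assert report.anchor_found
            assert (report.anchor.start, report.anchor.end) == tuple(record["vric"])
            assert len(report.candidates) == len(record["tsps"])
            assert [c.cluster_index for c in report.candidates] == list(
                range(1, len(record["tsps"]) + 1)
            )
            for candidate, planted in zip(report.candidates, record["tsps"]):
                assert candidate.protein == planted["protein"]

    def test_three_tsp_phage_yields_three_candidates(self):
        genomes, truth = generate_cohort(small_config(seed=5, p_three_tsp=1.0))
        report = extract_from_genome(genomes[0], anchor_references(), wedge_references())
        assert len(report.candidates) == 3
        assert truth.planted_types(genomes[0].identifier) == {1, 2, 4}

    def test_short_downstream_genes_discarded(self):
        rng = np.random.default_rng(4)
        vric = anchor_references()[0]
        genome = _genome_with_proteins(
            [vric, random_protein(rng, 120), random_protein(rng, 200)], rng
        )
        anchor = locate_anchor(genome, [vric])
        report = extract_cluster(genome, anchor, wedge_references())
        assert report.candidates == []
        assert report.discard_reason == "no_full_length_tsps"

    def test_anchor_at_terminal_position(self):
        rng = np.random.default_rng(5)
        vric = anchor_references()[0]
        genome = _genome_with_proteins([vric], rng)
        report = extract_cluster(genome, genome.features[0], wedge_references())
        assert report.discard_reason == "no_full_length_tsps"

    def test_strand_symmetry(self, small_cohort):
        """Reverse-complementing the genome (flipping features) yields the
        same candidate proteins in the same cluster order."""
        from Bio.Seq import Seq

        genomes, _ = small_cohort
        genome = genomes[0]
        n = len(genome.sequence)
        flipped = PhageGenome(
            genome.identifier,
            str(Seq(genome.sequence).reverse_complement()),
            [
                GeneFeature(
                    f.locus_tag,
                    f.product,
                    n - f.end + 1,
                    n - f.start + 1,
                    "-" if f.strand == "+" else "+",
                    f.translation,
                )
                for f in genome.features
            ],
            genome.taxonomy,
        )
        fwd = extract_from_genome(genome, anchor_references(), wedge_references())
        rev = extract_from_genome(flipped, anchor_references(), wedge_references())
        assert [c.protein for c in fwd.candidates] == [c.protein for c in rev.candidates]

    def test_no_false_anchors_without_planted_vric(self):
        rng = np.random.default_rng(6)
        genome = _genome_with_proteins(
            [random_protein(rng, 330), random_protein(rng, 700)], rng
        )
        report = extract_from_genome(genome, anchor_references(), wedge_references())
        assert not report.anchor_found
        assert report.discard_reason == "no_vriC"


class TestOrfFallback:
    def test_unannotated_genome_recovers_cluster(self, small_cohort):
        genomes, truth = small_cohort
        genome = genomes[0]
        bare = PhageGenome(genome.identifier, genome.sequence, [], genome.taxonomy)
        report = extract_from_genome(bare, anchor_references(), wedge_references())
        assert report.anchor_found
        assert len(report.candidates) == len(truth.phages[genome.identifier]["tsps"])

    def test_orf_caller_finds_planted_cds(self):
        rng = np.random.default_rng(7)
        protein = "M" + random_protein(rng, 350)
        from ackertsp.simulate import _Gene, back_translate

        cds = _Gene(protein, back_translate(protein, rng)).cds
        sequence = random_dna(rng, 500) + cds + random_dna(rng, 500)
        orfs = call_orfs(sequence, min_nt=900)
        spans = [(f.start, f.end) for f in orfs]
        # the planted CDS (or a short upstream in-frame extension) is called
        assert any(end == 500 + len(cds) and start <= 501 for start, end in spans)
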