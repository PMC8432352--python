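"""Shared fixtures: small deterministic cohorts and random-sequence helpers."""

from __future__ import annotations

import numpy as np
import pytest

from ackertsp.simulate import CohortConfig, generate_cohort

AA = "ACDEFGHIKLMNPQRSTVWY"
NT = "ACGT"


def random_protein(rng, n: int) -> str:
    return "".join(np.asarray(list(AA))[rng.integers(20, size=n)])


def random_dna(rng, n: int) -> str:
    return "".join(np.asarray(list(NT))[rng.integers(4, size=n)])


def small_config(seed: int = 11, **overrides) -> CohortConfig:
    """A desk-scale two-genus cohort with the default mutation rates."""
    defaults = dict(
        seed=seed,
        genera=(("Kuttervirus", 4, 0.02), ("Limestonevirus", 3, 0.015)),
        genome_length=8000,
    )
    defaults.update(overrides)
    return CohortConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    """One frozen small cohort shared across tests (seed 11)."""
    return generate_cohort(small_config())


@pytest.fixture(scope="session")
def typed_small_cohort(small_cohort):
    """The small cohort run through extraction and typing."""
    from ackertsp.cluster_extraction import extract_from_genome
    from ackertsp.references import anchor_references, wedge_references
    from ackertsp.tsp_typing import assign_type, default_typing_reference, resolve_phage_types

    genomes, truth = small_cohort
    reference = default_typing_reference()
    proteins = []
    reports = []
    for genome in genomes:
        report = extract_from_genome(genome, anchor_references(), wedge_references())
        reports.append(report)
        phage = [assign_type(c, reference) for c in report.candidates]
        proteins.extend(resolve_phage_types(phage))
    return genomes, truth, reports, proteins
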