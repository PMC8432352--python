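"""Subtype clustering: identity matrices, thresholding and genus association."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from ackertsp.subtypes import (
    IdentityMatrix,
    cluster_subtypes,
    genus_association,
    identity_matrix,
)
from ackertsp.tsp_typing import TspProtein

from conftest import random_protein, small_config


def _matrix(ids, values, tsp_type=1):
    return IdentityMatrix(ids=ids, values=np.array(values, dtype=float), tsp_type=tsp_type)


class TestIdentityMatrix:
    def test_single_protein(self):
        matrix = identity_matrix([TspProtein("p", 1, "MACDEF" * 20, tsp_type=1)])
        assert matrix.values.shape == (1, 1)
        assert matrix.values[0, 0] == 1.0

    def test_identical_pair(self):
        seq = random_protein(np.random.default_rng(0), 300)
        matrix = identity_matrix(
            [TspProtein("a", 1, seq, tsp_type=2), TspProtein("b", 1, seq, tsp_type=2)]
        )
        assert matrix.values[0, 1] == 1.0

    def test_mixed_types_rejected(self):
        with pytest.raises(ValueError, match="single TSP type"):
            identity_matrix(
                [TspProtein("a", 1, "MA", tsp_type=1), TspProtein("b", 1, "MA", tsp_type=2)]
            )

    def test_block_structure_of_planted_subtypes(self, typed_small_cohort):
        """Within-subtype identities sit far above the threshold, between-
        subtype identities far below: the separation the 75 % cut relies on."""
        _, truth, _, proteins = typed_small_cohort
        type1 = [p for p in proteins if p.tsp_type == 1]
        matrix = identity_matrix(type1)
        planted = truth.type_partition(1)
        n = len(type1)
        checked_within = checked_between = 0
        for i in range(n):
            for j in range(i + 1, n):
                same = planted[matrix.ids[i]] == planted[matrix.ids[j]]
                if same:
                    assert matrix.values[i, j] >= 0.88
                    checked_within += 1
                else:
                    assert matrix.values[i, j] <= 0.40
                    checked_between += 1
        assert checked_between > 0


class TestClusterSubtypes:
    def test_all_pairs_above_threshold_merge(self):
        matrix = _matrix(["a", "b", "c"], [[1, 0.9, 0.8], [0.9, 1, 0.95], [0.8, 0.95, 1]])
        assignment = cluster_subtypes(matrix)
        assert len(assignment.members) == 1

    def test_single_linkage_chain(self):
        """A-B and B-C above threshold pull A-C into one subtype even at
        40 % direct identity: the documented single-linkage semantics."""
        matrix = _matrix(["a", "b", "c"], [[1, 0.8, 0.4], [0.8, 1, 0.8], [0.4, 0.8, 1]])
        assignment = cluster_subtypes(matrix)
        assert len(assignment.members) == 1

    def test_threshold_is_inclusive(self):
        matrix = _matrix(["a", "b"], [[1, 0.75], [0.75, 1]])
        assert len(cluster_subtypes(matrix, 0.75).members) == 1

    def test_below_threshold_split(self):
        matrix = _matrix(["a", "b"], [[1, 0.7499], [0.7499, 1]])
        assert len(cluster_subtypes(matrix, 0.75).members) == 2

    def test_labels_ordered_by_size_then_member(self):
        matrix = _matrix(
            ["z", "a", "b"], [[1, 0.2, 0.2], [0.2, 1, 0.9], [0.2, 0.9, 1]], tsp_type=3
        )
        assignment = cluster_subtypes(matrix)
        assert assignment.members["TSP3-1"] == ["a", "b"]
        assert assignment.members["TSP3-2"] == ["z"]

    def test_order_invariance(self, typed_small_cohort):
        _, _, _, proteins = typed_small_cohort
        type4 = [p for p in proteins if p.tsp_type == 4]
        forward = cluster_subtypes(identity_matrix(type4))
        backward = cluster_subtypes(identity_matrix(list(reversed(type4))))
        assert forward.labels == backward.labels

    def test_refinement_monotonicity(self, typed_small_cohort):
        """Raising the threshold only ever splits subtypes, never merges:
        the partition at t2 >= t1 refines the partition at t1."""
        _, _, _, proteins = typed_small_cohort
        for t in (1, 2, 4):
            matrix = identity_matrix([p for p in proteins if p.tsp_type == t])
            previous = None
            for threshold in (0.6, 0.75, 0.9):
                assignment = cluster_subtypes(matrix, threshold)
                if previous is not None:
                    for members in assignment.members.values():
                        coarse_labels = {previous.labels[m] for m in members}
                        assert len(coarse_labels) == 1
                previous = assignment

    def test_planted_partition_recovered(self, typed_small_cohort):
        _, truth, _, proteins = typed_small_cohort
        for t in (1, 2, 3, 4):
            of_type = [p for p in proteins if p.tsp_type == t]
            if len(of_type) < 2:
                continue
            assignment = cluster_subtypes(identity_matrix(of_type))
            planted = truth.type_partition(t)
            ids = [p.protein_id for p in of_type]
            ari = adjusted_rand_score(
                [planted[i] for i in ids], [assignment.labels[i] for i in ids]
            )
            assert ari == 1.0


class TestGenusAssociation:
    def test_single_genus_subtypes(self, typed_small_cohort):
        """With genus-private module pools every subtype maps to one genus."""
        genomes, truth, _, proteins = typed_small_cohort
        genus_of = truth.genus_of()
        type1 = [p for p in proteins if p.tsp_type == 1]
        table = genus_association(cluster_subtypes(identity_matrix(type1)), genus_of)
        assert all(not info["cross_genus"] for info in table.values())

    def test_planted_cross_genus_subtype_flagged(self):
        """A TSP4 subtype shared between two genera — the TSP4-14 situation —
        is the only flagged entry."""
        from ackertsp.cluster_extraction import extract_from_genome
        from ackertsp.references import anchor_references, wedge_references
        from ackertsp.simulate import generate_cohort
        from ackertsp.tsp_typing import assign_type, resolve_phage_types

        config = small_config(seed=31, n_cross_genus_subtypes=1, module_library_size=2)
        genomes, truth = generate_cohort(config)
        proteins = []
        for genome in genomes:
            report = extract_from_genome(genome, anchor_references(), wedge_references())
            proteins.extend(resolve_phage_types([assign_type(c) for c in report.candidates]))
        genus_of = truth.genus_of()
        type4 = [p for p in proteins if p.tsp_type == 4]
        table = genus_association(cluster_subtypes(identity_matrix(type4)), genus_of)
        flagged = {label for label, info in table.items() if info["cross_genus"]}
        planted_cross = {
            key
            for key, phages in _subtype_to_phages(truth, 4).items()
            if len({genus_of[p] for p in phages}) > 1
        }
        assert (len(flagged) > 0) == (len(planted_cross) > 0)
        # flagged subtypes contain exactly the planted cross-genus members
        for label in flagged:
            members = {m.rsplit("/", 1)[0] for m in _members_of(table, label, type4)}
            assert len({genus_of[m] for m in members}) > 1

    def test_missing_genus_is_an_error(self, typed_small_cohort):
        _, _, _, proteins = typed_small_cohort
        type2 = [p for p in proteins if p.tsp_type == 2]
        assignment = cluster_subtypes(identity_matrix(type2))
        with pytest.raises(ValueError, match="no genus"):
            genus_association(assignment, {})


def _subtype_to_phages(truth, tsp_type):
    out: dict[str, list[str]] = {}
    for pid, key in truth.type_partition(tsp_type).items():
        out.setdefault(key, []).append(pid.rsplit("/", 1)[0])
    return out


def _members_of(table, label, proteins):
    from ackertsp.subtypes import cluster_subtypes, identity_matrix

    assignment = cluster_subtypes(identity_matrix(proteins))
    return assignment.members[label]
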