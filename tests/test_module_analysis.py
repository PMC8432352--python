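"""Shared-module detection, TD1 slicing and motif discovery."""

import numpy as np
import pytest

from ackertsp.modules import (
    TD1_REGIONS,
    detect_module_share,
    extract_td1,
    find_conserved_motif,
)
from ackertsp.references import MOTIF
from ackertsp.simulate import generate_cohort, mutate
from ackertsp.tsp_typing import TspProtein

from conftest import random_protein, small_config

AA = "ACDEFGHIKLMNPQRSTVWY"


def _planted_pair(rng, module_mut=0.0):
    """Type-1 and type-4 proteins sharing a C-terminal module; junction
    flank residues chosen distinct (as in the real type scaffolds) so the
    shared region starts exactly at the junction."""
    body = random_protein(rng, 493)
    m1 = MOTIF + (mutate(body, module_mut / 2, rng, AA) if module_mut else body)
    m2 = MOTIF + (mutate(body, module_mut / 2, rng, AA) if module_mut else body)
    while True:
        s1, s4 = random_protein(rng, 64), random_protein(rng, 390)
        if s1[-1] != s4[-1]:
            break
    a = TspProtein("phageA", 1, s1 + m1, tsp_type=1)
    b = TspProtein("phageB", 4, s4 + m2, tsp_type=4)
    return a, b


class TestDetectModuleShare:
    def test_planted_pair_reports_junction_positions(self):
        """The reported block starts are the module junctions: residue 65 on
        the type-1 side and 391 on the type-4 side."""
        rng = np.random.default_rng(17)
        for _ in range(10):
            a, b = _planted_pair(rng)
            hit = detect_module_share(a, b)
            assert hit is not None
            assert (hit.start_a, hit.start_b) == (65, 391)
            assert hit.block_identity > 0.99
            assert hit.block_length >= 400

    def test_positions_stable_under_module_substitution(self):
        rng = np.random.default_rng(18)
        for _ in range(10):
            a, b = _planted_pair(rng, module_mut=0.05)
            hit = detect_module_share(a, b)
            assert hit is not None
            assert abs(hit.start_a - 65) <= 2
            assert abs(hit.start_b - 391) <= 2

    def test_unrelated_modules_absent(self):
        rng = np.random.default_rng(19)
        a, _ = _planted_pair(rng)
        _, b = _planted_pair(rng)
        assert detect_module_share(a, b) is None

    def test_internal_block_without_cterm_anchor_absent(self):
        rng = np.random.default_rng(20)
        shared = random_protein(rng, 400)
        a = TspProtein("pA", 1, random_protein(rng, 64) + shared + random_protein(rng, 30), tsp_type=1)
        b = TspProtein("pB", 4, random_protein(rng, 390) + shared + random_protein(rng, 50), tsp_type=4)
        assert detect_module_share(a, b) is None

    def test_role_swap_gives_mirrored_hit(self):
        rng = np.random.default_rng(21)
        a, b = _planted_pair(rng)
        forward = detect_module_share(a, b)
        mirrored = detect_module_share(b, a)
        assert (forward.protein_a, forward.protein_b) == (mirrored.protein_a, mirrored.protein_b)
        assert (forward.start_a, forward.start_b) == (mirrored.start_a, mirrored.start_b)

    def test_wrong_types_rejected(self):
        a = TspProtein("pA", 1, "M" * 600, tsp_type=2)
        b = TspProtein("pB", 2, "M" * 600, tsp_type=4)
        with pytest.raises(ValueError, match="type"):
            detect_module_share(a, b)

    def test_planted_swaps_found_with_full_precision_and_recall(self):
        """On a cohort with planted swaps, detection recovers exactly the
        donor/acceptor pairs that share a module."""
        config = small_config(seed=41, p_swap=0.5)
        genomes, truth = generate_cohort(config)
        proteins = {}
        for phage_id, record in truth.phages.items():
            for tsp in record["tsps"]:
                proteins[f"{phage_id}/tsp{tsp['cluster_index']}"] = TspProtein(
                    phage_id, tsp["cluster_index"], tsp["protein"], tsp_type=tsp["tsp_type"]
                )
        planted_pairs = set()
        partition = {}
        for t in (1, 3, 4):
            partition.update(truth.type_partition(t))
        donors = {pid: key for pid, key in partition.items() if not key.endswith(":on4")}
        acceptors = {pid: key for pid, key in partition.items() if key.endswith(":on4")}
        for apid, akey in acceptors.items():
            for dpid, dkey in donors.items():
                if proteins[dpid].tsp_type in (1, 3) and akey == dkey + ":on4":
                    planted_pairs.add((dpid, apid))
        found = set()
        for dpid, donor in proteins.items():
            if donor.tsp_type not in (1, 3):
                continue
            for apid, acceptor in proteins.items():
                if acceptor.tsp_type != 4:
                    continue
                if detect_module_share(donor, acceptor) is not None:
                    found.add((dpid, apid))
        assert found == planted_pairs
        assert len(planted_pairs) > 0


class TestExtractTd1:
    @pytest.mark.parametrize("tsp_type,expected_len", [(1, 96), (2, 101), (3, 96), (4, 78)])
    def test_region_lengths(self, tsp_type, expected_len):
        protein = TspProtein("p", 1, "M" * 600, tsp_type=tsp_type)
        assert len(extract_td1(protein)) == expected_len

    def test_region_is_positional_slice(self):
        sequence = "".join(AA[i % 20] for i in range(600))
        protein = TspProtein("p", 1, sequence, tsp_type=4)
        start, end = TD1_REGIONS[4]
        assert extract_td1(protein) == sequence[start - 1 : end]

    def test_short_protein_is_an_error(self):
        protein = TspProtein("p", 1, "M" * 90, tsp_type=3)
        with pytest.raises(ValueError, match="shorter"):
            extract_td1(protein)


class TestFindConservedMotif:
    def test_planted_motif_is_top_hit(self):
        """TD1 slices that all contain GTTAVSL in unrelated contexts return
        it as the top hit at support 1.0."""
        rng = np.random.default_rng(30)
        regions = []
        for _ in range(12):
            left = random_protein(rng, int(rng.integers(40, 60)))
            right = random_protein(rng, int(rng.integers(20, 40)))
            regions.append(left + MOTIF + right)
        hits = find_conserved_motif(regions)
        assert hits[0].motif == MOTIF
        assert hits[0].support == 1.0
        # reported positions point at the motif in every region
        for idx, pos in hits[0].positions.items():
            assert regions[idx][pos - 1 : pos - 1 + len(MOTIF)] == MOTIF

    def test_random_regions_have_no_motif(self):
        rng = np.random.default_rng(31)
        regions = [random_protein(rng, 96) for _ in range(10)]
        hits = find_conserved_motif(regions, min_support=0.8)
        assert hits == []
        from oracles import scan_motifs

        assert scan_motifs(regions, 5, 10, 0.8) == {}

    def test_agrees_with_exhaustive_scan(self):
        rng = np.random.default_rng(32)
        shared = random_protein(rng, 8)
        regions = [
            random_protein(rng, 30) + shared + random_protein(rng, 20) for _ in range(5)
        ]
        from oracles import scan_motifs

        expected = scan_motifs(regions, 5, 10, 1.0)
        hits = find_conserved_motif(regions, min_support=1.0)
        # every reported motif is in the oracle set; the oracle's maximal
        # motifs all survive suppression
        assert all(h.motif in expected for h in hits)
        maximal = [m for m in expected if not any(m != o and m in o for o in expected)]
        assert set(m for m in maximal) <= {h.motif for h in hits}

    def test_identical_regions_suppression(self):
        region = "".join(AA[i % 20] for i in range(96))
        hits = find_conserved_motif([region] * 4)
        assert all(len(h.motif) == 10 for h in hits)
        assert all(h.support == 1.0 for h in hits)

    def test_cohort_td1_pool_recovers_motif_with_tsp2_negative(self, typed_small_cohort):
        """Pooled TD1 slices of types 1/3/4 carry GTTAVSL at full support;
        TSP2 TD1 slices — which sit before the type-2 junction — do not."""
        _, _, _, proteins = typed_small_cohort
        pool = [extract_td1(p) for p in proteins if p.tsp_type in (1, 3, 4)]
        hits = find_conserved_motif(pool)
        assert hits[0].motif == MOTIF and hits[0].support == 1.0
        tsp2 = [extract_td1(p) for p in proteins if p.tsp_type == 2]
        if len(tsp2) >= 2:
            assert all(h.motif != MOTIF for h in find_conserved_motif(tsp2))

    def test_needs_two_regions(self):
        with pytest.raises(ValueError, match="two regions"):
            find_conserved_motif(["MACDEF"])
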