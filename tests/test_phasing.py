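import numpy as np
import pytest

from conftest import random_recovery_config, simulate_truth
from silocus import datasets, phasing, simulator
from silocus.data_io import CohortObservation, PresenceMatrix
from silocus.phasing import (
    PhasingError,
    SUPPORT_COSEGREGATION,
    SUPPORT_F0_ASSOCIATION,
    cluster_cotransmitted,
    transmission_vectors,
)

STUDY_PAIRS = [
    {"B10", "B11"},
    {"A01", "A03"},
    {"B01", "B13"},
    {"B04", "C01"},
    {"A01", "A02"},
    {"A06", "A07"},
    {"B09", "B12"},
    {"B17", "B18"},
]


class TestTransmissionVectors:
    def test_cohort_18x1_patterns_pair_parental_labels(self, study_presence, study_cohorts):
        cohort = {c.cohort_id: c for c in study_cohorts}["18x1"]
        vectors = {
            v.label: v.pattern
            for v in transmission_vectors(cohort, "18", study_presence, datasets.UNTYPABLE)
        }
        assert vectors["A01"] == vectors["A02"]
        assert vectors["B04"] == vectors["C01"]
        assert vectors["A01"] == tuple(not x for x in vectors["B04"])

    def test_single_typable_label_gives_single_vector(self, study_presence, study_cohorts):
        # parent 9 carries B06 plus the untypable B17/B18
        cohort = {c.cohort_id: c for c in study_cohorts}["9x4"]
        vectors = transmission_vectors(cohort, "9", study_presence, datasets.UNTYPABLE)
        assert [v.label for v in vectors] == ["B06"]

    def test_non_parent_rejected(self, study_presence, study_cohorts):
        with pytest.raises(PhasingError, match="not a parent"):
            transmission_vectors(study_cohorts[0], "21", study_presence)

    def test_vectors_match_simulated_transmission_record(self):
        """On simulated data the transmission vector of a parental label must
        equal, class by class, the latent record of which haplotype the
        parent transmitted."""
        cfg = random_recovery_config(42)
        rng = np.random.default_rng(42)
        truth = simulate_truth(cfg, rng)
        dataset = simulator.emit_dataset(truth, cfg, rng)
        cohort = parent = vectors = None
        for candidate in dataset.cohorts:
            try:
                vectors = transmission_vectors(
                    candidate, candidate.parent1_id, dataset.presence
                )
                cohort, parent = candidate, candidate.parent1_id
                break
            except PhasingError:
                continue
        assert cohort is not None
        g = truth.genotypes[parent]
        # map each observed class to the parent haplotypes that produced it
        produced_by: dict[frozenset, set] = {}
        for h_p1, h_p2 in dataset.transmissions[cohort.cohort_id]:
            combo = truth.catalog[h_p1].labels | truth.catalog[h_p2].labels
            produced_by.setdefault(combo, set()).add(h_p1)
        for vec in vectors:
            carriers = {h for h in (g.h1, g.h2) if vec.label in truth.catalog[h].labels}
            for combo, present in zip(vec.classes, vec.pattern):
                expected = bool(produced_by[combo] & carriers)
                assert present == expected


class TestClustering:
    def _vectors(self, patterns):
        classes = tuple(frozenset((f"c{i}",)) for i in range(len(next(iter(patterns.values())))))
        return [
            phasing.TransmissionVector("p", "c", label, tuple(map(bool, pat)), classes)
            for label, pat in patterns.items()
        ]

    def test_two_complementary_groups(self):
        result = cluster_cotransmitted(
            self._vectors({"A01": (1, 1, 0, 1), "A02": (1, 1, 0, 1), "B04": (0, 0, 1, 0), "C01": (0, 0, 1, 0)})
        )
        assert result.consistent
        assert set(result.groups) == {frozenset({"A01", "A02"}), frozenset({"B04", "C01"})}

    def test_all_identical_patterns_single_group(self):
        result = cluster_cotransmitted(self._vectors({"B10": (1, 1), "B11": (1, 1)}))
        assert result.consistent and result.all_cotransmitted
        assert result.groups == (frozenset({"B10", "B11"}),)

    def test_shared_label_attached_to_both_groups(self):
        # a label transmitted to every offspring while others split in two
        result = cluster_cotransmitted(
            self._vectors({"A01": (1, 1, 1), "A02": (1, 0, 1), "A03": (0, 1, 0)})
        )
        assert result.consistent
        assert set(result.groups) == {frozenset({"A01", "A02"}), frozenset({"A01", "A03"})}

    def test_three_distinct_patterns_flagged(self):
        result = cluster_cotransmitted(
            self._vectors({"x": (1, 0, 0), "y": (0, 1, 0), "z": (0, 0, 1)})
        )
        assert not result.consistent


class TestLinkedPairs:
    def test_study_tables_give_the_eight_pairs(self, study_presence, study_cohorts):
        linkage = phasing.infer_linked_pairs(study_presence, study_cohorts, datasets.UNTYPABLE)
        assert {frozenset(p) for p in STUDY_PAIRS} == set(linkage.pairs)
        assert linkage.pairs[frozenset({"B01", "B13"})].support == SUPPORT_F0_ASSOCIATION
        assert linkage.pairs[frozenset({"B17", "B18"})].support == SUPPORT_F0_ASSOCIATION
        assert linkage.pairs[frozenset({"A01", "A02"})].support == SUPPORT_COSEGREGATION

    def test_disjoint_singletons_give_no_pairs(self):
        matrix = PresenceMatrix({"1": {"X1"}, "2": {"X2"}, "3": {"X3"}})
        assert phasing.infer_linked_pairs(matrix).pairs == {}

    def test_contradictory_evidence_names_cohorts(self, study_presence):
        together = CohortObservation(
            "together", "15", "19", 4,
            {frozenset({"A05", "B05", "B03"}): 2, frozenset({"A05", "B05", "B06"}): 2},
        )
        apart = CohortObservation(
            "apart", "15", "19", 4,
            {
                frozenset({"A05", "B03"}): 1,
                frozenset({"B05", "B03"}): 1,
                frozenset({"A05", "B06"}): 1,
                frozenset({"B05", "B06"}): 1,
            },
        )
        with pytest.raises(PhasingError, match="together.*apart"):
            phasing.infer_linked_pairs(study_presence, [together, apart])


class TestCatalogAndGenotypes:
    def test_catalog_counts_match_study(self, study_phase):
        catalog, _, _ = study_phase
        assert len(catalog) == 13
        assert len(catalog.labels) == 20
        assert sum(len(h.labels) == 2 for h in catalog) == 8

    def test_empty_pairs_give_singletons(self):
        matrix = PresenceMatrix({"1": {"X1", "X2"}})
        catalog = phasing.build_catalog(phasing.LinkageResult({}), matrix)
        assert sorted(sorted(h.labels) for h in catalog) == [["X1"], ["X2"]]

    def test_shared_label_genotype_disambiguated(self, study_phase):
        catalog, genotypes, _ = study_phase
        g6 = {g.individual_id: g for g in genotypes}["6"]
        assert {catalog[g6.h1].labels, catalog[g6.h2].labels} == {
            frozenset({"A01", "A02"}),
            frozenset({"A01", "A03"}),
        }

    def test_homozygotes_confirmed_only_for_3_and_17(self, study_phase):
        _, genotypes, _ = study_phase
        homs = {g.individual_id for g in genotypes if g.is_homozygote}
        assert homs == {"3", "17"}
        assert all(
            g.status == phasing.STATUS_CONFIRMED_HOM
            for g in genotypes
            if g.individual_id in homs
        )

    def test_uncoverable_label_set_rejected(self, study_phase):
        catalog, _, _ = study_phase
        matrix = PresenceMatrix({"x": {"B10"}})
        with pytest.raises(PhasingError, match="not coverable"):
            phasing.assign_genotypes(matrix, catalog)

    def test_every_label_in_at_least_one_haplotype(self, study_presence, study_phase):
        catalog, _, _ = study_phase
        assert set(study_presence.labels) <= catalog.labels
        assert len(catalog) <= len(study_presence.labels)


class TestMonotonicity:
    def test_adding_a_cohort_never_drops_a_cosegregation_pair(
        self, study_presence, study_cohorts
    ):
        base = phasing.infer_linked_pairs(
            study_presence, study_cohorts[:6], datasets.UNTYPABLE
        )
        full = phasing.infer_linked_pairs(
            study_presence, study_cohorts, datasets.UNTYPABLE
        )
        coseg_base = {
            p for p, lp in base.pairs.items() if lp.support == SUPPORT_COSEGREGATION
        }
        coseg_full = {
            p for p, lp in full.pairs.items() if lp.support == SUPPORT_COSEGREGATION
        }
        assert coseg_base <= coseg_full


def test_simulated_catalog_recovered_exactly():
    """Noise-free round trip on one representative simulated design."""
    cfg = random_recovery_config(7)
    rng = np.random.default_rng(7)
    truth = simulate_truth(cfg, rng)
    dataset = simulator.emit_dataset(truth, cfg, rng)
    catalog, genotypes, _ = phasing.phase_dataset(dataset.presence, dataset.cohorts)
    assert catalog.label_sets == truth.catalog.label_sets
    for g in genotypes:
        t = truth.genotypes[g.individual_id]
        assert {catalog[g.h1].labels, catalog[g.h2].labels} == {
            truth.catalog[t.h1].labels,
            truth.catalog[t.h2].labels,
        }
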