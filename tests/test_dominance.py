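import itertools

import numpy as np
import pytest
from scipy.stats import binom

from silocus import datasets, dominance, simulator
from silocus.data_io import CrossOutcome, DataError
from silocus.dominance import (
    AMBIGUOUS,
    COMPATIBLE,
    EXPRESSED,
    INCOMPATIBLE,
    SILENCED,
    UNDETERMINED,
    build_dominance,
    consolidate_crosses,
    infer_expression,
    predict_compatibility,
    summarize_compatibility,
)
from silocus.phasing import DiploidGenotype, STATUS_PUTATIVE_HOM


@pytest.fixture
def pair_genotypes():
    """Individuals 3 (S01 homozygote) and 4 (S01/S02) of the worked example."""
    return {
        "3": DiploidGenotype("3", "S01", "S01", STATUS_PUTATIVE_HOM),
        "4": DiploidGenotype("4", "S01", "S02"),
    }


class TestConsolidate:
    def test_unanimous_replicates_merge(self, pair_genotypes):
        crosses = [CrossOutcome("3", "4", "no_fruit", 3)]
        consensus = consolidate_crosses(crosses, pair_genotypes)
        ((key, co),) = consensus.items()
        assert co.outcome == INCOMPATIBLE and co.n_no_fruit == 3

    def test_not_done_excluded(self, pair_genotypes):
        assert consolidate_crosses([CrossOutcome("3", "4", "not_done", 1)], pair_genotypes) == {}

    def test_mixed_outcomes_conflict_under_strict_policy(self, pair_genotypes):
        crosses = [
            CrossOutcome("3", "4", "fruit", 1),
            CrossOutcome("3", "4", "no_fruit", 2),
        ]
        strict = consolidate_crosses(crosses, pair_genotypes)
        majority = consolidate_crosses(crosses, pair_genotypes, policy="majority")
        (strict_co,) = strict.values()
        (majority_co,) = majority.values()
        assert strict_co.outcome == "conflicting"
        assert majority_co.outcome == INCOMPATIBLE

    def test_ungenotyped_individual_rejected(self, pair_genotypes):
        with pytest.raises(DataError, match="ungenotyped"):
            consolidate_crosses([CrossOutcome("3", "99", "fruit", 1)], pair_genotypes)

    def test_majority_of_three_beats_single_replicate(self):
        """Binomial check: at 9% leakage / 29% failure the majority of three
        replicates miscalls less often than one replicate, on both sides."""
        for p_err in (0.09, 0.29):
            maj = sum(binom.pmf(k, 3, p_err) for k in (2, 3))
            assert maj < p_err


class TestWorkedExample:
    """The published individual 3/4 example: 4->3 compatible, 3->4 and both
    selfs incompatible, implying S01 is recessive in pollen of S01S02."""

    @pytest.fixture
    def model(self, pair_genotypes):
        consensus = consolidate_crosses(datasets.worked_example_crosses(), pair_genotypes)
        return infer_expression(consensus)

    def test_s01_silenced_in_pollen_of_heterozygote(self, model):
        assert model.state(frozenset({"S01", "S02"}), "pollen", "S01") == SILENCED

    def test_s01_expressed_in_stigma_of_heterozygote(self, model):
        assert model.state(frozenset({"S01", "S02"}), "stigma", "S01") == EXPRESSED

    def test_s01_expressed_in_both_organs_of_homozygote(self, model):
        hom = frozenset({"S01"})
        assert model.state(hom, "pollen", "S01") == EXPRESSED
        assert model.state(hom, "stigma", "S01") == EXPRESSED

    def test_prediction_reproduces_both_directions(self, model):
        het, hom = frozenset({"S01", "S02"}), frozenset({"S01"})
        assert predict_compatibility(het, hom, model) == COMPATIBLE
        assert predict_compatibility(hom, het, model) == INCOMPATIBLE

    def test_dominance_summary_has_s02_over_s01_in_pollen(self, model):
        dom = build_dominance(model)
        assert ("S02", "S01") in dom.dominant["pollen"]
        assert dom.cycles["pollen"] == []


class TestSelfIncompatibleHeterozygote:
    def test_lone_self_incompatibility_leaves_calls_ambiguous(self):
        xy = frozenset({"X", "Y"})
        consensus = {
            (xy, xy): dominance.ConsensusOutcome(xy, xy, INCOMPATIBLE, 0, 1)
        }
        model = infer_expression(consensus)
        for organ in ("pollen", "stigma"):
            for hap in ("X", "Y"):
                assert model.state(xy, organ, hap) == AMBIGUOUS
        # but at least one haplotype must stay possible per organ
        assert model.possible_set(xy, "pollen") == xy


def _brute_force_outcome(donor_states, receptor_states):
    """Enumerate every resolution of ambiguous states; return the prediction
    implied by exhaustive set intersection."""
    def resolutions(states):
        keys = sorted(states)
        options = [
            [EXPRESSED, SILENCED] if states[k] == AMBIGUOUS else [states[k]]
            for k in keys
        ]
        for combo in itertools.product(*options):
            yield {k: v for k, v in zip(keys, combo)}

    outcomes = set()
    for d in resolutions(donor_states):
        for r in resolutions(receptor_states):
            pollen = {h for h, s in d.items() if s == EXPRESSED}
            stigma = {h for h, s in r.items() if s == EXPRESSED}
            outcomes.add(INCOMPATIBLE if pollen & stigma else COMPATIBLE)
    if outcomes == {INCOMPATIBLE}:
        return INCOMPATIBLE
    if outcomes == {COMPATIBLE}:
        return COMPATIBLE
    return UNDETERMINED


def test_prediction_matches_brute_force_enumeration():
    """predict_compatibility equals exhaustive enumeration over all
    expression assignments for every genotype pair from 4 haplotypes."""
    haps = ["S1", "S2", "S3", "S4"]
    genotypes = [frozenset(p) for p in itertools.combinations(haps, 2)]
    genotypes += [frozenset((h,)) for h in haps]
    rng = np.random.default_rng(99)
    states = [EXPRESSED, SILENCED, AMBIGUOUS]
    for _ in range(60):
        model = dominance.ExpressionModel(genotypes)
        assignment = {}
        for g in genotypes:
            for organ in ("pollen", "stigma"):
                for h in g:
                    s = states[rng.integers(3)]
                    assignment[(g, organ, h)] = s
                    if s != AMBIGUOUS:
                        model.assign(g, organ, h, s)
        for gd, gr in itertools.product(genotypes, repeat=2):
            expected = _brute_force_outcome(
                {h: assignment[(gd, "pollen", h)] for h in gd},
                {h: assignment[(gr, "stigma", h)] for h in gr},
            )
            assert predict_compatibility(gd, gr, model) == expected


def test_full_diallel_with_homozygotes_resolves_linear_hierarchy():
    """A noise-free diallel over all genotypes of 6 haplotypes (15 het + 6
    hom individuals) resolves >= 90% of genotype/organ/haplotype triples and
    reconstructs the simulated pollen order without error."""
    cfg = simulator.SimulationConfig(
        n_haplotypes=6,
        paired_fraction=0.5,
        n_individuals=21,
        homozygote_probability=0.0,
        pollination_failure_rate=0.0,
        si_leakage_rate=0.0,
        dominance_spec={"stigma": "linear", "pollen": "linear"},
        seed=5,
    )
    rng = np.random.default_rng(5)
    truth = simulator.simulate_locus(cfg, rng)
    hap_ids = [h.haplotype_id for h in truth.catalog]
    # overwrite the sampled individuals with the full genotype panel
    truth.genotypes = {}
    idx = 0
    for a, b in itertools.combinations(hap_ids, 2):
        idx += 1
        truth.genotypes[str(idx)] = DiploidGenotype(str(idx), *sorted((a, b)))
    for h in hap_ids:
        idx += 1
        truth.genotypes[str(idx)] = DiploidGenotype(str(idx), h, h, STATUS_PUTATIVE_HOM)

    crosses = []
    for d in truth.genotypes:
        for r in truth.genotypes:
            crosses.extend(simulator.simulate_cross(d, r, truth, cfg, rng))
    consensus = consolidate_crosses(crosses, truth.genotypes)
    model = infer_expression(consensus)

    resolved = wrong = total = 0
    for call in model.calls():
        if len(call.genotype) < 2:
            continue
        total += 1
        if call.state in (EXPRESSED, SILENCED):
            resolved += 1
            if call.state != truth.expression_state(call.genotype, call.organ, call.haplotype):
                wrong += 1
    assert wrong == 0
    assert resolved / total >= 0.90

    dom = build_dominance(model)
    order = truth.dominance_order["pollen"]
    for (winner, loser) in dom.dominant["pollen"]:
        assert order.index(winner) < order.index(loser)
    # soundness: predictions reproduce the full latent cross matrix
    for d, gd in truth.genotypes.items():
        for r, gr in truth.genotypes.items():
            pred = predict_compatibility(gd.haplotypes, gr.haplotypes, model)
            if pred != UNDETERMINED:
                latent = truth.latent_compatible(d, r)
                assert (pred == COMPATIBLE) == latent


class TestSummaries:
    def test_synthetic_rates_recover_con_figured_noise(self):
        """Fruit rates of shared vs non-shared crosses track the configured
        leakage and failure rates on a large simulated diallel."""
        cfg = simulator.SimulationConfig(
            n_haplotypes=8,
            paired_fraction=0.5,
            n_individuals=40,
            homozygote_probability=0.1,
            dominance_spec={"stigma": "codominant", "pollen": "codominant"},
            replicate_count=3,
            seed=31,
        )
        rng = np.random.default_rng(31)
        truth = simulator.simulate_locus(cfg, rng)
        dataset = simulator.emit_dataset(truth, cfg, rng)
        table = summarize_compatibility(
            dataset.crosses, list(truth.genotypes.values()), truth.catalog
        )
        overall = table[table["scope"] == "overall"].set_index("shared_haplotype")
        # under full codominance shared => incompatible, non-shared => compatible
        shared = overall.loc[True]
        control = overall.loc[False]
        for row, p in ((shared, 0.09), (control, 0.71)):
            se = np.sqrt(p * (1 - p) / row["n_crosses"])
            assert abs(row["rate"] - p) < 4 * se

    def test_all_not_done_gives_empty_summary(self, pair_genotypes):
        table = summarize_compatibility(
            [CrossOutcome("3", "4", "not_done", 1)], pair_genotypes
        )
        assert len(table) == 0

    def test_single_incompatible_shared_cross_rate_zero(self, pair_genotypes):
        table = summarize_compatibility(
            [CrossOutcome("3", "4", "no_fruit", 1)], pair_genotypes
        )
        overall = table[(table["scope"] == "overall")]
        assert overall["rate"].tolist() == [0.0]
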