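import numpy as np
import pytest

from silocus import datasets, phasing, simulator


@pytest.fixture(scope="session")
def study_presence():
    """The 21-individual parental presence matrix, sub-variants merged."""
    return datasets.load_f0_presence()


@pytest.fixture(scope="session")
def study_cohorts(study_presence):
    return datasets.load_f1_cohorts(study_presence)


@pytest.fixture(scope="session")
def study_phase(study_presence, study_cohorts):
    """(catalog, genotypes, linkage) from the bundled study tables."""
    return phasing.phase_dataset(
        study_presence,
        study_cohorts,
        datasets.UNTYPABLE,
        class_map=datasets.class_map(),
        name_map=datasets.s_haplotype_names(),
    )


@pytest.fixture(scope="session")
def study_genotype_map(study_phase):
    _, genotypes, _ = study_phase
    return {g.individual_id: g for g in genotypes}


def random_recovery_config(seed: int) -> simulator.SimulationConfig:
    """A random noise-free, fully typable study design for recovery tests."""
    rng = np.random.default_rng(seed)
    n_hap = int(rng.integers(4, 9))
    return simulator.SimulationConfig(
        n_haplotypes=n_hap,
        paired_fraction=float(rng.uniform(0.3, 0.8)),
        shared_label=bool(rng.random() < 0.5),
        n_individuals=n_hap * 2,
        homozygote_probability=0.1,
        cohort_sizes=(25,),
        pollination_failure_rate=0.0,
        si_leakage_rate=0.0,
        replicate_count=1,
        seed=seed,
    )


def simulate_truth(config, rng):
    """simulate_locus with a fallback when the drawn class/pairing layout
    cannot host a shared label."""
    try:
        return simulator.simulate_locus(config, rng)
    except simulator.SimulationError:
        config.shared_label = False
        return simulator.simulate_locus(config, rng)
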