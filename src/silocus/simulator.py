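"""Synthetic-data generator for the whole S-locus pipeline.

Emulates a sporophytic self-incompatibility study design: a panel of
diploid individuals carrying two S-haplotypes each, haplotypes composed of
one or two linked sequence labels (optionally with one label shared
between two haplotypes), per-organ dominance among haplotypes, Mendelian
transmission in full-sib cohorts, and a noisy diallel of controlled
pollinations where a fraction of compatible crosses fails to set fruit
(pollination failure) and a fraction of incompatible crosses leaks
through (self-incompatibility leakage).

Offspring genotype frequencies are pure Mendelian (0.25 x 4 for het x het,
0.5 x 2 for hom x het): all pollen from one donor shares a single
sporophytic phenotype, so compatibility does not filter genotypes within
a compatible cross.

Every observation a dataset emits is reproducible from the
:class:`GroundTruth` and the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .data_io import (
    CohortObservation,
    CrossOutcome,
    PresenceMatrix,
    write_cohorts,
    write_crosses,
    write_presence_matrix,
)
from .phasing import (
    STATUS_HET,
    STATUS_PUTATIVE_HOM,
    DiploidGenotype,
    Haplotype,
    HaplotypeCatalog,
    SUPPORT_COSEGREGATION,
    SUPPORT_SINGLETON,
)

ORGANS = ("pollen", "stigma")
DOMINANCE_SPECS = ("codominant", "linear", "class_levels")


class SimulationError(ValueError):
    """Raised for unsatisfiable simulation configurations."""


@dataclass
class SimulationConfig:
    """Study-design parameters of a synthetic S-locus dataset.

    Defaults mirror the observed study conditions: about 29% of compatible
    pollinations fail to set fruit (71% of positive controls succeed) and
    about 9% of incompatible pollinations leak through; 8 of 13 haplotypes
    carry a linked label pair; stigma expression is mostly codominant while
    pollen shows a dominance hierarchy aligned with sequence classes.
    """

    n_haplotypes: int = 13
    paired_fraction: float = 8 / 13
    shared_label: bool = False
    class_a_fraction: float = 5 / 13
    dominance_spec: Mapping[str, str] = field(
        default_factory=lambda: {"stigma": "codominant", "pollen": "class_levels"}
    )
    n_individuals: int = 21
    homozygote_probability: float = 2 / 21
    cohort_sizes: tuple[int, ...] = (7, 13, 5, 7, 21, 7, 6, 16, 14, 30, 30, 50, 14)
    pollination_failure_rate: float = 0.29
    si_leakage_rate: float = 0.09
    untypable_labels: frozenset[str] = frozenset()
    replicate_count: int = 1
    seed: int = 20_131_223

    def validate(self) -> None:
        if self.n_haplotypes < 2:
            raise SimulationError("need at least 2 haplotypes")
        for rate in (
            self.paired_fraction,
            self.class_a_fraction,
            self.homozygote_probability,
            self.pollination_failure_rate,
            self.si_leakage_rate,
        ):
            if not 0 <= rate <= 1:
                raise SimulationError(f"rate {rate} outside [0, 1]")
        if self.shared_label and self.n_haplotypes < 4:
            raise SimulationError("a shared label needs >= 4 haplotypes to stay identifiable")
        for organ, spec in self.dominance_spec.items():
            if organ not in ORGANS or spec not in DOMINANCE_SPECS:
                raise SimulationError(f"bad dominance spec {organ}={spec}")


@dataclass
class GroundTruth:
    """Everything the generator knows: catalog, genotypes, dominance and the
    latent compatibility of any cross follows from these."""

    catalog: HaplotypeCatalog
    genotypes: dict[str, DiploidGenotype]
    hap_class: dict[str, str]
    dominance_order: dict[str, tuple[str, ...]]  # per organ; empty = codominant
    dominance_kind: dict[str, str]
    config: SimulationConfig

    def expressed(self, genotype_of: str | frozenset[str], organ: str) -> frozenset[str]:
        """Expressed haplotypes of an individual's (or raw genotype's)
        diploid genotype in the given organ."""
        if isinstance(genotype_of, str):
            g = self.genotypes[genotype_of]
            haps = {g.h1, g.h2}
        else:
            haps = set(genotype_of)
        if len(haps) == 1:
            return frozenset(haps)
        kind = self.dominance_kind[organ]
        if kind == "codominant":
            return frozenset(haps)
        if kind == "linear":
            order = self.dominance_order[organ]
            winner = min(haps, key=order.index)
            return frozenset((winner,))
        # class_levels: class A dominates class B; within a class codominant
        ranks = {h: (0 if self.hap_class[h] == "A" else 1) for h in haps}
        best = min(ranks.values())
        return frozenset(h for h in haps if ranks[h] == best)

    def latent_compatible(self, donor: str, receptor: str) -> bool:
        return not (self.expressed(donor, "pollen") & self.expressed(receptor, "stigma"))

    def expression_state(self, genotype: frozenset[str], organ: str, hap: str) -> str:
        return "expressed" if hap in self.expressed(genotype, organ) else "silenced"


def simulate_locus(config: SimulationConfig, rng: np.random.Generator | None = None) -> GroundTruth:
    """Build the haplotype catalog, assign classes and labels, sample diploid
    genotypes (every haplotype is carried at least once) and instantiate the
    per-organ dominance model."""
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)

    n = config.n_haplotypes
    n_paired = int(round(config.paired_fraction * n))
    n_class_a = int(round(config.class_a_fraction * n))
    classes = ["A"] * n_class_a + ["B"] * (n - n_class_a)
    rng.shuffle(classes)
    paired = [False] * n
    for idx in rng.choice(n, size=n_paired, replace=False):
        paired[idx] = True

    counters = {"A": 0, "B": 0}
    label_sets: list[tuple[str, ...]] = []
    for i in range(n):
        k = 2 if paired[i] else 1
        prefix = classes[i]
        labels = []
        for _ in range(k):
            counters[prefix] += 1
            labels.append(f"{prefix}{counters[prefix]:02d}")
        label_sets.append(tuple(labels))

    if config.shared_label:
        # one label shared between two paired haplotypes of the same class
        by_class: dict[str, list[int]] = {}
        for i in range(n):
            if paired[i]:
                by_class.setdefault(classes[i], []).append(i)
        candidates = [idxs for idxs in by_class.values() if len(idxs) >= 2]
        if not candidates:
            raise SimulationError("shared_label requires two paired haplotypes of one class")
        idxs = candidates[int(rng.integers(len(candidates)))]
        i, j = idxs[0], idxs[1]
        label_sets[j] = (label_sets[i][0], label_sets[j][1])

    haplotypes = []
    hap_class = {}
    for i, labels in enumerate(label_sets):
        hid = f"G{i + 1:02d}"
        support = SUPPORT_COSEGREGATION if len(labels) == 2 else SUPPORT_SINGLETON
        haplotypes.append(Haplotype(hid, frozenset(labels), support))
        hap_class[hid] = classes[i]
    catalog = HaplotypeCatalog(haplotypes)
    hap_ids = [h.haplotype_id for h in haplotypes]

    genotypes: dict[str, DiploidGenotype] = {}
    for i in range(config.n_individuals):
        ind = str(i + 1)
        if i < n:
            # coverage pass: every haplotype carried at least once
            first = hap_ids[i]
        else:
            first = hap_ids[int(rng.integers(n))]
        if rng.random() < config.homozygote_probability:
            genotypes[ind] = DiploidGenotype(ind, first, first, STATUS_PUTATIVE_HOM)
        else:
            others = [h for h in hap_ids if h != first]
            second = others[int(rng.integers(len(others)))]
            a, b = sorted((first, second))
            genotypes[ind] = DiploidGenotype(ind, a, b, STATUS_HET)

    dominance_order = {}
    dominance_kind = {}
    for organ in ORGANS:
        kind = config.dominance_spec.get(organ, "codominant")
        dominance_kind[organ] = kind
        if kind == "linear":
            order = list(hap_ids)
            rng.shuffle(order)
            dominance_order[organ] = tuple(order)
        else:
            dominance_order[organ] = ()

    return GroundTruth(
        catalog=catalog,
        genotypes=genotypes,
        hap_class=hap_class,
        dominance_order=dominance_order,
        dominance_kind=dominance_kind,
        config=config,
    )


def simulate_cross(
    donor: str,
    receptor: str,
    truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[CrossOutcome]:
    """Replicated pollinations of one ordered pair: fruit with probability
    (1 - failure) when latently compatible, with probability leakage when
    incompatible. Returns one outcome row per result observed."""
    compatible = truth.latent_compatible(donor, receptor)
    p_fruit = (1 - config.pollination_failure_rate) if compatible else config.si_leakage_rate
    fruits = int(rng.binomial(config.replicate_count, p_fruit))
    out = []
    if fruits:
        out.append(CrossOutcome(donor, receptor, "fruit", fruits))
    if config.replicate_count - fruits:
        out.append(CrossOutcome(donor, receptor, "no_fruit", config.replicate_count - fruits))
    return out


def simulate_cohort(
    parent1: str,
    parent2: str,
    n: int,
    truth: GroundTruth,
    rng: np.random.Generator,
    cohort_id: str = "",
    untypable: frozenset[str] | None = None,
) -> tuple[CohortObservation, list[tuple[str, str]]]:
    """Mendelian full-sib cohort: each offspring receives one haplotype per
    parent with probability 0.5; the observed combination is the union of
    the typable labels. Also returns the latent transmitted haplotypes."""
    if n < 1:
        raise SimulationError("cohort size must be >= 1")
    untypable = untypable if untypable is not None else truth.config.untypable_labels
    g1 = truth.genotypes[parent1]
    g2 = truth.genotypes[parent2]
    transmissions = []
    counts: dict[frozenset[str], int] = {}
    for _ in range(n):
        h1 = g1.h1 if rng.random() < 0.5 else g1.h2
        h2 = g2.h1 if rng.random() < 0.5 else g2.h2
        transmissions.append((h1, h2))
        combo = (
            truth.catalog.typable_labels(h1, untypable)
            | truth.catalog.typable_labels(h2, untypable)
        )
        counts[combo] = counts.get(combo, 0) + 1
    cohort = CohortObservation(
        cohort_id=cohort_id or f"{parent1}x{parent2}",
        parent1_id=parent1,
        parent2_id=parent2,
        n=n,
        offspring_counts=counts,
        collection="sim",
    )
    return cohort, transmissions


@dataclass
class SyntheticDataset:
    """A fully emitted dataset plus its generating truth."""

    truth: GroundTruth
    presence: PresenceMatrix
    cohorts: list[CohortObservation]
    crosses: list[CrossOutcome]
    transmissions: dict[str, list[tuple[str, str]]]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "presence": outdir / "presence.csv",
            "cohorts": outdir / "cohorts.csv",
            "crosses": outdir / "crosses.csv",
            "truth": outdir / "truth.json",
        }
        write_presence_matrix(self.presence, paths["presence"])
        write_cohorts(self.cohorts, paths["cohorts"])
        write_crosses(self.crosses, paths["crosses"])
        truth = self.truth
        record = {
            "catalog": {h.haplotype_id: sorted(h.labels) for h in truth.catalog},
            "genotypes": {
                ind: [g.h1, g.h2, g.status] for ind, g in sorted(truth.genotypes.items())
            },
            "hap_class": truth.hap_class,
            "dominance_kind": truth.dominance_kind,
            "dominance_order": {k: list(v) for k, v in truth.dominance_order.items()},
            "seed": truth.config.seed,
        }
        paths["truth"].write_text(json.dumps(record, indent=1), encoding="utf-8")
        return paths


def emit_dataset(
    truth: GroundTruth,
    config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
    cohort_pairs: Sequence[tuple[str, str]] | None = None,
    diallel: bool = True,
) -> SyntheticDataset:
    """Emit the observable layers of a simulated study.

    The parental presence matrix shows *all* labels (untypable labels are
    masked only in cohort observations, mirroring progeny typing). Cohorts
    default to pairing every individual once with a random distinct
    partner, cycling through ``config.cohort_sizes``; the cross matrix is a
    full ordered diallel including self-pollinations.
    """
    config = config if config is not None else truth.config
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    individuals = sorted(truth.genotypes, key=lambda x: (len(x), x))

    presence = PresenceMatrix(
        {
            ind: truth.catalog[g.h1].labels | truth.catalog[g.h2].labels
            for ind, g in truth.genotypes.items()
        },
        individuals,
    )

    if cohort_pairs is None:
        cohort_pairs = []
        for ind in individuals:
            partners = [x for x in individuals if x != ind]
            cohort_pairs.append((ind, partners[int(rng.integers(len(partners)))]))
    cohorts = []
    transmissions = {}
    sizes = config.cohort_sizes or (30,)
    for k, (p1, p2) in enumerate(cohort_pairs):
        n = sizes[k % len(sizes)]
        cohort, trans = simulate_cohort(
            p1, p2, n, truth, rng, cohort_id=f"c{k + 1:02d}", untypable=config.untypable_labels
        )
        cohorts.append(cohort)
        transmissions[cohort.cohort_id] = trans

    crosses: list[CrossOutcome] = []
    if diallel:
        for donor in individuals:
            for receptor in individuals:
                crosses.extend(simulate_cross(donor, receptor, truth, config, rng))

    return SyntheticDataset(truth, presence, cohorts, crosses, transmissions)


def paper_preset() -> SimulationConfig:
    """Configuration mirroring the study design the pipeline was built for:
    13 haplotypes (8 with linked label pairs, one shared label), 21
    individuals with two homozygotes expected, the observed cohort sizes,
    29% pollination failure and 9% SI leakage."""
    return SimulationConfig(shared_label=True)


def config_from_mapping(raw: Mapping[str, str]) -> SimulationConfig:
    """Build a config from flat key=value strings (see data_io.read_config)."""
    kwargs: dict = {}
    fields = {f.name: f for f in SimulationConfig.__dataclass_fields__.values()}
    for key, value in raw.items():
        if key not in fields:
            raise SimulationError(f"unknown config key {key!r}")
        if key == "dominance_spec":
            kwargs[key] = dict(
                part.split(":") for part in value.split(",") if part
            )
        elif key == "cohort_sizes":
            kwargs[key] = tuple(int(x) for x in value.split(",") if x)
        elif key == "untypable_labels":
            kwargs[key] = frozenset(x for x in value.split(",") if x)
        elif key == "shared_label":
            kwargs[key] = value.lower() in ("1", "true", "yes")
        elif key in ("n_haplotypes", "n_individuals", "replicate_count", "seed"):
            kwargs[key] = int(value)
        else:
            kwargs[key] = float(value)
    return SimulationConfig(**kwargs)
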