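"""Monte-Carlo test of Mendelian segregation in offspring cohorts.

At the S-locus a cross between two heterozygotes S1S2 x S3S4 produces the
four offspring genotypes S1S3, S1S4, S2S3, S2S4 at expected frequency 0.25
each (case 1); a homozygote x heterozygote cross S1S1 x S3S4 produces S1S3
and S1S4 at 0.5 each (case 2, considered only when at most two genotype
classes are observed in the sibship). For the observed cohort size n the
null distribution of class counts is obtained by simulating multinomial
cohorts; each class is tested with a one-sided empirical tail probability
in the direction of its observed deviation, with an add-one correction
p = (1 + #{simulated counts as or more extreme}) / (reps + 1).

No multiple-testing correction is applied across classes or cohorts; the
significance threshold defaults to alpha = 0.05.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import CohortObservation, DataError
from .phasing import DiploidGenotype, HaplotypeCatalog

CASE1 = "case1_het_x_het"
CASE2 = "case2_hom_x_het"

#: default number of simulated cohorts per test
DEFAULT_REPS = 100_000
#: fixed documented seed so that reported results are reproducible by default
DEFAULT_SEED = 20_131_223
DEFAULT_ALPHA = 0.05


class UnsupportedCaseError(ValueError):
    """Raised for cross designs outside the two supported segregation cases."""


@dataclass(frozen=True)
class SegregationCase:
    """Mendelian expectation for a cohort: k equiprobable genotype classes."""

    case_id: str
    expected_classes: int
    expected_freq: float

    def __post_init__(self) -> None:
        if abs(self.expected_classes * self.expected_freq - 1.0) > 1e-9:
            raise ValueError("class frequencies must sum to 1")


CASE1_SPEC = SegregationCase(CASE1, 4, 0.25)
CASE2_SPEC = SegregationCase(CASE2, 2, 0.5)


@dataclass
class SegregationResult:
    """Per-cohort test outcome.

    ``conforms`` is true iff no expected class deviates at ``alpha`` and no
    unexpected genotype class was observed.
    """

    cohort_id: str
    case_id: str
    n: int
    observed: tuple[int, ...]
    per_class_p: tuple[float, ...]
    flagged_classes: tuple[int, ...]
    extra_count: int
    conforms: bool
    reps: int
    seed: int
    alpha: float
    class_labels: tuple[str, ...] = ()


def classify_case(
    cohort: CohortObservation,
    genotypes: Mapping[str, DiploidGenotype],
) -> SegregationCase:
    """Classify a cohort as case 1 (het x het) or case 2 (hom x het).

    Case 2 requires one homozygous parent (putative or confirmed) *and* at
    most two observed genotype classes; otherwise the cohort falls back to
    case 1. Two homozygous parents are outside the supported scheme.
    """
    try:
        g1 = genotypes[cohort.parent1_id]
        g2 = genotypes[cohort.parent2_id]
    except KeyError as exc:
        raise DataError(f"cohort {cohort.cohort_id}: ungenotyped parent {exc}") from None
    homs = sum(g.is_homozygote for g in (g1, g2))
    if homs == 2:
        raise UnsupportedCaseError(
            f"cohort {cohort.cohort_id}: both parents homozygous is outside the "
            "supported segregation scheme"
        )
    if homs == 1 and len(cohort.offspring_counts) <= 2:
        return CASE2_SPEC
    return CASE1_SPEC


def simulate_null(
    n: int,
    case: SegregationCase,
    reps: int = DEFAULT_REPS,
    seed: int | np.random.Generator = DEFAULT_SEED,
) -> np.ndarray:
    """Simulated class counts under the Mendelian null: shape (reps, k)."""
    if n < 1 or reps < 1:
        raise ValueError("n and reps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    probs = np.full(case.expected_classes, case.expected_freq)
    return rng.multinomial(n, probs, size=reps)


def empirical_tail_p(column: np.ndarray, count: int, expected: float) -> float:
    """Add-one empirical tail probability of one class count, one-sided in
    the direction of the observed deviation (upper tail at the expectation)."""
    reps = len(column)
    if count >= expected:
        as_extreme = int(np.count_nonzero(column >= count))
    else:
        as_extreme = int(np.count_nonzero(column <= count))
    return (1 + as_extreme) / (reps + 1)


def test_cohort(
    observed: Sequence[int],
    case: SegregationCase,
    extra_count: int = 0,
    reps: int = DEFAULT_REPS,
    alpha: float = DEFAULT_ALPHA,
    seed: int | np.random.Generator = DEFAULT_SEED,
    cohort_id: str = "",
    class_labels: Sequence[str] = (),
) -> SegregationResult:
    """Test observed class counts against the Mendelian expectation.

    ``observed`` lists counts for the expected classes (shorter sequences
    are padded with zeros: unobserved expected classes are tested like any
    other, in the lower tail). ``extra_count`` is the number of offspring in
    genotype classes outside the expectation; any such offspring makes the
    cohort non-conforming (for case 2 this is the test of the "more than
    two progeny genotypes" alternative, rejected when the count is zero).
    """
    counts = list(observed)
    if len(counts) > case.expected_classes:
        raise DataError(
            f"{len(counts)} observed classes exceed the {case.expected_classes} expected"
        )
    counts += [0] * (case.expected_classes - len(counts))
    if extra_count < 0 or any(c < 0 for c in counts):
        raise DataError("negative counts")
    n = sum(counts) + extra_count
    if n < 1:
        raise DataError("empty cohort")

    sims = simulate_null(n, case, reps=reps, seed=seed)
    expected = n * case.expected_freq
    p_values = [
        empirical_tail_p(sims[:, i], count, expected) for i, count in enumerate(counts)
    ]
    flagged = tuple(i for i, p in enumerate(p_values) if p < alpha)
    conforms = not flagged and extra_count == 0
    return SegregationResult(
        cohort_id=cohort_id,
        case_id=case.case_id,
        n=n,
        observed=tuple(counts),
        per_class_p=tuple(p_values),
        flagged_classes=flagged,
        extra_count=extra_count,
        conforms=conforms,
        reps=reps,
        seed=seed if isinstance(seed, int) else -1,
        alpha=alpha,
        class_labels=tuple(class_labels),
    )


def expected_offspring_classes(
    g1: DiploidGenotype,
    g2: DiploidGenotype,
    catalog: HaplotypeCatalog,
    untypable: frozenset[str] = frozenset(),
) -> list[tuple[frozenset[str], str]]:
    """Expected offspring label combinations for a parent pair.

    Returns ``(typable label set, 'hapA x hapB')`` per expected genotype
    class, deduplicated on the genotype (a homozygous parent contributes
    one transmissible haplotype). Raises when two distinct expected classes
    are indistinguishable after removing untypable labels (the cohort would
    be uninformative for the test).
    """
    h1s = sorted({g1.h1, g1.h2})
    h2s = sorted({g2.h1, g2.h2})
    classes = []
    seen: dict[frozenset[str], str] = {}
    for a, b in itertools.product(h1s, h2s):
        combo = catalog.typable_labels(a, untypable) | catalog.typable_labels(b, untypable)
        desc = f"{a} x {b}"
        if combo in seen:
            raise DataError(
                f"expected classes {seen[combo]} and {desc} are indistinguishable "
                "after removing untypable labels"
            )
        seen[combo] = desc
        classes.append((combo, desc))
    return classes


def batch_test(
    cohorts: Sequence[CohortObservation],
    genotypes: Sequence[DiploidGenotype] | Mapping[str, DiploidGenotype],
    catalog: HaplotypeCatalog,
    untypable: frozenset[str] = frozenset(),
    reps: int = DEFAULT_REPS,
    alpha: float = DEFAULT_ALPHA,
    seed: int = DEFAULT_SEED,
) -> tuple[pd.DataFrame, list[SegregationResult]]:
    """Classify and test every cohort; deterministic given ``seed``.

    Observed label combinations are mapped onto the expected genotype
    classes; combinations matching no expected class count as unexpected
    genotypes. Returns a tidy summary table plus the full per-cohort results.
    """
    if not isinstance(genotypes, Mapping):
        genotypes = {g.individual_id: g for g in genotypes}
    streams = np.random.SeedSequence(seed).spawn(max(len(cohorts), 1))
    results = []
    rows = []
    for cohort, stream in zip(cohorts, streams):
        case = classify_case(cohort, genotypes)
        classes = expected_offspring_classes(
            genotypes[cohort.parent1_id],
            genotypes[cohort.parent2_id],
            catalog,
            untypable,
        )
        if case.case_id == CASE2:
            # keep only the classes actually producible: hom parent fixed
            combos = {combo: desc for combo, desc in classes}
            if len(combos) > case.expected_classes:
                # het x het parents demoted to case 2 cannot happen by
                # construction (classify_case requires a homozygous parent)
                raise DataError(f"cohort {cohort.cohort_id}: too many expected classes")
        counts = []
        labels = []
        mapped: set[frozenset[str]] = set()
        for combo, desc in classes:
            counts.append(cohort.offspring_counts.get(combo, 0))
            labels.append(desc)
            mapped.add(combo)
        extra = sum(
            count
            for combo, count in cohort.offspring_counts.items()
            if combo not in mapped
        )
        result = test_cohort(
            counts,
            case,
            extra_count=extra,
            reps=reps,
            alpha=alpha,
            seed=np.random.default_rng(stream),
            cohort_id=cohort.cohort_id,
            class_labels=labels,
        )
        result.seed = seed
        results.append(result)
        rows.append(
            {
                "cohort_id": cohort.cohort_id,
                "parent1": cohort.parent1_id,
                "parent2": cohort.parent2_id,
                "case": case.case_id,
                "n": result.n,
                "observed": "/".join(map(str, result.observed)),
                "classes": "; ".join(labels),
                "per_class_p": "/".join(f"{p:.5f}" for p in result.per_class_p),
                "flagged_classes": "; ".join(labels[i] for i in result.flagged_classes),
                "n_flagged": len(result.flagged_classes),
                "extra_count": result.extra_count,
                "conforms": result.conforms,
            }
        )
    columns = [
        "cohort_id", "parent1", "parent2", "case", "n", "observed", "classes",
        "per_class_p", "flagged_classes", "n_flagged", "extra_count", "conforms",
    ]
    return pd.DataFrame(rows, columns=columns), results
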