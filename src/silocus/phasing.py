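"""S-haplotype phasing from co-transmission in full-sib cohorts.

Diploid individuals carry two S-haplotypes, each composed of one or two
tightly linked sequence labels. The phasing procedure works in three steps:

1. For each parent of each cohort, build one boolean *transmission vector*
   per typable parental label over the cohort's observed offspring label
   combinations. A label is attributable to a parent only when the other
   parent does not carry it; labels carried by both parents are
   uninformative in that cohort.
2. Labels with identical transmission vectors co-segregate and belong to
   the same haplotype; a label transmitted to *every* offspring while the
   remaining labels split into two complementary groups is shared by both
   of the parent's haplotypes.
3. Pairs never tested in a cohort may still be linked by perfect
   association in the parental panel (every individual carries either both
   or neither, and they co-occur at least once); such pairs are reported
   with the lower support tier ``f0_association_only``.

The resulting catalog (sets of 1-2 labels per haplotype) is then used to
assign a diploid genotype to every individual; individuals whose labels are
explained by a single haplotype are flagged as putative homozygotes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .data_io import CohortObservation, PresenceMatrix

SUPPORT_COSEGREGATION = "cosegregation"
SUPPORT_F0_ASSOCIATION = "f0_association_only"
SUPPORT_SINGLETON = "singleton"

STATUS_HET = "heterozygous"
STATUS_PUTATIVE_HOM = "putative_homozygote"
STATUS_CONFIRMED_HOM = "confirmed_homozygote"


class PhasingError(ValueError):
    """Raised when segregation evidence is contradictory or insufficient."""


@dataclass(frozen=True)
class Haplotype:
    """An S-haplotype: 1-2 linked sequence labels plus its evidence tier.

    ``support`` is ``cosegregation`` when some cohort co-transmits the pair,
    ``f0_association_only`` when the pair rests on perfect association in
    the parental panel, and ``singleton`` for one-label haplotypes (no
    linkage claim to support). A label may belong to two haplotypes when it
    is shared between them (the two haplotypes still confer distinct
    incompatibility specificities).
    """

    haplotype_id: str
    labels: frozenset[str]
    support: str

    def __post_init__(self) -> None:
        if not 1 <= len(self.labels) <= 2:
            raise PhasingError(f"haplotype must carry 1-2 labels, got {sorted(self.labels)}")


class HaplotypeCatalog:
    """Ordered collection of haplotypes with lookup by id and label set."""

    def __init__(self, haplotypes: Sequence[Haplotype]) -> None:
        self.haplotypes: tuple[Haplotype, ...] = tuple(haplotypes)
        self._by_id = {h.haplotype_id: h for h in self.haplotypes}
        if len(self._by_id) != len(self.haplotypes):
            raise PhasingError("duplicate haplotype IDs")
        self._by_labels = {h.labels: h for h in self.haplotypes}

    def __len__(self) -> int:
        return len(self.haplotypes)

    def __iter__(self):
        return iter(self.haplotypes)

    def __getitem__(self, haplotype_id: str) -> Haplotype:
        return self._by_id[haplotype_id]

    def by_labels(self, labels: Iterable[str]) -> Haplotype:
        return self._by_labels[frozenset(labels)]

    @property
    def label_sets(self) -> set[frozenset[str]]:
        return set(self._by_labels)

    @property
    def labels(self) -> set[str]:
        out: set[str] = set()
        for h in self.haplotypes:
            out |= h.labels
        return out

    def typable_labels(self, haplotype_id: str, untypable: frozenset[str]) -> frozenset[str]:
        return self._by_id[haplotype_id].labels - untypable


@dataclass(frozen=True)
class DiploidGenotype:
    """An individual's unordered pair of haplotype IDs and homozygosity call."""

    individual_id: str
    h1: str
    h2: str
    status: str = STATUS_HET

    def __post_init__(self) -> None:
        if self.h1 == self.h2 and self.status == STATUS_HET:
            raise PhasingError(
                f"{self.individual_id}: identical haplotypes require a homozygote status"
            )

    @property
    def haplotypes(self) -> frozenset[str]:
        return frozenset((self.h1, self.h2))

    @property
    def is_homozygote(self) -> bool:
        return self.status in (STATUS_PUTATIVE_HOM, STATUS_CONFIRMED_HOM)


@dataclass(frozen=True)
class TransmissionVector:
    """Boolean transmission pattern of one parental label over a cohort's
    observed offspring combinations (``classes`` fixes the column order)."""

    parent_id: str
    cohort_id: str
    label: str
    pattern: tuple[bool, ...]
    classes: tuple[frozenset[str], ...]


@dataclass
class ClusterResult:
    """Partition of one parent's informative labels into haplotype groups."""

    parent_id: str
    cohort_id: str
    groups: tuple[frozenset[str], ...]
    shared_labels: frozenset[str]
    consistent: bool
    all_cotransmitted: bool
    note: str = ""


@dataclass(frozen=True)
class LinkedPair:
    labels: frozenset[str]
    support: str
    cohorts: tuple[str, ...] = ()


@dataclass(frozen=True)
class AmbiguousLinkage:
    """A singleton label whose linkage state the data cannot determine.

    Every carrier of ``singleton`` also carries ``paired_label`` (a member
    of an inferred linked pair) and no cohort ever separated the two, so a
    catalog in which ``paired_label`` is shared by a second haplotype
    ``{paired_label, singleton}`` explains the observations equally well.
    """

    singleton: str
    paired_label: str


@dataclass
class LinkageResult:
    pairs: dict[frozenset[str], LinkedPair]
    inconsistencies: list[ClusterResult] = field(default_factory=list)
    ambiguities: list[AmbiguousLinkage] = field(default_factory=list)


def _ordered_classes(cohort: CohortObservation) -> tuple[frozenset[str], ...]:
    return tuple(sorted(cohort.offspring_counts, key=sorted))


def transmission_vectors(
    cohort: CohortObservation,
    parent_id: str,
    presence: PresenceMatrix,
    untypable: frozenset[str] = frozenset(),
) -> list[TransmissionVector]:
    """One transmission vector per informative parental label.

    A label is informative when the parent carries it, it is typable in
    progeny, and the other parent does not carry it (otherwise the parental
    origin of the label in an offspring would be ambiguous).
    """
    if parent_id not in cohort.parents:
        raise PhasingError(f"{parent_id!r} is not a parent of cohort {cohort.cohort_id}")
    other = cohort.parent2_id if parent_id == cohort.parent1_id else cohort.parent1_id
    own = presence.labels_of(parent_id) - untypable
    informative = own - presence.labels_of(other)
    if not informative:
        raise PhasingError(
            f"cohort {cohort.cohort_id}: no informative labels for parent {parent_id!r}"
        )
    classes = _ordered_classes(cohort)
    return [
        TransmissionVector(
            parent_id=parent_id,
            cohort_id=cohort.cohort_id,
            label=label,
            pattern=tuple(label in combo for combo in classes),
            classes=classes,
        )
        for label in sorted(informative)
    ]


def cluster_cotransmitted(vectors: Sequence[TransmissionVector]) -> ClusterResult:
    """Group a parent's labels by identical transmission pattern.

    Labels transmitted to every offspring class are either shared between
    the parent's two haplotypes or the parent is homozygous; when the
    remaining labels split into exactly two complementary groups, the
    always-transmitted labels are attached to both groups (the shared-label
    case). More than two distinct non-trivial patterns violates diploidy
    and flags the cohort as inconsistent instead of forcing a partition.
    """
    if not vectors:
        raise PhasingError("no transmission vectors to cluster")
    parent_id = vectors[0].parent_id
    cohort_id = vectors[0].cohort_id
    n_classes = len(vectors[0].pattern)

    by_pattern: dict[tuple[bool, ...], set[str]] = {}
    for vec in vectors:
        by_pattern.setdefault(vec.pattern, set()).add(vec.label)

    all_true = tuple(True for _ in range(n_classes))
    shared = frozenset(by_pattern.pop(all_true, set()))
    groups = [frozenset(labels) for _, labels in sorted(by_pattern.items())]

    if len(groups) == 0:
        # every label always transmitted: single group, parent possibly homozygous
        return ClusterResult(
            parent_id, cohort_id, (shared,), frozenset(), True, True
        )
    if len(groups) == 1:
        merged = (groups[0] | shared, shared) if shared else (groups[0],)
        return ClusterResult(parent_id, cohort_id, merged, shared, True, False)
    if len(groups) == 2:
        pat1 = next(p for p, labs in by_pattern.items() if labs == set(groups[0]))
        pat2 = next(p for p, labs in by_pattern.items() if labs == set(groups[1]))
        complementary = all(a != b for a, b in zip(pat1, pat2))
        if not complementary:
            return ClusterResult(
                parent_id,
                cohort_id,
                tuple(groups),
                shared,
                False,
                False,
                note="two groups with non-complementary transmission patterns",
            )
        return ClusterResult(
            parent_id,
            cohort_id,
            (groups[0] | shared, groups[1] | shared),
            shared,
            True,
            False,
        )
    return ClusterResult(
        parent_id,
        cohort_id,
        tuple(groups),
        shared,
        False,
        False,
        note=f"{len(groups)} distinct transmission patterns (diploid violation)",
    )


def _pairs_within(group: frozenset[str]) -> Iterable[frozenset[str]]:
    for a, b in itertools.combinations(sorted(group), 2):
        yield frozenset((a, b))


def infer_linked_pairs(
    presence: PresenceMatrix,
    cohorts: Sequence[CohortObservation] = (),
    untypable: frozenset[str] = frozenset(),
) -> LinkageResult:
    """Infer linked label pairs from cohort co-transmission plus parental-panel
    association.

    Raises :class:`PhasingError` when a pair is co-clustered in one cohort
    but separated in another (the error message names both cohorts).
    Inconsistent single-cohort clusterings are collected, not raised.
    """
    coseg: dict[frozenset[str], set[str]] = {}
    separated: dict[frozenset[str], set[str]] = {}
    inconsistencies: list[ClusterResult] = []

    for cohort in cohorts:
        for parent in cohort.parents:
            own = presence.labels_of(parent) - untypable
            other = cohort.parent2_id if parent == cohort.parent1_id else cohort.parent1_id
            if not (own - presence.labels_of(other)):
                continue  # nothing informative for this parent here
            vectors = transmission_vectors(cohort, parent, presence, untypable)
            result = cluster_cotransmitted(vectors)
            if not result.consistent:
                inconsistencies.append(result)
                continue
            for group in result.groups:
                for pair in _pairs_within(group):
                    coseg.setdefault(pair, set()).add(cohort.cohort_id)
            for g1, g2 in itertools.combinations(result.groups, 2):
                for a in g1 - g2:
                    for b in g2 - g1:
                        separated.setdefault(frozenset((a, b)), set()).add(cohort.cohort_id)

    contradictions = set(coseg) & set(separated)
    if contradictions:
        msgs = [
            f"{sorted(pair)}: co-transmitted in {sorted(coseg[pair])}, "
            f"separated in {sorted(separated[pair])}"
            for pair in sorted(contradictions, key=sorted)
        ]
        raise PhasingError("contradictory linkage evidence: " + "; ".join(msgs))

    pairs: dict[frozenset[str], LinkedPair] = {
        pair: LinkedPair(pair, SUPPORT_COSEGREGATION, tuple(sorted(cids)))
        for pair, cids in coseg.items()
    }

    # perfect association across the parental panel for untested pairs
    labels = presence.labels
    carriers = {label: presence.carriers(label) for label in labels}
    for a, b in itertools.combinations(labels, 2):
        pair = frozenset((a, b))
        if pair in pairs or pair in separated:
            continue
        if carriers[a] and carriers[a] == carriers[b]:
            pairs[pair] = LinkedPair(pair, SUPPORT_F0_ASSOCIATION, ())

    # shared-label ambiguity: a typable singleton z always co-carried with a
    # pair member x, never separated from it in a cohort, is equally
    # explained by a second x-sharing haplotype {x, z}. Untypable candidates
    # are exempt (no cohort could ever resolve them; the singleton call is
    # the parsimonious convention there).
    paired_labels: set[str] = set()
    for pair in pairs:
        paired_labels |= pair
    ambiguities = []
    for z in labels:
        if z in paired_labels or z in untypable:
            continue
        for x in sorted(paired_labels - untypable):
            pair = frozenset((x, z))
            if pair in separated or pair in pairs:
                continue
            if carriers[z] and carriers[z] <= carriers[x]:
                ambiguities.append(AmbiguousLinkage(z, x))

    return LinkageResult(pairs=pairs, inconsistencies=inconsistencies, ambiguities=ambiguities)


def build_catalog(
    linkage: LinkageResult | Mapping[frozenset[str], LinkedPair],
    presence: PresenceMatrix,
    class_map: Mapping[str, str] | None = None,
    name_map: Mapping[frozenset[str], str] | None = None,
) -> HaplotypeCatalog:
    """Build the haplotype catalog: every linked pair becomes a two-label
    haplotype, every unpaired label a singleton haplotype.

    Haplotype IDs are assigned deterministically, sorted by (class tag of
    the first label, sorted label names); ``name_map`` can impose external
    names (e.g. an S01-S13 nomenclature) keyed by the haplotype's label set.
    """
    pairs = linkage.pairs if isinstance(linkage, LinkageResult) else dict(linkage)
    class_map = dict(class_map or {})
    paired_labels: set[str] = set()
    for pair in pairs:
        paired_labels |= pair
    label_sets = sorted(pairs, key=sorted)
    label_sets += [frozenset((lab,)) for lab in presence.labels if lab not in paired_labels]

    def sort_key(labels: frozenset[str]) -> tuple:
        first = min(labels)
        return (class_map.get(first, "other"), sorted(labels))

    label_sets.sort(key=sort_key)
    haplotypes = []
    for i, labels in enumerate(label_sets, start=1):
        if name_map and labels in name_map:
            hid = name_map[labels]
        else:
            hid = f"H{i:02d}"
        if len(labels) == 2:
            support = pairs[labels].support
        else:
            support = SUPPORT_SINGLETON
        haplotypes.append(Haplotype(hid, labels, support))
    return HaplotypeCatalog(haplotypes)


def _covers(labels: frozenset[str], catalog: HaplotypeCatalog) -> list[tuple[Haplotype, Haplotype]]:
    """All unordered haplotype pairs (h1 <= h2, possibly equal) whose label
    union equals ``labels``."""
    candidates = [h for h in catalog if h.labels <= labels]
    covers = []
    for h1, h2 in itertools.combinations_with_replacement(candidates, 2):
        if h1.labels | h2.labels == labels:
            covers.append((h1, h2))
    return covers


def assign_genotypes(
    presence: PresenceMatrix,
    catalog: HaplotypeCatalog,
    cohorts: Sequence[CohortObservation] = (),
) -> list[DiploidGenotype]:
    """Explain every individual's label set by exactly one or two catalog
    haplotypes.

    A single-haplotype cover is reported as a putative homozygote, upgraded
    to confirmed when the individual parents a cohort showing at most two
    offspring genotype classes (the hom x het structure; the statistical
    confirmation is the segregation module's test). When a label belongs to
    several haplotypes, the combination is disambiguated by which partner
    labels are present; a residual ambiguity raises rather than guessing.
    """
    genotypes: list[DiploidGenotype] = []
    parented: dict[str, list[CohortObservation]] = {}
    for cohort in cohorts:
        for parent in cohort.parents:
            parented.setdefault(parent, []).append(cohort)

    for ind in presence.individuals:
        labels = presence.labels_of(ind)
        covers = _covers(labels, catalog)
        het = [(h1, h2) for h1, h2 in covers if h1.haplotype_id != h2.haplotype_id]
        hom = sorted({h1.haplotype_id for h1, h2 in covers if h1.haplotype_id == h2.haplotype_id})
        if het:
            if len(het) > 1:
                options = [
                    f"{h1.haplotype_id}/{h2.haplotype_id}" for h1, h2 in het
                ]
                raise PhasingError(
                    f"individual {ind!r}: ambiguous genotype, label set "
                    f"{sorted(labels)} coverable as {options}"
                )
            h1, h2 = het[0]
            ids = sorted((h1.haplotype_id, h2.haplotype_id))
            genotypes.append(DiploidGenotype(ind, ids[0], ids[1], STATUS_HET))
        elif hom:
            hid = hom[0]
            status = STATUS_PUTATIVE_HOM
            for cohort in parented.get(ind, []):
                if len(cohort.offspring_counts) <= 2:
                    status = STATUS_CONFIRMED_HOM
                    break
            genotypes.append(DiploidGenotype(ind, hid, hid, status))
        else:
            raise PhasingError(
                f"individual {ind!r}: label set {sorted(labels)} not coverable "
                "by <=2 catalog haplotypes"
            )
    return genotypes


def phase_dataset(
    presence: PresenceMatrix,
    cohorts: Sequence[CohortObservation] = (),
    untypable: frozenset[str] = frozenset(),
    variant_merge_map: Mapping[str, str] | None = None,
    class_map: Mapping[str, str] | None = None,
    name_map: Mapping[frozenset[str], str] | None = None,
    strict_ambiguity: bool = True,
) -> tuple[HaplotypeCatalog, list[DiploidGenotype], LinkageResult]:
    """Convenience wrapper: merge variants, infer pairs, build the catalog
    and assign all genotypes.

    With ``strict_ambiguity`` (default) an unresolvable shared-label
    ambiguity raises instead of committing to the singleton catalog.
    """
    if variant_merge_map:
        presence = presence.merged(variant_merge_map)
    linkage = infer_linked_pairs(presence, cohorts, untypable)
    if strict_ambiguity and linkage.ambiguities:
        details = ", ".join(
            f"{a.singleton}~{a.paired_label}" for a in linkage.ambiguities
        )
        raise PhasingError(f"unresolved shared-label ambiguity: {details}")
    catalog = build_catalog(linkage, presence, class_map=class_map, name_map=name_map)
    genotypes = assign_genotypes(presence, catalog, cohorts)
    return catalog, genotypes, linkage
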