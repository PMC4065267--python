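"""Per-organ S-haplotype expression and dominance from diallel crosses.

Under sporophytic self-incompatibility the pollen phenotype is determined
by the diploid genotype of the paternal plant: a cross fails when some
haplotype is both expressed in the donor's pollen and expressed in the
receptor's stigma. Dominance means a haplotype can be silenced by its
partner in a heterozygote, independently per organ, so the observed
compatibility matrix carries information about which haplotype is
expressed where.

Expression states are inferred per (genotype, organ, haplotype) by
propagating two sound rules to a fixed point over the consolidated cross
outcomes:

* an *incompatible* cross must have at least one shared haplotype that is
  expressed in the donor's pollen and the receptor's stigma; when exactly
  one shared haplotype remains viable, it is called expressed on both
  sides (this covers the homozygote case, whose genotype set has a single
  element);
* a *compatible* cross excludes every joint expression: a shared haplotype
  known to be expressed in the receptor's stigma must be silenced in the
  donor's pollen, and vice versa.

States only ever move from unknown to expressed/silenced; a derivation
contradicting an earlier one marks the call ``conflicting`` rather than
overwriting it, so the iteration terminates. Calls left undetermined are
``ambiguous``.

Evidence is used only in the direction observed (non-reciprocal
incompatibility is never symmetrized), and expression is modelled per
genotype, not globally per haplotype; the aggregated dominance relations
are summaries of the per-genotype calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .data_io import CrossOutcome, DataError
from .phasing import DiploidGenotype, HaplotypeCatalog

ORGANS = ("pollen", "stigma")

EXPRESSED = "expressed"
SILENCED = "silenced"
AMBIGUOUS = "ambiguous"
CONFLICTING = "conflicting"

COMPATIBLE = "compatible"
INCOMPATIBLE = "incompatible"
CONFLICTING_OUTCOME = "conflicting"
UNDETERMINED = "undetermined"

Genotype = frozenset[str]  # set of 1 (homozygote) or 2 haplotype IDs


@dataclass
class ConsensusOutcome:
    """Merged outcome for an ordered (donor genotype, receptor genotype) pair."""

    donor: Genotype
    receptor: Genotype
    outcome: str
    n_fruit: int
    n_no_fruit: int
    crosses: tuple[tuple[str, str], ...] = ()


def consolidate_crosses(
    crosses: Sequence[CrossOutcome],
    genotypes: Sequence[DiploidGenotype] | Mapping[str, DiploidGenotype],
    policy: str = "strict",
) -> dict[tuple[Genotype, Genotype], ConsensusOutcome]:
    """Merge replicates and same-genotype crosses into one consensus outcome
    per ordered genotype pair.

    ``policy='strict'`` (default) calls a pair compatible/incompatible only
    when all replicates agree; mixed outcomes become ``conflicting`` and are
    excluded from inference. ``policy='majority'`` takes the majority vote
    (ties are conflicting); with independent noise this reduces the error
    rate relative to a single replicate.
    """
    if policy not in ("strict", "majority"):
        raise ValueError(f"unknown consolidation policy {policy!r}")
    if not isinstance(genotypes, Mapping):
        genotypes = {g.individual_id: g for g in genotypes}

    tallies: dict[tuple[Genotype, Genotype], list] = {}
    for cross in crosses:
        if cross.result == "not_done":
            continue
        for ind in (cross.donor_id, cross.receptor_id):
            if ind not in genotypes:
                raise DataError(f"cross references ungenotyped individual {ind!r}")
        key = (genotypes[cross.donor_id].haplotypes, genotypes[cross.receptor_id].haplotypes)
        entry = tallies.setdefault(key, [0, 0, set()])
        if cross.result == "fruit":
            entry[0] += cross.replicates
        else:
            entry[1] += cross.replicates
        entry[2].add((cross.donor_id, cross.receptor_id))

    consensus = {}
    for key, (n_fruit, n_no_fruit, pairs) in tallies.items():
        if policy == "strict":
            if n_fruit and n_no_fruit:
                outcome = CONFLICTING_OUTCOME
            else:
                outcome = COMPATIBLE if n_fruit else INCOMPATIBLE
        else:
            if n_fruit > n_no_fruit:
                outcome = COMPATIBLE
            elif n_no_fruit > n_fruit:
                outcome = INCOMPATIBLE
            else:
                outcome = CONFLICTING_OUTCOME
        consensus[key] = ConsensusOutcome(
            donor=key[0],
            receptor=key[1],
            outcome=outcome,
            n_fruit=n_fruit,
            n_no_fruit=n_no_fruit,
            crosses=tuple(sorted(pairs)),
        )
    return consensus


@dataclass(frozen=True)
class ExpressionCall:
    genotype: Genotype
    haplotype: str
    organ: str
    state: str


class ExpressionModel:
    """Per-(genotype, organ, haplotype) expression states with set queries."""

    def __init__(self, genotypes: Iterable[Genotype]) -> None:
        self.genotypes: set[Genotype] = set(genotypes)
        self._states: dict[tuple[Genotype, str, str], str] = {}
        self.anomalies: list[str] = []

    def state(self, genotype: Genotype, organ: str, haplotype: str) -> str:
        return self._states.get((genotype, organ, haplotype), AMBIGUOUS)

    def assign(self, genotype: Genotype, organ: str, haplotype: str, state: str) -> bool:
        """Set a state; contradictions become ``conflicting``. Returns True
        when anything changed."""
        key = (genotype, organ, haplotype)
        current = self._states.get(key)
        if current is None:
            self._states[key] = state
            return True
        if current == state or current == CONFLICTING:
            return False
        self._states[key] = CONFLICTING
        self.anomalies.append(
            f"{'/'.join(sorted(genotype))} {organ} {haplotype}: {current} vs {state}"
        )
        return True

    def expressed_set(self, genotype: Genotype, organ: str) -> frozenset[str]:
        """Haplotypes definitely expressed in this genotype/organ."""
        return frozenset(
            h for h in genotype if self.state(genotype, organ, h) == EXPRESSED
        )

    def possible_set(self, genotype: Genotype, organ: str) -> frozenset[str]:
        """Haplotypes not excluded (expressed, ambiguous or conflicting)."""
        return frozenset(
            h for h in genotype if self.state(genotype, organ, h) != SILENCED
        )

    def calls(self) -> list[ExpressionCall]:
        out = []
        for genotype in sorted(self.genotypes, key=sorted):
            for organ in ORGANS:
                for haplotype in sorted(genotype):
                    out.append(
                        ExpressionCall(genotype, haplotype, organ, self.state(genotype, organ, haplotype))
                    )
        return out


def infer_expression(
    consensus: Mapping[tuple[Genotype, Genotype], ConsensusOutcome],
    genotypes: Iterable[Genotype] = (),
) -> ExpressionModel:
    """Propagate compatibility evidence to a fixed point of expression calls."""
    universe = set(genotypes)
    for donor, receptor in consensus:
        universe.add(donor)
        universe.add(receptor)
    model = ExpressionModel(universe)

    informative = [
        co for co in consensus.values() if co.outcome in (COMPATIBLE, INCOMPATIBLE)
    ]
    changed = True
    while changed:
        changed = False
        for co in informative:
            shared = co.donor & co.receptor
            if not shared:
                if co.outcome == INCOMPATIBLE:
                    model.anomalies.append(
                        f"incompatible cross {'/'.join(sorted(co.donor))} -> "
                        f"{'/'.join(sorted(co.receptor))} shares no haplotype"
                    )
                continue
            if co.outcome == INCOMPATIBLE:
                viable = [
                    h
                    for h in sorted(shared)
                    if model.state(co.donor, "pollen", h) != SILENCED
                    and model.state(co.receptor, "stigma", h) != SILENCED
                ]
                if len(viable) == 1:
                    h = viable[0]
                    changed |= model.assign(co.donor, "pollen", h, EXPRESSED)
                    changed |= model.assign(co.receptor, "stigma", h, EXPRESSED)
                elif not viable:
                    model.anomalies.append(
                        f"incompatible cross {'/'.join(sorted(co.donor))} -> "
                        f"{'/'.join(sorted(co.receptor))} has no viable shared haplotype"
                    )
            else:  # compatible: no shared haplotype may be expressed on both sides
                for h in sorted(shared):
                    if model.state(co.receptor, "stigma", h) == EXPRESSED:
                        changed |= model.assign(co.donor, "pollen", h, SILENCED)
                    if model.state(co.donor, "pollen", h) == EXPRESSED:
                        changed |= model.assign(co.receptor, "stigma", h, SILENCED)
    return model


@dataclass
class DominanceModel:
    """Aggregated per-organ dominance relations among haplotypes.

    ``dominant[organ]`` maps (winner, loser) -> supporting genotype;
    ``codominant[organ]`` holds unordered expressed-expressed pairs;
    ``unresolved[organ]`` pairs with ambiguous or conflicting calls.
    Cycles in the aggregated dominance graph are reported, not resolved.
    """

    dominant: dict[str, dict[tuple[str, str], Genotype]]
    codominant: dict[str, set[frozenset[str]]]
    unresolved: dict[str, set[frozenset[str]]]
    cycles: dict[str, list[list[str]]]
    expression: ExpressionModel | None = None


def build_dominance(model: ExpressionModel) -> DominanceModel:
    """Summarize per-genotype expression calls into dominance relations."""
    dominant: dict[str, dict[tuple[str, str], Genotype]] = {o: {} for o in ORGANS}
    codominant: dict[str, set[frozenset[str]]] = {o: set() for o in ORGANS}
    unresolved: dict[str, set[frozenset[str]]] = {o: set() for o in ORGANS}
    for genotype in model.genotypes:
        if len(genotype) != 2:
            continue
        x, y = sorted(genotype)
        for organ in ORGANS:
            sx = model.state(genotype, organ, x)
            sy = model.state(genotype, organ, y)
            pair = frozenset((x, y))
            if sx == EXPRESSED and sy == SILENCED:
                dominant[organ][(x, y)] = genotype
            elif sy == EXPRESSED and sx == SILENCED:
                dominant[organ][(y, x)] = genotype
            elif sx == EXPRESSED and sy == EXPRESSED:
                codominant[organ].add(pair)
            else:
                unresolved[organ].add(pair)
    cycles = {}
    for organ in ORGANS:
        graph = nx.DiGraph(list(dominant[organ]))
        cycles[organ] = [sorted(c) for c in nx.simple_cycles(graph)]
    return DominanceModel(dominant, codominant, unresolved, cycles, expression=model)


def predict_compatibility(
    donor: Genotype,
    receptor: Genotype,
    model: ExpressionModel | DominanceModel,
) -> str:
    """Predict a cross outcome under the sporophytic rule.

    Incompatible iff a haplotype is definitely expressed in the donor's
    pollen and the receptor's stigma; compatible iff no haplotype could be
    expressed on both sides even resolving every ambiguity; undetermined
    otherwise (including genotypes the model has never seen).
    """
    expr = model.expression if isinstance(model, DominanceModel) else model
    if expr is None:
        raise ValueError("dominance model carries no expression model")
    if expr.expressed_set(donor, "pollen") & expr.expressed_set(receptor, "stigma"):
        return INCOMPATIBLE
    if not (expr.possible_set(donor, "pollen") & expr.possible_set(receptor, "stigma")):
        return COMPATIBLE
    return UNDETERMINED


def summarize_compatibility(
    crosses: Sequence[CrossOutcome],
    genotypes: Sequence[DiploidGenotype] | Mapping[str, DiploidGenotype],
    catalog: HaplotypeCatalog | None = None,
    class_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Fruit-set rates for crosses sharing >=1 haplotype vs sharing none,
    overall and per haplotype/organ (and per class when a class map and
    catalog are provided).

    Each realized pollination (replicate) counts once. Returns a tidy table
    with columns scope/key/organ/shared/n_crosses/n_fruit/rate.
    """
    if not isinstance(genotypes, Mapping):
        genotypes = {g.individual_id: g for g in genotypes}

    def hap_class(hid: str) -> str:
        if catalog is None or class_map is None:
            return "unknown"
        labels = catalog[hid].labels
        return class_map.get(min(labels), "other")

    buckets: dict[tuple[str, str, str, bool], list[int]] = {}

    def add(scope: str, key: str, organ: str, shared: bool, fruits: int, total: int) -> None:
        entry = buckets.setdefault((scope, key, organ, shared), [0, 0])
        entry[0] += fruits
        entry[1] += total

    for cross in crosses:
        if cross.result == "not_done":
            continue
        gd = genotypes[cross.donor_id].haplotypes
        gr = genotypes[cross.receptor_id].haplotypes
        shared = bool(gd & gr)
        fruits = cross.replicates if cross.result == "fruit" else 0
        total = cross.replicates
        add("overall", "all", "both", shared, fruits, total)
        for h in gd:
            add("haplotype", h, "pollen", shared, fruits, total)
            add("class", hap_class(h), "pollen", shared, fruits, total)
        for h in gr:
            add("haplotype", h, "stigma", shared, fruits, total)
            add("class", hap_class(h), "stigma", shared, fruits, total)

    rows = []
    for (scope, key, organ, shared), (fruits, total) in sorted(buckets.items()):
        rows.append(
            {
                "scope": scope,
                "key": key,
                "organ": organ,
                "shared_haplotype": shared,
                "n_crosses": total,
                "n_fruit": fruits,
                "rate": fruits / total if total else float("nan"),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["scope", "key", "organ", "shared_haplotype", "n_crosses", "n_fruit", "rate"],
    )
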