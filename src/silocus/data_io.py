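"""Tabular and sequence input/output plus the shared domain types.

The pipeline consumes four kinds of input:

* a presence/absence matrix of sequence labels per individual (CSV),
* offspring cohort tables with per-genotype-combination counts (CSV),
* a matrix of controlled-cross outcomes (CSV),
* codon-aligned coding sequences (FASTA).

All identifiers (individuals, sequence labels) are opaque strings. CSVs are
comma-separated UTF-8 with a header row. Sub-variants of a sequence label
(e.g. ``A01a``/``A01b``) can be merged onto a canonical label through an
explicit ``variant_merge_map``; merging is never guessed from names.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

CLASS_TAGS = frozenset({"A", "B", "C", "ARK3L", "P327420L", "other"})
CROSS_RESULTS = frozenset({"fruit", "no_fruit", "not_done"})
ALIGNMENT_ALPHABET = frozenset("ACGT-N")


class DataError(ValueError):
    """Raised for malformed or inconsistent input tables."""


@dataclass(frozen=True)
class SequenceLabel:
    """A typed sequence label, e.g. ``A01`` with class tag ``A``.

    Class tags come from a user-supplied mapping (they reflect phylogenetic
    clustering done upstream); they are never inferred from the name.
    """

    name: str
    class_tag: str = "other"

    def __post_init__(self) -> None:
        if self.class_tag not in CLASS_TAGS:
            raise DataError(f"unknown class tag {self.class_tag!r} for {self.name!r}")


class PresenceMatrix:
    """Boolean presence of sequence labels per diploid individual.

    Parameters
    ----------
    presence:
        Mapping individual id -> set of label names present.
    individuals:
        Optional explicit row order (defaults to insertion order).
    variant_merge_map:
        Mapping of sub-variant label -> canonical label that *has already
        been applied* (kept for provenance) or should be applied via
        :meth:`merged`.
    """

    def __init__(
        self,
        presence: Mapping[str, Iterable[str]],
        individuals: Sequence[str] | None = None,
        variant_merge_map: Mapping[str, str] | None = None,
    ) -> None:
        self._presence: dict[str, frozenset[str]] = {
            ind: frozenset(labels) for ind, labels in presence.items()
        }
        self.individuals: list[str] = (
            list(individuals) if individuals is not None else list(self._presence)
        )
        if set(self.individuals) != set(self._presence):
            raise DataError("individuals list does not match presence mapping")
        if len(set(self.individuals)) != len(self.individuals):
            raise DataError("duplicate individual IDs")
        for ind, labels in self._presence.items():
            if not labels:
                raise DataError(f"individual {ind!r} carries no sequence label")
        self.variant_merge_map = dict(variant_merge_map or {})

    @property
    def labels(self) -> list[str]:
        """All label names, sorted."""
        out: set[str] = set()
        for labels in self._presence.values():
            out |= labels
        return sorted(out)

    def labels_of(self, individual: str) -> frozenset[str]:
        try:
            return self._presence[individual]
        except KeyError:
            raise DataError(f"unknown individual {individual!r}") from None

    def carriers(self, label: str) -> frozenset[str]:
        return frozenset(
            ind for ind, labels in self._presence.items() if label in labels
        )

    def merged(self, variant_merge_map: Mapping[str, str] | None = None) -> "PresenceMatrix":
        """Return a matrix with sub-variant labels replaced by canonical ones.

        Idempotent: merging an already-merged matrix is a no-op.
        """
        merge = dict(variant_merge_map if variant_merge_map is not None else self.variant_merge_map)
        merged = {
            ind: frozenset(merge.get(lab, lab) for lab in labels)
            for ind, labels in self._presence.items()
        }
        for variant, canonical in sorted(merge.items()):
            if any(variant in labels for labels in self._presence.values()):
                logger.info("merged sub-variant %s -> %s", variant, canonical)
        return PresenceMatrix(merged, self.individuals, merge)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, PresenceMatrix)
            and self._presence == other._presence
            and self.individuals == other.individuals
        )

    def __repr__(self) -> str:
        return f"PresenceMatrix({len(self.individuals)} individuals, {len(self.labels)} labels)"


@dataclass(frozen=True)
class UntypableSet:
    """Labels that cannot be scored in progeny (their linkage can only be
    supported by association in the parental generation)."""

    labels: frozenset[str]

    def validate(self, matrix: PresenceMatrix) -> None:
        extra = self.labels - set(matrix.labels)
        if extra:
            raise DataError(f"untypable labels not in matrix: {sorted(extra)}")


@dataclass
class CohortObservation:
    """One full-sib cohort: parents and counts per observed label combination."""

    cohort_id: str
    parent1_id: str
    parent2_id: str
    n: int
    offspring_counts: dict[frozenset[str], int]
    collection: str = ""

    def __post_init__(self) -> None:
        if self.n < 1:
            raise DataError(f"cohort {self.cohort_id}: n must be >= 1")
        total = sum(self.offspring_counts.values())
        if total != self.n:
            raise DataError(
                f"cohort {self.cohort_id}: counts sum to {total}, declared n={self.n}"
            )

    @property
    def parents(self) -> tuple[str, str]:
        return (self.parent1_id, self.parent2_id)


@dataclass(frozen=True)
class CrossOutcome:
    """One controlled pollination: ordered (donor, receptor) pair and result.

    ``donor_id`` may equal ``receptor_id`` (self-pollination).
    """

    donor_id: str
    receptor_id: str
    result: str
    replicates: int = 1

    def __post_init__(self) -> None:
        if self.result not in CROSS_RESULTS:
            raise DataError(f"unknown cross result {self.result!r}")
        if self.result != "not_done" and self.replicates < 1:
            raise DataError("replicates must be >= 1 for realized crosses")


@dataclass(frozen=True)
class CodonAlignment:
    """In-frame nucleotide alignment (length divisible by 3)."""

    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise DataError("empty alignment")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            raise DataError(f"inconsistent sequence lengths: {sorted(lengths)}")
        length = lengths.pop()
        if length % 3 != 0:
            raise DataError(f"alignment length {length} not divisible by 3")
        for name, seq in self.records:
            bad = set(seq) - ALIGNMENT_ALPHABET
            if bad:
                raise DataError(f"record {name!r}: invalid characters {sorted(bad)}")

    @property
    def alignment_length(self) -> int:
        return len(self.records[0][1])

    @property
    def n_codons(self) -> int:
        return self.alignment_length // 3

    @property
    def ids(self) -> list[str]:
        return [name for name, _ in self.records]

    def sequence(self, name: str) -> str:
        for rec_name, seq in self.records:
            if rec_name == name:
                return seq
        raise DataError(f"no record named {name!r}")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_presence_matrix(
    path: str | Path,
    variant_merge_map: Mapping[str, str] | None = None,
) -> PresenceMatrix:
    """Read a presence/absence CSV (rows = individuals, columns = labels).

    Cells must be ``0`` or ``1``. An empty cell is accepted as absence only
    when the row's optional ``typed`` column says ``complete``; otherwise it
    is an error, so "not typed" is never silently confused with "absent".
    Sub-variants are merged onto canonical labels when a map is given.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise DataError(f"{path}: empty file")
        if "individual" not in reader.fieldnames:
            raise DataError(f"{path}: missing 'individual' column")
        label_cols = [c for c in reader.fieldnames if c not in ("individual", "typed")]
        presence: dict[str, frozenset[str]] = {}
        order: list[str] = []
        for row in reader:
            ind = row["individual"]
            if ind in presence:
                raise DataError(f"{path}: duplicate individual ID {ind!r}")
            complete = row.get("typed", "complete") == "complete"
            labels = set()
            for col in label_cols:
                cell = (row[col] or "").strip()
                if cell == "":
                    if not complete:
                        raise DataError(
                            f"{path}: individual {ind!r}, label {col!r}: missing cell "
                            "without typed=complete flag"
                        )
                    continue
                if cell not in ("0", "1"):
                    raise DataError(
                        f"{path}: individual {ind!r}, label {col!r}: non-binary cell {cell!r}"
                    )
                if cell == "1":
                    labels.add(col)
            presence[ind] = frozenset(labels)
            order.append(ind)
    if not presence:
        raise DataError(f"{path}: no individuals")
    matrix = PresenceMatrix(presence, order)
    if variant_merge_map:
        known = set(label_cols) | set(variant_merge_map.values())
        unknown = set(variant_merge_map) - known
        if unknown:
            raise DataError(f"{path}: merge map names unknown label {sorted(unknown)}")
        matrix = matrix.merged(variant_merge_map)
    return matrix


def read_cohorts(
    path: str | Path,
    presence: PresenceMatrix | None = None,
) -> list[CohortObservation]:
    """Read cohort observations (one row per observed label combination).

    Columns: ``cohort_id, collection, parent1, parent2, n, labels, count``
    with ``labels`` a ``;``-separated set. When a presence matrix is given,
    parent IDs are validated against it.
    """
    path = Path(path)
    rows_by_cohort: dict[str, list[dict[str, str]]] = {}
    order: list[str] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"cohort_id", "parent1", "parent2", "n", "labels", "count"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise DataError(f"{path}: expected columns {sorted(required)}")
        for row in reader:
            cid = row["cohort_id"]
            if cid not in rows_by_cohort:
                rows_by_cohort[cid] = []
                order.append(cid)
            rows_by_cohort[cid].append(row)
    cohorts = []
    for cid in order:
        rows = rows_by_cohort[cid]
        head = rows[0]
        parents = (head["parent1"], head["parent2"])
        for row in rows:
            if (row["parent1"], row["parent2"]) != parents or row["n"] != head["n"]:
                raise DataError(f"{path}: cohort {cid}: inconsistent header fields")
        if presence is not None:
            for parent in parents:
                if parent not in presence.individuals:
                    raise DataError(f"{path}: cohort {cid}: unknown parent ID {parent!r}")
        counts: dict[frozenset[str], int] = {}
        for row in rows:
            combo = frozenset(x for x in row["labels"].split(";") if x)
            if combo in counts:
                raise DataError(f"{path}: cohort {cid}: duplicate combination {sorted(combo)}")
            counts[combo] = int(row["count"])
        cohorts.append(
            CohortObservation(
                cohort_id=cid,
                parent1_id=parents[0],
                parent2_id=parents[1],
                n=int(head["n"]),
                offspring_counts=counts,
                collection=head.get("collection", "") or "",
            )
        )
    return cohorts


def read_crosses(path: str | Path) -> list[CrossOutcome]:
    """Read cross outcomes: columns ``donor, receptor, result, replicates``."""
    path = Path(path)
    out = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"donor", "receptor", "result"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise DataError(f"{path}: expected columns {sorted(required)}")
        for row in reader:
            out.append(
                CrossOutcome(
                    donor_id=row["donor"],
                    receptor_id=row["receptor"],
                    result=row["result"],
                    replicates=int(row.get("replicates") or 1),
                )
            )
    return out


def read_codon_alignment(path: str | Path) -> CodonAlignment:
    """Read an in-frame FASTA alignment (uppercased; U -> T)."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.id, str(rec.seq).upper().replace("U", "T")))
    if not records:
        raise DataError(f"{path}: no FASTA records")
    return CodonAlignment(tuple(records))


def read_config(path: str | Path) -> dict[str, str]:
    """Read a flat ``key=value`` config file; '#' starts a comment line."""
    out: dict[str, str] = {}
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise DataError(f"config line without '=': {raw!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out


# ---------------------------------------------------------------------------
# writers (round-trip partners of the readers)
# ---------------------------------------------------------------------------

def write_presence_matrix(matrix: PresenceMatrix, path: str | Path) -> None:
    labels = matrix.labels
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["individual", *labels])
        for ind in matrix.individuals:
            carried = matrix.labels_of(ind)
            writer.writerow([ind, *("1" if lab in carried else "0" for lab in labels)])


def write_cohorts(cohorts: Sequence[CohortObservation], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["cohort_id", "collection", "parent1", "parent2", "n", "labels", "count"])
        for cohort in cohorts:
            for combo in sorted(cohort.offspring_counts, key=sorted):
                writer.writerow(
                    [
                        cohort.cohort_id,
                        cohort.collection,
                        cohort.parent1_id,
                        cohort.parent2_id,
                        cohort.n,
                        ";".join(sorted(combo)),
                        cohort.offspring_counts[combo],
                    ]
                )


def write_crosses(crosses: Sequence[CrossOutcome], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["donor", "receptor", "result", "replicates"])
        for cross in crosses:
            writer.writerow([cross.donor_id, cross.receptor_id, cross.result, cross.replicates])


def write_codon_alignment(alignment: CodonAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in alignment.records
    ]
    SeqIO.write(records, str(path), "fasta")
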