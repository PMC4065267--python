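"""Bundled reference dataset: the published S-locus typing study tables.

The CSVs here transcribe the printed tables of the Biscutella neustriaca
S-locus study: the parental (F0) presence/absence matrix of 21 individuals
over the SRK-like sequence labels, the 13 full-sib cohort segregation
tables, the S01-S13 haplotype nomenclature, the label class map (A/B/C
sequence classes) and the A01a/A01b sub-variant merge map.

Two presences in the F0 matrix (B13 in individual 10 and B17 in
individual 9) were marked "supposed by association" in the source table
rather than directly typed; they are part of the table's genotype calls
and are included here as presences, since the association-based linkage
tier (``f0_association_only``) is exactly the evidence they carry.

``worked_example_crosses.csv`` holds the four pollinations of the
individual 3/4 dominance worked example, derived from the study's text
(the full diallel matrix is published only as a figure and is not
transcribed here).

The three labels ``B13``, ``B17``, ``B18`` could not be typed in progeny
(:data:`UNTYPABLE`).
"""

from __future__ import annotations

import csv
from importlib import resources
from pathlib import Path

from ..data_io import CrossOutcome, PresenceMatrix, read_cohorts, read_crosses, read_presence_matrix

#: labels that could not be scored in offspring
UNTYPABLE = frozenset({"B13", "B17", "B18"})


def _path(name: str) -> Path:
    return Path(resources.files(__package__) / name)


def f0_presence_path() -> Path:
    return _path("f0_presence.csv")


def f1_cohorts_path() -> Path:
    return _path("f1_cohorts.csv")


def variant_merge_map() -> dict[str, str]:
    """A01a/A01b -> A01 (the sub-variants differ by one nonsynonymous
    substitution and segregate as one allele)."""
    with _path("variant_merge.csv").open(newline="", encoding="utf-8") as fh:
        return {row["variant"]: row["canonical"] for row in csv.DictReader(fh)}


def class_map() -> dict[str, str]:
    """Sequence label -> phylogenetic class (A, B or C)."""
    with _path("label_classes.csv").open(newline="", encoding="utf-8") as fh:
        return {row["label"]: row["class"] for row in csv.DictReader(fh)}


def s_haplotype_names() -> dict[frozenset[str], str]:
    """Label set -> published S-haplotype name (S01-S13)."""
    with _path("s_haplotype_names.csv").open(newline="", encoding="utf-8") as fh:
        return {
            frozenset(row["labels"].split(";")): row["haplotype"]
            for row in csv.DictReader(fh)
        }


def load_f0_presence(merged: bool = True) -> PresenceMatrix:
    """The 21-individual presence matrix; sub-variants merged by default."""
    return read_presence_matrix(
        f0_presence_path(), variant_merge_map() if merged else None
    )


def load_f1_cohorts(presence: PresenceMatrix | None = None):
    """The 13 cohort observations (labels already canonical)."""
    return read_cohorts(f1_cohorts_path(), presence)


def expected_f0_genotypes() -> dict[str, tuple[frozenset[frozenset[str]], str]]:
    """Published genotype per individual: ({hap1 labels, hap2 labels}, status)."""
    out = {}
    with _path("f0_genotypes.csv").open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            pair = frozenset(
                (
                    frozenset(row["hap1_labels"].split(";")),
                    frozenset(row["hap2_labels"].split(";")),
                )
            )
            out[row["individual"]] = (pair, row["status"])
    return out


def worked_example_crosses() -> list[CrossOutcome]:
    """The individual 3/4 dominance worked example (text-derived)."""
    return read_crosses(_path("worked_example_crosses.csv"))
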