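"""Single entry point chaining phasing, segregation and dominance, with a
run manifest for reproducibility.

Outputs are plain CSVs mirroring the study's report tables: the haplotype
catalog, per-individual genotypes, the per-cohort segregation summary, the
per-genotype expression calls, the aggregated dominance relations and the
compatibility-rate summary. The manifest records inputs, parameters, seed
and per-stage row counts; re-running with the same inputs and seed
reproduces every output byte-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import version, PackageNotFoundError
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import data_io, dominance, phasing, segregation

logger = logging.getLogger(__name__)


def _package_version() -> str:
    try:
        return version("silocus")
    except PackageNotFoundError:
        return "unknown"


@dataclass
class RunManifest:
    inputs: dict[str, str]
    parameters: dict[str, object]
    seed: int
    package_version: str
    row_counts: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.__dict__, indent=1, sort_keys=True, default=str),
            encoding="utf-8",
        )


def catalog_table(catalog: phasing.HaplotypeCatalog) -> pd.DataFrame:
    rows = [
        {
            "haplotype_id": h.haplotype_id,
            "labels": ";".join(sorted(h.labels)),
            "n_labels": len(h.labels),
            "support": h.support,
        }
        for h in catalog
    ]
    return pd.DataFrame(rows, columns=["haplotype_id", "labels", "n_labels", "support"])


def genotype_table(genotypes: list[phasing.DiploidGenotype]) -> pd.DataFrame:
    rows = [
        {
            "individual": g.individual_id,
            "haplotype_1": g.h1,
            "haplotype_2": g.h2,
            "status": g.status,
        }
        for g in genotypes
    ]
    return pd.DataFrame(rows, columns=["individual", "haplotype_1", "haplotype_2", "status"])


def expression_table(model: dominance.ExpressionModel) -> pd.DataFrame:
    rows = [
        {
            "genotype": "/".join(sorted(call.genotype)),
            "haplotype": call.haplotype,
            "organ": call.organ,
            "state": call.state,
        }
        for call in model.calls()
    ]
    return pd.DataFrame(rows, columns=["genotype", "haplotype", "organ", "state"])


def dominance_table(model: dominance.DominanceModel) -> pd.DataFrame:
    rows = []
    for organ in dominance.ORGANS:
        for (winner, loser), genotype in sorted(model.dominant[organ].items()):
            rows.append(
                {
                    "organ": organ,
                    "relation": "dominant",
                    "haplotype_1": winner,
                    "haplotype_2": loser,
                    "genotype": "/".join(sorted(genotype)),
                }
            )
        for pair in sorted(model.codominant[organ], key=sorted):
            a, b = sorted(pair)
            rows.append(
                {
                    "organ": organ,
                    "relation": "codominant",
                    "haplotype_1": a,
                    "haplotype_2": b,
                    "genotype": f"{a}/{b}",
                }
            )
        for pair in sorted(model.unresolved[organ], key=sorted):
            a, b = sorted(pair)
            rows.append(
                {
                    "organ": organ,
                    "relation": "unresolved",
                    "haplotype_1": a,
                    "haplotype_2": b,
                    "genotype": f"{a}/{b}",
                }
            )
    return pd.DataFrame(
        rows, columns=["organ", "relation", "haplotype_1", "haplotype_2", "genotype"]
    )


def run_all(
    presence_path: str | Path,
    cohorts_path: str | Path,
    crosses_path: str | Path | None = None,
    outdir: str | Path = "silocus_out",
    untypable: frozenset[str] = frozenset(),
    variant_merge_map: Mapping[str, str] | None = None,
    class_map: Mapping[str, str] | None = None,
    name_map: Mapping[frozenset[str], str] | None = None,
    reps: int = segregation.DEFAULT_REPS,
    alpha: float = segregation.DEFAULT_ALPHA,
    seed: int = segregation.DEFAULT_SEED,
) -> RunManifest:
    """Run the full pipeline on file inputs and write the report bundle.

    A missing crosses file skips the dominance stage with a warning; any
    stage error aborts with the stage named.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        inputs={
            "presence": str(presence_path),
            "cohorts": str(cohorts_path),
            "crosses": str(crosses_path) if crosses_path else "",
        },
        parameters={
            "reps": reps,
            "alpha": alpha,
            "untypable": sorted(untypable),
            "variant_merge_map": dict(variant_merge_map or {}),
        },
        seed=seed,
        package_version=_package_version(),
    )

    def stage(name: str):
        logger.info("stage: %s", name)
        return name

    current = stage("read inputs")
    try:
        presence = data_io.read_presence_matrix(presence_path, variant_merge_map)
        cohorts = data_io.read_cohorts(cohorts_path, presence)

        current = stage("phasing")
        catalog, genotypes, linkage = phasing.phase_dataset(
            presence, cohorts, untypable, class_map=class_map, name_map=name_map
        )
        catalog_table(catalog).to_csv(outdir / "catalog.csv", index=False)
        genotype_table(genotypes).to_csv(outdir / "genotypes.csv", index=False)
        manifest.row_counts["catalog"] = len(catalog)
        manifest.row_counts["genotypes"] = len(genotypes)
        for incons in linkage.inconsistencies:
            manifest.warnings.append(
                f"inconsistent clustering: parent {incons.parent_id} "
                f"cohort {incons.cohort_id}: {incons.note}"
            )

        current = stage("segregation")
        seg_table, _ = segregation.batch_test(
            cohorts, genotypes, catalog, untypable, reps=reps, alpha=alpha, seed=seed
        )
        seg_table.to_csv(outdir / "segregation.csv", index=False)
        manifest.row_counts["segregation"] = len(seg_table)

        if crosses_path and Path(crosses_path).exists():
            current = stage("dominance")
            crosses = data_io.read_crosses(crosses_path)
            consensus = dominance.consolidate_crosses(crosses, genotypes)
            model = dominance.infer_expression(consensus)
            dom = dominance.build_dominance(model)
            expression_table(model).to_csv(outdir / "expression.csv", index=False)
            dominance_table(dom).to_csv(outdir / "dominance.csv", index=False)
            summary = dominance.summarize_compatibility(crosses, genotypes, catalog, class_map)
            summary.to_csv(outdir / "summary.csv", index=False)
            manifest.row_counts["crosses"] = len(crosses)
            manifest.row_counts["expression_calls"] = len(model.calls())
            for note in model.anomalies:
                manifest.warnings.append(f"expression anomaly: {note}")
        else:
            manifest.warnings.append("no crosses file: dominance stage skipped")
            logger.warning("no crosses file: dominance stage skipped")
    except Exception as exc:
        raise RuntimeError(f"stage '{current}' failed: {exc}") from exc

    manifest.write(outdir / "manifest.json")
    return manifest
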