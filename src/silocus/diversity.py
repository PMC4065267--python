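"""Codon-aware synonymous/nonsynonymous nucleotide diversity.

Synonymous (pi_S) and nonsynonymous (pi_N) per-site diversity within a
group of aligned coding sequences, by unweighted pathway counting:

* *sites* — each of the three single-nucleotide changes of a codon
  contributes 1/3 of a site, classified synonymous or nonsynonymous by the
  genetic code; changes producing a stop codon are excluded, so a codon's
  site total is 3 minus the excluded fraction;
* *differences* — per codon pair, differences at k positions are resolved
  by averaging the synonymous/nonsynonymous step counts over all k!
  minimal substitution pathways, excluding pathways that traverse a stop
  codon;
* *pi* — the mean over all unordered sequence pairs of (differences /
  sites), with sites averaged between the two sequences of a pair.

Codons containing a gap, an N, or a stop in either sequence of a pair are
excluded pairwise (complete-codon deletion); the reported ``n_sites`` is
the minimum number of retained nucleotide columns over pairs. The raw
proportion is reported by default; a Jukes-Cantor correction can be
enabled per estimate.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio.Data import CodonTable

from .data_io import CodonAlignment, DataError

BASES = "ACGT"


@lru_cache(maxsize=None)
def genetic_code(table_id: int = 1) -> dict[str, str]:
    """Full 64-codon table, stops encoded as ``*`` (NCBI table id)."""
    table = CodonTable.unambiguous_dna_by_id[table_id]
    code = dict(table.forward_table)
    for stop in table.stop_codons:
        code[stop] = "*"
    return code


def _check_codon(codon: str, code: Mapping[str, str]) -> str:
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise DataError(f"invalid codon {codon!r}")
    aa = code[codon]
    if aa == "*":
        raise DataError(f"stop codon {codon!r}")
    return aa


@lru_cache(maxsize=None)
def codon_site_counts(codon: str, table_id: int = 1) -> tuple[float, float]:
    """(synonymous sites, nonsynonymous sites) of one codon.

    Each single-nucleotide change weighs 1/3 site; changes to stop codons
    are excluded, so the two counts sum to 3 minus the excluded fraction.
    """
    code = genetic_code(table_id)
    aa = _check_codon(codon, code)
    syn = nonsyn = 0.0
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            alt_aa = code[alt]
            if alt_aa == "*":
                continue
            if alt_aa == aa:
                syn += 1 / 3
            else:
                nonsyn += 1 / 3
    return syn, nonsyn


@lru_cache(maxsize=None)
def codon_pair_differences(
    codon_a: str, codon_b: str, table_id: int = 1
) -> tuple[float, float] | None:
    """Average (synonymous, nonsynonymous) differences between two codons
    over all minimal substitution pathways avoiding stops.

    Returns None when every pathway traverses a stop codon (the codon pair
    is then excluded from the estimate entirely).
    """
    code = genetic_code(table_id)
    _check_codon(codon_a, code)
    _check_codon(codon_b, code)
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return (0.0, 0.0)
    syn_total = nonsyn_total = 0.0
    n_paths = 0
    for order in itertools.permutations(diff_positions):
        current = codon_a
        syn = nonsyn = 0
        valid = True
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if code[nxt] == "*":
                valid = False
                break
            if code[nxt] == code[current]:
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        if valid:
            syn_total += syn
            nonsyn_total += nonsyn
            n_paths += 1
    if n_paths == 0:
        return None
    return (syn_total / n_paths, nonsyn_total / n_paths)


def _usable(codon: str, code: Mapping[str, str]) -> bool:
    return all(b in BASES for b in codon) and code.get(codon) != "*"


def pairwise_syn_nonsyn(
    seq_a: str, seq_b: str, table_id: int = 1
) -> tuple[float, float, float, float, int]:
    """Nei-Gojobori counts for one sequence pair.

    Returns (synonymous differences, nonsynonymous differences, synonymous
    sites, nonsynonymous sites, codons retained). Codons with a gap, N or
    stop in either sequence are excluded pairwise.
    """
    if len(seq_a) != len(seq_b):
        raise DataError("sequence length mismatch")
    if len(seq_a) % 3:
        raise DataError("sequence length not divisible by 3")
    code = genetic_code(table_id)
    sd = nd = ss = ns = 0.0
    used = 0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        if not (_usable(ca, code) and _usable(cb, code)):
            continue
        diffs = codon_pair_differences(ca, cb, table_id)
        if diffs is None:
            continue
        sa = codon_site_counts(ca, table_id)
        sb = codon_site_counts(cb, table_id)
        ss += (sa[0] + sb[0]) / 2
        ns += (sa[1] + sb[1]) / 2
        sd += diffs[0]
        nd += diffs[1]
        used += 1
    return sd, nd, ss, ns, used


@dataclass(frozen=True)
class DiversityEstimate:
    """Per-site synonymous/nonsynonymous diversity of a sequence group."""

    group_id: str
    n_seq: int
    n_sites: int
    pi_s: float
    pi_n: float

    @property
    def ratio(self) -> float:
        """pi_N / pi_S; NaN when pi_S is zero."""
        return self.pi_n / self.pi_s if self.pi_s > 0 else float("nan")


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        raise DataError(f"proportion {p:.4f} too large for Jukes-Cantor correction")
    return -0.75 * math.log1p(-4 * p / 3)


def group_pi(
    alignment: CodonAlignment,
    members: Sequence[str] | None = None,
    group_id: str = "group",
    table_id: int = 1,
    jukes_cantor: bool = False,
) -> DiversityEstimate:
    """pi_S and pi_N for a group of sequences: the mean over all unordered
    pairs of per-pair proportions (Jukes-Cantor corrected per pair when
    requested)."""
    names = list(members) if members is not None else alignment.ids
    if len(names) < 2:
        raise DataError("group_pi needs at least 2 sequences")
    seqs = {name: alignment.sequence(name) for name in names}
    ps_values = []
    pn_values = []
    min_codons = None
    for a, b in itertools.combinations(names, 2):
        sd, nd, ss, ns, used = pairwise_syn_nonsyn(seqs[a], seqs[b], table_id)
        if used == 0:
            raise DataError(f"pair {a}/{b}: no codon retained")
        ps = sd / ss if ss > 0 else 0.0
        pn = nd / ns if ns > 0 else 0.0
        if jukes_cantor:
            ps = _jukes_cantor(ps)
            pn = _jukes_cantor(pn)
        ps_values.append(ps)
        pn_values.append(pn)
        min_codons = used if min_codons is None else min(min_codons, used)
    return DiversityEstimate(
        group_id=group_id,
        n_seq=len(names),
        n_sites=3 * (min_codons or 0),
        pi_s=sum(ps_values) / len(ps_values),
        pi_n=sum(pn_values) / len(pn_values),
    )


# ---------------------------------------------------------------------------
# per-column amino-acid variability with region overlay
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionAnnotation:
    """Named 1-based inclusive intervals over amino-acid columns (e.g. the
    hypervariable regions HV2/HV3 of the stigma receptor ectodomain)."""

    intervals: tuple[tuple[str, int, int], ...]

    def covering(self, position: int) -> list[str]:
        return [name for name, start, end in self.intervals if start <= position <= end]

    def validate(self, n_columns: int) -> None:
        for name, start, end in self.intervals:
            if not (1 <= start <= end <= n_columns):
                raise DataError(f"region {name}: interval [{start},{end}] outside 1..{n_columns}")


def read_regions(path: str | Path) -> RegionAnnotation:
    """Read region annotations from 3-column text: name, start, end
    (whitespace-separated, 1-based inclusive)."""
    intervals = []
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 3:
            raise DataError(f"region line needs 3 columns: {raw!r}")
        intervals.append((parts[0], int(parts[1]), int(parts[2])))
    return RegionAnnotation(tuple(intervals))


def per_column_variability(
    alignment: CodonAlignment,
    regions: RegionAnnotation | None = None,
    table_id: int = 1,
) -> pd.DataFrame:
    """Distinct-residue count and residue frequencies per amino-acid column.

    Codons with gaps or Ns are masked (excluded from the column's counts);
    full-gap codons count as alignment gaps. Returns a table with 1-based
    ``position``, ``n_residues``, ``frequencies`` (residue -> fraction of
    scored sequences) and the covering region names.
    """
    code = genetic_code(table_id)
    n_codons = alignment.n_codons
    if regions is not None:
        regions.validate(n_codons)
    rows = []
    for col in range(n_codons):
        residues = []
        for _, seq in alignment.records:
            codon = seq[col * 3 : col * 3 + 3]
            if all(b in BASES for b in codon):
                residues.append(code[codon])
        counts: dict[str, int] = {}
        for aa in residues:
            counts[aa] = counts.get(aa, 0) + 1
        total = len(residues)
        rows.append(
            {
                "position": col + 1,
                "n_residues": len(counts),
                "frequencies": {aa: c / total for aa, c in sorted(counts.items())} if total else {},
                "regions": ";".join(regions.covering(col + 1)) if regions else "",
            }
        )
    return pd.DataFrame(rows, columns=["position", "n_residues", "frequencies", "regions"])


def plot_variability(table: pd.DataFrame, path: str | Path) -> None:
    """Bar plot of per-column distinct-residue counts (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(6, len(table) / 10), 3))
    ax.bar(table["position"], table["n_residues"], color="0.3", width=1.0)
    in_region = table[table["regions"] != ""]
    if len(in_region):
        ax.bar(in_region["position"], in_region["n_residues"], color="tab:red", width=1.0)
    ax.set_xlabel("alignment position (aa)")
    ax.set_ylabel("distinct residues")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
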