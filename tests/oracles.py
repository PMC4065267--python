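"""Independent brute-force oracles, kept separate from the library code.

The synonymous/nonsynonymous oracle re-derives everything from the raw
codon table by exhaustive enumeration (recursive pathway search, explicit
per-change site bookkeeping); it shares no code with
``silocus.diversity`` beyond Biopython's published code table.
"""

from __future__ import annotations

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]
AA = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    AA[_stop] = "*"
BASES = "ACGT"


def oracle_codon_sites(codon: str) -> tuple[float, float]:
    """Enumerate all nine single-base changes; 1/3 site each, stops dropped."""
    syn = nonsyn = 0.0
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if AA[mutant] == "*":
                continue
            if AA[mutant] == AA[codon]:
                syn += 1.0 / 3.0
            else:
                nonsyn += 1.0 / 3.0
    return syn, nonsyn


def _paths(codon_from: str, codon_to: str):
    """All stop-free minimal substitution pathways as lists of (syn?) steps."""
    if codon_from == codon_to:
        yield []
        return
    for pos in range(3):
        if codon_from[pos] != codon_to[pos]:
            step = codon_from[:pos] + codon_to[pos] + codon_from[pos + 1 :]
            if AA[step] == "*":
                continue
            for rest in _paths(step, codon_to):
                yield [AA[step] == AA[codon_from]] + rest


def oracle_codon_differences(codon_a: str, codon_b: str) -> tuple[float, float] | None:
    paths = list(_paths(codon_a, codon_b))
    if codon_a != codon_b and not paths:
        return None
    if codon_a == codon_b:
        return (0.0, 0.0)
    syn = sum(sum(1 for s in path if s) for path in paths) / len(paths)
    total = len(paths[0])
    return (syn, total - syn)


def oracle_pairwise(seq_a: str, seq_b: str) -> tuple[float, float, float, float]:
    """(syn diffs, nonsyn diffs, syn sites, nonsyn sites), complete-codon
    pairwise deletion, sites averaged between sequences."""
    sd = nd = ss = ns = 0.0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        if any(x not in BASES for x in ca + cb) or AA[ca] == "*" or AA[cb] == "*":
            continue
        diffs = oracle_codon_differences(ca, cb)
        if diffs is None:
            continue
        sa, na = oracle_codon_sites(ca)
        sb, nb = oracle_codon_sites(cb)
        ss += (sa + sb) / 2
        ns += (na + nb) / 2
        sd += diffs[0]
        nd += diffs[1]
    return sd, nd, ss, ns
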