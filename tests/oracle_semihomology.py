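"""Independent brute-force oracle for the codon-pair classification.

Enumerates every codon pair of two amino acids straight from Biopython's
codon tables, takes the minimum Hamming distance, and classifies
distance-1 pairs by the nucleotide exchange type.  Deliberately written
against the raw tables, not through the package's GeneticCode wrapper.
"""

from itertools import product

from Bio.Data import CodonTable

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def codons_of(aa: str, table_id: int) -> list[str]:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    return [c for c, a in table.forward_table.items() if a == aa]


def brute_force_class(a: str, b: str, table_id: int) -> str:
    """Return 'R', '#', '$' or '-' for a pair of standard amino acids."""
    if a == b:
        return "R"
    pairs = list(product(codons_of(a, table_id), codons_of(b, table_id)))
    dists = {}
    for c1, c2 in pairs:
        diff = [(x, y) for x, y in zip(c1, c2) if x != y]
        dists.setdefault(len(diff), []).append(diff)
    min_dist = min(dists)
    if min_dist >= 2:
        return "-"
    if any(diff[0] in TRANSITIONS for diff in dists[1]):
        return "#"
    return "$"
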