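"""Genetic-code tables keyed by NCBI translation table number.

Built-in tables come from Biopython's codon-table registry; additional
tables can be loaded from a plain two-column text file (codon, amino-acid
letter or ``*`` for stop).  Codons are handled in the DNA alphabet; ``U``
on input is normalized to ``T``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio.Data import CodonTable

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
STOP = "*"

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

_NUCLEOTIDES = "TCAG"
ALL_CODONS = tuple(a + b + c for a in _NUCLEOTIDES for b in _NUCLEOTIDES for c in _NUCLEOTIDES)

#: NCBI table ids shipped as built-ins.  1 = standard, 2 = vertebrate
#: mitochondrial (the code under which cytochrome b is actually encoded).
BUILTIN_TABLE_IDS = (1, 2)


class GeneticCodeError(ValueError):
    """Unknown table id or malformed custom table."""


def normalize_codon(codon: str) -> str:
    return codon.upper().replace("U", "T")


@dataclass(frozen=True)
class GeneticCode:
    """A complete 64-codon translation table.

    Parameters
    ----------
    table_id
        NCBI translation table number (0 for user-supplied tables without
        an official id).
    codon_to_aa
        Map from each of the 64 DNA triplets to a one-letter amino acid,
        or ``"*"`` for stop codons.
    """

    table_id: int
    codon_to_aa: dict[str, str] = field(repr=False)

    def __post_init__(self) -> None:
        if set(self.codon_to_aa) != set(ALL_CODONS):
            missing = set(ALL_CODONS) - set(self.codon_to_aa)
            extra = set(self.codon_to_aa) - set(ALL_CODONS)
            raise GeneticCodeError(
                f"table must cover exactly the 64 codons (missing {sorted(missing)!r}, "
                f"unexpected {sorted(extra)!r})"
            )
        bad = {aa for aa in self.codon_to_aa.values() if aa != STOP and aa not in STANDARD_AA}
        if bad:
            raise GeneticCodeError(f"non-standard amino-acid letters in table: {sorted(bad)!r}")

    @classmethod
    def from_ncbi_id(cls, table_id: int) -> "GeneticCode":
        """Build from Biopython's registry of NCBI translation tables."""
        try:
            table = CodonTable.unambiguous_dna_by_id[table_id]
        except KeyError:
            raise GeneticCodeError(f"unknown NCBI translation table id {table_id}") from None
        mapping = {c: STOP for c in table.stop_codons}
        mapping.update(table.forward_table)
        return cls(table_id=table_id, codon_to_aa={c: mapping[c] for c in ALL_CODONS})

    @classmethod
    def from_file(cls, path: str | Path, table_id: int = 0) -> "GeneticCode":
        """Load a custom table: one ``codon<whitespace>aa`` pair per line.

        Lines starting with ``#`` and blank lines are ignored.
        """
        mapping: dict[str, str] = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2 or len(parts[0]) != 3 or len(parts[1]) != 1:
                raise GeneticCodeError(f"{path}:{lineno}: expected 'codon aa', got {raw!r}")
            codon = normalize_codon(parts[0])
            if codon in mapping:
                raise GeneticCodeError(f"{path}:{lineno}: duplicate codon {codon}")
            mapping[codon] = parts[1].upper()
        return cls(table_id=table_id, codon_to_aa=mapping)

    def codons_for(self, aa: str) -> tuple[str, ...]:
        """All codons translating to ``aa`` (stop codons never included)."""
        return tuple(c for c, a in self.codon_to_aa.items() if a == aa and a != STOP)

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return tuple(c for c, a in self.codon_to_aa.items() if a == STOP)

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(c for c, a in self.codon_to_aa.items() if a != STOP)

    def translate(self, codon_seq: str) -> str:
        """Translate a codon string (length divisible by 3) to amino acids."""
        seq = normalize_codon(codon_seq)
        if len(seq) % 3:
            raise GeneticCodeError(f"codon sequence length {len(seq)} not divisible by 3")
        return "".join(self.codon_to_aa[seq[i : i + 3]] for i in range(0, len(seq), 3))


def get_genetic_code(table_id: int) -> GeneticCode:
    """Return a built-in genetic code by NCBI table id."""
    return GeneticCode.from_ncbi_id(table_id)


def is_transition(n1: str, n2: str) -> bool:
    """True for purine<->purine (A<->G) or pyrimidine<->pyrimidine (C<->T)."""
    return (n1 in PURINES and n2 in PURINES) or (n1 in PYRIMIDINES and n2 in PYRIMIDINES)
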