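"""Semihomologous (codon-aware) comparison of amino-acid sequences.

Two aligned residues are compared through their codon sets under a chosen
genetic code.  A position is classified as:

* ``R``  — homologous: the same amino acid on both sides;
* ``#``  — semihomologous via a transition: some codon of one residue turns
  into a codon of the other by a single A<->G or C<->T exchange;
* ``$``  — semihomologous via a transversion: a single-point codon path
  exists but only through purine<->pyrimidine exchanges;
* ``-``  — every codon pair differs at two or three nucleotide positions;
* positions involving a non-standard symbol (gaps, pads, ambiguity codes)
  are non-comparable and excluded from all denominators.

When both transition and transversion single-point paths exist the position
is classified ``#``: transitions are the more frequent point-mutation type,
which is the premise of the whole approach.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field

from .genetic_code import STANDARD_AA, GeneticCode, is_transition


class PairClass(enum.Enum):
    """Classification of one aligned amino-acid pair."""

    R = "R"
    TRANSITION = "#"
    TRANSVERSION = "$"
    MULTI = "-"
    NONCOMPARABLE = "?"

    @property
    def symbol(self) -> str:
        return self.value

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Characters tolerated in input sequences but never comparable.
NONSTANDARD_CHARS = frozenset("-XBZJUO*.")


class SemihomologyError(ValueError):
    pass


def _codon_pair_class(c1: str, c2: str) -> tuple[int, bool]:
    """(Hamming distance, is the single difference a transition?)."""
    diffs = [(a, b) for a, b in zip(c1, c2) if a != b]
    if len(diffs) == 1:
        return 1, is_transition(*diffs[0])
    return len(diffs), False


@dataclass(frozen=True)
class SemihomologyMatrix:
    """Symmetric lookup from unordered amino-acid pairs to :class:`PairClass`."""

    code: GeneticCode
    classes: dict[tuple[str, str], PairClass] = field(repr=False)

    def classify(self, a: str, b: str) -> PairClass:
        """Total classification of one residue pair.

        Non-standard symbols (including the pad character ``-``) yield
        ``NONCOMPARABLE``; never raises.
        """
        a, b = a.upper(), b.upper()
        if a not in STANDARD_AA or b not in STANDARD_AA:
            return PairClass.NONCOMPARABLE
        return self.classes[(a, b) if a <= b else (b, a)]


def build_semihomology_matrix(code: GeneticCode) -> SemihomologyMatrix:
    """Derive the R/#/$/- relation for all 20x20 standard pairs.

    For each unordered pair of distinct amino acids every codon pair
    (stop codons excluded) is enumerated.  If any pair differs at exactly
    one nucleotide the amino acids are semihomologous: ``#`` when at least
    one single-difference pair is a transition, ``$`` otherwise.  With no
    single-difference pair the class is ``-``.  Identical residues are
    always ``R``.
    """
    codon_sets = {aa: code.codons_for(aa) for aa in STANDARD_AA}
    empty = [aa for aa, cs in codon_sets.items() if not cs]
    if empty:
        raise SemihomologyError(
            f"amino acid(s) {''.join(empty)} have no codons under table {code.table_id}"
        )

    classes: dict[tuple[str, str], PairClass] = {}
    for aa in STANDARD_AA:
        classes[(aa, aa)] = PairClass.R
    for a, b in itertools.combinations(sorted(STANDARD_AA), 2):
        has_single = False
        has_transition = False
        for c1, c2 in itertools.product(codon_sets[a], codon_sets[b]):
            dist, ts = _codon_pair_class(c1, c2)
            if dist == 1:
                has_single = True
                if ts:
                    has_transition = True
                    break
        if not has_single:
            cls = PairClass.MULTI
        elif has_transition:
            cls = PairClass.TRANSITION
        else:
            cls = PairClass.TRANSVERSION
        classes[(a, b)] = cls
    return SemihomologyMatrix(code=code, classes=classes)


def classify_pair(a: str, b: str, matrix: SemihomologyMatrix) -> PairClass:
    """Look up the class of one residue pair (total function)."""
    return matrix.classify(a, b)


@dataclass(frozen=True)
class ComparisonProfile:
    """Per-position classes and summary statistics for one aligned pair.

    Percentages are taken over ``length_compared``, the number of positions
    where both symbols are standard amino acids.  ``ts_tv_factor`` is the
    ratio of ``#`` to ``$`` counts and is ``None`` (undefined) when the
    ``$`` count is zero.
    """

    per_position: tuple[PairClass, ...]
    length_compared: int
    counts: dict[str, int]
    pct_R: float
    pct_semihomologous: float
    pct_multi: float
    ts_tv_factor: float | None


def compare_sequences(s1: str, s2: str, matrix: SemihomologyMatrix) -> ComparisonProfile:
    """Position-by-position semihomologous comparison of two equal-length sequences."""
    if len(s1) != len(s2):
        raise SemihomologyError(f"sequence lengths differ: {len(s1)} vs {len(s2)}")
    per_position = tuple(matrix.classify(a, b) for a, b in zip(s1, s2))
    counts = {"R": 0, "#": 0, "$": 0, "-": 0}
    for cls in per_position:
        if cls is not PairClass.NONCOMPARABLE:
            counts[cls.symbol] += 1
    n = sum(counts.values())
    if n:
        pct_r = 100.0 * counts["R"] / n
        pct_semi = 100.0 * (counts["#"] + counts["$"]) / n
        pct_multi = 100.0 * counts["-"] / n
    else:
        pct_r = pct_semi = pct_multi = float("nan")
    ts_tv = counts["#"] / counts["$"] if counts["$"] else None
    return ComparisonProfile(
        per_position=per_position,
        length_compared=n,
        counts=counts,
        pct_R=pct_r,
        pct_semihomologous=pct_semi,
        pct_multi=pct_multi,
        ts_tv_factor=ts_tv,
    )


@dataclass(frozen=True)
class DotMatrix:
    """All-against-all residue classification of two sequences."""

    seq1: str
    seq2: str
    cells: tuple[tuple[PairClass, ...], ...]  # cells[i][j] = class(seq1[i], seq2[j])

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.seq1), len(self.seq2)

    def render(self) -> str:
        """Text grid, one row per residue of seq1; ``.`` marks - and non-comparable."""
        visible = {PairClass.R: "R", PairClass.TRANSITION: "#", PairClass.TRANSVERSION: "$"}
        return "\n".join(
            "".join(visible.get(cell, ".") for cell in row) for row in self.cells
        )

    def to_long_records(self) -> list[tuple[int, int, str]]:
        """(i, j, class-symbol) triples, 1-based coordinates."""
        return [
            (i + 1, j + 1, cell.symbol)
            for i, row in enumerate(self.cells)
            for j, cell in enumerate(row)
        ]


def dot_matrix(s1: str, s2: str, matrix: SemihomologyMatrix) -> DotMatrix:
    """Full cross-product classification of two sequences (may be empty)."""
    cells = tuple(
        tuple(matrix.classify(a, b) for b in s2) for a in s1
    )
    return DotMatrix(seq1=s1, seq2=s2, cells=cells)
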