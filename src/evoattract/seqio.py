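"""Sequence and group-table I/O plus length normalization.

Protein sequences travel as FASTA (read/written through Biopython); group
assignments as a TSV with columns ``organism_id``, ``group``, ``role`` and
optionally ``is_reference``.  Sequences are normalized to the fixed network
input length by padding with ``-`` at the end or truncating — no alignment
is ever performed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

PAD_CHAR = "-"
DEFAULT_LENGTH = 400

ROLES = ("teach", "examine")


class SeqIOError(ValueError):
    pass


@dataclass(frozen=True)
class SequenceRecord:
    """One named amino-acid sequence.

    ``teaching_index`` is the 1-based position in the teaching set and hence
    the output-neuron assignment; ``None`` for examined-only organisms.
    """

    id: str
    residues: str
    teaching_index: int | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqIOError("sequence id must be nonempty")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read protein FASTA; uppercases residues and strips terminal ``*``.

    Record order is preserved (it defines teaching order for teaching sets).
    """
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise SeqIOError(
                    f"{path}:{lineno}: expected FASTA header '>' before sequence data"
                )
            break
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper().rstrip("*")
        records.append(SequenceRecord(id=rec.id, residues=residues))
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path) -> None:
    bio = [
        BioSeqRecord(Seq(r.residues), id=r.id, description="") for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def pad_or_trim(residues: str, target_length: int = DEFAULT_LENGTH) -> str:
    """Pad with ``-`` at the end or cut so the result has exactly ``target_length``."""
    if target_length < 1:
        raise SeqIOError(f"target_length must be >= 1, got {target_length}")
    if len(residues) >= target_length:
        return residues[:target_length]
    return residues + PAD_CHAR * (target_length - len(residues))


@dataclass(frozen=True)
class GroupRow:
    organism_id: str
    group: str
    role: str
    is_reference: bool = False


@dataclass(frozen=True)
class GroupTable:
    """Organism -> attractor-group assignment with teach/examine roles."""

    rows: tuple[GroupRow, ...]

    def __post_init__(self) -> None:
        ids = [r.organism_id for r in self.rows]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise SeqIOError(f"duplicate organism id(s): {', '.join(dupes)}")
        bad_roles = sorted({r.role for r in self.rows} - set(ROLES))
        if bad_roles:
            raise SeqIOError(
                f"unknown role(s) {', '.join(bad_roles)}; must be one of {'/'.join(ROLES)}"
            )

    @property
    def group_names(self) -> tuple[str, ...]:
        """Group names in order of first appearance."""
        seen: dict[str, None] = {}
        for r in self.rows:
            seen.setdefault(r.group, None)
        return tuple(seen)

    def members_of(self, group: str) -> tuple[str, ...]:
        return tuple(r.organism_id for r in self.rows if r.group == group)

    @property
    def reference_id(self) -> str:
        """The unique reference organism; error when zero or several are flagged."""
        refs = [r.organism_id for r in self.rows if r.is_reference]
        if len(refs) != 1:
            raise SeqIOError(
                "exactly one reference organism required, found "
                f"{len(refs)}: {', '.join(refs) or '(none)'}"
            )
        return refs[0]


def read_group_table(path: str | Path) -> GroupTable:
    """Read and validate the TSV group table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"organism_id", "group", "role"}
    missing = required - set(df.columns)
    if missing:
        raise SeqIOError(f"{path}: missing column(s) {', '.join(sorted(missing))}")
    if "is_reference" not in df.columns:
        df["is_reference"] = "0"
    truthy = {"1", "true", "yes"}
    rows = tuple(
        GroupRow(
            organism_id=str(r.organism_id),
            group=str(r.group),
            role=str(r.role),
            is_reference=str(r.is_reference).strip().lower() in truthy,
        )
        for r in df.itertuples(index=False)
    )
    return GroupTable(rows=rows)


def write_group_table(table: GroupTable, path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "organism_id": r.organism_id,
                "group": r.group,
                "role": r.role,
                "is_reference": int(r.is_reference),
            }
            for r in table.rows
        ]
    )
    df.to_csv(path, sep="\t", index=False)
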