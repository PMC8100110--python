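"""Synthetic codon-level sequence families with controlled divergence.

Families emulate what the real study data look like: groups of ~400-residue
proteins descended from a common codon ancestor, each group at its own
divergence from the ancestor, mutated by a two-parameter point process with
a tunable transition/transversion rate ratio (kappa).  Descent is a star
phylogeny — every member evolves independently from the ancestor — with no
indels, selection or rate heterogeneity, which keeps the realized
divergence of every member exactly known.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genetic_code import GeneticCode, get_genetic_code
from .seqio import SequenceRecord

_TRANSITION_OF = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS_OF = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class GroupSpec:
    name: str
    n_members: int
    substitutions_per_site: float

    def __post_init__(self) -> None:
        if self.n_members < 1:
            raise SyntheticError(f"group {self.name!r}: n_members must be >= 1")
        if self.substitutions_per_site < 0:
            raise SyntheticError(f"group {self.name!r}: divergence must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic family.

    ``substitutions_per_site`` is the expected number of attempted point
    substitutions per nucleotide site; ``kappa`` is the rate ratio of the
    one transition to each of the two transversions a site can undergo
    (kappa = 1 means all three changes equally likely).
    """

    groups: tuple[GroupSpec, ...]
    n_codons: int = 400
    kappa: float = 2.0
    table_id: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_codons < 1:
            raise SyntheticError("n_codons must be >= 1")
        if self.kappa < 0:
            raise SyntheticError("kappa must be >= 0")
        if not self.groups:
            raise SyntheticError("at least one group required")


@dataclass(frozen=True)
class SyntheticFamily:
    """One simulated family: codon ancestor plus translated descendants."""

    ancestor_codons: str
    reference: SequenceRecord  # translated ancestor
    members: tuple[SequenceRecord, ...]
    group_of: dict[str, str]  # member id -> group name
    true_divergences: dict[str, int]  # member id -> realized substitution events


def random_ancestor(n_codons: int, code: GeneticCode, seed: int) -> str:
    """Uniformly random sense-codon (never stop) sequence, deterministic per seed."""
    if n_codons < 1:
        raise SyntheticError("n_codons must be >= 1")
    rng = np.random.default_rng(seed)
    sense = code.sense_codons
    return "".join(sense[i] for i in rng.integers(0, len(sense), size=n_codons))


def evolve_member(
    ancestor: str,
    substitutions_per_site: float,
    kappa: float,
    code: GeneticCode,
    seed: int,
) -> tuple[str, int]:
    """Mutate a codon sequence by random point substitutions.

    The number of events is Poisson with mean ``substitutions_per_site``
    times the number of nucleotide sites.  Each event picks a site
    uniformly and proposes a transition with probability kappa/(kappa+2),
    else one of the two transversions; an event that would create a stop
    codon is resampled.  Returns the mutated codon string and the realized
    event count.
    """
    rng = np.random.default_rng(seed)
    n_sites = len(ancestor)
    if n_sites % 3:
        raise SyntheticError("ancestor length must be divisible by 3")
    seq = list(ancestor)
    n_events = int(rng.poisson(substitutions_per_site * n_sites))
    p_transition = kappa / (kappa + 2.0) if kappa + 2.0 > 0 else 0.0
    realized = 0
    while realized < n_events:
        site = int(rng.integers(0, n_sites))
        old = seq[site]
        if rng.random() < p_transition:
            new = _TRANSITION_OF[old]
        else:
            new = _TRANSVERSIONS_OF[old][int(rng.integers(0, 2))]
        codon_start = site - site % 3
        codon = seq[codon_start : codon_start + 3]
        codon[site % 3] = new
        if code.codon_to_aa["".join(codon)] == "*":
            continue  # resample: a path through a stop is not allowed
        seq[site] = new
        realized += 1
    return "".join(seq), realized


def generate_family(config: SimulationConfig) -> SyntheticFamily:
    """One ancestor plus, per group, independent descendants at that group's divergence."""
    code = get_genetic_code(config.table_id)
    ss = np.random.SeedSequence(config.seed)
    anc_seed, *member_seeds = [
        int(c.generate_state(1)[0] % 2**31)
        for c in ss.spawn(1 + sum(g.n_members for g in config.groups))
    ]
    ancestor = random_ancestor(config.n_codons, code, anc_seed)
    members: list[SequenceRecord] = []
    group_of: dict[str, str] = {}
    true_div: dict[str, int] = {}
    seed_iter = iter(member_seeds)
    for spec in config.groups:
        for i in range(1, spec.n_members + 1):
            codons, realized = evolve_member(
                ancestor, spec.substitutions_per_site, config.kappa, code, next(seed_iter)
            )
            member_id = f"{spec.name}_{i}"
            members.append(SequenceRecord(id=member_id, residues=code.translate(codons)))
            group_of[member_id] = spec.name
            true_div[member_id] = realized
    return SyntheticFamily(
        ancestor_codons=ancestor,
        reference=SequenceRecord(id="ancestor", residues=code.translate(ancestor)),
        members=tuple(members),
        group_of=group_of,
        true_divergences=true_div,
    )
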