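"""Group-level attractor analysis.

A "genome attractor" is represented operationally as a named group of
organisms whose recognition vectors (ensemble similarities to the teaching
organisms) cluster together.  This module computes:

* per-group semihomologous characteristics — means of %R, %(#+$), %(-) and
  the #/$ factor over members, each compared against a common reference
  organism;
* orbit geometry — each group sits on an orbit around the reference at
  radius 1 / (mean similarity to the reference output); the distance factor
  between consecutive orbits is the ratio of the outer to the inner radius,
  which equals the inverse ratio of the mean similarities and is therefore
  scale-invariant;
* disturbances — the pull a group feels toward teaching organisms outside
  its own lineage, measured as the group's mean similarity at those outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .semihomology import ComparisonProfile


class AttractorError(ValueError):
    pass


@dataclass(frozen=True)
class AttractorGroup:
    """A named organism set with recognition vectors and (optionally) profiles."""

    name: str
    member_ids: tuple[str, ...]
    member_similarities: np.ndarray | None = None  # (n_members, k)
    member_profiles: tuple[ComparisonProfile, ...] | None = None

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise AttractorError(f"group {self.name!r} is empty")
        if (
            self.member_similarities is not None
            and len(self.member_similarities) != len(self.member_ids)
        ):
            raise AttractorError(f"group {self.name!r}: similarity rows != members")
        if self.member_profiles is not None and len(self.member_profiles) != len(self.member_ids):
            raise AttractorError(f"group {self.name!r}: profiles != members")


@dataclass(frozen=True)
class GroupCharacteristics:
    """Semihomologous averages over the members of one attractor group."""

    group: str
    avg_R: float
    avg_semihomologous: float
    avg_multi: float
    avg_ts_tv: float | None  # undefined #/$ factors excluded; None if all undefined


def group_characteristics(group: AttractorGroup) -> GroupCharacteristics:
    """Arithmetic means of the member comparison profiles vs. the reference."""
    if not group.member_profiles:
        raise AttractorError(f"group {group.name!r} has no comparison profiles")
    profiles = group.member_profiles
    ts_tv = [p.ts_tv_factor for p in profiles if p.ts_tv_factor is not None]
    return GroupCharacteristics(
        group=group.name,
        avg_R=float(np.mean([p.pct_R for p in profiles])),
        avg_semihomologous=float(np.mean([p.pct_semihomologous for p in profiles])),
        avg_multi=float(np.mean([p.pct_multi for p in profiles])),
        avg_ts_tv=float(np.mean(ts_tv)) if ts_tv else None,
    )


@dataclass(frozen=True)
class OrbitReport:
    """Orbit radii and consecutive distance factors, nearest group first."""

    group_names: tuple[str, ...]
    mean_similarities: tuple[float, ...]  # to the reference output
    radii: tuple[float, ...]
    distance_factors: tuple[float, ...]  # len = n_groups - 1; outer/inner, >= 1


def orbit_radii(
    groups: list[AttractorGroup],
    ref_output_index: int,
    rtol: float = 1e-9,
) -> OrbitReport:
    """Orbit geometry for groups ordered nearest to farthest from the reference.

    Group similarity is the mean member similarity at ``ref_output_index``;
    the orbit radius is its reciprocal, and consecutive distance factors are
    ratios radius(farther)/radius(nearer).  The given order must be
    consistent with the radii (factors >= 1 up to ``rtol``).
    """
    sims = []
    for g in groups:
        if g.member_similarities is None:
            raise AttractorError(f"group {g.name!r} has no recognition vectors")
        if not 0 <= ref_output_index < g.member_similarities.shape[1]:
            raise AttractorError(f"reference output index {ref_output_index} out of range")
        s = float(np.mean(g.member_similarities[:, ref_output_index]))
        if s <= 0:
            raise AttractorError(
                f"group {g.name!r} has zero mean similarity to the reference output"
            )
        sims.append(s)
    radii = [1.0 / s for s in sims]
    factors = []
    for inner, outer, g in zip(radii, radii[1:], groups[1:]):
        factor = outer / inner
        if factor < 1.0 - rtol:
            raise AttractorError(
                f"group order inconsistent with radii at {g.name!r}: "
                f"distance factor {factor:.6g} < 1"
            )
        factors.append(factor)
    return OrbitReport(
        group_names=tuple(g.name for g in groups),
        mean_similarities=tuple(sims),
        radii=tuple(radii),
        distance_factors=tuple(factors),
    )


@dataclass(frozen=True)
class DisturbanceReport:
    """Teaching organisms ranked by the pull they exert on one group."""

    group: str
    ranking: tuple[tuple[str, float], ...]  # (teaching id, mean similarity), descending


def disturbances(
    group: AttractorGroup,
    teaching_ids: tuple[str, ...],
    exclude_outputs: frozenset[str] | set[str] = frozenset(),
    top_k: int | None = None,
) -> DisturbanceReport:
    """Rank non-lineage teaching outputs by the group's mean similarity there.

    ``exclude_outputs`` names the teaching organisms belonging to the
    group's own lineage; ties rank in teaching order.
    """
    if group.member_similarities is None:
        raise AttractorError(f"group {group.name!r} has no recognition vectors")
    if group.member_similarities.shape[1] != len(teaching_ids):
        raise AttractorError("similarity width != number of teaching organisms")
    unknown = set(exclude_outputs) - set(teaching_ids)
    if unknown:
        raise AttractorError(f"excluded ids not in teaching set: {', '.join(sorted(unknown))}")
    means = np.mean(group.member_similarities, axis=0)
    entries = [
        (tid, float(means[i]))
        for i, tid in enumerate(teaching_ids)
        if tid not in exclude_outputs
    ]
    if not entries:
        raise AttractorError(f"all teaching outputs excluded for group {group.name!r}")
    entries.sort(key=lambda e: -e[1])  # stable: ties keep teaching order
    if top_k is not None:
        entries = entries[:top_k]
    return DisturbanceReport(group=group.name, ranking=tuple(entries))
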