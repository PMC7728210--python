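"""Closest-cell-type assignment of a query sample by Ward set distance.

A query sample ζ (e.g. a leukemic patient sample, binarized at the same
(M_cut, p_G) as the reference cohort) is compared against every reference
cell type ν by the Ward set distance H_Ward({ζ}, S_ν).  Sorting the types by
this distance yields the type ranking ν^(1), ν^(2), …; the rank gap of a
reference type T0 is q - 1 where T0 = ν^(q), so rank gap 0 means T0 is the
closest type.  Only the distances involving ζ are newly computed — the
reference pairwise distances are reused from a cached matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

from .clustering import set_distance_ward
from .hamming import DistanceMatrix, distance_matrix
from .penalty import LabeledCohort
from .ranking import BinaryTrack

__all__ = ["TypeRanking", "type_distances", "closest_types", "rank_gap", "classify_sample"]


@dataclass(frozen=True)
class TypeRanking:
    """Reference types ordered by ascending Ward distance to the query."""

    query: str
    types: tuple[str, ...]
    distances: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.types) != len(set(self.types)):
            raise ValueError("each type must be ranked exactly once")
        if any(a > b for a, b in zip(self.distances, self.distances[1:])):
            raise ValueError("distances must be non-decreasing along the ranking")

    def rank_of(self, type_label: str) -> int:
        """1-based rank q of a type in the ordering."""
        try:
            return self.types.index(type_label) + 1
        except ValueError:
            raise ValueError(f"type {type_label!r} not in ranking") from None


def type_distances(
    query_track: BinaryTrack,
    reference_tracks: Mapping[str, BinaryTrack],
    cohort: LabeledCohort,
    query_id: str = "query",
    base: DistanceMatrix | None = None,
) -> dict[str, float]:
    """H_Ward({ζ}, S_ν) for every reference type ν.

    ``base`` may hold the cached pairwise distances among reference samples;
    only the distances between the query and each reference are computed.
    Empty reference types are skipped with a warning.
    """
    if query_id in reference_tracks:
        raise ValueError(f"query id {query_id!r} collides with a reference sample")
    tracks = dict(reference_tracks)
    tracks[query_id] = query_track
    d = distance_matrix(tracks, metric="hamming", base=base)
    out: dict[str, float] = {}
    for nu in cohort.types:
        members = sorted(cohort.members(nu))
        if not members:
            warnings.warn(f"reference type {nu!r} has no samples; skipped")
            continue
        out[nu] = set_distance_ward([query_id], members, d)
    return out


def closest_types(distances: Mapping[str, float], query_id: str = "query") -> TypeRanking:
    """Rank types by ascending distance; ties broken alphabetically."""
    if not distances:
        raise ValueError("empty distance mapping")
    ordered = sorted(distances.items(), key=lambda kv: (kv[1], kv[0]))
    return TypeRanking(
        query_id,
        tuple(t for t, _ in ordered),
        tuple(float(v) for _, v in ordered),
    )


def rank_gap(ranking: TypeRanking, T0: str) -> int:
    """q - 1 where the reference type T0 is the q-th closest type."""
    return ranking.rank_of(T0) - 1


def classify_sample(
    query_track: BinaryTrack,
    reference_tracks: Mapping[str, BinaryTrack],
    cohort: LabeledCohort,
    query_id: str = "query",
    base: DistanceMatrix | None = None,
    expected_type: str | None = None,
) -> tuple[TypeRanking, int | None]:
    """Full query classification: type ranking plus optional rank gap.

    Returns ``(ranking, gap)`` where ``gap`` is the rank gap against
    ``expected_type`` (None when no expectation is given).  Queries are
    processed independently: reference distances are never modified.
    """
    dist = type_distances(query_track, reference_tracks, cohort, query_id, base)
    ranking = closest_types(dist, query_id)
    gap = rank_gap(ranking, expected_type) if expected_type is not None else None
    return ranking, gap
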