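"""Pairwise distances between binary genome tracks.

The Hamming distance between two samples' binary tracks is the number of
genomic positions at which the indicators differ.  It is computed exactly by
inclusion–exclusion on interval lengths,

    H(a, b) = covered(a) + covered(b) - 2 * covered(a ∩ b),

with the intersection length obtained from a sorted sweep over interval
endpoints, so genome-length vectors are never materialized.  Distances are
exact integers (bp); no floating point enters before linkage.

The Dice coefficient 2|a∩b| / (|a|+|b|) is provided as an alternative
similarity; the clustering engine consumes its dissimilarity ``1 - Dice``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .ranking import BinaryTrack

__all__ = [
    "intersection_length",
    "hamming_distance",
    "dice_coefficient",
    "DistanceMatrix",
    "distance_matrix",
]


def _chrom_intersection(a: np.ndarray, b: np.ndarray) -> int:
    """Length of the intersection of two disjoint sorted interval lists."""
    if len(a) == 0 or len(b) == 0:
        return 0
    # Endpoint sweep: +1 at each start, -1 just past each (inclusive) end;
    # positions where the running depth is 2 lie in both supports.
    pos = np.concatenate([a[:, 0], b[:, 0], a[:, 1] + 1, b[:, 1] + 1])
    delta = np.concatenate(
        [np.ones(len(a) + len(b), dtype=np.int64),
         -np.ones(len(a) + len(b), dtype=np.int64)]
    )
    order = np.argsort(pos, kind="stable")
    pos, delta = pos[order], delta[order]
    depth = np.cumsum(delta)
    both = depth[:-1] == 2
    return int(np.sum((pos[1:] - pos[:-1])[both]))


def _check_same_layout(a: BinaryTrack, b: BinaryTrack) -> None:
    if a.layout.lengths != b.layout.lengths:
        raise ValueError("tracks are defined on different genome layouts")


def intersection_length(a: BinaryTrack, b: BinaryTrack) -> int:
    """Number of positions covered by both tracks."""
    _check_same_layout(a, b)
    return sum(
        _chrom_intersection(a.chrom_intervals(c), b.chrom_intervals(c))
        for c in a.layout.chromosomes
    )


def hamming_distance(a: BinaryTrack, b: BinaryTrack) -> int:
    """Number of genomic positions where the two binary tracks differ (bp)."""
    _check_same_layout(a, b)
    return a.covered_length + b.covered_length - 2 * intersection_length(a, b)


def dice_coefficient(a: BinaryTrack, b: BinaryTrack) -> float:
    """Overlap similarity ``2|a∩b| / (|a| + |b|)`` in [0, 1]."""
    _check_same_layout(a, b)
    total = a.covered_length + b.covered_length
    if total == 0:
        raise ValueError("Dice coefficient undefined: both tracks are empty")
    return 2.0 * intersection_length(a, b) / total


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise sample distances with their parameter provenance."""

    ids: tuple[str, ...]
    values: np.ndarray
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise ValueError("duplicate sample ids")
        if values.shape != (n, n):
            raise ValueError(f"matrix shape {values.shape} != ({n}, {n})")
        if not np.array_equal(values, values.T):
            raise ValueError("matrix is not symmetric")
        if np.any(np.diag(values) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(values < 0):
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "metadata", dict(self.metadata))

    @property
    def n_samples(self) -> int:
        return len(self.ids)

    def value(self, i: str, j: str) -> float:
        a, b = self.ids.index(i), self.ids.index(j)
        v = self.values[a, b]
        return int(v) if np.issubdtype(self.values.dtype, np.integer) else float(v)

    def to_tsv(self, path: str | os.PathLike) -> None:
        pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids)).to_csv(
            path, sep="\t"
        )

    @classmethod
    def from_tsv(cls, path: str | os.PathLike, **metadata) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(tuple(str(c) for c in df.columns), df.to_numpy(), metadata)

    def to_phylip(self, path: str | os.PathLike) -> None:
        """Lower-triangle PHYLIP distance format for interoperability."""
        with open(path, "w") as fh:
            fh.write(f"{self.n_samples}\n")
            for i, sid in enumerate(self.ids):
                row = "\t".join(str(self.values[i, j]) for j in range(i))
                fh.write(f"{sid}\t{row}\n" if row else f"{sid}\n")


def distance_matrix(
    tracks: Mapping[str, BinaryTrack],
    metric: str = "hamming",
    base: DistanceMatrix | None = None,
    **metadata,
) -> DistanceMatrix:
    """All-pairs distance matrix over a cohort of binary tracks.

    With ``base`` given (a matrix over a subset of ``tracks`` computed with
    the same metric and parameters), only the pairs involving new samples are
    computed and the existing entries are copied untouched — adding one
    sample to a cohort of N costs N distance evaluations, not N^2.
    """
    if metric == "hamming":
        func, dtype = hamming_distance, np.int64
    elif metric == "dice":
        def func(a, b):  # dissimilarity form for clustering
            return 1.0 - dice_coefficient(a, b)

        dtype = np.float64
    else:
        raise ValueError(f"unknown metric {metric!r}")

    ids = tuple(tracks)
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate sample ids")
    n = len(ids)
    values = np.zeros((n, n), dtype=dtype)

    known: dict[frozenset, object] = {}
    if base is not None:
        if base.metadata.get("metric", metric) != metric:
            raise ValueError("base matrix was computed with a different metric")
        missing = set(base.ids) - set(ids)
        if missing:
            raise ValueError(f"base matrix has samples not in tracks: {missing}")
        for i, a in enumerate(base.ids):
            for j in range(i + 1, base.n_samples):
                known[frozenset((a, base.ids[j]))] = base.values[i, j]

    for i in range(n):
        for j in range(i + 1, n):
            key = frozenset((ids[i], ids[j]))
            d = known[key] if key in known else func(tracks[ids[i]], tracks[ids[j]])
            values[i, j] = values[j, i] = d
    return DistanceMatrix(ids, values, {"metric": metric, **metadata})
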