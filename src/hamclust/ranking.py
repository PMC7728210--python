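"""Peak ranking, rank truncation and interval-backed genome binarization.

A sample's peaks are sorted by ascending p-value (descending ``-log10 p``),
truncated to the ``M_cut`` most significant, and turned into a binary genome
track: the indicator of whether each position lies inside a retained peak.
The track is stored as disjoint sorted intervals per chromosome — never as a
genome-length 0/1 vector, which would be infeasible at ~3e9 bp.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genome import BoundsError, GenomeLayout, Peak

__all__ = ["RankedPeakSet", "BinaryTrack", "rank_peaks", "truncate", "binarize"]


@dataclass(frozen=True)
class RankedPeakSet:
    """Peaks ordered by ascending p-value, with the calling threshold p_G.

    The order index ``k`` (0-based here) satisfies ``p_k <= p_k'`` for
    ``k < k'``; ties are broken by genomic coordinate so the ranking is
    deterministic across runs and platforms.
    """

    peaks: tuple[Peak, ...]
    p_G: float = 1.0

    def __post_init__(self) -> None:
        scores = [p.neg_log10_p for p in self.peaks]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ValueError("peaks are not sorted by descending -log10 p")
        min_score = -math.log10(self.p_G) if 0 < self.p_G < 1 else 0.0
        if scores and scores[-1] < min_score - 1e-9:
            raise ValueError(
                f"peak p-value exceeds calling threshold p_G={self.p_G}"
            )

    def __len__(self) -> int:
        return len(self.peaks)


def rank_peaks(
    peaks: Sequence[Peak],
    layout: GenomeLayout | None = None,
    p_G: float = 1.0,
) -> RankedPeakSet:
    """Sort peaks by ascending p-value into a :class:`RankedPeakSet`.

    Sort key: ``-log10 p`` descending, then chromosome (layout order when a
    layout is given, else label order), then start, then end.
    """
    if layout is not None:
        chrom_key = {c: i for i, c in enumerate(layout.chromosomes)}

        def key(p: Peak):
            return (-p.neg_log10_p, chrom_key[p.chrom], p.start, p.end)

    else:

        def key(p: Peak):
            return (-p.neg_log10_p, p.chrom, p.start, p.end)

    return RankedPeakSet(tuple(sorted(peaks, key=key)), p_G=p_G)


def truncate(ranked: RankedPeakSet, M_cut: int | float) -> RankedPeakSet:
    """Keep the first ``min(M_cut, M)`` peaks; ``M_cut = math.inf`` keeps all."""
    if M_cut != math.inf:
        if not float(M_cut).is_integer() or M_cut <= 0:
            raise ValueError(f"M_cut must be a positive integer or inf, got {M_cut}")
        return RankedPeakSet(ranked.peaks[: int(M_cut)], p_G=ranked.p_G)
    return ranked


@dataclass(frozen=True)
class BinaryTrack:
    """Support of the binary accessibility indicator, as merged intervals.

    ``intervals[chrom]`` is an ``(n, 2)`` int64 array of 1-based inclusive
    ``[start, end]`` rows, sorted and pairwise disjoint with no two intervals
    adjacent (``[a,b]`` and ``[b+1,c]`` are merged), so the representation of
    a pointwise indicator is canonical.
    """

    layout: GenomeLayout
    intervals: Mapping[str, np.ndarray]
    M_cut: float = math.inf

    def __post_init__(self) -> None:
        canon: dict[str, np.ndarray] = {}
        for chrom, arr in self.intervals.items():
            arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
            if arr.size:
                if np.any(arr[:, 0] > arr[:, 1]):
                    raise ValueError(f"start > end in track intervals on {chrom}")
                if np.any(np.diff(arr[:, 0]) < 0):
                    raise ValueError(f"track intervals not sorted on {chrom}")
                if np.any(arr[1:, 0] <= arr[:-1, 1] + 1):
                    raise ValueError(
                        f"track intervals overlap or abut on {chrom}; "
                        "use binarize() to build canonical tracks"
                    )
                canon[chrom] = arr
        object.__setattr__(self, "intervals", canon)

    @property
    def covered_length(self) -> int:
        """Total number of positions with indicator 1."""
        return int(
            sum((a[:, 1] - a[:, 0] + 1).sum() for a in self.intervals.values())
        )

    def chrom_intervals(self, chrom: str) -> np.ndarray:
        return self.intervals.get(chrom, np.empty((0, 2), dtype=np.int64))

    def to_bed(self, path: str | os.PathLike) -> None:
        """Write the support as sorted 3-column BED (0-based half-open)."""
        with open(path, "w") as fh:
            for chrom in self.layout.chromosomes:
                for start, end in self.chrom_intervals(chrom):
                    fh.write(f"{chrom}\t{start - 1}\t{end}\n")


def _merge_sorted(arr: np.ndarray) -> np.ndarray:
    """Merge overlapping/adjacent intervals of a start-sorted (n,2) array."""
    if len(arr) == 0:
        return arr
    out_start = [arr[0, 0]]
    out_end = [arr[0, 1]]
    for s, e in arr[1:]:
        if s <= out_end[-1] + 1:
            if e > out_end[-1]:
                out_end[-1] = e
        else:
            out_start.append(s)
            out_end.append(e)
    return np.column_stack([out_start, out_end]).astype(np.int64)


def binarize(ranked: RankedPeakSet | Iterable[Peak], layout: GenomeLayout) -> BinaryTrack:
    """Union the retained peak intervals into a canonical binary track."""
    peaks = ranked.peaks if isinstance(ranked, RankedPeakSet) else tuple(ranked)
    M_cut = len(peaks) if isinstance(ranked, RankedPeakSet) else math.inf
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        if p.chrom not in layout:
            raise BoundsError(f"peak chromosome {p.chrom!r} not in layout")
        if p.end > layout.length(p.chrom):
            raise BoundsError(
                f"peak [{p.start},{p.end}] outside {p.chrom} "
                f"(length {layout.length(p.chrom)})"
            )
        per_chrom.setdefault(p.chrom, []).append((p.start, p.end))
    intervals = {}
    for chrom, ivs in per_chrom.items():
        arr = np.array(sorted(ivs), dtype=np.int64)
        intervals[chrom] = _merge_sorted(arr)
    return BinaryTrack(layout, intervals, M_cut=float(M_cut))
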