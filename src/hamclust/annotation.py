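"""Functional-annotation composition of ranked peaks in rank windows.

Peaks are taken in rank order and grouped into consecutive windows of 1000;
within each window the fraction of peaks whose center lies inside each
chromatin-state interval of a segmentation is recorded.  A peak with center
(start + end)/2 belongs to state y when some state interval [σ, ε] satisfies
σ ≤ (start + end)/2 ≤ ε; the test is done on integers as
2σ ≤ start + end ≤ 2ε, so half-integer centers need no rounding convention.
Fractions always use the window size as denominator.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import ChromSegmentation
from .penalty import LabeledCohort
from .ranking import RankedPeakSet

__all__ = ["AnnotationProfile", "annotation_profile", "aggregate_profiles"]


@dataclass(frozen=True)
class AnnotationProfile:
    """Per-(window, state) peak-center fractions for one sample.

    ``table`` has columns ``window_start`` (1-based start rank of the
    window), ``state`` and ``fraction``.
    """

    sample_id: str
    window: int
    table: pd.DataFrame

    def fraction(self, window_start: int, state: str) -> float:
        sel = self.table[
            (self.table.window_start == window_start) & (self.table.state == state)
        ]
        return float(sel.fraction.iloc[0]) if len(sel) else 0.0


def _center_state_counts(
    peaks, seg: ChromSegmentation
) -> dict[str, int]:
    counts = {state: 0 for state in seg.states}
    for state in seg.states:
        per_chrom = seg.intervals[state]
        for p in peaks:
            ivs = per_chrom.get(p.chrom)
            if not ivs:
                continue
            s2 = p.start + p.end  # = 2 * center
            # first interval with 2*end >= s2
            idx = bisect_left([2 * e for _, e in ivs], s2)
            if idx < len(ivs) and 2 * ivs[idx][0] <= s2:
                counts[state] += 1
    return counts


def annotation_profile(
    ranked: RankedPeakSet,
    seg: ChromSegmentation,
    window: int = 1000,
    n_windows: int = 80,
    sample_id: str = "sample",
) -> AnnotationProfile:
    """Fractions of peak centers per chromatin state in 1000-peak rank windows.

    Window j (1-based) covers ranks ``1 + (j-1)·window`` to ``j·window``.
    Windows that would run past the available peaks are dropped (a sample
    with fewer than ``window`` peaks yields an empty profile).
    """
    if window <= 0:
        raise ValueError(f"window must be positive, got {window}")
    rows = []
    n_full = min(n_windows, len(ranked.peaks) // window)
    for j in range(n_full):
        start_rank = 1 + j * window
        chunk = ranked.peaks[j * window : (j + 1) * window]
        for state, count in _center_state_counts(chunk, seg).items():
            rows.append(
                {"window_start": start_rank, "state": state, "fraction": count / window}
            )
    table = pd.DataFrame(rows, columns=["window_start", "state", "fraction"])
    return AnnotationProfile(sample_id, window, table)


def aggregate_profiles(
    profiles: Sequence[AnnotationProfile],
    cohort: LabeledCohort,
) -> pd.DataFrame:
    """Mean and sample standard deviation per (type, window, state).

    Each profile's ``sample_id`` is looked up in the cohort; profiles of the
    same cell type are averaged window-by-window.  Singleton types get SD 0.
    """
    frames = []
    for prof in profiles:
        t = prof.table.copy()
        t["type"] = cohort.labels[prof.sample_id]
        frames.append(t)
    long = pd.concat(frames, ignore_index=True)
    agg = (
        long.groupby(["type", "window_start", "state"], sort=True)["fraction"]
        .agg(mean="mean", sd=lambda x: float(np.std(x, ddof=1)) if len(x) > 1 else 0.0)
        .reset_index()
    )
    return agg
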