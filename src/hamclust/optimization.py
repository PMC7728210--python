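"""Parameter optimization and read-loss robustness.

The pipeline's two tunables are the peak-calling significance threshold
``p_G`` and the rank cutoff ``M_cut``.  They are chosen by grid search
minimizing the global penalty λ(M_cut, p_G); within the minimizing plateau
of M_cut values the midpoint is reported, since any value on the plateau
classifies equally well.  Robustness to sequencing-depth loss is probed by
removing ``⌈r·N_r⌉`` reads uniformly at random and re-running the whole
pipeline at fixed (M_cut, p_G).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeLayout, Peak, ReadSet
from .hamming import distance_matrix
from .clustering import agglomerate
from .penalty import LabeledCohort, global_penalty, penalty_bounds, penalty_report
from .ranking import RankedPeakSet, binarize, rank_peaks, truncate

__all__ = [
    "GridResult",
    "grid_search",
    "plateau_midpoint",
    "downsample_reads",
    "robustness_curve",
    "cohort_penalty",
]


def cohort_penalty(
    ranked: Mapping[str, RankedPeakSet],
    cohort: LabeledCohort,
    M_cut: int | float,
    layout: GenomeLayout,
    method: str = "ward",
    metric: str = "hamming",
) -> int:
    """Run truncate → binarize → distances → agglomerate → global penalty."""
    tracks = {s: binarize(truncate(r, M_cut), layout) for s, r in ranked.items()}
    d = distance_matrix(tracks, metric=metric, M_cut=M_cut)
    return global_penalty(agglomerate(d, method=method), cohort)


@dataclass(frozen=True)
class GridResult:
    """λ over the (M_cut, p_G) grid with the plateau-midpoint selection."""

    table: pd.DataFrame  # columns: M_cut, p_G, type, lambda_type
    summary: pd.DataFrame  # columns: M_cut, p_G, lambda
    argmin: tuple[tuple[float, float], ...]  # (M_cut, p_G) attaining min λ
    selected: tuple[float, float]  # (M_cut*, p_G*)

    @property
    def min_penalty(self) -> int:
        return int(self.summary["lambda"].min())


def grid_search(
    peaks_by_pg: Mapping[float, Mapping[str, RankedPeakSet]],
    cohort: LabeledCohort,
    mcut_grid: Sequence[int | float],
    layout: GenomeLayout,
    method: str = "ward",
    metric: str = "hamming",
) -> GridResult:
    """Exhaustive λ evaluation over the (M_cut, p_G) grid.

    ``peaks_by_pg`` maps each calling threshold to its per-sample ranked
    peak sets (peak calling is per-p_G, so rankings are supplied, and hence
    computed, once per threshold).  The selected point takes the p_G
    attaining the global minimum (first in mapping order on ties, longest
    M_cut plateau preferred) and the plateau midpoint of its minimizing
    M_cut values.
    """
    mcut_grid = list(mcut_grid)
    if not mcut_grid or not peaks_by_pg:
        raise ValueError("both grids must be nonempty")
    if sorted(mcut_grid) != mcut_grid:
        raise ValueError("M_cut grid must be increasing")

    lo, hi = penalty_bounds(cohort)
    rows, summary_rows = [], []
    for p_G, ranked in peaks_by_pg.items():
        for m in mcut_grid:
            tracks = {s: binarize(truncate(r, m), layout) for s, r in ranked.items()}
            d = distance_matrix(tracks, metric=metric, M_cut=m, p_G=p_G)
            report = penalty_report(agglomerate(d, method=method), cohort)
            lam = report.global_penalty
            assert lo <= lam <= hi
            summary_rows.append({"M_cut": m, "p_G": p_G, "lambda": lam})
            for t, lam_t in report.per_type.items():
                rows.append({"M_cut": m, "p_G": p_G, "type": t, "lambda_type": lam_t})

    summary = pd.DataFrame(summary_rows)
    best = summary["lambda"].min()
    argmin = tuple(
        (row["M_cut"], row["p_G"])
        for row in summary_rows
        if row["lambda"] == best
    )

    # choose p_G: among thresholds attaining the minimum, prefer the longest
    # contiguous minimizing M_cut run; first in grid order on ties
    best_pg, best_run = None, ()
    for p_G in peaks_by_pg:
        mins = [m for (m, pg) in argmin if pg == p_G]
        if not mins:
            continue
        run = _longest_run(mins)
        if len(run) > len(best_run):
            best_pg, best_run = p_G, run
    selected = (plateau_midpoint(best_run), best_pg)
    return GridResult(pd.DataFrame(rows), summary, argmin, selected)


def _longest_run(values: Sequence[int | float], step: float | None = None) -> tuple:
    values = list(values)
    if len(values) == 1:
        return tuple(values)
    if step is None:
        step = min(b - a for a, b in zip(values, values[1:]))
    runs, current = [], [values[0]]
    for a, b in zip(values, values[1:]):
        if b - a <= step:
            current.append(b)
        else:
            runs.append(current)
            current = [b]
    runs.append(current)
    return tuple(max(runs, key=len))  # max is stable: first longest wins


def plateau_midpoint(minimizers: Sequence[int | float], step: float | None = None):
    """Midpoint of the contiguous minimizing run of M_cut values.

    ``minimizers`` are the increasing grid values attaining the minimum λ.
    Contiguity is judged against ``step`` (default: the smallest gap in the
    sequence).  An even-length run yields its lower median; non-contiguous
    minimizers yield the midpoint of the longest run, first on ties.
    """
    minimizers = list(minimizers)
    if not minimizers:
        raise ValueError("empty minimizer set")
    if sorted(minimizers) != minimizers:
        raise ValueError("minimizers must be increasing")
    run = _longest_run(minimizers, step)
    return run[(len(run) - 1) // 2]


def downsample_reads(reads: ReadSet, r: float, seed: int) -> ReadSet:
    """Remove exactly ``⌈r·N_r⌉`` reads, uniformly without replacement.

    Deterministic given ``seed``; the surviving reads keep their original
    order.  ``r = 0`` returns the input unchanged.
    """
    if not (0.0 <= r <= 1.0):
        raise ValueError(f"r must be in [0, 1], got {r}")
    n_remove = math.ceil(r * reads.count)
    if n_remove == 0:
        return reads
    rng = np.random.default_rng(seed)
    drop = set(rng.choice(reads.count, size=n_remove, replace=False).tolist())
    return ReadSet(tuple(rd for i, rd in enumerate(reads.reads) if i not in drop))


def robustness_curve(
    reads_by_sample: Mapping[str, ReadSet],
    r_values: Sequence[float],
    seed: int,
    peak_caller: Callable[[ReadSet, float], Sequence[Peak]],
    M_cut: int | float,
    p_G: float,
    cohort: LabeledCohort,
    layout: GenomeLayout,
    method: str = "ward",
    n_replicates: int = 3,
) -> pd.DataFrame:
    """λ after random read loss, per removal fraction and replicate.

    All samples are downsampled simultaneously at each (r, replicate), then
    peaks are re-called with ``peak_caller`` (any callable satisfying the
    external-caller contract, e.g. the toy caller) and the full pipeline is
    re-run at fixed (M_cut, p_G).  The ``r = 0`` rows involve no randomness
    and reproduce the baseline λ exactly.
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    for r in r_values:
        for rep in range(n_replicates):
            ranked: dict[str, RankedPeakSet] = {}
            for k, (sample, reads) in enumerate(reads_by_sample.items()):
                sub_seed = int(
                    np.random.SeedSequence(
                        entropy=ss.entropy, spawn_key=(int(round(r * 10**9)), rep, k)
                    ).generate_state(1)[0] % (2**31)
                )
                try:
                    sub = downsample_reads(reads, r, sub_seed)
                    peaks = peak_caller(sub, p_G)
                except Exception as exc:
                    raise RuntimeError(
                        f"peak calling failed at r={r}, replicate={rep}, "
                        f"sample={sample!r}: {exc}"
                    ) from exc
                ranked[sample] = rank_peaks(peaks, layout, p_G=p_G)
            lam = cohort_penalty(ranked, cohort, M_cut, layout, method=method)
            rows.append({"r": r, "replicate": rep, "lambda": lam})
    return pd.DataFrame(rows)
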