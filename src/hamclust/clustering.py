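"""Agglomerative hierarchical clustering with explicit set-distance functions.

Two set distances between disjoint sample clusters C1, C2 are first-class:

* UPGMA: the mean of all pairwise sample distances between C1 and C2.
* Ward: the square root of

      Q = D12/(n1+n2) - n2*D1/(n1*(n1+n2)) - n1*D2/(n2*(n1+n2)),

  where D1 and D2 are half the sums of squared within-cluster distances and
  D12 the sum of squared between-cluster distances.  For singletons
  Q = d^2/2, so the reported height of a singleton merge is d/sqrt(2); the
  raw Q is retained in merge records for audit.  (Q itself is a squared-
  distance-like quantity; taking the square root makes the singleton
  identity H({a},{b}) = d/sqrt(2) hold with distance units.  Merge order is
  unchanged by this monotone transform.)

Agglomeration repeatedly merges the uncombined pair at minimum set distance;
ties are broken by the lexicographically smallest historical cluster index
pair so the algorithm is total and deterministic.  The default path updates
distances with Lance–Williams recurrences; ``direct=True`` re-evaluates the
set formulas from the original matrix at every step (an O(n^4) oracle used
to validate the fast path).  WPGMA, UPGMC and WPGMC use the standard
Lance–Williams coefficients on squared distances.
"""

from __future__ import annotations

import itertools
import math
import os
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .hamming import DistanceMatrix

__all__ = [
    "LINKAGE_METHODS",
    "set_distance_upgma",
    "set_distance_ward",
    "ward_q",
    "MergeRecord",
    "Dendrogram",
    "agglomerate",
]

LINKAGE_METHODS = ("ward", "upgma", "wpgma", "upgmc", "wpgmc")

#: methods whose working quantity is a squared distance (height = sqrt)
_SQUARED = {"ward", "upgmc", "wpgmc"}


def _check_disjoint(c1: Sequence, c2: Sequence) -> None:
    if set(c1) & set(c2):
        raise ValueError(f"clusters overlap: {set(c1) & set(c2)}")


def set_distance_upgma(c1: Sequence[str], c2: Sequence[str], d: DistanceMatrix) -> float:
    """Mean pairwise distance between two disjoint clusters (0 if either empty)."""
    _check_disjoint(c1, c2)
    if not c1 or not c2:
        return 0.0
    idx = {s: i for i, s in enumerate(d.ids)}
    i1 = [idx[s] for s in c1]
    i2 = [idx[s] for s in c2]
    return float(d.values[np.ix_(i1, i2)].mean())


def ward_q(c1: Sequence[str], c2: Sequence[str], d: DistanceMatrix) -> float:
    """The raw Ward quantity Q (squared-distance units); 0 if either empty."""
    _check_disjoint(c1, c2)
    if not c1 or not c2:
        return 0.0
    idx = {s: i for i, s in enumerate(d.ids)}
    i1 = [idx[s] for s in c1]
    i2 = [idx[s] for s in c2]
    sq = d.values.astype(np.float64) ** 2
    n1, n2 = len(i1), len(i2)
    d1 = 0.5 * sq[np.ix_(i1, i1)].sum()
    d2 = 0.5 * sq[np.ix_(i2, i2)].sum()
    d12 = sq[np.ix_(i1, i2)].sum()
    n = n1 + n2
    return d12 / n - n2 * d1 / (n1 * n) - n1 * d2 / (n2 * n)


def set_distance_ward(c1: Sequence[str], c2: Sequence[str], d: DistanceMatrix) -> float:
    """Ward set distance ``sqrt(max(Q, 0))`` between two disjoint clusters."""
    return math.sqrt(max(ward_q(c1, c2, d), 0.0))


@dataclass(frozen=True)
class MergeRecord:
    """One agglomeration step: clusters tau1 < tau2 merged at ``height``.

    ``raw`` is the working quantity before the square root for the squared
    methods (Ward's Q; squared centroid distance), equal to ``height`` for
    the arithmetic-mean methods.
    """

    tau1: int
    tau2: int
    height: float
    raw: float


class Dendrogram:
    """The full agglomeration history over ``n`` samples.

    Clusters carry 1-based historical indices: tau = 1..n are the leaves in
    input order, and the t-th merge (t = 1..n-1) creates cluster ``t + n``.
    A merged cluster's member order is the first operand's order followed by
    the second's; the root's order is the leaf ordering used for drawing.
    """

    def __init__(self, ids: Sequence[str], merges: Sequence[MergeRecord], method: str):
        self.ids = tuple(ids)
        self.merges = tuple(merges)
        self.method = method
        n = len(self.ids)
        if len(self.merges) != n - 1:
            raise ValueError(f"expected {n - 1} merges, got {len(self.merges)}")
        clusters: list[tuple[str, ...]] = [(s,) for s in self.ids]
        for t, m in enumerate(self.merges, start=1):
            if not (1 <= m.tau1 < m.tau2 < t + n):
                raise ValueError(f"merge {t}: invalid cluster indices ({m.tau1}, {m.tau2})")
            clusters.append(clusters[m.tau1 - 1] + clusters[m.tau2 - 1])
        if set(clusters[-1]) != set(self.ids):
            raise ValueError("root cluster does not contain all samples")
        self._clusters = tuple(clusters)

    @property
    def n_samples(self) -> int:
        return len(self.ids)

    @property
    def n_clusters(self) -> int:
        return 2 * self.n_samples - 1

    def cluster(self, tau: int) -> tuple[str, ...]:
        """Ordered members of historical cluster ``tau`` (1-based)."""
        if not (1 <= tau <= self.n_clusters):
            raise IndexError(f"cluster index {tau} out of range 1..{self.n_clusters}")
        return self._clusters[tau - 1]

    def offspring(self, tau: int) -> frozenset:
        """The offspring set of node ``tau``: its cluster without ordering."""
        return frozenset(self.cluster(tau))

    @property
    def leaf_order(self) -> tuple[str, ...]:
        """Left-to-right leaf ordering of the drawn dendrogram (root's order)."""
        return self._clusters[-1]

    def heights(self) -> tuple[float, ...]:
        return tuple(m.height for m in self.merges)

    def layout(self) -> dict[int, tuple[float, float]]:
        """Node coordinates: leaf tau at (a_tau, 0) with a_tau its 1-based
        position in the leaf ordering; each internal node at the midpoint of
        its children's x at its merge height."""
        pos = {s: i + 1 for i, s in enumerate(self.leaf_order)}
        coords: dict[int, tuple[float, float]] = {
            tau: (float(pos[s]), 0.0) for tau, s in enumerate(self.ids, start=1)
        }
        n = self.n_samples
        for t, m in enumerate(self.merges, start=1):
            x = (coords[m.tau1][0] + coords[m.tau2][0]) / 2.0
            coords[t + n] = (x, m.height)
        return coords

    # -- serialization ------------------------------------------------------

    def merge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": range(1, self.n_samples),
                "tau1": [m.tau1 for m in self.merges],
                "tau2": [m.tau2 for m in self.merges],
                "height": [m.height for m in self.merges],
                "raw": [m.raw for m in self.merges],
            }
        )

    def to_merge_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("# ids: " + "\t".join(self.ids) + "\n")
            fh.write("# method: " + self.method + "\n")
            self.merge_table().to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_merge_tsv(cls, path: str | os.PathLike) -> "Dendrogram":
        with open(path) as fh:
            ids = fh.readline().removeprefix("# ids: ").rstrip("\n").split("\t")
            method = fh.readline().removeprefix("# method: ").strip()
            df = pd.read_csv(fh, sep="\t")
        merges = [
            MergeRecord(int(r.tau1), int(r.tau2), float(r.height), float(r.raw))
            for r in df.itertuples()
        ]
        return cls(ids, merges, method)

    def to_newick(self) -> str:
        """Newick string with branch lengths = parent height - child height."""
        n = self.n_samples
        height = {tau: 0.0 for tau in range(1, n + 1)}
        sub = {tau: s for tau, s in enumerate(self.ids, start=1)}
        for t, m in enumerate(self.merges, start=1):
            tau = t + n
            height[tau] = m.height
            b1 = m.height - height[m.tau1]
            b2 = m.height - height[m.tau2]
            sub[tau] = f"({sub[m.tau1]}:{b1:g},{sub[m.tau2]}:{b2:g})"
        return sub[self.n_clusters] + ";"


# ---------------------------------------------------------------------------
# Agglomeration


def _lance_williams_update(method, w, members, ta, tb, tc, dab):
    """New working value between merged cluster (a ∪ b) and cluster c."""
    na, nb, nc = len(members[ta]), len(members[tb]), len(members[tc])
    dac, dbc = w[frozenset((ta, tc))], w[frozenset((tb, tc))]
    if method == "upgma":
        return (na * dac + nb * dbc) / (na + nb)
    if method == "wpgma":
        return 0.5 * (dac + dbc)
    if method == "ward":
        n = na + nb + nc
        return ((na + nc) * dac + (nb + nc) * dbc - nc * dab) / n
    if method == "upgmc":
        n = na + nb
        return (na * dac + nb * dbc) / n - na * nb * dab / n**2
    if method == "wpgmc":
        return 0.5 * dac + 0.5 * dbc - 0.25 * dab
    raise ValueError(f"unknown linkage method {method!r}")


def agglomerate(d: DistanceMatrix, method: str = "ward", direct: bool = False) -> Dendrogram:
    """Build a dendrogram by successive minimum-set-distance merges.

    At each step the pair of uncombined clusters at minimum set distance is
    merged (tie: smallest historical index pair).  ``direct=True`` evaluates
    the UPGMA/Ward set formulas from the original matrix at every step
    instead of the Lance–Williams recurrence; results agree to rounding.
    """
    if method not in LINKAGE_METHODS:
        raise ValueError(f"method must be one of {LINKAGE_METHODS}, got {method!r}")
    if direct and method not in ("ward", "upgma"):
        raise ValueError("direct evaluation is defined for 'ward' and 'upgma' only")
    n = d.n_samples
    if n < 2:
        raise ValueError("need at least 2 samples to cluster")

    members: dict[int, tuple[str, ...]] = {
        tau: (s,) for tau, s in enumerate(d.ids, start=1)
    }
    base = d.values.astype(np.float64)

    # working values between active clusters; squared-like for ward/centroid
    w: dict[frozenset, float] = {}
    for i, j in itertools.combinations(range(n), 2):
        dij = base[i, j]
        if method == "ward":
            val = dij**2 / 2.0
        elif method in ("upgmc", "wpgmc"):
            val = dij**2
        else:
            val = dij
        w[frozenset((i + 1, j + 1))] = val

    active = list(range(1, n + 1))
    merges: list[MergeRecord] = []
    for t in range(1, n):
        if direct:
            for ta, tb in itertools.combinations(active, 2):
                key = frozenset((ta, tb))
                if method == "ward":
                    w[key] = ward_q(members[ta], members[tb], d)
                else:
                    w[key] = set_distance_upgma(members[ta], members[tb], d)
        best = min(
            (tuple(sorted(pair)) for pair in itertools.combinations(active, 2)),
            key=lambda p: (w[frozenset(p)], p),
        )
        ta, tb = best
        raw = w[frozenset(best)]
        height = math.sqrt(max(raw, 0.0)) if method in _SQUARED else raw
        new = t + n
        if not direct:
            for tc in active:
                if tc in (ta, tb):
                    continue
                w[frozenset((new, tc))] = _lance_williams_update(
                    method, w, members, ta, tb, tc, raw
                )
        members[new] = members[ta] + members[tb]
        active = [tau for tau in active if tau not in (ta, tb)] + [new]
        merges.append(MergeRecord(ta, tb, height, raw))
    return Dendrogram(d.ids, merges, method)
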