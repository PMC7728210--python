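"""Penalty cost of a dendrogram against known cell-type labels.

For each cell type ν the type penalty λ_ν counts the foreign samples in the
smallest historical cluster containing all samples of ν: with τ(ν) the
minimum cluster index τ such that S_ν ⊆ C_τ,

    λ_ν = |C_τ(ν)| - |S_ν|,        λ = Σ_ν λ_ν.

λ = 0 exactly when every type coincides with an offspring set (a perfectly
classified dendrogram); the upper bound is (|T| - 1)·|S|.  λ depends only on
the merge topology and order, never on merge heights.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .clustering import Dendrogram

__all__ = [
    "LabeledCohort",
    "PenaltyReport",
    "read_labels",
    "type_penalty",
    "global_penalty",
    "penalty_report",
    "penalty_bounds",
]


@dataclass(frozen=True)
class LabeledCohort:
    """Sample-to-cell-type assignment; the types partition the sample set.

    ``type_universe`` optionally declares the full type set T, which may
    include types with no samples (their penalty is 0 by convention); it
    must cover every label in use.
    """

    labels: Mapping[str, str]
    type_universe: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", dict(self.labels))
        if self.type_universe is not None:
            universe = tuple(dict.fromkeys(self.type_universe))
            missing = set(self.labels.values()) - set(universe)
            if missing:
                raise ValueError(f"labels use types outside the universe: {missing}")
            object.__setattr__(self, "type_universe", universe)

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(self.labels)

    @property
    def types(self) -> tuple[str, ...]:
        if self.type_universe is not None:
            return self.type_universe
        return tuple(dict.fromkeys(self.labels.values()))

    def members(self, type_label: str) -> frozenset:
        """S_ν: the set of samples of the given type (may be empty)."""
        return frozenset(s for s, t in self.labels.items() if t == type_label)

    def __len__(self) -> int:
        return len(self.labels)


def read_labels(path: str | os.PathLike) -> LabeledCohort:
    """Read a 2-column TSV (sample id, type); a header line is optional."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected 2 columns")
    if df.iloc[0, 0].lower() in ("sample", "sample_id", "id"):
        df = df.iloc[1:]
    return LabeledCohort(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))


def _find_tau(dendro: Dendrogram, target: frozenset) -> int:
    for tau in range(1, dendro.n_clusters + 1):
        if target <= dendro.offspring(tau):
            return tau
    raise AssertionError("root must contain every sample")  # pragma: no cover


def type_penalty(dendro: Dendrogram, cohort: LabeledCohort, type_label: str) -> int:
    """λ_ν: foreign samples in the smallest cluster containing all of S_ν."""
    if type_label not in cohort.types:
        raise ValueError(f"unknown type {type_label!r}")
    s_nu = cohort.members(type_label)
    if not s_nu:
        return 0
    missing = s_nu - set(dendro.ids)
    if missing:
        raise ValueError(f"samples of type {type_label!r} not in dendrogram: {missing}")
    tau = _find_tau(dendro, s_nu)
    return len(dendro.offspring(tau)) - len(s_nu)


def global_penalty(dendro: Dendrogram, cohort: LabeledCohort) -> int:
    """λ: sum of type penalties over all types."""
    return sum(type_penalty(dendro, cohort, t) for t in cohort.types)


def penalty_bounds(cohort: LabeledCohort) -> tuple[int, int]:
    """Attainability bounds (0, (|T| - 1)·|S|) for the global penalty."""
    return 0, (len(cohort.types) - 1) * len(cohort)


@dataclass(frozen=True)
class PenaltyReport:
    """Per-type penalties λ_ν with their τ(ν), the global λ and its bounds."""

    per_type: Mapping[str, int]
    tau: Mapping[str, int | None]
    global_penalty: int
    bounds: tuple[int, int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "type": list(self.per_type),
                "tau": [self.tau[t] for t in self.per_type],
                "lambda": [self.per_type[t] for t in self.per_type],
            }
        )

    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            self.to_frame().to_csv(fh, sep="\t", index=False)
            fh.write(
                f"# global\t{self.global_penalty}\t"
                f"bounds=[{self.bounds[0]},{self.bounds[1]}]\n"
            )


def penalty_report(dendro: Dendrogram, cohort: LabeledCohort) -> PenaltyReport:
    per_type: dict[str, int] = {}
    taus: dict[str, int | None] = {}
    for t in cohort.types:
        s_nu = cohort.members(t)
        if not s_nu:
            per_type[t], taus[t] = 0, None
            continue
        tau = _find_tau(dendro, s_nu)
        per_type[t] = len(dendro.offspring(tau)) - len(s_nu)
        taus[t] = tau
    lam = sum(per_type.values())
    return PenaltyReport(per_type, taus, lam, penalty_bounds(cohort))
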