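"""Synthetic cohorts with planted cell-type structure.

The generator emulates the structure the clustering pipeline assumes of real
chromatin-accessibility cohorts: each cell type has an archetype set of
"informative" peaks whose significance scores all exceed those of
sample-specific noise peaks by a margin, so truncating the per-sample
ranking at the archetype size discards exactly the noise.  Types share a
configurable fraction of archetype peaks (biological overlap between related
cell types); each sample is a positionally jittered copy of its type's
archetype plus uniform noise peaks.

A toy read simulator and a toy pileup-threshold peak caller let the external
peak-caller code path (and the read-downsampling robustness analysis) run
hermetically.  Neither claims fidelity to a real caller's statistics.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .genome import GenomeLayout, Peak, ReadSet, write_narrowpeak
from .penalty import LabeledCohort
from .ranking import RankedPeakSet, rank_peaks

__all__ = [
    "CohortSpec",
    "simulate_cohort",
    "sample_from_type",
    "simulate_reads",
    "toy_peak_caller",
    "write_cohort",
]

_DEFAULT_LAYOUT = {"chr1": 100_000, "chr2": 100_000}


@dataclass(frozen=True)
class CohortSpec:
    """The stated world of a planted-cohort simulation.

    Defaults give 3 cell types x 4 samples on a 2 x 100 kb toy genome, 300
    informative peaks per type (one third shared across all types) and 200
    noise peaks per sample.  Informative scores lie in [20, 300) -log10 p
    units and noise scores in [2, 10), so every informative peak outranks
    every noise peak with a 10-unit margin, and all scores respect the
    default calling threshold p_G = 1e-2.
    """

    layout: GenomeLayout = field(
        default_factory=lambda: GenomeLayout(_DEFAULT_LAYOUT)
    )
    types: tuple[str, ...] = ("HSC", "B", "Mono")
    samples_per_type: int = 4
    k_info: int = 300
    shared_fraction: float = 1.0 / 3.0
    k_noise: int = 200
    width_range: tuple[int, int] = (40, 80)
    info_score_range: tuple[float, float] = (20.0, 300.0)
    noise_score_range: tuple[float, float] = (2.0, 10.0)
    jitter_sd: float = 5.0
    p_G: float = 1e-2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_score_range[1] > self.info_score_range[0]:
            raise ValueError("noise scores must lie strictly below informative scores")
        if -math.log10(self.p_G) > self.noise_score_range[0]:
            raise ValueError("noise scores would violate the calling threshold p_G")


class GenerationError(RuntimeError):
    """The requested peak geometry cannot fit on the toy genome."""


def _archetypes(spec: CohortSpec) -> dict[str, list[tuple[str, int, int, float]]]:
    """Per-type archetype peaks (chrom, start, end, score), deterministic.

    Archetype slots are laid out on a regular grid over the concatenated
    genome so archetype peaks never overlap each other even after jitter;
    slot-to-type assignment and scores come from a dedicated RNG stream so
    archetypes depend only on the spec, not on how many samples are drawn.
    """
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0xA5C)))
    n_shared = int(round(spec.k_info * spec.shared_fraction))
    n_specific = spec.k_info - n_shared
    n_slots = n_shared + n_specific * len(spec.types)
    genome = sum(spec.layout.lengths.values())
    spacing = genome // n_slots
    margin = int(6 * spec.jitter_sd) + 2
    if spacing < spec.width_range[1] + margin + 1:
        raise GenerationError(
            f"{n_slots} peaks of width <= {spec.width_range[1]} (+{margin} bp "
            f"jitter margin) cannot fit a {genome} bp genome"
        )
    # slot -> (chrom, start) on the concatenated coordinate
    bounds = np.cumsum([spec.layout.lengths[c] for c in spec.layout.chromosomes])
    slots = []
    for i in range(n_slots):
        g = i * spacing + margin // 2
        ci = int(np.searchsorted(bounds, g, side="right"))
        offset = g - (0 if ci == 0 else bounds[ci - 1])
        chrom = spec.layout.chromosomes[ci]
        width = int(rng.integers(spec.width_range[0], spec.width_range[1] + 1))
        start = offset + 1
        if start + width > spec.layout.lengths[chrom]:
            start = spec.layout.lengths[chrom] - width
        slots.append((chrom, start, start + width))
    order = rng.permutation(n_slots)
    scores = rng.uniform(*spec.info_score_range, size=n_slots)
    shared = [
        (*slots[order[i]], float(scores[order[i]])) for i in range(n_shared)
    ]
    arch: dict[str, list[tuple[str, int, int, float]]] = {}
    cursor = n_shared
    for t in spec.types:
        own = [
            (*slots[order[i]], float(scores[order[i]]))
            for i in range(cursor, cursor + n_specific)
        ]
        cursor += n_specific
        arch[t] = shared + own
    return arch


def _draw_sample(
    spec: CohortSpec,
    archetype: Sequence[tuple[str, int, int, float]],
    rng: np.random.Generator,
) -> RankedPeakSet:
    peaks: list[Peak] = []
    for chrom, start, end, score in archetype:
        shift = int(round(rng.normal(0.0, spec.jitter_sd))) if spec.jitter_sd else 0
        L = spec.layout.lengths[chrom]
        s = min(max(1, start + shift), L - (end - start))
        peaks.append(Peak(chrom, s, s + (end - start), score))
    for _ in range(spec.k_noise):
        chrom = spec.layout.chromosomes[int(rng.integers(len(spec.layout.chromosomes)))]
        width = int(rng.integers(spec.width_range[0], spec.width_range[1] + 1))
        s = int(rng.integers(1, spec.layout.lengths[chrom] - width + 1))
        score = float(rng.uniform(*spec.noise_score_range))
        peaks.append(Peak(chrom, s, s + width, score))
    return rank_peaks(peaks, spec.layout, p_G=spec.p_G)


def simulate_cohort(spec: CohortSpec) -> tuple[dict[str, RankedPeakSet], LabeledCohort]:
    """Draw the labelled cohort: per-sample ranked peaks plus labels.

    Sample ids are ``{type}{i}`` with i = 1..samples_per_type.  Deterministic
    given ``spec`` (including its seed).
    """
    arch = _archetypes(spec)
    ranked: dict[str, RankedPeakSet] = {}
    labels: dict[str, str] = {}
    for ti, t in enumerate(spec.types):
        for i in range(spec.samples_per_type):
            rng = np.random.default_rng(
                np.random.SeedSequence((spec.seed, 1, ti, i))
            )
            sid = f"{t}{i + 1}"
            ranked[sid] = _draw_sample(spec, arch[t], rng)
            labels[sid] = t
    return ranked, LabeledCohort(labels)


def sample_from_type(spec: CohortSpec, type_label: str, seed: int) -> RankedPeakSet:
    """An extra held-out sample drawn from a type's archetype.

    Uses an RNG stream disjoint from the cohort's, so held-out queries are
    independent of the reference samples while sharing their archetype.
    """
    if type_label not in spec.types:
        raise ValueError(f"unknown type {type_label!r}")
    arch = _archetypes(spec)
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 2, seed)))
    return _draw_sample(spec, arch[type_label], rng)


def write_cohort(
    ranked: Mapping[str, RankedPeakSet],
    cohort: LabeledCohort,
    layout: GenomeLayout,
    outdir: str | os.PathLike,
) -> None:
    """Emit the cohort in on-disk formats the real pipeline consumes:
    per-sample narrowPeak, a labels TSV and a chromosome-sizes TSV."""
    os.makedirs(outdir, exist_ok=True)
    for sid, rps in ranked.items():
        write_narrowpeak(rps.peaks, os.path.join(outdir, f"{sid}.narrowPeak"))
    with open(os.path.join(outdir, "labels.tsv"), "w") as fh:
        for sid in cohort.samples:
            fh.write(f"{sid}\t{cohort.labels[sid]}\n")
    with open(os.path.join(outdir, "chrom.sizes"), "w") as fh:
        for chrom in layout.chromosomes:
            fh.write(f"{chrom}\t{layout.lengths[chrom]}\n")


# ---------------------------------------------------------------------------
# Toy reads and peak caller


def simulate_reads(
    ranked: RankedPeakSet,
    layout: GenomeLayout,
    depth_per_peak: int = 30,
    background_rate: float = 0.0,
    seed: int = 0,
    read_length: int = 50,
) -> ReadSet:
    """Reads piled inside each peak plus uniform background.

    Each peak receives exactly ``depth_per_peak`` reads whose positions are
    uniform within the peak (clipped to fit); background reads arrive as a
    Poisson process at ``background_rate`` reads per bp genome-wide.
    """
    rng = np.random.default_rng(seed)
    reads: list[tuple[str, int, int]] = []
    for p in ranked.peaks:
        lo = p.start
        hi = max(p.start, p.end - read_length + 1)
        for _ in range(depth_per_peak):
            s = int(rng.integers(lo, hi + 1))
            reads.append((p.chrom, s, min(s + read_length - 1, p.end)))
    if background_rate > 0:
        for chrom in layout.chromosomes:
            L = layout.lengths[chrom]
            n_bg = int(rng.poisson(background_rate * L))
            for _ in range(n_bg):
                s = int(rng.integers(1, max(1, L - read_length + 1) + 1))
                reads.append((chrom, s, min(s + read_length - 1, L)))
    return ReadSet(tuple(reads))


def toy_peak_caller(
    reads: ReadSet,
    layout: GenomeLayout,
    coverage_threshold: int = 5,
    p_G: float = 1e-2,
) -> list[Peak]:
    """Maximal pileup runs above a coverage threshold, as peaks.

    The score is ``-log10 p_G + max pileup`` within the run — monotone in
    enrichment and never below the calling floor, so every emitted peak has
    implied p <= p_G.  Deterministic; a fixture stand-in for the external
    caller, with no claim of statistical fidelity.
    """
    floor = -math.log10(p_G)
    peaks: list[Peak] = []
    per_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in layout.chromosomes}
    for chrom, s, e in reads.reads:
        per_chrom[chrom].append((s, e))
    for chrom in layout.chromosomes:
        ivs = per_chrom[chrom]
        if not ivs:
            continue
        L = layout.lengths[chrom]
        diff = np.zeros(L + 2, dtype=np.int64)
        for s, e in ivs:
            diff[s] += 1
            diff[e + 1] -= 1
        pile = np.cumsum(diff)[1 : L + 1]  # pile[x-1] = coverage at position x
        above = pile >= coverage_threshold
        if not above.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate([[0], above.view(np.int8), [0]])))
        for lo, hi in zip(edges[::2], edges[1::2]):
            start, end = int(lo) + 1, int(hi)
            score = floor + float(pile[lo:hi].max())
            peaks.append(Peak(chrom, start, end, score))
    return peaks
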