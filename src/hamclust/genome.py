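"""Core genomic types and file I/O.

Coordinates are 1-based inclusive ``[start, end]`` throughout the package,
matching the pointwise definition of the binary accessibility indicator
``h_{chrom,x} = 1`` for ``start <= x <= end``.  All BED-family I/O converts
to/from the 0-based half-open convention at the boundary.
"""

from __future__ import annotations

import os
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "GenomeLayout",
    "Peak",
    "ReadSet",
    "ChromSegmentation",
    "ParseError",
    "BoundsError",
    "read_chrom_sizes",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_reads_bed",
    "write_reads_bed",
    "read_chromhmm",
    "call_peaks_external",
    "peak_width",
    "peak_span",
]


class ParseError(ValueError):
    """A line of an input file violates its format."""


class BoundsError(ValueError):
    """A genomic coordinate falls outside the declared genome layout."""


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosomes and their lengths in bp.

    Parameters
    ----------
    lengths:
        Mapping from chromosome label to its length ``L_chrom`` (bp).
        Insertion order defines the canonical chromosome order used for
        tie-breaking and serialization.
    """

    lengths: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.lengths:
            raise ValueError("layout must contain at least one chromosome")
        for chrom, length in self.lengths.items():
            if int(length) < 1:
                raise ValueError(f"chromosome {chrom!r} has length {length} < 1")
        object.__setattr__(self, "lengths", dict(self.lengths))

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(self.lengths)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def length(self, chrom: str) -> int:
        return self.lengths[chrom]

    def chrom_index(self, chrom: str) -> int:
        return self.chromosomes.index(chrom)


@dataclass(frozen=True, order=True)
class Peak:
    """A called peak ``(chrom, start, end)`` with its significance score.

    ``start``/``end`` are 1-based inclusive.  ``neg_log10_p`` is the
    ``-log10 p`` emitted by the peak caller (narrowPeak column 8); it is the
    ranking score and is never exponentiated back to a (possibly denormal)
    p-value.
    """

    chrom: str
    start: int
    end: int
    neg_log10_p: float

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"invalid peak interval [{self.start}, {self.end}] on {self.chrom}"
            )
        if self.neg_log10_p < 0:
            raise ValueError("neg_log10_p must be non-negative")


def peak_width(peak: Peak) -> int:
    """Width ``end - start`` of a peak (bp).

    This is the conventional width statistic for called peaks; note the
    inclusive interval actually covers ``end - start + 1`` positions, for
    which see :func:`peak_span`.
    """
    return peak.end - peak.start


def peak_span(peak: Peak) -> int:
    """Number of genomic positions covered by the peak, ``end - start + 1``."""
    return peak.end - peak.start + 1


@dataclass(frozen=True)
class ReadSet:
    """A set of aligned read locations as ``(chrom, start, end)`` records."""

    reads: tuple[tuple[str, int, int], ...]

    @property
    def count(self) -> int:
        return len(self.reads)

    def __len__(self) -> int:
        return len(self.reads)


@dataclass(frozen=True)
class ChromSegmentation:
    """A genome segmentation into labelled chromatin states.

    ``intervals[state][chrom]`` is a list of ``(start, end)`` pairs, 1-based
    inclusive, non-overlapping within one state (adjacent intervals are kept
    as given, never auto-merged).
    """

    intervals: Mapping[str, Mapping[str, tuple[tuple[int, int], ...]]]

    @property
    def states(self) -> tuple[str, ...]:
        return tuple(self.intervals)

    def __post_init__(self) -> None:
        frozen: dict[str, dict[str, tuple[tuple[int, int], ...]]] = {}
        for state, per_chrom in self.intervals.items():
            frozen[state] = {}
            for chrom, ivs in per_chrom.items():
                ivs = tuple(sorted((int(s), int(e)) for s, e in ivs))
                for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                    if s2 <= e1:
                        raise ValueError(
                            f"state {state!r} has overlapping intervals on "
                            f"{chrom}: [{s1},{e1}] and [{s2},{e2}]"
                        )
                for s, e in ivs:
                    if s > e:
                        raise ValueError(f"interval [{s},{e}] has start > end")
                frozen[state][chrom] = ivs
        object.__setattr__(self, "intervals", frozen)


# ---------------------------------------------------------------------------
# File I/O


def read_chrom_sizes(path: str | os.PathLike) -> GenomeLayout:
    """Read a 2-column TSV of (chromosome label, length in bp)."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            chrom, length = fields[0], fields[1]
            if chrom in lengths:
                raise ParseError(f"{path}:{lineno}: duplicate chromosome {chrom!r}")
            try:
                lengths[chrom] = int(length)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad length {length!r}") from exc
    return GenomeLayout(lengths)


def _check_bounds(chrom: str, start: int, end: int, layout: GenomeLayout, where: str) -> None:
    if chrom not in layout:
        raise BoundsError(f"{where}: chromosome {chrom!r} not in layout")
    if start < 1 or end > layout.length(chrom):
        raise BoundsError(
            f"{where}: interval [{start},{end}] outside {chrom} "
            f"(length {layout.length(chrom)})"
        )


def read_narrowpeak(path: str | os.PathLike, layout: GenomeLayout) -> list[Peak]:
    """Parse a MACS2 narrowPeak (BED6+4) file into 1-based inclusive peaks.

    Column 8 (``-log10 p``) becomes the peak score; columns 7 and 9 are
    ignored.  BED's 0-based half-open ``[start, end)`` becomes
    ``[start+1, end]``.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise ParseError(f"{path}:{lineno}: expected >= 8 columns, got {len(fields)}")
            chrom = fields[0]
            try:
                bed_start, bed_end = int(fields[1]), int(fields[2])
                score = float(fields[7])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if bed_end <= bed_start:
                raise ParseError(
                    f"{path}:{lineno}: end {bed_end} <= start {bed_start}"
                )
            if score < 0:
                raise ParseError(f"{path}:{lineno}: negative -log10 p {score}")
            start, end = bed_start + 1, bed_end
            _check_bounds(chrom, start, end, layout, f"{path}:{lineno}")
            peaks.append(Peak(chrom, start, end, score))
    return peaks


def write_narrowpeak(peaks: Iterable[Peak], path: str | os.PathLike) -> None:
    """Write peaks as narrowPeak, converting back to 0-based half-open."""
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            fh.write(
                f"{p.chrom}\t{p.start - 1}\t{p.end}\tpeak_{i + 1}\t0\t.\t"
                f"0.0\t{p.neg_log10_p!r}\t-1\t-1\n"
            )


def read_reads_bed(path: str | os.PathLike, layout: GenomeLayout) -> ReadSet:
    """Read aligned read locations from a 3+ column BED file."""
    reads: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]) + 1, int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            _check_bounds(chrom, start, end, layout, f"{path}:{lineno}")
            reads.append((chrom, start, end))
    return ReadSet(tuple(reads))


def write_reads_bed(reads: ReadSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in reads.reads:
            fh.write(f"{chrom}\t{start - 1}\t{end}\n")


#: Default translation of ChromHMM core-15 mnemonics to readable state names.
CHROMHMM_ALIASES: dict[str, str] = {
    "1_TssA": "ActiveTSS",
    "2_TssAFlnk": "FlankingActiveTSS",
    "7_Enh": "Enhancers",
    "15_Quies": "Quiescent_Low",
}


def read_chromhmm(
    path: str | os.PathLike,
    layout: GenomeLayout,
    aliases: Mapping[str, str] | None = None,
) -> ChromSegmentation:
    """Read a ChromHMM segmentation (4-column BED: chrom, start, end, state).

    ``aliases`` optionally translates file mnemonics (e.g. ``1_TssA``) to
    working labels (e.g. ``ActiveTSS``); unlisted mnemonics pass through
    verbatim.
    """
    aliases = dict(aliases) if aliases is not None else {}
    acc: dict[str, dict[str, list[tuple[int, int]]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns")
            chrom, raw_state = fields[0], fields[3]
            try:
                start, end = int(fields[1]) + 1, int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if end < start:
                raise ParseError(f"{path}:{lineno}: empty interval")
            _check_bounds(chrom, start, end, layout, f"{path}:{lineno}")
            state = aliases.get(raw_state, raw_state)
            acc.setdefault(state, {}).setdefault(chrom, []).append((start, end))
    return ChromSegmentation(
        {state: {c: tuple(ivs) for c, ivs in per.items()} for state, per in acc.items()}
    )


# ---------------------------------------------------------------------------
# External peak-caller wrapper


class PeakCallerError(RuntimeError):
    """The external peak caller failed; the captured log is attached."""

    def __init__(self, message: str, log: str = "") -> None:
        super().__init__(message)
        self.log = log


def macs2_command(
    reads_file: str | os.PathLike,
    p_G: float,
    outdir: str | os.PathLike,
    name: str = "hamclust",
    executable: str = "macs2",
) -> list[str]:
    """Build the peak-calling command line.

    The caller is invoked with ``--nomodel --nolambda --keep-dup all -p p_G``;
    input reads are expected analysis-ready (deduplicated, MQ-filtered), which
    is a documented prerequisite, not something this wrapper performs.
    """
    if not (0.0 < p_G < 1.0):
        raise ValueError(f"p_G must be in (0, 1), got {p_G}")
    return [
        executable,
        "callpeak",
        "-t",
        str(reads_file),
        "-f",
        "BED",
        "--nomodel",
        "--nolambda",
        "--keep-dup",
        "all",
        "-p",
        f"{p_G:g}",
        "-n",
        name,
        "--outdir",
        str(outdir),
    ]


def call_peaks_external(
    reads_file: str | os.PathLike,
    p_G: float,
    workdir: str | os.PathLike,
    layout: GenomeLayout,
    executable: str = "macs2",
) -> list[Peak]:
    """Call peaks on a reads file with the external caller at threshold p_G.

    Returns the parsed narrowPeak output.  There is no guarantee that peak
    sets nest across different ``p_G``: a stricter threshold can split one
    broad peak into several narrower ones.
    """
    if shutil.which(executable) is None:
        raise EnvironmentError(
            f"peak caller {executable!r} not found on PATH; install it or use "
            "the toy caller from hamclust.synthetic for hermetic runs"
        )
    name = "hamclust"
    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        cmd = macs2_command(reads_file, p_G, tmp, name=name, executable=executable)
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise PeakCallerError(
                f"{executable} exited with status {proc.returncode}",
                log=proc.stdout + proc.stderr,
            )
        out = os.path.join(tmp, f"{name}_peaks.narrowPeak")
        if not os.path.exists(out):
            raise PeakCallerError(f"{executable} produced no narrowPeak output",
                                  log=proc.stdout + proc.stderr)
        return read_narrowpeak(out, layout)
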