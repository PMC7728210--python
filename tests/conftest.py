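import numpy as np
import pytest

from hamclust.genome import GenomeLayout, Peak
from hamclust.ranking import BinaryTrack, binarize
from hamclust.synthetic import CohortSpec, simulate_cohort


@pytest.fixture
def toy_layout() -> GenomeLayout:
    return GenomeLayout({"chr1": 50_000, "chr2": 50_000})


@pytest.fixture(scope="session")
def default_spec() -> CohortSpec:
    return CohortSpec()


@pytest.fixture(scope="session")
def default_cohort(default_spec):
    """The seeded planted cohort shared by pipeline-level tests."""
    return simulate_cohort(default_spec)


def random_track(layout: GenomeLayout, rng: np.random.Generator, n_peaks: int = 40) -> BinaryTrack:
    """A track built from random peaks (overlaps allowed; binarize merges)."""
    peaks = []
    for _ in range(n_peaks):
        chrom = layout.chromosomes[int(rng.integers(len(layout.chromosomes)))]
        L = layout.lengths[chrom]
        width = int(rng.integers(1, 400))
        start = int(rng.integers(1, L - width + 1))
        peaks.append(Peak(chrom, start, start + width, 1.0))
    return binarize(peaks, layout)


def stamp_vector(track: BinaryTrack, chrom: str) -> np.ndarray:
    """Explicit 0/1 position vector of a track on one chromosome (oracle)."""
    vec = np.zeros(track.layout.lengths[chrom], dtype=np.int8)
    for start, end in track.chrom_intervals(chrom):
        vec[start - 1 : end] = 1
    return vec


def xor_hamming(a: BinaryTrack, b: BinaryTrack) -> int:
    """Brute-force Hamming distance by XOR-counting explicit vectors."""
    return int(
        sum(
            np.sum(stamp_vector(a, c) != stamp_vector(b, c))
            for c in a.layout.chromosomes
        )
    )
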