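"""Shared fixtures: toy genomes, random peak sets, and the per-base oracle.

The boolean-array oracle is the independent ground truth for all interval
set operations: a chromosome is a per-base bool vector, and union / merge /
intersection / overlap queries are plain array logic. It is deliberately
naive and never shares code with the library implementation.
"""

from __future__ import annotations

import numpy as np
import pytest

from peakconcord.intervals import GenomicInterval, PeakSet

TOY_GENOME = {"chrA": 50_000, "chrB": 50_000}


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_peakset(
    rng: np.random.Generator,
    genome: dict[str, int] = TOY_GENOME,
    n: int = 200,
    max_len: int = 2000,
    label: str = "rand",
) -> PeakSet:
    """Uniform random (possibly overlapping) intervals on a toy genome."""
    chroms = sorted(genome)
    ivs = []
    for _ in range(n):
        c = chroms[rng.integers(0, len(chroms))]
        length = int(rng.integers(1, max_len + 1))
        start = int(rng.integers(0, genome[c] - length))
        ivs.append(GenomicInterval(c, start, start + length))
    return PeakSet(ivs, label=label)


def base_mask(peaks: PeakSet, genome: dict[str, int]) -> dict[str, np.ndarray]:
    """Per-base boolean coverage mask — the brute-force oracle currency."""
    masks = {c: np.zeros(n, dtype=bool) for c, n in genome.items()}
    for iv in peaks:
        masks[iv.chrom][iv.start : iv.end] = True
    return masks


def covered_bases(peaks: PeakSet, genome: dict[str, int]) -> int:
    return int(sum(m.sum() for m in base_mask(peaks, genome).values()))


def oracle_overlaps(iv: GenomicInterval, mask: dict[str, np.ndarray]) -> bool:
    """Does the interval share >=1 covered base with the mask?"""
    return bool(mask[iv.chrom][iv.start : iv.end].any())
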