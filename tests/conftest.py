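"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from g4se.genome import GenomeLayout, Interval, IntervalSet

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def toy_layout() -> GenomeLayout:
    return GenomeLayout(("chr1", "chr2"), (10_000, 5_000))


def bitmap(iset: IntervalSet) -> dict[str, np.ndarray]:
    """Per-base boolean occupancy oracle; only usable on toy genomes."""
    out = {
        c: np.zeros(L, dtype=bool)
        for c, L in zip(iset.layout.chrom_names, iset.layout.chrom_lengths)
    }
    for iv in iset:
        out[iv.chrom][iv.start : iv.end] = True
    return out


def brute_force_overlap_mask(a: IntervalSet, b: IntervalSet) -> np.ndarray:
    """Quadratic double-loop overlap oracle."""
    mask = np.zeros(len(a), dtype=bool)
    for i, x in enumerate(a):
        for y in b:
            if x.chrom == y.chrom and x.start < y.end and y.start < x.end:
                mask[i] = True
                break
    return mask


def random_interval_set(
    rng: np.random.Generator,
    layout: GenomeLayout,
    n: int,
    max_len: int = 500,
) -> IntervalSet:
    ivs = []
    for _ in range(n):
        ci = int(rng.integers(0, len(layout.chrom_names)))
        chrom = layout.chrom_names[ci]
        L = int(rng.integers(1, max_len + 1))
        L = min(L, layout.length(chrom))
        start = int(rng.integers(0, layout.length(chrom) - L + 1))
        ivs.append(Interval(chrom, start, start + L))
    return IntervalSet(ivs, layout)
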