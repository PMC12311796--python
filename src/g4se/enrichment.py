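"""Permutation-based enrichment of one interval set within another.

The observed statistic is the fraction of query intervals (e.g. folded-G4
peaks) overlapping the region set (e.g. superenhancers) by >= 1 bp. Each of n
replicates redraws a control set with the query's exact length multiset
placed uniformly over the genome, and the empirical p-value is
p = (r + 1) / (n + 1), where r counts control replicates whose overlap
fraction is at least the observed one (conservative tie rule; a strict
"greater-than" rule is available via ``tie="gt"``). p is therefore never 0
and never below 1/(n+1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import GenomeLayout, Interval, IntervalSet
from .intervals import _mask_against_merged, merge

__all__ = [
    "PermutationResult",
    "random_control_set",
    "permutation_enrichment",
    "enrichment_by_class",
]


@dataclass
class PermutationResult:
    """Result of a permutation enrichment test."""

    observed_fraction: float
    control_fractions: np.ndarray
    fold_enrichment: float
    r: int
    n: int
    p_empirical: float
    skipped: bool = False

    def __post_init__(self) -> None:
        if not self.skipped:
            assert 0 <= self.r <= self.n
            assert abs(self.p_empirical - (self.r + 1) / (self.n + 1)) < 1e-12


def _sample_global_starts(
    lengths: np.ndarray, layout: GenomeLayout, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one uniform placement per template length.

    The chromosome is chosen with probability proportional to its number of
    placeable start positions (chrom_length - L + 1) and the start uniformly
    among them. Returns (chromosome index, local start) arrays.
    """
    chrom_lengths = np.asarray(layout.chrom_lengths, dtype=np.int64)
    placeable = chrom_lengths[None, :] - lengths[:, None] + 1  # (k, C)
    placeable = np.maximum(placeable, 0)
    totals = placeable.sum(axis=1)
    if np.any(totals == 0):
        bad = int(lengths[totals == 0][0])
        raise ValueError(f"interval of length {bad} does not fit on any chromosome")
    cum = np.cumsum(placeable, axis=1)
    u = rng.random(len(lengths)) * totals
    ci = (u[:, None] < cum).argmax(axis=1)
    starts = rng.integers(0, placeable[np.arange(len(lengths)), ci])
    return ci, starts


def random_control_set(
    template: IntervalSet,
    layout: GenomeLayout,
    rng: np.random.Generator | int,
) -> IntervalSet:
    """Random control intervals preserving the template's length multiset.

    Controls may overlap each other (matching naive random-BED shuffles);
    strands, names and scores are not carried over.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    lengths = np.array([len(iv) for iv in template], dtype=np.int64)
    ci, starts = _sample_global_starts(lengths, layout, rng)
    return IntervalSet(
        (
            Interval(layout.chrom_names[c], int(s), int(s) + int(L))
            for c, s, L in zip(ci, starts, lengths)
        ),
        layout,
    )


def permutation_enrichment(
    query: IntervalSet,
    regions: IntervalSet,
    n: int = 20,
    rng: np.random.Generator | int = 0,
    tie: str = "ge",
) -> PermutationResult:
    """Permutation test of query enrichment within regions.

    Parameters
    ----------
    n : replicate count (>= 1; 20 is the conventional floor).
    tie : {"ge", "gt"}
        Whether a control fraction exactly equal to the observed one
        increments r ("ge", conservative default) or not ("gt").
    """
    if len(query) == 0 or len(regions) == 0:
        raise ValueError("query and regions must be non-empty")
    if n < 1:
        raise ValueError("n must be >= 1")
    if tie not in ("ge", "gt"):
        raise ValueError("tie must be 'ge' or 'gt'")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    layout = query.layout
    ms, me = merge(regions).global_coords()
    qs, qe = query.global_coords()
    observed = float(_mask_against_merged(qs, qe, ms, me).mean())

    lengths = np.array([len(iv) for iv in query], dtype=np.int64)
    chrom_offsets = np.array(
        [layout.offsets()[name] for name in layout.chrom_names], dtype=np.int64
    )
    control = np.empty(n)
    for i in range(n):
        ci, starts = _sample_global_starts(lengths, layout, rng)
        gs = chrom_offsets[ci] + starts
        ge = gs + lengths
        control[i] = float(_mask_against_merged(gs, ge, ms, me).mean())
    if tie == "ge":
        r = int(np.sum(control >= observed))
    else:
        r = int(np.sum(control > observed))
    mean_control = float(control.mean())
    fold = observed / mean_control if mean_control > 0 else np.inf
    return PermutationResult(
        observed_fraction=observed,
        control_fractions=control,
        fold_enrichment=fold,
        r=r,
        n=n,
        p_empirical=(r + 1) / (n + 1),
    )


def enrichment_by_class(
    query: IntervalSet,
    classed_regions: dict[str, IntervalSet],
    n: int = 20,
    rng: np.random.Generator | int = 0,
    tie: str = "ge",
) -> dict[str, PermutationResult]:
    """Per-class permutation enrichment (e.g. active/poised/repressed SEs).

    All classes share the same control-generation parameters; an empty class
    yields a result flagged ``skipped=True`` rather than an error.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    results: dict[str, PermutationResult] = {}
    for cls, regions in classed_regions.items():
        if len(regions) == 0:
            results[cls] = PermutationResult(
                observed_fraction=float("nan"),
                control_fractions=np.empty(0),
                fold_enrichment=float("nan"),
                r=0,
                n=0,
                p_empirical=float("nan"),
                skipped=True,
            )
            continue
        results[cls] = permutation_enrichment(query, regions, n=n, rng=rng, tie=tie)
    return results
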