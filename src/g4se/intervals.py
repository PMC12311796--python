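"""Interval algebra and distance statistics.

Strand is carried by intervals but ignored here: every overlap computation is
strand-agnostic, and the overlap predicate is "shares >= 1 base" (the
BEDTools intersect default). All coordinates are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import Interval, IntervalSet

__all__ = [
    "merge",
    "extend",
    "intersect_any",
    "window_overlap",
    "overlap_counts",
    "coverage_fraction",
    "relative_distances",
    "RelDistDistribution",
]


@dataclass
class RelDistDistribution:
    """Relative distances of query midpoints to flanking reference midpoints.

    Each value is d/g in [0, 0.5], where g is the gap between the two
    reference midpoints bracketing the query midpoint and d the distance to
    the nearer one. Queries outside the reference midpoint span on their
    chromosome are counted in ``n_dropped``.
    """

    values: np.ndarray
    n_dropped: int


def merge(iset: IntervalSet) -> IntervalSet:
    """Merge overlapping or bookended intervals into disjoint ones."""
    merged: list[Interval] = []
    for chrom, ivs in iset.by_chrom().items():
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(Interval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(Interval(chrom, cur_start, cur_end))
    return IntervalSet(merged, iset.layout)


def extend(iset: IntervalSet, flank: int) -> IntervalSet:
    """Extend every interval symmetrically by ``flank`` bp, clipped at
    chromosome bounds."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    out = [
        Interval(
            iv.chrom,
            max(0, iv.start - flank),
            min(iset.layout.length(iv.chrom), iv.end + flank),
            name=iv.name,
            score=iv.score,
            strand=iv.strand,
        )
        for iv in iset
    ]
    return IntervalSet(out, iset.layout)


def _mask_against_merged(
    qstarts: np.ndarray, qends: np.ndarray, ms: np.ndarray, me: np.ndarray
) -> np.ndarray:
    """Overlap mask of query global coords against merged (disjoint, sorted)
    global coords: query i overlaps iff the last merged interval starting
    before qends[i] extends past qstarts[i]."""
    if len(ms) == 0:
        return np.zeros(len(qstarts), dtype=bool)
    j = np.searchsorted(ms, qends, side="left") - 1
    return (j >= 0) & (me[np.maximum(j, 0)] > qstarts)


def _overlap_mask(a: IntervalSet, b: IntervalSet) -> np.ndarray:
    """Boolean mask over a's intervals: True iff >=1 bp overlap with b."""
    if a.layout != b.layout:
        raise ValueError("interval sets must share a genome layout")
    ms, me = merge(b).global_coords()
    qs, qe = a.global_coords()
    return _mask_against_merged(qs, qe, ms, me)


def intersect_any(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Subset of ``a`` whose intervals share >= 1 base with some interval of
    ``b`` (half-open: [10,20) and [20,30) do not overlap)."""
    mask = _overlap_mask(a, b)
    return a.replace_intervals(iv for iv, keep in zip(a, mask) if keep)


def window_overlap(a: IntervalSet, b: IntervalSet, flank: int) -> IntervalSet:
    """Subset of ``a`` overlapping ``b`` after extending b by ``flank`` bp on
    both sides (colocalization within +/- flank), clipped at chromosome ends."""
    return intersect_any(a, extend(b, flank))


def overlap_counts(a: IntervalSet, b: IntervalSet) -> np.ndarray:
    """Number of intervals of ``b`` overlapping each interval of ``a``.

    Unlike :func:`intersect_any` this does not merge b: each b interval is
    counted individually (used for per-SE peak counts)."""
    if a.layout != b.layout:
        raise ValueError("interval sets must share a genome layout")
    bs, be = b.global_coords()
    qs, qe = a.global_coords()
    # b intervals overlapping query q: (bstart < qend) minus (bend <= qstart);
    # the second set is a subset of the first since bstart < bend.
    n_start_before = np.searchsorted(np.sort(bs), qe, side="left")
    n_end_before = np.searchsorted(np.sort(be), qs, side="right")
    return (n_start_before - n_end_before).astype(int)


def coverage_fraction(region: Interval, peaks: IntervalSet) -> float:
    """Fraction of the region's bases covered by the union of peaks."""
    covered = 0
    for chrom, ivs in merge(peaks).by_chrom().items():
        if chrom != region.chrom:
            continue
        for iv in ivs:
            covered += max(0, min(iv.end, region.end) - max(iv.start, region.start))
    return covered / len(region)


def relative_distances(
    query: IntervalSet, reference: IntervalSet
) -> RelDistDistribution:
    """Relative distance of each query midpoint to its flanking reference
    midpoints (0 = on a reference midpoint, 0.5 = exactly between two).

    Independent placement of queries yields values uniform on [0, 0.5];
    attraction to the reference skews mass toward 0.
    """
    if len(reference) == 0:
        raise ValueError("reference set is empty")
    ref_mids: dict[str, np.ndarray] = {}
    for chrom, ivs in reference.by_chrom().items():
        mids = np.unique(np.array([iv.midpoint for iv in ivs]))
        ref_mids[chrom] = mids
    values: list[float] = []
    n_dropped = 0
    for iv in query:
        mids = ref_mids.get(iv.chrom)
        q = iv.midpoint
        if mids is None or len(mids) < 2 or q < mids[0] or q > mids[-1]:
            n_dropped += 1
            continue
        j = int(np.searchsorted(mids, q, side="right"))
        if j == len(mids):  # q equals the last midpoint
            values.append(0.0)
            continue
        left, right = int(mids[j - 1]), int(mids[j])
        gap = right - left
        d = min(q - left, right - q)
        values.append(d / gap)
    return RelDistDistribution(values=np.asarray(values, dtype=float), n_dropped=n_dropped)
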