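"""Superenhancer activity and G4-richness classification.

Activity labels follow the catalog-membership x enhancer-RNA (CAGE) truth
table used for SE annotation:

* in the target cell's catalog, CAGE-overlapping  -> active
* in the target cell's catalog, no CAGE           -> poised
* only in other cells' catalogs, no CAGE          -> repressed
* only in other cells' catalogs, CAGE-overlapping -> not_applicable (excluded)

An SE present in the target cell and elsewhere is classified by the
target-cell rule. G4-richness is assigned over the active+poised population:
SEs with zero overlapping folded-G4 (BG4) peaks are g4_free; the top quartile
by BG4 peak frequency — overlapping-peak count per kb of SE length, i.e. the
top ceil(N/4) SEs with ties included — is g4_rich; the rest are intermediate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .genome import Interval, IntervalSet
from .intervals import _overlap_mask, coverage_fraction, merge, overlap_counts

__all__ = [
    "SERecord",
    "ColocalizationProfile",
    "classify_activity",
    "classify_g4_richness",
    "compute_coverage",
    "compare_coverage",
    "colocalization_profile",
    "rank_ses_for_motif_search",
]


@dataclass
class SERecord:
    """One superenhancer with its classification state."""

    interval: Interval
    present_in: frozenset[str]
    cage_positive: bool
    activity: str  # active | poised | repressed | not_applicable
    rank: int | None = None
    coverage: dict = field(default_factory=dict)
    peak_counts: dict = field(default_factory=dict)
    g4_class: str | None = None  # g4_rich | g4_free | intermediate

    @property
    def length_kb(self) -> float:
        return len(self.interval) / 1000.0

    def peak_frequency(self, mark: str) -> float:
        """Overlapping peaks per kb of SE length."""
        return self.peak_counts[mark] / self.length_kb


def classify_activity(
    se_catalogs: dict[str, IntervalSet],
    cage: IntervalSet,
    target_cell: str,
) -> list[SERecord]:
    """Label SEs as active/poised/repressed/not_applicable.

    The record list contains every interval of the target-cell catalog plus
    the intervals of other catalogs that do not overlap the target catalog
    (deduplicated by merging across the other catalogs).
    """
    if target_cell not in se_catalogs:
        raise ValueError(f"target cell {target_cell!r} not among catalogs")
    target = se_catalogs[target_cell]
    if len(target) == 0:
        raise ValueError("target-cell SE catalog is empty")

    def mask(a: IntervalSet, b: IntervalSet) -> np.ndarray:
        if len(a) == 0 or len(b) == 0:
            return np.zeros(len(a), dtype=bool)
        return _overlap_mask(a, b)

    records: list[SERecord] = []
    other_names = [c for c in se_catalogs if c != target_cell]
    cage_t = mask(target, cage)
    other_t = {o: mask(target, se_catalogs[o]) for o in other_names}
    for i, iv in enumerate(target):
        present = {target_cell} | {o for o in other_names if other_t[o][i]}
        records.append(
            SERecord(
                interval=iv,
                present_in=frozenset(present),
                cage_positive=bool(cage_t[i]),
                activity="active" if cage_t[i] else "poised",
            )
        )

    if other_names:
        pooled = [iv for other in other_names for iv in se_catalogs[other]]
        others_merged = merge(IntervalSet(pooled, target.layout))
        in_target = mask(others_merged, target)
        absent_set = others_merged.replace_intervals(
            iv for iv, hit in zip(others_merged, in_target) if not hit
        )
        cage_o = mask(absent_set, cage)
        other_o = {o: mask(absent_set, se_catalogs[o]) for o in other_names}
        for i, iv in enumerate(absent_set):
            present = {o for o in other_names if other_o[o][i]}
            records.append(
                SERecord(
                    interval=iv,
                    present_in=frozenset(present),
                    cage_positive=bool(cage_o[i]),
                    activity="not_applicable" if cage_o[i] else "repressed",
                )
            )
    return records


def classify_g4_richness(
    records: list[SERecord],
    bg4: IntervalSet,
    by: str = "frequency",
) -> list[SERecord]:
    """Assign g4_rich / g4_free / intermediate over active+poised records.

    ``by`` selects the ranking statistic: "frequency" (peaks per kb, default)
    or "count" (absolute overlapping-peak count). The g4_rich threshold is
    the ceil(N/4)-th largest value with ties included, so distinct values
    yield exactly ceil(N/4) g4_rich SEs.
    """
    if by not in ("frequency", "count"):
        raise ValueError("by must be 'frequency' or 'count'")
    pop = [r for r in records if r.activity in ("active", "poised")]
    if len(pop) < 4:
        raise ValueError("need >= 4 active/poised records to define a quartile")
    layout = bg4.layout
    ses = IntervalSet([r.interval for r in pop], layout)
    counts = overlap_counts(ses, bg4)
    # overlap_counts follows normalized (sorted) order; map back to records
    order = {
        (iv.chrom, iv.start, iv.end): c for iv, c in zip(ses, counts)
    }
    for r in pop:
        key = (r.interval.chrom, r.interval.start, r.interval.end)
        r.peak_counts["BG4"] = int(order[key])
    values = np.array(
        [
            r.peak_frequency("BG4") if by == "frequency" else r.peak_counts["BG4"]
            for r in pop
        ],
        dtype=float,
    )
    k = math.ceil(len(pop) / 4)
    threshold = np.sort(values)[::-1][k - 1]
    for r, v in zip(pop, values):
        if r.peak_counts["BG4"] == 0:
            r.g4_class = "g4_free"
        elif v >= threshold:
            r.g4_class = "g4_rich"
        else:
            r.g4_class = "intermediate"
    return records


def compute_coverage(
    records: list[SERecord], marks: dict[str, IntervalSet]
) -> list[SERecord]:
    """Fill each record's per-mark base-coverage fraction."""
    merged = {name: merge(m) for name, m in marks.items()}
    for r in records:
        for name, m in merged.items():
            r.coverage[name] = coverage_fraction(r.interval, m)
    return records


def compare_coverage(
    group_a: list[SERecord], group_b: list[SERecord], mark: str
) -> dict:
    """Two-sided Mann-Whitney U comparison of a mark's coverage.

    Uses the exact U distribution when both groups have <= 20 records and the
    pooled values are tie-free; otherwise the tie-corrected normal
    approximation.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    a = np.array([r.coverage[mark] for r in group_a])
    b = np.array([r.coverage[mark] for r in group_b])
    no_ties = len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
    method = "exact" if (len(a) <= 20 and len(b) <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return {
        "U": float(res.statistic),
        "p": float(res.pvalue),
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "method": method,
    }


@dataclass
class ColocalizationProfile:
    """Signed peak-center offsets around anchor centers, binned."""

    bin_edges: np.ndarray
    counts: dict  # mark -> np.ndarray of per-bin counts
    offsets: dict  # mark -> np.ndarray of raw signed offsets

    def frac_within(self, mark: str, radius: int) -> float:
        off = self.offsets[mark]
        if len(off) == 0:
            return float("nan")
        return float(np.mean(np.abs(off) <= radius))


def colocalization_profile(
    anchors: IntervalSet,
    marks: dict[str, IntervalSet],
    window: int = 1000,
    bin_size: int = 50,
) -> ColocalizationProfile:
    """Distribution of mark-peak centers relative to the nearest anchor center.

    A mark peak contributes one signed offset if its center (floor of the
    interval midpoint) lies within +/- window of the nearest anchor center on
    the same chromosome.
    """
    if len(anchors) == 0:
        raise ValueError("no anchors")
    if window % bin_size != 0:
        raise ValueError("window must be a multiple of bin_size")
    anchor_mids: dict[str, np.ndarray] = {}
    for chrom, ivs in anchors.by_chrom().items():
        anchor_mids[chrom] = np.sort(np.array([iv.midpoint for iv in ivs]))
    edges = np.arange(-window, window + bin_size, bin_size)
    counts: dict[str, np.ndarray] = {}
    offsets: dict[str, np.ndarray] = {}
    for name, peaks in marks.items():
        offs: list[int] = []
        for iv in peaks:
            mids = anchor_mids.get(iv.chrom)
            if mids is None:
                continue
            c = iv.midpoint
            j = int(np.searchsorted(mids, c))
            best = None
            for cand in (j - 1, j):
                if 0 <= cand < len(mids):
                    d = c - int(mids[cand])
                    if best is None or abs(d) < abs(best):
                        best = d
            if best is not None and abs(best) <= window:
                offs.append(best)
        arr = np.asarray(offs, dtype=int)
        offsets[name] = arr
        counts[name], _ = np.histogram(arr, bins=edges)
    return ColocalizationProfile(bin_edges=edges, counts=counts, offsets=offsets)


def rank_ses_for_motif_search(
    records: list[SERecord],
    peak_sets: dict[str, IntervalSet],
    k: int = 5,
) -> list[SERecord]:
    """Top-k SEs per (peak set x {frequency, total count}) category, pooled.

    Mirrors the motif-discovery pre-selection: SEs are sorted per category,
    the top k of each are taken, and the union is returned with duplicates
    removed (order: first appearance across categories).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not records:
        raise ValueError("no records")
    layout = next(iter(peak_sets.values())).layout
    ses = IntervalSet([r.interval for r in records], layout)
    for name, peaks in peak_sets.items():
        counts = overlap_counts(ses, peaks)
        order = {(iv.chrom, iv.start, iv.end): c for iv, c in zip(ses, counts)}
        for r in records:
            key = (r.interval.chrom, r.interval.start, r.interval.end)
            r.peak_counts[name] = int(order[key])
    selected: list[SERecord] = []
    seen: set[int] = set()
    for name in peak_sets:
        for stat in ("frequency", "count"):
            keyfn = (
                (lambda r: r.peak_frequency(name))
                if stat == "frequency"
                else (lambda r: r.peak_counts[name])
            )
            top = sorted(records, key=keyfn, reverse=True)[:k]
            for r in top:
                if id(r) not in seen:
                    seen.add(id(r))
                    selected.append(r)
    return selected
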