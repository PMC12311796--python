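"""G-quadruplex folding-propensity scoring (G4Hunter scheme).

Per-base scores: every G in a run of k consecutive Gs scores +min(k, 4);
every C in a run of k Cs scores -min(k, 4); all other bases score 0. The
sliding-window score is the mean per-base score over the window (default 25
nt), and regions whose window scores stay at or above a threshold (default
1.2, the conventional cutoff) are reported as G4 candidates. Positive scores
indicate a G-rich (same-strand) candidate, negative scores a C-rich one,
i.e. a G4 on the reverse complement.

This module is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .genome import IntervalSet

__all__ = [
    "G4Candidate",
    "base_scores",
    "window_scores",
    "extract_candidates",
    "score_interval_set",
    "DEFAULT_WINDOW",
    "DEFAULT_THRESHOLD",
]

DEFAULT_WINDOW = 25
DEFAULT_THRESHOLD = 1.2


@dataclass(frozen=True)
class G4Candidate:
    """A contiguous above-threshold region within a source sequence.

    Offsets are 0-based half-open within the source. ``score`` is the mean
    per-base score over the merged span; its sign records orientation
    (positive = G-rich on the given strand).
    """

    source_name: str
    start: int
    end: int
    score: float
    sequence: str


def base_scores(sequence: str) -> np.ndarray:
    """Per-base integer scores in [-4, 4]; unknown characters score 0."""
    n = len(sequence)
    scores = np.zeros(n, dtype=np.int8)
    i = 0
    while i < n:
        ch = sequence[i]
        if ch in ("G", "C"):
            j = i
            while j < n and sequence[j] == ch:
                j += 1
            run = min(j - i, 4)
            scores[i:j] = run if ch == "G" else -run
            i = j
        else:
            i += 1
    return scores


def window_scores(sequence: str, window: int = DEFAULT_WINDOW) -> np.ndarray:
    """Sliding-window means of the per-base scores.

    Returns an empty array (with a warning via the empty length) when the
    sequence is shorter than the window.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    b = base_scores(sequence).astype(float)
    if len(b) < window:
        return np.empty(0)
    csum = np.concatenate(([0.0], np.cumsum(b)))
    return (csum[window:] - csum[:-window]) / window


def extract_candidates(
    sequence: str,
    window: int = DEFAULT_WINDOW,
    threshold: float = DEFAULT_THRESHOLD,
    source_name: str = "seq",
) -> list[G4Candidate]:
    """Candidates from merged overlapping windows with |score| >= threshold.

    Qualifying windows of the same orientation whose spans overlap are
    merged into a single region (first window start to last window end),
    then trimmed to its G-run core (C-run core for negative orientation) so
    the reported span starts and ends on scoring bases — the refined-region
    convention. The candidate score is the mean base score over the trimmed
    span; it is reported as-is, not re-thresholded.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    ws = window_scores(sequence, window)
    if len(ws) == 0:
        return []
    b = base_scores(sequence).astype(float)
    sign = np.where(ws >= threshold, 1, np.where(ws <= -threshold, -1, 0))
    candidates: list[G4Candidate] = []
    n = len(sign)
    qualifying = np.flatnonzero(sign)
    groups: list[tuple[int, int, int]] = []  # (first idx, last idx, sign)
    for idx in qualifying:
        s = int(sign[idx])
        if groups and s == groups[-1][2] and idx < groups[-1][1] + window:
            groups[-1] = (groups[-1][0], int(idx), s)
        else:
            groups.append((int(idx), int(idx), s))
    for first, last, s in groups:
        start, end = first, last + window  # union span of merged windows
        core = "G" if s > 0 else "C"
        while start < end and sequence[start] != core:
            start += 1
        while end > start and sequence[end - 1] != core:
            end -= 1
        if end == start:  # no core base in span (cannot occur above threshold)
            continue
        span_score = float(b[start:end].mean())
        candidates.append(
            G4Candidate(
                source_name=source_name,
                start=start,
                end=end,
                score=span_score,
                sequence=sequence[start:end],
            )
        )
    return candidates


def score_interval_set(
    iset: IntervalSet,
    fasta: Mapping[str, str],
    window: int = DEFAULT_WINDOW,
    threshold: float = DEFAULT_THRESHOLD,
    g_rich_only: bool = False,
) -> list[G4Candidate]:
    """Run candidate extraction over every interval of a set.

    Sequences are looked up by interval name, then by "chrom:start-end", and
    finally by slicing a chromosome-level sequence keyed by ``chrom``.
    Intervals whose sequence cannot be found are skipped and reported
    together in a ValueError only if *no* interval could be scored.
    """
    candidates: list[G4Candidate] = []
    missing: list[str] = []
    scored = 0
    for iv in iset:
        key = f"{iv.chrom}:{iv.start}-{iv.end}"
        if iv.name is not None and iv.name in fasta:
            seq, label = fasta[iv.name], iv.name
        elif key in fasta:
            seq, label = fasta[key], key
        elif iv.chrom in fasta and len(fasta[iv.chrom]) >= iv.end:
            seq, label = fasta[iv.chrom][iv.start : iv.end], key
        else:
            missing.append(key)
            continue
        scored += 1
        for cand in extract_candidates(seq, window, threshold, source_name=label):
            if g_rich_only and cand.score < 0:
                continue
            candidates.append(cand)
    if missing and scored == 0:
        raise ValueError(f"no sequence found for any interval (e.g. {missing[0]})")
    return candidates


def revcomp(sequence: str) -> str:
    comp = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")
    return sequence.translate(comp)[::-1]
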