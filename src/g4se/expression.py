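"""Relative qPCR quantification (delta-delta-Cq) and feature correlation.

Technical replicates are averaged per (gene, condition, biological
replicate); dCq = Cq_gene - mean(Cq of the reference genes) in the same
(condition, biological replicate); ddCq = mean_bio dCq(treated) - mean_bio
dCq(control); log2 fold change = -ddCq (one planted log2FC unit = one Cq
cycle). Gene-level p-values come from a two-sided Welch t-test on the
per-biological-replicate dCq values between conditions — biological
replicates are the inference unit, and with the conventional two of them the
test is flagged as low-powered rather than silently trusted.

Regulation calls use the stringent rule: up if p < 0.05 and log2FC > 2, down
if p < 0.05 and log2FC < -2, otherwise unchanged.

Feature correlations are Spearman rank correlations (average ranks on ties)
with a two-tailed p by exact permutation when n <= 10 (gene panels here are
that small) and by the t approximation otherwise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegulationResult",
    "FeatureCorrelation",
    "ddcq_log2fc",
    "analyze_regulation",
    "classify_regulation",
    "spearman",
    "correlate_with_features",
]

REQUIRED_COLUMNS = ("gene", "condition", "bio_rep", "tech_rep", "cq")


@dataclass
class RegulationResult:
    gene: str
    log2fc: float
    p_value: float
    regulation: str  # up | down | unchanged


@dataclass
class FeatureCorrelation:
    feature_name: str
    r_s: float
    p_two_tailed: float
    n: int
    flag: str | None = None


def _validate(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Cq table missing columns: {missing}")


def _dcq_per_bio_rep(
    table: pd.DataFrame, gene: str, condition: str, reference_genes
) -> pd.Series:
    """dCq per biological replicate for one gene in one condition."""
    sub = table[table.condition == condition]
    refs = list(reference_genes)
    for ref in refs:
        if not ((sub.gene == ref).any()):
            raise ValueError(f"reference gene {ref!r} missing in {condition!r}")
    if not (sub.gene == gene).any():
        raise ValueError(f"gene {gene!r} missing in condition {condition!r}")
    tech_avg = (
        sub.groupby(["gene", "bio_rep"], sort=True)["cq"].mean().unstack("gene")
    )
    ref_mean = tech_avg[refs].mean(axis=1)
    return tech_avg[gene] - ref_mean


def ddcq_log2fc(
    table: pd.DataFrame,
    gene: str,
    treated_condition: str,
    control_condition: str = "control",
    reference_genes=("RPLP0", "RPS18"),
) -> dict:
    """log2 fold change of one gene, treated vs control.

    Returns a dict with ``log2fc``, per-condition per-biological-replicate
    dCq values, and the Welch t-test p-value (nan if either condition has a
    single biological replicate).
    """
    _validate(table)
    dcq_t = _dcq_per_bio_rep(table, gene, treated_condition, reference_genes)
    dcq_c = _dcq_per_bio_rep(table, gene, control_condition, reference_genes)
    ddcq = dcq_t.mean() - dcq_c.mean()
    if len(dcq_t) > 1 and len(dcq_c) > 1 and (dcq_t.std() + dcq_c.std()) > 1e-9:
        p = float(stats.ttest_ind(dcq_t, dcq_c, equal_var=False).pvalue)
    elif len(dcq_t) > 1 and len(dcq_c) > 1:
        p = 1.0 if abs(ddcq) < 1e-9 else 0.0  # zero within-group variance
    else:
        p = float("nan")
    return {
        "gene": gene,
        "log2fc": float(-ddcq),
        "p_value": p,
        "dcq_treated": dcq_t.to_dict(),
        "dcq_control": dcq_c.to_dict(),
    }


def analyze_regulation(
    table: pd.DataFrame,
    treated_condition: str,
    control_condition: str = "control",
    reference_genes=("RPLP0", "RPS18"),
    p_threshold: float = 0.05,
    fc_threshold: float = 2.0,
) -> list[RegulationResult]:
    """ddCq + classification for every non-reference gene in the table."""
    _validate(table)
    genes = [g for g in table.gene.unique() if g not in set(reference_genes)]
    out = []
    for gene in genes:
        r = ddcq_log2fc(
            table, gene, treated_condition, control_condition, reference_genes
        )
        out.append((gene, r["log2fc"], r["p_value"]))
    return classify_regulation(out, p_threshold, fc_threshold)


def classify_regulation(
    results,
    p_threshold: float = 0.05,
    fc_threshold: float = 2.0,
) -> list[RegulationResult]:
    """Three-way call from (gene, log2FC, p) triples.

    up iff p < p_threshold and log2FC > fc_threshold; down iff p < p_threshold
    and log2FC < -fc_threshold; else unchanged.
    """
    out: list[RegulationResult] = []
    for gene, log2fc, p in results:
        if not math.isnan(p) and p < p_threshold and log2fc > fc_threshold:
            cls = "up"
        elif not math.isnan(p) and p < p_threshold and log2fc < -fc_threshold:
            cls = "down"
        else:
            cls = "unchanged"
        out.append(RegulationResult(gene, float(log2fc), float(p), cls))
    return out


def _rank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


_PERM_CACHE: dict[int, np.ndarray] = {}


def _permutation_indices(n: int) -> np.ndarray:
    """All n! permutations of range(n) as an (n!, n) int8 array, cached."""
    if n not in _PERM_CACHE:
        _PERM_CACHE[n] = np.array(
            list(itertools.permutations(range(n))), dtype=np.int8
        )
    return _PERM_CACHE[n]


def spearman(x, y, exact_max_n: int = 10) -> tuple[float, float]:
    """Spearman rho with a two-tailed p.

    Exact permutation p (enumeration of all n! orderings of y) for
    n <= exact_max_n; Student-t approximation above. Ties get average ranks.
    Raises if either input is constant (correlation undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need >= 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    rx, ry = _rank(x), _rank(y)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = math.sqrt(float(rx_c @ rx_c) * float(ry_c @ ry_c))
    rho = float(rx_c @ ry_c) / denom
    n = len(x)
    if n <= exact_max_n:
        # enumerate all orderings of y-ranks in vectorized chunks
        obs = abs(float(rx_c @ ry_c))
        perms = _permutation_indices(n)
        count = 0
        for lo in range(0, len(perms), 500_000):
            s = np.abs(ry_c[perms[lo : lo + 500_000]] @ rx_c)
            count += int(np.sum(s >= obs - 1e-9))
        p = count / len(perms)
    else:
        t = rho * math.sqrt((n - 2) / max(1e-300, 1.0 - rho * rho))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
        p = min(p, 1.0)
    return rho, p


def correlate_with_features(
    results: list[RegulationResult],
    feature_table: pd.DataFrame,
    exact_max_n: int = 10,
) -> list[FeatureCorrelation]:
    """Spearman correlation of log2FC against each genomic feature column.

    ``feature_table`` is indexed by gene (or has a 'gene' column); every
    other column is a feature. Constant features are flagged, not computed.
    """
    if "gene" in feature_table.columns:
        feature_table = feature_table.set_index("gene")
    fc = {r.gene: r.log2fc for r in results}
    genes = [g for g in feature_table.index if g in fc]
    if len(genes) < 4:
        raise ValueError("need >= 4 genes shared between results and features")
    y = np.array([fc[g] for g in genes])
    out: list[FeatureCorrelation] = []
    for col in feature_table.columns:
        x = feature_table.loc[genes, col].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            out.append(
                FeatureCorrelation(col, float("nan"), float("nan"), len(genes),
                                   flag="constant feature")
            )
            continue
        rho, p = spearman(x, y, exact_max_n=exact_max_n)
        out.append(FeatureCorrelation(col, rho, p, len(genes)))
    return out
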