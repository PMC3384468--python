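"""Category-level GC3 statistics: the Blue < Black < Red hierarchy test,
ΔGC3 between genomes over ortholog pairs, and coding/non-coding correlations.

The hierarchy test asks whether, within one genome, the GC3 of genes in the
metabolism category (RED) exceeds that of cellular processes and signaling
(BLACK), which in turn exceeds information storage and processing (BLUE).
All pairwise tests are two-sided Mann-Whitney rank-sum tests, with direction
read post hoc from the sample means; no multiple-testing correction is
applied across the three pairwise tests (flagged in the output).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .composition import CATEGORIES, GeneRecord
from .orthology import OrthologPair

logger = logging.getLogger("gc3kog")

BLUE, BLACK, RED = CATEGORIES

PATTERN = "PATTERN"
PARTIAL = "PARTIAL"
NONE = "NONE"


@dataclass(frozen=True)
class CategoryComparison:
    genome: str
    pair: tuple[str, str]
    statistic: float  # Mann-Whitney U for the first member of the pair
    p_two_sided: float
    direction: str  # category with the higher sample mean

    def __post_init__(self) -> None:
        if not (0 < self.p_two_sided <= 1):
            raise ValueError("p-value must be in (0, 1]")


@dataclass(frozen=True)
class DeltaRecord:
    ref_id: str
    target_id: str
    category: str
    delta_gc3: float  # gc3(ref) − gc3(target)

    def __post_init__(self) -> None:
        if not (-1.0 <= self.delta_gc3 <= 1.0):
            raise ValueError("delta_gc3 must lie in [-1, 1]")


def mann_whitney(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> tuple[float, float]:
    """Mann-Whitney U test; returns (U for x, p).

    The exact null distribution is used when min(n, m) ≤ 8 and the pooled
    sample has no ties; otherwise the normal approximation with tie and
    continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney requires non-empty samples")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (min(x.size, y.size) <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative=alternative, method=method, use_continuity=True
    )
    # the normal approximation can underflow to 0; keep p strictly positive
    p = max(float(res.pvalue), float(np.finfo(float).tiny))
    return float(res.statistic), min(p, 1.0)


def category_hierarchy_test(
    records: Sequence[GeneRecord], alpha: float = 0.05, genome: str | None = None
) -> tuple[list[CategoryComparison], str]:
    """Pairwise Red-vs-Black, Red-vs-Blue, Black-vs-Blue tests + verdict.

    Verdicts: ``PATTERN`` — all three tests significant at ``alpha`` and the
    sample means are ordered Blue < Black < Red; ``PARTIAL`` — Red
    significantly exceeds both Black and Blue but Black-vs-Blue is not
    significant; ``NONE`` otherwise.
    """
    samples: dict[str, list[float]] = {c: [] for c in CATEGORIES}
    for r in records:
        if r.category in samples:
            samples[r.category].append(r.gc3)
    missing = [c for c in CATEGORIES if not samples[c]]
    if missing:
        raise ValueError(f"missing categories: {missing}")
    if genome is None:
        genome = records[0].species

    means = {c: float(np.mean(samples[c])) for c in CATEGORIES}
    comparisons = []
    results: dict[tuple[str, str], tuple[float, bool]] = {}
    for a, b in [(RED, BLACK), (RED, BLUE), (BLACK, BLUE)]:
        u, p = mann_whitney(samples[a], samples[b], "two-sided")
        direction = a if means[a] >= means[b] else b
        comparisons.append(CategoryComparison(genome, (a, b), u, p, direction))
        results[(a, b)] = (p, direction == a and p < alpha)

    ordered = means[BLUE] < means[BLACK] < means[RED]
    red_over_black = results[(RED, BLACK)][1]
    red_over_blue = results[(RED, BLUE)][1]
    black_blue_sig = results[(BLACK, BLUE)][0] < alpha
    if ordered and red_over_black and red_over_blue and black_blue_sig:
        verdict = PATTERN
    elif red_over_black and red_over_blue and not black_blue_sig:
        verdict = PARTIAL
    else:
        verdict = NONE
    return comparisons, verdict


@dataclass
class DeltaGc3Result:
    deltas: list[DeltaRecord]
    per_category: pd.DataFrame  # columns: category, n, mean_delta, se_delta
    tests: list[CategoryComparison]
    degenerate: bool  # all deltas identical; tests are meaningless


def _pairs_as_ids(pairs: Iterable) -> list[tuple[str, str]]:
    out = []
    for p in pairs:
        if isinstance(p, OrthologPair):
            out.append((p.ref_id, p.target_id))
        else:
            out.append((p[0], p[1]))
    return out


def delta_gc3(
    pairs: Iterable,
    ref_records: Sequence[GeneRecord],
    target_records: Sequence[GeneRecord],
) -> DeltaGc3Result:
    """ΔGC3 = gc3(reference) − gc3(target) per ortholog pair, grouped by the
    reference gene's category, with Red-vs-Black and Red-vs-Blue tests."""
    ref_by_id = {r.id: r for r in ref_records}
    tgt_by_id = {r.id: r for r in target_records}
    deltas: list[DeltaRecord] = []
    for ref_id, tgt_id in _pairs_as_ids(pairs):
        if ref_id not in ref_by_id or tgt_id not in tgt_by_id:
            raise KeyError(f"pair ({ref_id}, {tgt_id}) references an unknown gene")
        ref = ref_by_id[ref_id]
        if ref.category is None:
            continue
        deltas.append(
            DeltaRecord(ref_id, tgt_id, ref.category, ref.gc3 - tgt_by_id[tgt_id].gc3)
        )
    if not deltas:
        raise ValueError("no categorized ortholog pairs")

    by_cat: dict[str, list[float]] = {}
    for d in deltas:
        by_cat.setdefault(d.category, []).append(d.delta_gc3)
    rows = []
    for cat in CATEGORIES:
        vals = np.asarray(by_cat.get(cat, []), dtype=float)
        if vals.size == 0:
            continue
        se = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
        rows.append({"category": cat, "n": vals.size, "mean_delta": float(vals.mean()), "se_delta": se})
    per_category = pd.DataFrame(rows)

    all_vals = np.array([d.delta_gc3 for d in deltas])
    degenerate = bool(np.all(all_vals == all_vals[0]))
    genome = f"{deltas[0].ref_id.split('_')[0]}"
    tests = []
    if not degenerate:
        for a, b in [(RED, BLACK), (RED, BLUE)]:
            if a in by_cat and b in by_cat:
                u, p = mann_whitney(by_cat[a], by_cat[b], "two-sided")
                direction = a if np.mean(by_cat[a]) >= np.mean(by_cat[b]) else b
                tests.append(CategoryComparison(genome, (a, b), u, p, direction))
    else:
        logger.warning("all ΔGC3 values identical; rank tests skipped")
    return DeltaGc3Result(deltas, per_category, tests, degenerate)


def gc_correlations(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson and Spearman correlations with p-values.

    ``table`` holds one row per gene and one column per compositional
    variable (e.g. gc3, intron GC, 5'/3' flank GC); rows with any missing
    value are dropped.  At least 3 complete rows are required.
    """
    complete = table.dropna()
    if len(complete) < 3:
        raise ValueError("gc_correlations requires at least 3 complete rows")
    cols = list(complete.columns)
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            pr, pp = stats.pearsonr(complete[a], complete[b])
            sr, sp = stats.spearmanr(complete[a], complete[b])
            rows.append(
                {
                    "x": a, "y": b, "n": len(complete),
                    "pearson_r": float(pr), "pearson_p": float(pp),
                    "spearman_rho": float(sr), "spearman_p": float(sp),
                }
            )
    return pd.DataFrame(rows)
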