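"""Butterfly analysis: per-class deviation of mean GC3 from the genome mean.

Each functional class's gene-level GC3 values are tested against the genome
mean (a one-sample two-sided t-test with the genome mean treated as a
constant), with Bonferroni correction over the retained classes.  Sorting
the deviations ascending puts negatives left and positives right — the
butterfly shape.  Across genomes, recurrence reports how often each class
falls on the positive side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .composition import GeneRecord
from .kog_catalog import category_of

logger = logging.getLogger("gc3kog")


@dataclass(frozen=True)
class ButterflyEntry:
    genome: str
    kog_class: str
    category: str
    n: int
    delta: float  # class mean GC3 − genome mean GC3
    t_stat: float | None
    p_raw: float | None
    p_bonferroni: float | None
    significant_higher: bool
    zero_variance: bool = False

    def __post_init__(self) -> None:
        if self.significant_higher and self.delta <= 0:
            raise ValueError("significant_higher requires delta > 0")


def genome_mean(
    all_cds_records: Sequence[GeneRecord] | None,
    kog_records: Sequence[GeneRecord],
) -> float:
    """Mean GC3 of the full CDS set; falls back to the KOG subset (with a
    warning) when the full set is unavailable."""
    if all_cds_records:
        return float(np.mean([r.gc3 for r in all_cds_records]))
    if not kog_records:
        raise ValueError("no records to average")
    logger.warning("full CDS set unavailable; genome mean computed on the KOG subset")
    return float(np.mean([r.gc3 for r in kog_records]))


def butterfly_analysis(
    class_records: Sequence[GeneRecord],
    genome_gc3_mean: float,
    alpha: float = 0.05,
    genome: str | None = None,
) -> list[ButterflyEntry]:
    """One entry per class, sorted ascending by delta.

    Classes with fewer than 2 genes are excluded with a warning; zero-variance
    classes report the delta's sign only (t undefined).  Bonferroni multiplies
    the raw p by the number of retained classes, capped at 1.
    """
    by_class: dict[str, list[float]] = {}
    for r in class_records:
        if r.kog_class is not None:
            by_class.setdefault(r.kog_class, []).append(r.gc3)
    usable = {}
    for letter, vals in sorted(by_class.items()):
        if len(vals) < 2:
            logger.warning("class %s has n=%d < 2; excluded from butterfly", letter, len(vals))
            continue
        usable[letter] = np.asarray(vals, dtype=float)
    if not usable:
        raise ValueError("no class with n >= 2")
    if genome is None:
        genome = class_records[0].species
    m = len(usable)

    entries = []
    for letter, vals in usable.items():
        delta = float(vals.mean() - genome_gc3_mean)
        if vals.std(ddof=1) == 0.0:
            entries.append(
                ButterflyEntry(genome, letter, category_of(letter), vals.size,
                               delta, None, None, None, False, zero_variance=True)
            )
            continue
        t, p = stats.ttest_1samp(vals, popmean=genome_gc3_mean)
        p_bonf = min(1.0, float(p) * m)
        entries.append(
            ButterflyEntry(
                genome, letter, category_of(letter), vals.size, delta,
                float(t), float(p), p_bonf,
                significant_higher=bool(delta > 0 and p_bonf < alpha),
            )
        )
    entries.sort(key=lambda e: e.delta)
    return entries


def recurrence(entries: Sequence[ButterflyEntry]) -> pd.DataFrame:
    """Across-genome recurrence: per class, the percentage of genomes where
    the class sits on the positive side of the butterfly plot, and where it
    is significantly higher."""
    genomes = {e.genome for e in entries}
    if len(genomes) < 2:
        raise ValueError("recurrence requires entries from at least 2 genomes")
    by_class: dict[str, list[ButterflyEntry]] = {}
    for e in entries:
        by_class.setdefault(e.kog_class, []).append(e)
    rows = []
    for letter in sorted(by_class):
        es = by_class[letter]
        n = len(es)
        rows.append(
            {
                "kog_class": letter,
                "category": es[0].category,
                "n_genomes": n,
                "pct_positive": 100.0 * sum(e.delta > 0 for e in es) / n,
                "pct_significant_higher": 100.0 * sum(e.significant_higher for e in es) / n,
            }
        )
    return pd.DataFrame(rows)


def entries_table(entries: Sequence[ButterflyEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "genome": [e.genome for e in entries],
            "kog_class": [e.kog_class for e in entries],
            "category": [e.category for e in entries],
            "n": [e.n for e in entries],
            "delta": [e.delta for e in entries],
            "t": [e.t_stat for e in entries],
            "p_raw": [e.p_raw for e in entries],
            "p_bonferroni": [e.p_bonferroni for e in entries],
            "significant_higher": [e.significant_higher for e in entries],
            "zero_variance": [e.zero_variance for e in entries],
        }
    )
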