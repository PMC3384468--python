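"""Association of KOG classes and categories with chromosomal band types.

The four human compositional band types, in order of increasing GC content,
are L1+, L1-, H3- and H3+ (H3+ being the GC-richest).  The band map is an
input — band calling from karyotypes is out of scope.  Tests: a Pearson χ²
of category × {H3-, H3+}, pooled two-proportion one-sided Z-tests per class,
and the positive/negative butterfly-group comparison of H3+ vs L1+ shares.

Two normalizations are emitted for the frequency tables: the class-internal
profile (fraction of a class's genes per band, rows sum to 1) and the
per-band composition (a class's share of the band's genes) — the latter is
the denominator used by the Z-tests.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportions_ztest

from .composition import BANDS, CATEGORIES, GeneRecord
from .butterfly import ButterflyEntry

logger = logging.getLogger("gc3kog")


def load_band_map(path: str | Path) -> dict[str, str]:
    """Read a gene_id → band TSV; bands must be one of L1+, L1-, H3-, H3+."""
    out: dict[str, str] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            gene, band = row[0], row[1].strip()
            if band not in BANDS:
                raise ValueError(f"invalid band label {band!r} for gene {gene!r}")
            out[gene] = band
    return out


def band_coverage(records: Sequence[GeneRecord], band_map: Mapping[str, str]) -> float:
    """Fraction of the records with a band assignment."""
    if not records:
        raise ValueError("no records")
    return sum(r.id in band_map for r in records) / len(records)


@dataclass
class BandTable:
    counts: pd.DataFrame  # classes × 4 bands, fixed band order
    class_profiles: pd.DataFrame  # rows sum to 1 (class-internal)
    band_composition: pd.DataFrame  # columns sum to 1 (class share of band)

    @property
    def band_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)


def band_frequencies(records: Sequence[GeneRecord]) -> BandTable:
    """Class × band gene counts plus both normalizations."""
    assigned = [r for r in records if r.band is not None and r.kog_class is not None]
    if not assigned:
        raise ValueError("no records with both class and band assignments")
    letters = sorted({r.kog_class for r in assigned})
    counts = pd.DataFrame(0, index=letters, columns=list(BANDS))
    for r in assigned:
        counts.loc[r.kog_class, r.band] += 1
    profiles = counts.div(counts.sum(axis=1), axis=0)
    composition = counts.div(counts.sum(axis=0), axis=1)
    return BandTable(counts, profiles, composition)


def category_band_chisq(counts: pd.DataFrame | np.ndarray) -> tuple[float, int, float]:
    """Pearson χ² (no continuity correction) of a 3-category × 2-band table,
    typically categories × {H3-, H3+}."""
    arr = np.asarray(counts, dtype=float)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in the contingency table")
    chi2, p, df, expected = stats.chi2_contingency(arr, correction=False)
    if (expected < 5).any():
        logger.warning("χ²: some expected counts below 5")
    return float(chi2), int(df), float(p)


def category_band_counts(records: Sequence[GeneRecord], bands: Sequence[str] = ("H3-", "H3+")) -> pd.DataFrame:
    """Category × selected-bands gene counts (default the two H3 band types)."""
    table = pd.DataFrame(0, index=list(CATEGORIES), columns=list(bands))
    for r in records:
        if r.category in CATEGORIES and r.band in bands:
            table.loc[r.category, r.band] += 1
    return table


def class_proportion_ztest(
    k1: int, n1: int, k2: int, n2: int, alternative: str = "greater"
) -> tuple[float, float]:
    """Pooled two-proportion Z-test of k1/n1 vs k2/n2, one-sided.

    ``alternative="greater"`` tests whether the first proportion exceeds the
    second; swapping the groups flips the sign of z.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group totals must be positive")
    alt = {"greater": "larger", "less": "smaller"}[alternative]
    z, p = proportions_ztest([k1, k2], [n1, n2], alternative=alt)
    return float(z), float(p)


@dataclass
class GroupBandComparison:
    group_shares: pd.DataFrame  # 2 groups × 4 bands; columns sum to 1
    z: float
    p_one_sided: float
    positive_classes: tuple[str, ...]
    negative_classes: tuple[str, ...]


def group_band_comparison(
    entries: Sequence[ButterflyEntry], records: Sequence[GeneRecord]
) -> GroupBandComparison:
    """Partition classes by butterfly delta sign and compare the positive
    group's share of H3+ vs L1+ band genes (one-tailed pooled Z)."""
    sign = {e.kog_class: e.delta > 0 for e in entries}
    positive = tuple(sorted(c for c, s in sign.items() if s))
    negative = tuple(sorted(c for c, s in sign.items() if not s))
    if not positive or not negative:
        raise ValueError("both a positive and a negative class group are required")

    assigned = [r for r in records if r.band is not None and r.kog_class in sign]
    if not assigned:
        raise ValueError("no banded records for the grouped classes")
    counts = pd.DataFrame(0, index=["positive", "negative"], columns=list(BANDS))
    for r in assigned:
        grp = "positive" if sign[r.kog_class] else "negative"
        counts.loc[grp, r.band] += 1
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("a band has no genes")
    shares = counts.div(totals, axis=1)

    z, p = class_proportion_ztest(
        int(counts.loc["positive", "H3+"]), int(totals["H3+"]),
        int(counts.loc["positive", "L1+"]), int(totals["L1+"]),
        alternative="greater",
    )
    return GroupBandComparison(shares, z, p, positive, negative)
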