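"""Ternary (de Finetti) occupancy of functional categories and the
class-permutation confinement test.

Per genome, the range of class-mean GC3 values is split into three
equal-width intervals (Low, Medium, High); each category's classes are
counted per interval and normalized to a point on the 2-simplex.  The
confinement of the metabolism (RED) category toward the High corner is
summarized by S = mean over genomes of (p_high − p_low) of the Red point,
and its significance is assessed by shuffling category labels over classes
independently within each genome, preserving category sizes.

An alternative confinement statistic — the mean Euclidean distance of the
Red point from the Low vertex (1, 0, 0) — is available via ``stat=
"distance_from_low"``; the default is the simpler, signed ``"high_minus_low"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .composition import CATEGORIES
from .kog_catalog import ClassSummary

RED = "RED"

LOW, MEDIUM, HIGH = 0, 1, 2


class DegenerateRangeError(ValueError):
    """All class means equal: the GC3 range cannot be split."""


@dataclass(frozen=True)
class TernaryPoint:
    genome: str
    category: str
    p_low: float
    p_med: float
    p_high: float

    def __post_init__(self) -> None:
        ps = (self.p_low, self.p_med, self.p_high)
        if any(p < 0 for p in ps) or abs(sum(ps) - 1.0) > 1e-12:
            raise ValueError("ternary proportions must be >= 0 and sum to 1")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.p_low, self.p_med, self.p_high)


def gc3_intervals(class_means: Sequence[float]) -> tuple[float, float, float, float]:
    """Bounds (lo, b1, b2, hi) splitting [min, max] of the class means into
    three equal-width intervals."""
    if len(class_means) < 2:
        raise ValueError("need at least 2 class means")
    lo, hi = float(min(class_means)), float(max(class_means))
    if lo == hi:
        raise DegenerateRangeError("all class means are equal")
    w = (hi - lo) / 3.0
    return lo, lo + w, lo + 2.0 * w, hi


def interval_of(value: float, bounds: tuple[float, float, float, float]) -> int:
    """0 = Low, 1 = Medium, 2 = High.  Intervals are half-open [a, b) except
    the last, which is closed; a value on an interior boundary therefore goes
    to the upper interval."""
    _, b1, b2, _ = bounds
    if value < b1:
        return LOW
    if value < b2:
        return MEDIUM
    return HIGH


def ternary_points(
    class_summaries: Sequence[ClassSummary],
    bounds: tuple[float, float, float, float],
    genome: str,
) -> dict[str, TernaryPoint]:
    """One TernaryPoint per category: its classes' occupancy of (Low, Medium,
    High), normalized by the category's class count."""
    counts = {c: np.zeros(3) for c in CATEGORIES}
    for s in class_summaries:
        if s.category not in counts:
            continue
        counts[s.category][interval_of(s.mean_gc3, bounds)] += 1
    points = {}
    for cat, c in counts.items():
        total = c.sum()
        if total == 0:
            raise ValueError(f"category {cat} has no classes")
        points[cat] = TernaryPoint(genome, cat, *(c / total))
    return points


def confinement_statistic(
    red_points: Sequence[TernaryPoint], stat: str = "high_minus_low"
) -> float:
    """Scalar confinement of the Red category toward the High vertex, averaged
    over genomes."""
    if not red_points:
        raise ValueError("no points")
    if stat == "high_minus_low":
        return float(np.mean([p.p_high - p.p_low for p in red_points]))
    if stat == "distance_from_low":
        return float(
            np.mean(
                [
                    np.sqrt((p.p_low - 1.0) ** 2 + p.p_med**2 + p.p_high**2)
                    for p in red_points
                ]
            )
        )
    raise ValueError(f"unknown statistic {stat!r}")


@dataclass
class PermutationResult:
    observed_stat: float
    null_stats: np.ndarray
    p_value: float
    n_perm: int
    seed: int
    stat: str = "high_minus_low"

    def __post_init__(self) -> None:
        if not (self.p_value >= 1.0 / (self.n_perm + 1)):
            raise ValueError("p-value below the add-one permutation floor")

    def to_dict(self) -> dict:
        return {
            "observed_stat": self.observed_stat,
            "p_value": self.p_value,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "stat": self.stat,
        }


@dataclass(frozen=True)
class GenomeClasses:
    """Fixed per-genome inputs to the permutation test: each class's interval
    assignment and category label."""

    genome: str
    intervals: tuple[int, ...]  # 0/1/2 per class
    categories: tuple[str, ...]  # category label per class, aligned


def genome_classes_from_summaries(
    class_summaries: Sequence[ClassSummary], genome: str
) -> GenomeClasses:
    means = [s.mean_gc3 for s in class_summaries]
    bounds = gc3_intervals(means)
    return GenomeClasses(
        genome,
        tuple(interval_of(m, bounds) for m in means),
        tuple(s.category for s in class_summaries),
    )


def _red_stat_per_genome(intervals: np.ndarray, red_mask: np.ndarray, stat: str) -> float:
    red = intervals[red_mask]
    k = red.size
    p_low = float((red == LOW).sum()) / k
    p_med = float((red == MEDIUM).sum()) / k
    p_high = float((red == HIGH).sum()) / k
    if stat == "high_minus_low":
        return p_high - p_low
    return float(np.sqrt((p_low - 1.0) ** 2 + p_med**2 + p_high**2))


def permutation_test(
    genomes: Sequence[GenomeClasses],
    n_perm: int = 1000,
    seed: int = 0,
    stat: str = "high_minus_low",
) -> PermutationResult:
    """Within-genome label-permutation test of Red confinement.

    Each permutation shuffles category labels over classes independently in
    every genome (category sizes preserved), recomputes the Red ternary point
    and S; p = (1 + #{S_perm ≥ S_obs}) / (n_perm + 1) — the add-one estimator
    never returns 0.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not genomes:
        raise ValueError("no genomes")
    rng = np.random.default_rng(seed)

    obs = 0.0
    null = np.zeros(n_perm)
    for g in genomes:
        iv = np.asarray(g.intervals, dtype=np.int8)
        red_mask = np.array([c == RED for c in g.categories])
        k = int(red_mask.sum())
        if k == 0:
            raise ValueError(f"{g.genome}: no Red classes")
        obs += _red_stat_per_genome(iv, red_mask, stat)
        # random permutations of labels: Red positions = first k of a shuffle
        order = np.argsort(rng.random((n_perm, iv.size)), axis=1)[:, :k]
        vals = iv[order]  # (n_perm, k)
        p_low = (vals == LOW).sum(axis=1) / k
        p_med = (vals == MEDIUM).sum(axis=1) / k
        p_high = (vals == HIGH).sum(axis=1) / k
        if stat == "high_minus_low":
            null += p_high - p_low
        elif stat == "distance_from_low":
            null += np.sqrt((p_low - 1.0) ** 2 + p_med**2 + p_high**2)
        else:
            raise ValueError(f"unknown statistic {stat!r}")

    n_g = len(genomes)
    obs /= n_g
    null /= n_g
    p = (1.0 + float((null >= obs - 1e-12).sum())) / (n_perm + 1.0)
    return PermutationResult(obs, null, p, n_perm, seed, stat)


def points_table(points: Mapping[str, TernaryPoint] | Sequence[TernaryPoint]):
    import pandas as pd

    pts = list(points.values()) if isinstance(points, Mapping) else list(points)
    return pd.DataFrame(
        {
            "genome": [p.genome for p in pts],
            "category": [p.category for p in pts],
            "p_low": [p.p_low for p in pts],
            "p_med": [p.p_med for p in pts],
            "p_high": [p.p_high for p in pts],
        }
    )
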