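"""Synthetic inputs for the whole pipeline: CDS sets with planted per-class
GC3 structure, diverged ortholog genomes, and GC3-dependent band maps.

Every generator is a pure function of its parameters and seed.  GC3 is
realized *exactly* at sequence construction (the requested number of G/C
third positions), so composition tests are sharp; biological noise enters
only through the Normal draw of per-gene GC3 targets, truncated to
[0.02, 0.98] to keep third-position construction away from degenerate
all-GC / all-AT extremes.

The default genome specification, :func:`human_kog_reference_spec`, plants
the per-class gene counts, mean GC3 and sd of the human KOG reference
dataset shipped in :mod:`gc3kog.kog_catalog`; per-species category-level
parameters for the 16-genome comparison are in
:data:`SPECIES_CATEGORY_REFERENCE`.

What this emulates — and what it does not: per-class GC3 distributions are
approximately normal with class-specific means ≈0.50–0.66 and sd ≈0.10–0.18,
orthologous divergence is i.i.d. substitution plus an optional planted
category-wise ΔGC3, and banding follows a GC3-dependent categorical model.
Codon-usage structure, amino-acid composition, indels and paralog families
are not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .composition import BANDS, CodingSequence
from .kog_catalog import CATALOG, REFERENCE_CLASS_STATS, category_of

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_PREFIXES = [a + b for a in "ACGT" for b in "ACGT"]
# allowed third bases per prefix that keep the codon sense
_GC_THIRD = {p: ("C",) if p == "TA" else (("C", "G") if p == "TG" else ("G", "C")) for p in _PREFIXES}
_AT_THIRD = {p: ("T",) if p in ("TA", "TG") else ("A", "T") for p in _PREFIXES}

GC3_TRUNCATION = (0.02, 0.98)

#: per-species category-level reference parameters of the 16-genome
#: comparison (KOG subset and BLUE/BLACK/RED: mean GC3, sd, gene count),
#: as printed in the source dataset tables
SPECIES_CATEGORY_REFERENCE: dict[str, dict[str, dict[str, float | int]]] = {
    sp: {
        grp: {"gc3": g, "sd": s, "n": n}
        for grp, (g, s, n) in zip(("KOG", "BLUE", "BLACK", "RED"), vals)
    }
    for sp, vals in {
        "H_sapiens": [(0.584, 0.159, 12942), (0.568, 0.154, 3564), (0.584, 0.163, 6745), (0.604, 0.155, 2663)],
        "G_gorilla": [(0.609, 0.162, 6268), (0.593, 0.166, 1491), (0.609, 0.166, 3357), (0.626, 0.148, 1420)],
        "P_pygmaeus": [(0.594, 0.164, 7455), (0.583, 0.167, 1766), (0.593, 0.166, 4012), (0.611, 0.154, 1677)],
        "M_musculus": [(0.606, 0.114, 7505), (0.596, 0.127, 1780), (0.605, 0.122, 4032), (0.617, 0.101, 1693)],
        "O_cuniculus": [(0.630, 0.175, 5413), (0.609, 0.179, 1296), (0.629, 0.177, 2867), (0.653, 0.164, 1250)],
        "S_tridecemlineatus": [(0.565, 0.154, 5455), (0.542, 0.157, 1325), (0.567, 0.155, 2900), (0.584, 0.144, 1230)],
        "B_taurus": [(0.630, 0.167, 7139), (0.613, 0.171, 1706), (0.632, 0.169, 3794), (0.642, 0.155, 1639)],
        "E_caballus": [(0.609, 0.164, 7102), (0.594, 0.170, 1646), (0.608, 0.165, 3840), (0.626, 0.153, 1613)],
        "P_vampyrus": [(0.605, 0.164, 6780), (0.590, 0.170, 1638), (0.607, 0.165, 3607), (0.619, 0.155, 1535)],
        "T_truncatus": [(0.618, 0.167, 6812), (0.602, 0.172, 1635), (0.617, 0.169, 3634), (0.635, 0.155, 1543)],
        "L_africana": [(0.583, 0.152, 5704), (0.575, 0.157, 1413), (0.582, 0.153, 3007), (0.595, 0.141, 1284)],
        "D_novemcinctus": [(0.585, 0.180, 5358), (0.563, 0.181, 1310), (0.585, 0.182, 2832), (0.607, 0.173, 1216)],
        "O_anatinus": [(0.648, 0.166, 5287), (0.646, 0.169, 1319), (0.646, 0.166, 2734), (0.657, 0.161, 1234)],
        "M_domestica": [(0.533, 0.145, 3598), (0.529, 0.153, 1641), (0.531, 0.144, 3598), (0.542, 0.137, 1578)],
        "A_carolinensis": [(0.539, 0.159, 5959), (0.535, 0.158, 3063), (0.546, 0.1655, 1498), (0.539, 0.153, 1398)],
        "X_tropicalis": [(0.500, 0.112, 3584), (0.499, 0.112, 1753), (0.499, 0.1174, 961), (0.501, 0.108, 870)],
    }.items()
}

MAMMAL_SPECIES = tuple(
    sp for sp in SPECIES_CATEGORY_REFERENCE if sp not in ("A_carolinensis", "X_tropicalis")
)


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class GenomeSpec:
    """Per-class (n genes, mean GC3, sd GC3) for one synthetic genome."""

    species: str
    classes: Mapping[str, tuple[int, float, float]]  # letter -> (n, mu, sigma)
    n_codons: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_codons < 10:
            raise ValueError("n_codons must be >= 10")
        for letter, (n, mu, sigma) in self.classes.items():
            if letter not in CATALOG:
                raise ValueError(f"unknown KOG class {letter!r}")
            if n < 0 or not (0.0 < mu < 1.0) or sigma <= 0:
                raise ValueError(f"invalid parameters for class {letter}")


def human_kog_reference_spec(
    seed: int = 0, scale: float = 1.0, n_codons: int = 150
) -> GenomeSpec:
    """The default spec: the human reference dataset's 25 classes with their
    published counts, means and sds; ``scale`` shrinks class sizes
    proportionally (minimum 2 genes per class)."""
    classes = {
        letter: (max(2, int(round(n * scale))), mu, sd)
        for letter, (n, mu, sd) in REFERENCE_CLASS_STATS.items()
    }
    return GenomeSpec("H_sapiens", classes, n_codons=n_codons, seed=seed)


def sequence_from_gc3(target: float, n_codons: int, seed: int | np.random.Generator = 0) -> str:
    """A CDS of ``n_codons`` sense codons whose third positions contain
    exactly round(target·n_codons) G/C bases.  No internal stops."""
    if not (0.0 <= target <= 1.0):
        raise ValueError("target GC3 must lie in [0, 1]")
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    rng = _rng(seed)
    k = int(round(target * n_codons))
    gc_mask = np.zeros(n_codons, dtype=bool)
    gc_mask[rng.permutation(n_codons)[:k]] = True
    prefixes = rng.choice(_PREFIXES, size=n_codons)
    codons = []
    for prefix, is_gc in zip(prefixes, gc_mask):
        pool = _GC_THIRD[prefix] if is_gc else _AT_THIRD[prefix]
        codons.append(prefix + (pool[0] if len(pool) == 1 else pool[rng.integers(len(pool))]))
    return "".join(codons)


def draw_gc3_targets(
    mu: float, sigma: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Normal(mu, sigma) draws truncated to the feasible GC3 window."""
    lo, hi = GC3_TRUNCATION
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    return truncnorm.rvs(a, b, loc=mu, scale=sigma, size=n, random_state=rng)


def generate_genome(spec: GenomeSpec) -> tuple[list[CodingSequence], pd.DataFrame]:
    """Realize a spec as CDS plus a truth table (id, class, category, target GC3)."""
    rng = _rng(spec.seed)
    seqs: list[CodingSequence] = []
    rows = []
    for letter in sorted(spec.classes):
        n, mu, sigma = spec.classes[letter]
        targets = draw_gc3_targets(mu, sigma, n, rng)
        for i, t in enumerate(targets):
            gid = f"{spec.species}_{letter}_{i:05d}"
            seqs.append(
                CodingSequence(gid, spec.species, sequence_from_gc3(float(t), spec.n_codons, rng))
            )
            rows.append(
                {
                    "id": gid,
                    "kog_class": letter,
                    "category": category_of(letter),
                    "gc3_target": float(t),
                }
            )
    return seqs, pd.DataFrame(rows)


def _fix_stops(codons: list[str], rng: np.random.Generator) -> None:
    for i, c in enumerate(codons):
        if c in STOP_CODONS:
            prefix = c[:2]
            # keep the third-position GC state when a sense alternative exists
            pool = _GC_THIRD[prefix] if c[2] in "GC" else _AT_THIRD[prefix]
            pool = [b for b in pool if prefix + b not in STOP_CODONS]
            codons[i] = prefix + (pool[rng.integers(len(pool))] if pool else "C")


def _third_gc_count(codons: list[str]) -> int:
    return sum(c[2] in "GC" for c in codons)


def _rebalance_gc3(codons: list[str], desired: int, rng: np.random.Generator) -> None:
    """Flip third positions between AT and GC states (sense-preserving) until
    the third-position GC count equals ``desired``."""
    current = _third_gc_count(codons)
    if current == desired:
        return
    to_gc = desired > current
    idx = [i for i, c in enumerate(codons) if (c[2] in "GC") != to_gc]
    picks = rng.permutation(len(idx))[: abs(desired - current)]
    for j in picks:
        i = idx[j]
        prefix = codons[i][:2]
        pool = _GC_THIRD[prefix] if to_gc else _AT_THIRD[prefix]
        codons[i] = prefix + pool[rng.integers(len(pool))]


def mutate_orthologs(
    genome: Sequence[CodingSequence],
    substitution_rate: float,
    delta_gc3_by_category: Mapping[str, float] | None = None,
    seed: int | np.random.Generator = 0,
    categories: Mapping[str, str] | None = None,
    target_species: str = "target",
) -> tuple[list[CodingSequence], list[tuple[str, str]]]:
    """Diverged copy of a genome plus the true ortholog pairing.

    Each CDS is copied with i.i.d. substitutions at ``substitution_rate``
    (codons that would become stops are re-drawn).  When
    ``delta_gc3_by_category`` is given (with ``categories`` mapping reference
    ids to categories), the copy's third positions are re-balanced so that
    gc3(reference) − gc3(copy) ≈ the category's planted Δ.
    """
    if not (0.0 <= substitution_rate < 0.5):
        raise ValueError("substitution_rate must lie in [0, 0.5)")
    if delta_gc3_by_category and categories is None:
        raise ValueError("categories mapping required to plant ΔGC3")
    rng = _rng(seed)
    bases = np.array(list("ACGT"))
    targets: list[CodingSequence] = []
    pairs: list[tuple[str, str]] = []
    for cds in genome:
        seq = np.array(list(cds.seq))
        mask = rng.random(seq.size) < substitution_rate
        if mask.any():
            offsets = rng.integers(1, 4, size=int(mask.sum()))
            pos = {b: i for i, b in enumerate(bases)}
            cur = np.array([pos[b] for b in seq[mask]])
            seq[mask] = bases[(cur + offsets) % 4]
        codons = ["".join(seq[i : i + 3]) for i in range(0, seq.size, 3)]
        _fix_stops(codons, rng)
        if delta_gc3_by_category:
            cat = categories.get(cds.id)
            delta = delta_gc3_by_category.get(cat, 0.0) if cat else 0.0
            n = len(codons)
            ref_k = sum(b in "GC" for b in cds.seq[2::3])
            desired = int(np.clip(round(ref_k - delta * n), 0, n))
            _rebalance_gc3(codons, desired, rng)
        tid = f"{target_species}_{cds.id}"
        targets.append(CodingSequence(tid, target_species, "".join(codons)))
        pairs.append((cds.id, tid))
    return targets, pairs


def generate_decoys(
    n: int, n_codons: int, species: str, seed: int | np.random.Generator = 0
) -> list[CodingSequence]:
    """Unrelated sequences with uniform-random GC3 targets, for planted-pair
    recovery tests."""
    rng = _rng(seed)
    lo, hi = GC3_TRUNCATION
    return [
        CodingSequence(
            f"{species}_decoy_{i:05d}",
            species,
            sequence_from_gc3(float(rng.uniform(lo, hi)), n_codons, rng),
        )
        for i in range(n)
    ]


def generate_band_map(
    records,
    slope: float,
    seed: int | np.random.Generator = 0,
    center: float | None = None,
) -> dict[str, str]:
    """Band assignment whose log-odds toward GC-richer bands increase
    linearly with a gene's GC3.

    Band j ∈ {0..3} (L1+ … H3+) gets weight exp(slope·(gc3 − center)·j), so
    the log-odds between adjacent bands is slope·(gc3 − center); slope 0
    gives the uniform distribution.  ``center`` defaults to the median GC3.
    """
    rng = _rng(seed)
    gc3s = np.array([r.gc3 for r in records], dtype=float)
    if gc3s.size == 0:
        raise ValueError("no records")
    if center is None:
        center = float(np.median(gc3s))
    j = np.arange(4)
    out = {}
    for r, g in zip(records, gc3s):
        w = np.exp(np.clip(slope * (g - center) * j, -700, 700))
        out[r.id] = BANDS[rng.choice(4, p=w / w.sum())]
    return out


def write_kog_map(truth: pd.DataFrame, path) -> None:
    """Truth table → gene_id / class_letters TSV (the kog_catalog input)."""
    truth[["id", "kog_class"]].to_csv(path, sep="\t", header=False, index=False)


def write_band_map(band_map: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for gene, band in band_map.items():
            fh.write(f"{gene}\t{band}\n")
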