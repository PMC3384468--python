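"""KOG functional classes, their three-category grouping, and dataset filters.

The euKaryotic Orthologous Groups (KOG) scheme assigns proteins to 25
single-letter functional classes grouped in three broad categories —
information storage and processing (BLUE), cellular processes and signaling
(BLACK), metabolism (RED) — plus two poorly-characterized classes.  The
catalog here is frozen reference data, shipped with the human reference
dataset's per-class gene counts and GC3 statistics.

Filtering reproduces the standard dataset-cleaning rules for this analysis:
multi-class genes are discarded, the poorly-characterized classes R
(general function prediction only) and S (function unknown) are dropped, and
classes left with fewer than ``min_class_size`` genes are removed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .composition import CATEGORIES, GeneRecord

BLUE, BLACK, RED = CATEGORIES
POORLY_CHARACTERIZED = "POORLY_CHARACTERIZED"


@dataclass(frozen=True)
class KogClass:
    letter: str
    name: str
    category: str


# letter -> (name, category, reference n, reference mean GC3, reference sd)
_CATALOG_ROWS = [
    ("A", "RNA processing and modification", BLUE, 600, 0.517, 0.151),
    ("B", "Chromatin structure and dynamics", BLUE, 224, 0.610, 0.172),
    ("J", "Translation, ribosomal structure and biogenesis", BLUE, 1273, 0.545, 0.117),
    ("K", "Transcription", BLUE, 1137, 0.619, 0.170),
    ("L", "Replication, recombination and repair", BLUE, 300, 0.546, 0.154),
    ("D", "Cell cycle control, cell division, chromosome partitioning", BLACK, 267, 0.552, 0.160),
    ("M", "Cell wall/membrane/envelope biogenesis", BLACK, 63, 0.576, 0.164),
    ("N", "Cell motility", BLACK, 26, 0.586, 0.163),
    ("O", "Posttranslational modification, protein turnover, chaperones", BLACK, 1471, 0.557, 0.151),
    ("T", "Signal transduction mechanisms", BLACK, 2214, 0.616, 0.158),
    ("U", "Intracellular trafficking, secretion, and vesicular transport", BLACK, 685, 0.571, 0.161),
    ("V", "Defense mechanisms", BLACK, 1023, 0.527, 0.172),
    ("W", "Extracellular structures", BLACK, 284, 0.588, 0.150),
    ("Y", "Nuclear structure", BLACK, 17, 0.534, 0.150),
    ("Z", "Cytoskeleton", BLACK, 801, 0.638, 0.158),
    ("C", "Energy production and conversion", RED, 403, 0.576, 0.153),
    ("E", "Amino acid transport and metabolism", RED, 499, 0.618, 0.154),
    ("F", "Nucleotide transport and metabolism", RED, 187, 0.588, 0.151),
    ("G", "Carbohydrate transport and metabolism", RED, 469, 0.606, 0.150),
    ("H", "Coenzyme transport and metabolism", RED, 102, 0.563, 0.135),
    ("I", "Lipid transport and metabolism", RED, 410, 0.595, 0.154),
    ("P", "Inorganic ion transport and metabolism", RED, 402, 0.646, 0.161),
    ("Q", "Secondary metabolites biosynthesis, transport and catabolism", RED, 191, 0.591, 0.155),
    ("R", "General function prediction only", POORLY_CHARACTERIZED, 1889, 0.593, 0.162),
    ("S", "Function unknown", POORLY_CHARACTERIZED, 1171, 0.568, 0.162),
]

CATALOG: dict[str, KogClass] = {
    letter: KogClass(letter, name, cat) for letter, name, cat, *_ in _CATALOG_ROWS
}

#: human reference dataset per-class (n, mean GC3, sd GC3)
REFERENCE_CLASS_STATS: dict[str, tuple[int, float, float]] = {
    letter: (n, mean, sd) for letter, _, _, n, mean, sd in _CATALOG_ROWS
}

POORLY_CHARACTERIZED_CLASSES = ("R", "S")


def category_of(letter: str) -> str:
    return CATALOG[letter].category


@dataclass(frozen=True)
class ClassSummary:
    """Per-class gene count and GC3 statistics within one genome."""

    letter: str
    n: int
    mean_gc3: float
    sd_gc3: float
    category: str = ""


def load_catalog(path: str | Path) -> tuple[dict[str, KogClass], dict[str, tuple[str, ...]]]:
    """Load a gene→class-letters TSV against the built-in catalog.

    Columns: gene_id, class_letters (comma-separated for multi-class genes).
    Rows are retained verbatim — multi-class genes are removed later, by
    :func:`apply_filters`, so the raw mapping stays auditable.
    """
    mapping: dict[str, tuple[str, ...]] = {}
    bad_rows: list[str] = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            gene, letters_field = row[0], row[1]
            letters = tuple(tok.strip() for tok in letters_field.split(",") if tok.strip())
            if any(l not in CATALOG for l in letters) or not letters:
                bad_rows.append(f"{gene}\t{letters_field}")
                continue
            mapping[gene] = letters
    if bad_rows:
        raise ValueError(
            "unknown KOG class letter(s) in rows:\n" + "\n".join(bad_rows)
        )
    return CATALOG, mapping


@dataclass
class FilterReport:
    """Bookkeeping for the three filter rules, in application order."""

    n_input: int
    removed_multiclass: int
    removed_poorly_characterized: int
    removed_small_classes: dict[str, int] = field(default_factory=dict)
    n_retained: int = 0
    #: R/S share of the raw dataset and of the post-multiclass dataset
    poorly_characterized_share_of_input: float = 0.0
    poorly_characterized_share_after_multiclass: float = 0.0

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "removed_multiclass": self.removed_multiclass,
            "removed_poorly_characterized": self.removed_poorly_characterized,
            "removed_small_classes": dict(self.removed_small_classes),
            "n_retained": self.n_retained,
            "poorly_characterized_share_of_input": self.poorly_characterized_share_of_input,
            "poorly_characterized_share_after_multiclass": self.poorly_characterized_share_after_multiclass,
        }


def apply_filters(
    mapping: Mapping[str, tuple[str, ...]], min_class_size: int = 100
) -> tuple[dict[str, str], FilterReport]:
    """Apply the three dataset filters; returns a single-class map + report.

    Order: (i) multi-class genes, (ii) classes R and S, (iii) classes whose
    count after (i)+(ii) is strictly below ``min_class_size`` (a class of
    exactly ``min_class_size`` genes survives).  Idempotent.
    """
    n_input = len(mapping)
    single = {g: ls[0] for g, ls in mapping.items() if len(ls) == 1}
    n_multi = n_input - len(single)

    n_rs_input = sum(
        1
        for ls in mapping.values()
        if len(ls) == 1 and ls[0] in POORLY_CHARACTERIZED_CLASSES
    )
    kept = {g: l for g, l in single.items() if l not in POORLY_CHARACTERIZED_CLASSES}
    n_rs = len(single) - len(kept)

    counts: dict[str, int] = {}
    for l in kept.values():
        counts[l] = counts.get(l, 0) + 1
    small = {l: c for l, c in counts.items() if c < min_class_size}
    final = {g: l for g, l in kept.items() if l not in small}

    report = FilterReport(
        n_input=n_input,
        removed_multiclass=n_multi,
        removed_poorly_characterized=n_rs,
        removed_small_classes=small,
        n_retained=len(final),
        poorly_characterized_share_of_input=(n_rs_input / n_input if n_input else 0.0),
        poorly_characterized_share_after_multiclass=(
            n_rs / len(single) if single else 0.0
        ),
    )
    return final, report


def annotate_records(
    records: Sequence[GeneRecord], gene_to_class: Mapping[str, str]
) -> list[GeneRecord]:
    """Attach class letter and category to the records present in the map."""
    out = []
    for r in records:
        letter = gene_to_class.get(r.id)
        if letter is None:
            continue
        cat = category_of(letter)
        out.append(
            GeneRecord(
                id=r.id,
                species=r.species,
                gc=r.gc,
                gc3=r.gc3,
                n_codons=r.n_codons,
                kog_class=letter,
                category=cat if cat in CATEGORIES else None,
                band=r.band,
            )
        )
    return out


def summarize_by_class(
    records: Sequence[GeneRecord],
) -> tuple[list[ClassSummary], dict[str, ClassSummary]]:
    """Per-class summaries plus per-category roll-ups.

    The category roll-up is computed by pooling member genes, which equals the
    count-weighted mean of the member class means.
    """
    by_class: dict[str, list[float]] = {}
    by_cat: dict[str, list[float]] = {}
    for r in records:
        if r.kog_class is None:
            continue
        by_class.setdefault(r.kog_class, []).append(r.gc3)
        if r.category is not None:
            by_cat.setdefault(r.category, []).append(r.gc3)

    summaries = []
    for letter in sorted(by_class):
        vals = np.asarray(by_class[letter], dtype=float)
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        summaries.append(
            ClassSummary(letter, len(vals), float(vals.mean()), sd, category_of(letter))
        )
    rollups = {}
    for cat, vals_list in by_cat.items():
        vals = np.asarray(vals_list, dtype=float)
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        rollups[cat] = ClassSummary(cat, len(vals), float(vals.mean()), sd, cat)
    return summaries, rollups


def pooled_mean(ns: Sequence[int], means: Sequence[float]) -> float:
    """Count-weighted mean of group means: Σ nᵢ·mᵢ / Σ nᵢ."""
    ns = np.asarray(ns, dtype=float)
    means = np.asarray(means, dtype=float)
    if ns.sum() <= 0:
        raise ValueError("pooled_mean requires a positive total count")
    return float((ns * means).sum() / ns.sum())
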