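"""Coding-sequence composition: GC and GC3 per gene, dataset summaries.

GC3 — the molar fraction of guanine plus cytosine at third (wobble) codon
positions — is the central quantity of the pipeline.  Ambiguity codes (N) are
excluded from both numerator and denominator, so composition is computed over
unambiguous bases only.  Terminal stop codons count like any other codon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger("gc3kog")

VALID_BASES = frozenset("ACGTN")

CATEGORIES = ("BLUE", "BLACK", "RED")
BANDS = ("L1+", "L1-", "H3-", "H3+")  # fixed order, increasing GC


class CompositionError(ValueError):
    """Raised for undefined composition (e.g. an all-N sequence)."""


class CdsValidationError(ValueError):
    """Raised when a CDS violates the length or alphabet contract."""


class FastaParseError(ValueError):
    """Raised for malformed FASTA input; carries the offending line number."""


@dataclass(frozen=True)
class CodingSequence:
    """One nucleotide CDS (frame 0) with its identifier and species tag."""

    id: str
    species: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise CdsValidationError("CodingSequence id must be non-empty")
        object.__setattr__(self, "seq", self.seq.upper())


@dataclass
class GeneRecord:
    """Per-gene composition plus optional KOG class, category and band type."""

    id: str
    species: str
    gc: float
    gc3: float
    n_codons: int
    kog_class: str | None = None
    category: str | None = None
    band: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.gc <= 1.0 and 0.0 <= self.gc3 <= 1.0):
            raise ValueError(f"gc/gc3 outside [0,1] for gene {self.id!r}")
        if self.category is not None and self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.band is not None and self.band not in BANDS:
            raise ValueError(f"unknown band {self.band!r}")


def read_fasta(path: str | Path, species: str) -> list[CodingSequence]:
    """Read nucleotide FASTA into :class:`CodingSequence` records.

    The id is the first whitespace-delimited token of the header.  Duplicate
    ids raise ``FastaParseError``; records with empty sequences are skipped
    with a warning.
    """
    path = Path(path)
    with open(path) as fh:
        first = None
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                first = (lineno, line)
                break
        if first is None:
            return []
        if not first[1].startswith(">"):
            raise FastaParseError(
                f"{path}: line {first[0]}: expected FASTA header starting with '>'"
            )
    out: list[CodingSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        if len(rec.seq) == 0:
            logger.warning("%s: skipping empty record %r", path, rec.id)
            continue
        out.append(CodingSequence(id=rec.id, species=species, seq=str(rec.seq)))
    return out


def write_fasta(seqs: Iterable[CodingSequence], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.seq), width):
                fh.write(s.seq[i : i + width] + "\n")


def validate_cds(
    seq: CodingSequence, policy: Literal["strict", "truncate"] = "strict"
) -> CodingSequence:
    """Enforce the CDS contract: alphabet {A,C,G,T,N} and length ≡ 0 (mod 3).

    ``strict`` rejects a length not divisible by 3; ``truncate`` drops the
    trailing partial codon with a warning (real annotation sets occasionally
    carry one).  Alphabet violations are rejected under both policies.
    """
    bad = set(seq.seq) - VALID_BASES
    if bad:
        raise CdsValidationError(
            f"{seq.id}: invalid characters {sorted(bad)!r} (alphabet is A,C,G,T,N)"
        )
    rem = len(seq.seq) % 3
    if rem:
        if policy == "strict":
            raise CdsValidationError(
                f"{seq.id}: length {len(seq.seq)} not divisible by 3"
            )
        logger.warning("%s: truncating %d trailing nt", seq.id, rem)
        seq = replace(seq, seq=seq.seq[: len(seq.seq) - rem])
    if len(seq.seq) < 3:
        raise CdsValidationError(f"{seq.id}: fewer than one codon after validation")
    return seq


def gc(seq: str) -> float:
    """GC fraction over unambiguous bases: (#G + #C) / (#A + #C + #G + #T)."""
    s = seq.upper()
    num = s.count("G") + s.count("C")
    den = num + s.count("A") + s.count("T")
    if den == 0:
        raise CompositionError("GC undefined: no unambiguous bases")
    return num / den


def gc3(seq: str) -> float:
    """GC fraction at third codon positions; N third-positions are excluded.

    The sequence length must be a multiple of 3.  Every codon counts,
    including a terminal stop if present.
    """
    s = seq.upper()
    if len(s) % 3:
        raise CdsValidationError("gc3 requires a length divisible by 3")
    third = s[2::3]
    num = third.count("G") + third.count("C")
    den = num + third.count("A") + third.count("T")
    if den == 0:
        raise CompositionError("GC3 undefined: no unambiguous third positions")
    return num / den


@dataclass(frozen=True)
class DatasetSummary:
    n: int
    mean_gc3: float
    sd_gc3: float
    mean_gc: float
    degenerate: bool = False  # True when n == 1 and sd is reported as 0


def dataset_summary(records: Sequence[GeneRecord]) -> DatasetSummary:
    """n, mean GC3, sample sd of GC3 (n−1 denominator) and mean GC."""
    if not records:
        raise ValueError("dataset_summary requires at least one record")
    g3 = np.array([r.gc3 for r in records], dtype=float)
    g = np.array([r.gc for r in records], dtype=float)
    if len(records) == 1:
        return DatasetSummary(1, float(g3[0]), 0.0, float(g[0]), degenerate=True)
    return DatasetSummary(
        n=len(records),
        mean_gc3=float(g3.mean()),
        sd_gc3=float(g3.std(ddof=1)),
        mean_gc=float(g.mean()),
    )


def records_from_cds(
    seqs: Iterable[CodingSequence], policy: Literal["strict", "truncate"] = "strict"
) -> list[GeneRecord]:
    """Validate each CDS and compute its per-gene composition."""
    out = []
    for s in seqs:
        v = validate_cds(s, policy)
        out.append(
            GeneRecord(
                id=v.id,
                species=v.species,
                gc=gc(v.seq),
                gc3=gc3(v.seq),
                n_codons=len(v.seq) // 3,
            )
        )
    return out


def table_to_records(df) -> list[GeneRecord]:
    """Inverse of :func:`records_to_table` (missing optional fields allowed)."""

    def _opt(v):
        return None if v is None or (isinstance(v, float) and np.isnan(v)) else v

    return [
        GeneRecord(
            id=str(row.id),
            species=str(row.species),
            gc=float(row.gc),
            gc3=float(row.gc3),
            n_codons=int(row.n_codons),
            kog_class=_opt(getattr(row, "kog_class", None)),
            category=_opt(getattr(row, "category", None)),
            band=_opt(getattr(row, "band", None)),
        )
        for row in df.itertuples()
    ]


def records_to_table(records: Sequence[GeneRecord]):
    """Per-gene table (id, species, n_codons, gc, gc3 [, kog_class, category, band])."""
    import pandas as pd

    return pd.DataFrame(
        {
            "id": [r.id for r in records],
            "species": [r.species for r in records],
            "n_codons": [r.n_codons for r in records],
            "gc": [r.gc for r in records],
            "gc3": [r.gc3 for r in records],
            "kog_class": [r.kog_class for r in records],
            "category": [r.category for r in records],
            "band": [r.band for r in records],
        }
    )
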