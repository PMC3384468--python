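"""Best-reciprocal-hit (BRH) orthology and KOG label transfer.

Orthologs between a reference and a target species are called operationally:
two protein sequences that are each other's top-scoring cross-species search
hit, with both e-values below a threshold (default 1e-05), form an ortholog
pair, and the target gene inherits the reference gene's KOG class.

Two search backends are supported.  The builtin scorer runs a word-seeded
Smith-Waterman with BLOSUM62 (only sequence pairs sharing at least one
``word_size``-mer are aligned, mirroring seeded search heuristics), and
converts raw scores to a pseudo-e-value with a Karlin-Altschul-style
monotone transform — adequate for threshold filtering, not a calibrated
significance.  Alternatively, precomputed hits from an external search tool
can be imported in the standard 12-column tabular format.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import TranslationError
from Bio.Seq import Seq

from .composition import CodingSequence

# gapped BLOSUM62 (open 11 / extend 1) Karlin-Altschul parameters
_LAMBDA = 0.267
_K = 0.041

TABULAR_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


class InvalidCdsError(ValueError):
    """Raised when a CDS cannot be translated (internal stop codon)."""


@dataclass(frozen=True)
class SearchHit:
    query_id: str
    subject_id: str
    score: float  # similarity score, higher = better
    evalue: float  # lower = better

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


@dataclass(frozen=True)
class OrthologPair:
    ref_id: str
    target_id: str
    forward_hit: SearchHit
    reverse_hit: SearchHit

    def __post_init__(self) -> None:
        ok = (
            self.forward_hit.query_id == self.ref_id
            and self.forward_hit.subject_id == self.target_id
            and self.reverse_hit.query_id == self.target_id
            and self.reverse_hit.subject_id == self.ref_id
        )
        if not ok:
            raise ValueError("forward/reverse hits must mirror the same id pair")


def translate_cds(seq: CodingSequence) -> str:
    """Translate with the standard genetic code; a terminal stop is trimmed,
    an internal stop raises :class:`InvalidCdsError`."""
    try:
        prot = str(Seq(seq.seq).translate(table=1, cds=False))
    except TranslationError as e:  # pragma: no cover - malformed length
        raise InvalidCdsError(f"{seq.id}: {e}") from e
    if prot.endswith("*"):
        prot = prot[:-1]
    if "*" in prot:
        raise InvalidCdsError(f"{seq.id}: internal stop codon")
    return prot


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def _word_index(proteins: Sequence[tuple[str, str]], word_size: int) -> dict[str, set[int]]:
    index: dict[str, set[int]] = {}
    for i, (_, seq) in enumerate(proteins):
        for j in range(len(seq) - word_size + 1):
            index.setdefault(seq[j : j + word_size], set()).add(i)
    return index


def pseudo_evalue(score: float, query_len: int, subject_len: int, n_subjects: int) -> float:
    """Monotone score→e-value transform: E = K·m·n·N·exp(−λ·S)."""
    with np.errstate(over="ignore", under="ignore"):
        return float(_K * query_len * subject_len * n_subjects * np.exp(-_LAMBDA * score))


def all_vs_all_search(
    queries: Sequence[tuple[str, str]],
    subjects: Sequence[tuple[str, str]],
    *,
    word_size: int = 5,
    min_score: float = 30.0,
) -> list[SearchHit]:
    """Seeded local-alignment search of every query against the subject set.

    ``queries``/``subjects`` are (id, protein) pairs.  Subjects sharing no
    exact ``word_size``-mer with the query are skipped; candidate pairs are
    scored by Smith-Waterman (BLOSUM62, gap open 11 / extend 1) and hits with
    score below ``min_score`` are not emitted.
    """
    if not queries or not subjects:
        raise ValueError("all_vs_all_search requires non-empty query and subject sets")
    aligner = _make_aligner()
    index = _word_index(subjects, word_size)
    hits: list[SearchHit] = []
    n_subj = len(subjects)
    for qid, qseq in queries:
        if len(qseq) >= word_size:
            cand: set[int] = set()
            for j in range(len(qseq) - word_size + 1):
                cand |= index.get(qseq[j : j + word_size], set())
        else:  # too short to seed: align against everything
            cand = set(range(n_subj))
        for i in sorted(cand):
            sid, sseq = subjects[i]
            score = float(aligner.score(qseq, sseq))
            if score < min_score:
                continue
            hits.append(
                SearchHit(qid, sid, score, pseudo_evalue(score, len(qseq), len(sseq), n_subj))
            )
    return hits


def read_tabular_hits(path: str | Path) -> list[SearchHit]:
    """Import hits from 12-column tab-separated search output.

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend sstart
    send evalue bitscore.  The bitscore is used as the similarity score.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None, names=TABULAR_COLUMNS,
            dtype={"qseqid": str, "sseqid": str},
        )
    except (pd.errors.ParserError, ValueError) as e:
        raise ValueError(f"{path}: malformed 12-column tabular hits file: {e}") from e
    if df.shape[1] != 12 or df["evalue"].isna().any() or df["bitscore"].isna().any():
        raise ValueError(f"{path}: malformed 12-column tabular hits file")
    return [
        SearchHit(r.qseqid, r.sseqid, float(r.bitscore), float(r.evalue))
        for r in df.itertuples()
    ]


def _best_hits(hits: Iterable[SearchHit]) -> dict[str, SearchHit]:
    """Per query, the unique best hit by (score desc, evalue asc).

    A query whose top (score, evalue) is attained by more than one subject is
    dropped: a true tie has no unique best reciprocal hit.
    """
    by_query: dict[str, list[SearchHit]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    best: dict[str, SearchHit] = {}
    for q, hs in by_query.items():
        hs.sort(key=lambda h: (-h.score, h.evalue, h.subject_id))
        if len(hs) > 1 and (hs[0].score, hs[0].evalue) == (hs[1].score, hs[1].evalue):
            continue
        best[q] = hs[0]
    return best


def best_reciprocal_hits(
    forward: Iterable[SearchHit],
    reverse: Iterable[SearchHit],
    evalue_max: float = 1e-05,
) -> list[OrthologPair]:
    """Pairs (a, b) where b is a's best forward hit, a is b's best reverse
    hit, and both e-values are below ``evalue_max``.

    The output is a partial matching (each id occurs in at most one pair),
    sorted by reference id.
    """
    fwd_best = _best_hits(forward)
    rev_best = _best_hits(reverse)
    pairs = []
    for a, fh in fwd_best.items():
        b = fh.subject_id
        rh = rev_best.get(b)
        if rh is None or rh.subject_id != a:
            continue
        if fh.evalue >= evalue_max or rh.evalue >= evalue_max:
            continue
        pairs.append(OrthologPair(a, b, fh, rh))
    pairs.sort(key=lambda p: p.ref_id)
    return pairs


def transfer_labels(
    pairs: Iterable[OrthologPair], ref_labels: Mapping[str, str]
) -> dict[str, str]:
    """Target gene → KOG class of its reference partner; unpaired or
    unlabeled-reference targets are absent from the output."""
    out = {}
    for p in pairs:
        letter = ref_labels.get(p.ref_id)
        if letter is not None:
            out[p.target_id] = letter
    return out


def pairs_to_table(pairs: Sequence[OrthologPair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "ref_id": [p.ref_id for p in pairs],
            "target_id": [p.target_id for p in pairs],
            "fwd_evalue": [p.forward_hit.evalue for p in pairs],
            "rev_evalue": [p.reverse_hit.evalue for p in pairs],
        }
    )
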