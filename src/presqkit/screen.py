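"""Ungapped substitution-matrix screening of proteome N-termini.

Ranks every ORF by the ungapped BLOSUM similarity between its N-terminal
window (anchored at the initiator Met, position 1) and a query peptide.
No gaps, shifts or alignment statistics: the score is the plain positional
sum of matrix entries, matching how a designed presequence is compared
against the first 24 residues of every ORF in a proteome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .io import SubstitutionMatrix, load_blosum30
from .peptide import Peptide, as_peptide

logger = logging.getLogger("presqkit")


@dataclass(frozen=True)
class ScreenHit:
    """One ORF's N-terminal similarity to the query, with its dense rank."""

    orf_id: str
    nterm_seq: Peptide
    score: int
    rank: int


def ungapped_score(a: Peptide | str, b: Peptide | str, m: SubstitutionMatrix) -> int:
    """Sum of per-position matrix scores between two equal-length peptides."""
    a = as_peptide(a, "a")
    b = as_peptide(b, "b")
    if len(a) != len(b):
        raise ValueError(f"unequal lengths: {len(a)} vs {len(b)}")
    return sum(m.score(x, y) for x, y in zip(a.seq, b.seq))


def screen_proteome(
    proteome: Sequence[Peptide],
    query: Peptide | str,
    k: int = 24,
    m: SubstitutionMatrix | None = None,
) -> list[ScreenHit]:
    """Score every ORF's first `k` residues against a length-`k` query.

    ORFs shorter than `k` are skipped (counted in a log summary) rather than
    padded, since no gap score is defined. Hits are sorted by descending
    score with a deterministic secondary order by ORF id, and dense-ranked so
    equal scores share a rank and ranks are contiguous from 1.
    """
    query = as_peptide(query, "query")
    if len(query) != k:
        raise ValueError(f"query length {len(query)} != window k={k}")
    if m is None:
        m = load_blosum30()
    scored = []
    skipped = 0
    for orf in proteome:
        if len(orf) < k:
            skipped += 1
            continue
        nterm = orf.subsequence(1, k, id=f"{orf.id}_1-{k}")
        scored.append((orf.id, nterm, ungapped_score(nterm, query, m)))
    if skipped:
        logger.info("screen_proteome: skipped %d ORFs shorter than %d", skipped, k)
    scored.sort(key=lambda t: (-t[2], t[0]))
    hits = []
    rank = 0
    prev_score: int | None = None
    for orf_id, nterm, score in scored:
        if score != prev_score:
            rank += 1
            prev_score = score
        hits.append(ScreenHit(orf_id, nterm, score, rank))
    return hits


def hits_to_frame(hits: Sequence[ScreenHit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "rank": h.rank,
            "orf_id": h.orf_id,
            "score": h.score,
            "nterm_seq": h.nterm_seq.seq,
        }
        for h in hits
    )
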