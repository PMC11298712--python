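"""Presequence dataset curation.

Delineates targeting-peptide (TP) regions from N-terminal alignment overhangs,
applies the 10-150 residue length filter, extracts single alpha-helix TP
segments, and summarizes TP lengths.

Delineation replaces by-eye inspection of homolog alignments with a
deterministic aggregation over the earliest aligned query positions of a
protein's homologs: the presequence is the unaligned N-terminal overhang, so
``tp_end = aggregate(query_aln_start) - 1`` and 0 means no presequence.
"""

from __future__ import annotations

import logging
import math
import statistics
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import pandas as pd

from .peptide import Peptide
from .io import parse_segments

logger = logging.getLogger("presqkit")

Aggregation = Literal["median", "min", "max"]

#: The length filter bounds: TPs shorter than 10 or longer than 150 residues
#: are omitted from dataset statistics.
LENGTH_FILTER = (10, 150)


@dataclass(frozen=True)
class PresequenceRecord:
    """One protein's delineated TP region with annotations."""

    protein_id: str
    organelle: str
    tp_seq: Peptide
    helix_class: str = "none"
    helix_segments: tuple[tuple[int, int], ...] = ()

    @property
    def tp_length(self) -> int:
        return len(self.tp_seq)

    @property
    def passed_filter(self) -> bool:
        lo, hi = LENGTH_FILTER
        return lo <= self.tp_length <= hi


@dataclass(frozen=True)
class SummaryStats:
    n: int
    mean: float
    sd: float


def delineate_tp(starts: Iterable[int], aggregation: Aggregation = "median") -> int:
    """TP end position from homolog earliest-aligned-query-position values.

    Returns ``aggregate(starts) - 1``; 0 means the N-terminus is fully
    conserved (no presequence). `median` uses the lower median so the result
    is always one of the observed integers and min <= median <= max holds.
    """
    starts = list(starts)
    if not starts:
        raise ValueError("delineate_tp requires at least one overhang row")
    if any(s < 1 for s in starts):
        raise ValueError("query_aln_start values must be >= 1")
    if aggregation == "median":
        agg = statistics.median_low(starts)
    elif aggregation == "min":
        agg = min(starts)
    elif aggregation == "max":
        agg = max(starts)
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    return agg - 1


def delineate_from_overhangs(
    overhangs: pd.DataFrame, aggregation: Aggregation = "median"
) -> pd.Series:
    """Per-query tp_end from an overhang table (query_id, query_aln_start)."""
    return (
        overhangs.groupby("query_id")["query_aln_start"]
        .apply(lambda s: delineate_tp(s.tolist(), aggregation))
        .rename("tp_end")
    )


def build_records(
    proteome: Sequence[Peptide],
    annotations: pd.DataFrame,
) -> list[PresequenceRecord]:
    """Join an annotation table against proteome sequences.

    Annotation rows whose protein is absent from the proteome are skipped with
    a logged notice; tp_end is clipped to the protein length.
    """
    by_id = {p.id: p for p in proteome}
    records = []
    skipped = 0
    for row in annotations.itertuples(index=False):
        protein = by_id.get(row.protein_id)
        if protein is None:
            skipped += 1
            continue
        tp_end = min(int(row.tp_end), len(protein))
        segments = row.helix_segments
        if not isinstance(segments, (list, tuple)):
            segments = parse_segments(segments)
        records.append(
            PresequenceRecord(
                protein_id=row.protein_id,
                organelle=row.organelle,
                tp_seq=protein.subsequence(1, tp_end, id=f"{row.protein_id}_TP"),
                helix_class=row.helix_class,
                helix_segments=tuple(segments),
            )
        )
    if skipped:
        logger.info("build_records: %d annotations without proteome sequence", skipped)
    return records


def apply_length_filter(
    records: Iterable[PresequenceRecord],
    bounds: tuple[int, int] = LENGTH_FILTER,
) -> tuple[list[PresequenceRecord], list[PresequenceRecord]]:
    """Partition records into (kept, omitted) by inclusive TP-length bounds."""
    lo, hi = bounds
    kept, omitted = [], []
    for record in records:
        (kept if lo <= record.tp_length <= hi else omitted).append(record)
    return kept, omitted


def select_single_helices(
    records: Iterable[PresequenceRecord],
    max_len: int = 25,
    strict_less: bool = True,
) -> list[Peptide]:
    """Helix-segment peptides of single-alpha-helix TPs below a length cutoff.

    Only records annotated `single_alpha` with exactly one helix segment
    qualify; with `strict_less` (default) the segment must be shorter than
    `max_len` residues.
    """
    helices = []
    for record in records:
        if record.helix_class != "single_alpha":
            continue
        if len(record.helix_segments) != 1:
            continue
        start, end = record.helix_segments[0]
        seg_len = end - start + 1
        if (seg_len >= max_len) if strict_less else (seg_len > max_len):
            continue
        helices.append(
            record.tp_seq.subsequence(start, end, id=f"{record.protein_id}_helix")
        )
    return helices


def summarize_lengths(records: Sequence[PresequenceRecord]) -> SummaryStats:
    """Mean and sample (n-1) standard deviation of TP lengths."""
    lengths = [record.tp_length for record in records]
    if not lengths:
        raise ValueError("summarize_lengths requires at least one record")
    mean = sum(lengths) / len(lengths)
    if len(lengths) == 1:
        logger.info("summarize_lengths: single record, reporting sd = 0")
        return SummaryStats(1, mean, 0.0)
    var = sum((x - mean) ** 2 for x in lengths) / (len(lengths) - 1)
    return SummaryStats(len(lengths), mean, math.sqrt(var))


def records_to_frame(records: Iterable[PresequenceRecord]) -> pd.DataFrame:
    from .io import format_segments

    return pd.DataFrame(
        {
            "protein_id": r.protein_id,
            "organelle": r.organelle,
            "tp_length": r.tp_length,
            "tp_seq": r.tp_seq.seq,
            "helix_class": r.helix_class,
            "helix_segments": format_segments(r.helix_segments),
            "passed_filter": r.passed_filter,
        }
        for r in records
    )
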