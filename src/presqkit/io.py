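"""Readers and writers: FASTA, NCBI substitution matrices, TSV tables.

All tables are tab-separated with a header row; lines starting with ``#`` are
comments. Coordinates in tables are 1-based inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Align import substitution_matrices

from .peptide import AMINO_ACIDS, Peptide

logger = logging.getLogger("presqkit")

ORGANELLES = ("mito", "chloro", "other")
HELIX_CLASSES = ("single_alpha", "multi_alpha", "beta", "mixed", "none")


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s: %(message)s",
    )


def data_path(name: str) -> Path:
    """Path to a data file shipped with the package."""
    return Path(resources.files("presqkit").joinpath("data", name))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[Peptide]:
    """Read a protein FASTA file into validated peptides.

    Ids are the first whitespace-delimited token of each header; order is
    preserved and sequences are folded to upper case.
    """
    path = Path(path)
    peptides: list[Peptide] = []
    with open(path) as handle:
        first = handle.readline()
        while first and not first.strip():
            first = handle.readline()
        if not first.startswith(">"):
            raise ValueError(
                f"{path}: malformed FASTA, line 1 does not start with '>'"
            )
        handle.seek(0)
        for record in SeqIO.parse(handle, "fasta"):
            peptides.append(Peptide(record.id, str(record.seq)))
    if not peptides:
        raise ValueError(f"{path}: no FASTA records found")
    return peptides


def write_fasta(peptides: Iterable[Peptide], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as out:
        for p in peptides:
            out.write(f">{p.id}\n")
            for i in range(0, len(p.seq), width):
                out.write(p.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Substitution matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubstitutionMatrix:
    """A symmetric 20x20 integer substitution matrix."""

    name: str
    scores: Mapping[tuple[str, str], int]

    def score(self, a: str, b: str) -> int:
        return self.scores[(a, b)]

    def max_diagonal(self) -> int:
        return max(self.scores[(aa, aa)] for aa in AMINO_ACIDS)


def read_matrix(path: str | Path, name: str | None = None) -> SubstitutionMatrix:
    """Parse an NCBI-format substitution matrix file.

    Extra columns beyond the canonical 20 residues (B, Z, X, ``*``) are parsed
    and dropped with a logged notice. Asymmetric or incomplete matrices are
    rejected.
    """
    path = Path(path)
    arr = substitution_matrices.read(str(path))
    alphabet = list(arr.alphabet)
    extra = [a for a in alphabet if a not in AMINO_ACIDS]
    if extra:
        logger.info("%s: dropping non-canonical matrix columns %s", path.name, extra)
    missing = [a for a in AMINO_ACIDS if a not in alphabet]
    if missing:
        raise ValueError(f"{path}: matrix is missing residues {missing}")
    scores: dict[tuple[str, str], int] = {}
    for a in AMINO_ACIDS:
        for b in AMINO_ACIDS:
            sab = int(arr[a, b])
            sba = int(arr[b, a])
            if sab != sba:
                raise ValueError(
                    f"{path}: asymmetric entries score({a},{b})={sab} != "
                    f"score({b},{a})={sba}"
                )
            scores[(a, b)] = sab
    return SubstitutionMatrix(name or path.stem or path.name, scores)


def load_blosum30() -> SubstitutionMatrix:
    """The shipped NCBI BLOSUM30 matrix."""
    return read_matrix(data_path("BLOSUM30"), name="BLOSUM30")


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype={0: str})


def parse_segments(text: str) -> list[tuple[int, int]]:
    """Parse helix segments serialized as ``start-end;start-end``."""
    if not text or (isinstance(text, float) and pd.isna(text)):
        return []
    segments = []
    for part in str(text).split(";"):
        start_s, end_s = part.split("-")
        segments.append((int(start_s), int(end_s)))
    return segments


def format_segments(segments: Iterable[tuple[int, int]]) -> str:
    return ";".join(f"{s}-{e}" for s, e in segments)


def read_annotations(path: str | Path, allow_no_tp: bool = False) -> pd.DataFrame:
    """Read a presequence annotation table.

    Columns: protein_id, organelle, tp_end, helix_segments, helix_class.
    Validates organelle/helix-class vocabularies, tp_end >= 1, and that helix
    segments are sorted, non-overlapping and contained in 1..tp_end. With
    `allow_no_tp`, tp_end = 0 marks a protein without a presequence (used by
    ground-truth tables from the simulator).
    """
    df = _read_tsv(path)
    required = {"protein_id", "organelle", "tp_end", "helix_segments", "helix_class"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {required - set(df.columns)}")
    df = df.copy()
    df["tp_end"] = df["tp_end"].astype(int)
    for row in df.itertuples(index=False):
        if row.organelle not in ORGANELLES:
            raise ValueError(f"{path}: unknown organelle {row.organelle!r}")
        if row.helix_class not in HELIX_CLASSES:
            raise ValueError(f"{path}: unknown helix class {row.helix_class!r}")
        if row.tp_end < (0 if allow_no_tp else 1):
            raise ValueError(f"{path}: tp_end < 1 for {row.protein_id}")
        segments = parse_segments(row.helix_segments)
        if row.tp_end == 0 and segments:
            raise ValueError(
                f"{path}: helix segments without a presequence for {row.protein_id}"
            )
        prev_end = 0
        for start, end in segments:
            if not (1 <= start <= end <= row.tp_end):
                raise ValueError(
                    f"{path}: segment {start}-{end} outside 1..{row.tp_end} "
                    f"for {row.protein_id}"
                )
            if start <= prev_end:
                raise ValueError(
                    f"{path}: overlapping/unsorted segments for {row.protein_id}"
                )
            prev_end = end
    return df


def write_annotations(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_overhangs(path: str | Path) -> pd.DataFrame:
    """Read a pairwise-alignment overhang table.

    Columns: query_id, homolog_id, query_aln_start (1-based earliest aligned
    query position).
    """
    df = _read_tsv(path)
    required = {"query_id", "homolog_id", "query_aln_start"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {required - set(df.columns)}")
    df = df.copy()
    df["query_aln_start"] = df["query_aln_start"].astype(int)
    if (df["query_aln_start"] < 1).any():
        bad = df.loc[df["query_aln_start"] < 1, "query_id"].iloc[0]
        raise ValueError(f"{path}: query_aln_start < 1 for query {bad}")
    return df
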