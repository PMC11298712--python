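"""Peptide physicochemistry.

Implements the quantities used to characterize organellar targeting peptides:

* residue-class composition (basic / acidic / polar uncharged / nonpolar),
* Henderson-Hasselbalch net charge at a given pH,
* mean hydrophobicity ``<H>`` on the Fauchere-Pliska octanol scale,
* the helical hydrophobic moment ``<muH>`` (Eisenberg), normalized by length,
  with residues placed at 100 degrees per residue for an ideal alpha-helix,
* helical-wheel coordinates, and
* per-position residue frequency matrices for logo export and consensus design.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import data_path
from .peptide import AMINO_ACIDS, Peptide, as_peptide

logger = logging.getLogger("presqkit")

CLASS_NAMES = ("basic", "acidic", "polar_uncharged", "nonpolar")

#: Standard textbook residue-class grouping.
DEFAULT_CLASS_SCHEME: Mapping[str, str] = {
    **{aa: "basic" for aa in "KRH"},
    **{aa: "acidic" for aa in "DE"},
    **{aa: "polar_uncharged" for aa in "STNQCY"},
    **{aa: "nonpolar" for aa in "GAVLIPFMW"},
}


def validate_class_scheme(scheme: Mapping[str, str]) -> None:
    """A scheme must map each of the 20 residues to exactly one known class."""
    if set(scheme) != set(AMINO_ACIDS):
        raise ValueError("class scheme must cover the 20 canonical residues exactly")
    unknown = set(scheme.values()) - set(CLASS_NAMES)
    if unknown:
        raise ValueError(f"unknown residue classes: {sorted(unknown)}")


@dataclass(frozen=True)
class PkaSet:
    """Side-chain and terminal pKa values for charge calculation."""

    name: str
    side_chain: Mapping[str, float]  # K, R, H (positive); D, E, C, Y (negative)
    n_terminus: float
    c_terminus: float

    def __post_init__(self) -> None:
        required = set("KRHDECY")
        if set(self.side_chain) != required:
            raise ValueError(f"pKa set must define side chains {sorted(required)}")
        for value in (*self.side_chain.values(), self.n_terminus, self.c_terminus):
            if not 0.0 < value < 14.0:
                raise ValueError(f"pKa {value} outside (0, 14)")


#: Approximates the Protein Calculator v3.4 values; the package default.
PKA_PROTCALC = PkaSet(
    "protcalc",
    {"K": 10.0, "R": 12.0, "H": 6.5, "D": 4.4, "E": 4.4, "C": 8.5, "Y": 10.0},
    n_terminus=8.0,
    c_terminus=3.1,
)

PKA_EMBOSS = PkaSet(
    "emboss",
    {"K": 10.8, "R": 12.5, "H": 6.5, "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1},
    n_terminus=8.6,
    c_terminus=3.6,
)

PKA_SETS: Mapping[str, PkaSet] = {"protcalc": PKA_PROTCALC, "emboss": PKA_EMBOSS}

_POSITIVE = "KRH"
_NEGATIVE = "DECY"

_SCALE_CACHE: dict[str, Mapping[str, float]] = {}


def get_scale(name: str = "fauchere-pliska") -> Mapping[str, float]:
    """A named per-residue hydrophobicity scale (shipped as a data file)."""
    if name not in _SCALE_CACHE:
        fname = name.replace("-", "_") + ".tsv"
        df = pd.read_csv(data_path(fname), sep="\t", comment="#", header=None,
                         names=["residue", "hydrophobicity"])
        scale = dict(zip(df["residue"], df["hydrophobicity"].astype(float)))
        if set(scale) != set(AMINO_ACIDS):
            raise ValueError(f"scale {name!r} does not cover the 20 residues")
        _SCALE_CACHE[name] = scale
    return _SCALE_CACHE[name]


# ---------------------------------------------------------------------------
# Scalar properties
# ---------------------------------------------------------------------------

def net_charge(
    p: Peptide | str,
    pka: PkaSet | str = PKA_PROTCALC,
    ph: float = 7.0,
    include_termini: bool = True,
    *,
    n_terminus: bool | None = None,
    c_terminus: bool | None = None,
) -> float:
    """Henderson-Hasselbalch net charge in elementary charges at a given pH.

    Each positive group (the free N-terminus if included, K, R, H) contributes
    ``+1 / (1 + 10**(pH - pKa))``; each negative group (the free C-terminus if
    included, D, E, C, Y) contributes ``-1 / (1 + 10**(pKa - pH))``.
    The `n_terminus` / `c_terminus` keywords override `include_termini`
    per terminus (used for internally truncated domains).
    """
    if isinstance(pka, str):
        pka = PKA_SETS[pka]
    if not 0.0 < ph < 14.0:
        raise ValueError(f"pH {ph} outside (0, 14)")
    p = as_peptide(p)
    use_n = include_termini if n_terminus is None else n_terminus
    use_c = include_termini if c_terminus is None else c_terminus

    def pos(pk: float) -> float:
        return 1.0 / (1.0 + 10.0 ** (ph - pk))

    def neg(pk: float) -> float:
        return -1.0 / (1.0 + 10.0 ** (pk - ph))

    charge = 0.0
    if use_n:
        charge += pos(pka.n_terminus)
    if use_c:
        charge += neg(pka.c_terminus)
    for aa in p.seq:
        if aa in _POSITIVE:
            charge += pos(pka.side_chain[aa])
        elif aa in _NEGATIVE:
            charge += neg(pka.side_chain[aa])
    return charge


def mean_hydrophobicity(p: Peptide | str, scale: Mapping[str, float] | None = None) -> float:
    """Arithmetic mean of per-residue hydrophobicities (H units)."""
    scale = scale or get_scale()
    p = as_peptide(p)
    return sum(scale[aa] for aa in p.seq) / len(p)


def _moment(values: Sequence[float], delta_deg: float, phase: float = 0.0) -> float:
    delta = math.radians(delta_deg)
    phi = math.radians(phase)
    cos_sum = sum(h * math.cos(delta * i + phi) for i, h in enumerate(values))
    sin_sum = sum(h * math.sin(delta * i + phi) for i, h in enumerate(values))
    return math.hypot(cos_sum, sin_sum) / len(values)


def hydrophobic_moment(
    p: Peptide | str,
    scale: Mapping[str, float] | None = None,
    delta_deg: float = 100.0,
    window: int | None = None,
) -> float:
    """Mean helical hydrophobic moment <muH>.

    ``muH = (1/N) * |sum_i H_i * exp(i * delta * (i-1))|`` with residue i
    placed at angle ``(i-1) * delta`` (delta = 100 degrees/residue for an ideal
    alpha-helix). With `window` set, returns the maximum windowed moment over
    all windows of that length (HELIQUEST-style; windows longer than the
    peptide fall back to the full length).
    """
    scale = scale or get_scale()
    p = as_peptide(p)
    values = [scale[aa] for aa in p.seq]
    if window is None or window >= len(values):
        return _moment(values, delta_deg)
    return max(
        _moment(values[i : i + window], delta_deg)
        for i in range(len(values) - window + 1)
    )


def helical_wheel(
    p: Peptide | str, delta_deg: float = 100.0
) -> list[tuple[int, str, float]]:
    """(position, residue, angle in degrees mod 360) for a wheel projection."""
    p = as_peptide(p)
    return [
        (i, aa, ((i - 1) * delta_deg) % 360.0)
        for i, aa in enumerate(p.seq, start=1)
    ]


# ---------------------------------------------------------------------------
# Set-level composition and frequency matrices
# ---------------------------------------------------------------------------

def class_composition(
    peptides: Iterable[Peptide | str],
    scheme: Mapping[str, str] | None = None,
) -> dict[str, float]:
    """Residue-class fractions pooled over all residues of the input set."""
    scheme = scheme or DEFAULT_CLASS_SCHEME
    validate_class_scheme(scheme)
    counts = {name: 0 for name in CLASS_NAMES}
    total = 0
    for p in peptides:
        p = as_peptide(p)
        for aa in p.seq:
            counts[scheme[aa]] += 1
            total += 1
    if total == 0:
        raise ValueError("class_composition requires at least one residue")
    return {name: counts[name] / total for name in CLASS_NAMES}


@dataclass
class FrequencyMatrix:
    """Per-position residue counts over a left-anchored peptide set.

    `counts` is a (length x 20) integer frame indexed by 1-based position;
    `coverage[p]` is the number of input sequences of length >= p. Frequencies
    are counts normalized by coverage; they sum to 1 wherever coverage > 0.
    """

    counts: pd.DataFrame
    coverage: pd.Series

    @property
    def length(self) -> int:
        return len(self.counts)

    @property
    def frequencies(self) -> pd.DataFrame:
        cov = self.coverage.replace(0, np.nan)
        return self.counts.div(cov, axis=0)

    def to_tsv(self, path) -> None:
        out = self.frequencies.copy()
        out.insert(0, "coverage", self.coverage)
        out.to_csv(path, sep="\t", index_label="position")


def frequency_matrix(
    peptides: Sequence[Peptide | str], length: int | None = None
) -> FrequencyMatrix:
    """Count residues per position over sequences anchored at position 1.

    Position p pools the residues of all sequences with length >= p; `length`
    defaults to the longest input sequence.
    """
    peps = [as_peptide(p) for p in peptides]
    if not peps:
        raise ValueError("frequency_matrix requires at least one peptide")
    if length is None:
        length = max(len(p) for p in peps)
    if length < 1:
        raise ValueError("length must be >= 1")
    index = pd.RangeIndex(1, length + 1, name="position")
    counts = pd.DataFrame(0, index=index, columns=list(AMINO_ACIDS))
    coverage = pd.Series(0, index=index)
    for p in peps:
        upto = min(len(p), length)
        coverage.iloc[:upto] += 1
        for i in range(upto):
            counts.iloc[i, counts.columns.get_loc(p.seq[i])] += 1
    return FrequencyMatrix(counts, coverage)


# ---------------------------------------------------------------------------
# Profiles and the sklearn-style featurizer
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhyschemProfile:
    """Physicochemical summary of one peptide."""

    length: int
    net_charge: float
    mean_hydrophobicity: float
    hydrophobic_moment: float
    class_fractions: Mapping[str, float] = field(default_factory=dict)


def physchem_profile(
    p: Peptide | str,
    pka: PkaSet | str = PKA_PROTCALC,
    ph: float = 7.0,
    include_termini: bool = True,
    scale: Mapping[str, float] | None = None,
    delta_deg: float = 100.0,
    moment_window: int | None = None,
    scheme: Mapping[str, str] | None = None,
) -> PhyschemProfile:
    p = as_peptide(p)
    return PhyschemProfile(
        length=len(p),
        net_charge=net_charge(p, pka, ph, include_termini),
        mean_hydrophobicity=mean_hydrophobicity(p, scale),
        hydrophobic_moment=hydrophobic_moment(p, scale, delta_deg, moment_window),
        class_fractions=class_composition([p], scheme),
    )


class PhyschemFeaturizer(TransformerMixin, BaseEstimator):
    """Transform peptides into a physicochemical feature frame.

    Stateless apart from resolving the named pKa set and hydrophobicity scale
    at fit time (``pka_``, ``scale_``). `transform` accepts peptides or raw
    sequences and returns a DataFrame with one row per peptide and columns
    length, net_charge, mean_hydrophobicity, hydrophobic_moment and the four
    class fractions.
    """

    def __init__(
        self,
        pka: str = "protcalc",
        ph: float = 7.0,
        include_termini: bool = True,
        scale: str = "fauchere-pliska",
        delta_deg: float = 100.0,
        moment_window: int | None = None,
    ):
        self.pka = pka
        self.ph = ph
        self.include_termini = include_termini
        self.scale = scale
        self.delta_deg = delta_deg
        self.moment_window = moment_window

    def fit(self, X: Sequence[Peptide | str], y=None) -> "PhyschemFeaturizer":
        self.pka_ = PKA_SETS[self.pka] if isinstance(self.pka, str) else self.pka
        self.scale_ = get_scale(self.scale)
        if not 0.0 < self.ph < 14.0:
            raise ValueError(f"pH {self.ph} outside (0, 14)")
        return self

    def transform(self, X: Sequence[Peptide | str]) -> pd.DataFrame:
        if not hasattr(self, "pka_"):
            self.fit(X)
        rows = []
        ids = []
        for i, item in enumerate(X):
            p = as_peptide(item, id=f"peptide_{i}")
            profile = physchem_profile(
                p,
                pka=self.pka_,
                ph=self.ph,
                include_termini=self.include_termini,
                scale=self.scale_,
                delta_deg=self.delta_deg,
                moment_window=self.moment_window,
            )
            ids.append(p.id)
            rows.append(
                {
                    "length": profile.length,
                    "net_charge": profile.net_charge,
                    "mean_hydrophobicity": profile.mean_hydrophobicity,
                    "hydrophobic_moment": profile.hydrophobic_moment,
                    **{f"frac_{k}": v for k, v in profile.class_fractions.items()},
                }
            )
        return pd.DataFrame(rows, index=pd.Index(ids, name="id"))
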