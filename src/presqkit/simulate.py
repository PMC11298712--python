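"""Synthetic proteomes, presequence sets and fixtures.

Generates data with the statistical structure the analysis assumes, so every
pipeline stage runs without downloads:

* proteomes of single-exon ORFs with a realistic background residue
  composition (class profile of a compact algal proteome: 11.2% basic,
  14.0% acidic, 22.2% polar uncharged, 52.5% nonpolar),
* planted mitochondrial / chloroplast targeting peptides with lengths drawn
  from truncated normals whose *truncated* mean and sd equal the reported
  organellar values (mito 59.3 +/- 23.4, chloro 78.4 +/- 17.3, support
  [10, 150]),
* amphipathic alpha-helical TP segments whose residue composition follows the
  presequence-helix class profile (17.3/3.6/26.2/52.9) and whose hydrophobic
  face separation is calibrated to the observed mean hydrophobic moment
  (~0.29 muH),
* alignment-overhang tables emulating homology-search output, and
* the in-vivo construct truth-table fixture.

All sampling flows through one numpy Generator derived from a single integer
seed; no global random state is touched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .dataset import PresequenceRecord, select_single_helices
from .io import format_segments
from .peptide import AMINO_ACIDS, Peptide
from .physchem import DEFAULT_CLASS_SCHEME, get_scale
from .rules import MITO, CYTO

#: Residue-class fractions of the whole-proteome background.
ALL_ORF_CLASS_FRACTIONS: Mapping[str, float] = {
    "basic": 0.112, "acidic": 0.140, "polar_uncharged": 0.222, "nonpolar": 0.525,
}

#: Residue-class fractions of presequence alpha-helices.
HELIX_CLASS_FRACTIONS: Mapping[str, float] = {
    "basic": 0.173, "acidic": 0.036, "polar_uncharged": 0.262, "nonpolar": 0.529,
}

#: Within-class residue weights emulating the reported abundance pattern in
#: presequence helices: R, S, T, A, L, V abundant; D, E, P, I scarce; basic
#: content dominated by R over K with little H. Used by the synthetic
#: supplement stand-in; plain class profiles default to uniform within class.
TP_HELIX_WITHIN_CLASS_WEIGHTS: Mapping[str, Mapping[str, float]] = {
    "basic": {"R": 0.70, "K": 0.27, "H": 0.03},
    "acidic": {"D": 0.40, "E": 0.60},
    "polar_uncharged": {"S": 0.36, "T": 0.30, "N": 0.10, "Q": 0.12,
                        "C": 0.04, "Y": 0.08},
    "nonpolar": {"A": 0.24, "L": 0.22, "V": 0.18, "G": 0.10, "M": 0.08,
                 "F": 0.07, "I": 0.05, "P": 0.04, "W": 0.02},
}

#: Face-assignment noise (H units) of the amphipathic helix model, calibrated
#: once so the mean hydrophobic moment of generated helices matches the
#: observed ~0.29 muH (see docs/methods.md).
AMPHIPATHIC_SIGMA = 2.3

_AA = np.array(list(AMINO_ACIDS))


def residue_profile(
    class_fractions: Mapping[str, float],
    within_class_weights: Mapping[str, Mapping[str, float]] | None = None,
) -> pd.Series:
    """A 20-residue probability vector from class fractions.

    Class mass is spread uniformly over the residues of each class unless
    explicit within-class weights are given; the result is normalized.
    """
    members: dict[str, list[str]] = {}
    for aa, cls in DEFAULT_CLASS_SCHEME.items():
        members.setdefault(cls, []).append(aa)
    probs = pd.Series(0.0, index=list(AMINO_ACIDS))
    for cls, fraction in class_fractions.items():
        if within_class_weights and cls in within_class_weights:
            weights = within_class_weights[cls]
            total = sum(weights.values())
            for aa, w in weights.items():
                probs[aa] = fraction * w / total
        else:
            for aa in members[cls]:
                probs[aa] = fraction / len(members[cls])
    return probs / probs.sum()


def background_profile() -> pd.Series:
    return residue_profile(ALL_ORF_CLASS_FRACTIONS)


def helix_profile(uniform_within_class: bool = True) -> pd.Series:
    weights = None if uniform_within_class else TP_HELIX_WITHIN_CLASS_WEIGHTS
    return residue_profile(HELIX_CLASS_FRACTIONS, weights)


# ---------------------------------------------------------------------------
# Amphipathic helix model
# ---------------------------------------------------------------------------

def sample_amphipathic_helix(
    rng: np.random.Generator,
    length: int,
    profile: pd.Series | None = None,
    sigma: float = AMPHIPATHIC_SIGMA,
    delta_deg: float = 100.0,
    phase_deg: float | None = None,
) -> str:
    """One helix: residues drawn iid from `profile`, arranged amphipathically.

    Residues are first sampled independently from the profile (so the
    composition marginal is exactly the profile), then assigned to positions
    by matching hydrophobicity rank (plus Gaussian noise of scale `sigma`) to
    the positions' helical-face projection cos((i-1)*delta - phase). Small
    `sigma` gives a sharply segregated hydrophobic face; large `sigma`
    approaches a random arrangement. The face phase is uniform-random per
    helix unless given.
    """
    if profile is None:
        profile = helix_profile(uniform_within_class=False)
    residues = rng.choice(_AA, size=length, p=profile.to_numpy())
    if phase_deg is None:
        phase_deg = float(rng.uniform(0.0, 360.0))
    angles = np.radians(np.arange(length) * delta_deg - phase_deg)
    face = np.cos(angles)
    scale = get_scale()
    scores = np.array([scale[aa] for aa in residues])
    scores = scores + rng.normal(0.0, sigma, size=length)
    # Highest-scoring residues occupy the most hydrophobic-face positions.
    placed = np.empty(length, dtype=residues.dtype)
    placed[np.argsort(-face, kind="stable")] = residues[
        np.argsort(-scores, kind="stable")
    ]
    return "".join(placed)


def generate_helix_set(
    n: int,
    rng: np.random.Generator,
    lengths: Sequence[int] | None = None,
    length_range: tuple[int, int] = (18, 24),
    profile: pd.Series | None = None,
    sigma: float = AMPHIPATHIC_SIGMA,
    ensure_full_length: bool = True,
) -> list[Peptide]:
    """A left-anchored set of synthetic presequence alpha-helices.

    Lengths are uniform over `length_range` (inclusive) unless given. With
    `ensure_full_length` at least one helix spans the top of the range so a
    full-length consensus is always defined, mirroring a curated helix set
    that supports its design window.
    """
    if lengths is None:
        lo, hi = length_range
        lengths = rng.integers(lo, hi + 1, size=n)
        lengths = np.asarray(lengths)
        if ensure_full_length and lengths.max() < hi:
            lengths[int(rng.integers(0, n))] = hi
    return [
        Peptide(f"helix_{i:03d}", sample_amphipathic_helix(rng, int(L), profile, sigma))
        for i, L in enumerate(lengths)
    ]


# ---------------------------------------------------------------------------
# Targeting-peptide lengths
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _truncnorm_parent(
    mean: float, sd: float, lo: float, hi: float
) -> tuple[float, float]:
    """Parent (mu, sigma) whose [lo, hi]-truncated normal has the given
    mean and sd. Solved once per parameter set."""

    def residual(params):
        mu, sigma = params
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        d = stats.truncnorm(a, b, loc=mu, scale=sigma)
        return [d.mean() - mean, d.std() - sd]

    (mu, sigma), info, ok, msg = optimize.fsolve(
        residual, [mean, sd], full_output=True
    )
    if ok != 1:
        raise RuntimeError(f"truncated-normal moment matching failed: {msg}")
    return float(mu), float(sigma)


def sample_tp_lengths(
    rng: np.random.Generator,
    n: int,
    mean: float,
    sd: float,
    bounds: tuple[int, int] = (10, 150),
) -> np.ndarray:
    """Integer TP lengths from a truncated normal with the stated moments."""
    lo, hi = bounds
    mu, sigma = _truncnorm_parent(mean, sd, float(lo), float(hi))
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    values = stats.truncnorm(a, b, loc=mu, scale=sigma).rvs(n, random_state=rng)
    return np.clip(np.rint(values).astype(int), lo, hi)


# ---------------------------------------------------------------------------
# Proteome generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteomeSpec:
    """Conditions for a synthetic single-exon proteome.

    Defaults emulate a compact algal nuclear genome: ~4,803 ORFs, ~14% of
    them carrying an organellar targeting peptide (split evenly between
    mitochondrial and chloroplast, matching the predicted organellar protein
    counts), organelle-specific TP length distributions, and alpha-helical
    TP segments in three quarters of mitochondrial presequences.
    """

    n_orfs: int = 4803
    orf_length_median: float = 280.0
    orf_length_sigma: float = 0.45
    min_mature_length: int = 50
    tp_fraction: float = 0.14
    mito_share: float = 0.5
    mito_tp_mean: float = 59.3
    mito_tp_sd: float = 23.4
    chloro_tp_mean: float = 78.4
    chloro_tp_sd: float = 17.3
    tp_length_bounds: tuple[int, int] = (10, 150)
    helix_fraction: float = 0.75
    helix_length_range: tuple[int, int] = (18, 24)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_orfs < 1:
            raise ValueError("n_orfs must be >= 1")
        if not 0.0 <= self.tp_fraction <= 1.0:
            raise ValueError("tp_fraction must be in [0, 1]")
        if not 0.0 <= self.mito_share <= 1.0:
            raise ValueError("mito_share must be in [0, 1]")
        lo, hi = self.tp_length_bounds
        if not 0 < lo <= hi:
            raise ValueError("invalid tp_length_bounds")


def _draw_from_profile(
    rng: np.random.Generator, n: int, profile: pd.Series
) -> str:
    return "".join(rng.choice(_AA, size=n, p=profile.to_numpy()))


def _make_tp(
    rng: np.random.Generator,
    length: int,
    tp_profile: pd.Series,
    helix_span: tuple[int, int] | None,
    sigma: float = AMPHIPATHIC_SIGMA,
) -> str:
    """A TP sequence: Met, profile-drawn residues, optional amphipathic helix
    segment, and a guaranteed basic residue outside the flanking positions."""
    seq = list("M" + _draw_from_profile(rng, length - 1, tp_profile))
    if helix_span is not None:
        start, end = helix_span
        seq[start - 1 : end] = sample_amphipathic_helix(
            rng, end - start + 1, tp_profile, sigma
        )
    if not any(aa in "RK" for aa in seq[2:]):
        lo = helix_span[0] if helix_span else 3
        hi = helix_span[1] if helix_span else length
        lo = max(lo, 3)
        seq[int(rng.integers(lo, hi + 1)) - 1] = "R"
    return "".join(seq)


def generate_proteome(
    spec: ProteomeSpec,
    rng: np.random.Generator | None = None,
) -> tuple[list[Peptide], pd.DataFrame]:
    """A synthetic proteome plus its ground-truth annotation table.

    Every ORF starts with Met. TP-bearing ORFs carry a planted presequence
    drawn from the helix residue profile, with an annotated amphipathic
    single-alpha-helix segment in `helix_fraction` of mitochondrial TPs and
    at least one basic residue outside positions 1-2. The truth table records
    organelle, tp_end, helix class and segment. Deterministic given the spec
    seed: the same spec yields byte-identical output.
    """
    rng = rng or np.random.default_rng(spec.seed)
    bg = background_profile()
    tp_profile = helix_profile(uniform_within_class=False)

    n_tp = int(round(spec.n_orfs * spec.tp_fraction))
    n_mito = int(round(n_tp * spec.mito_share))
    n_chloro = n_tp - n_mito
    organelles = np.array(
        ["mito"] * n_mito + ["chloro"] * n_chloro
        + ["other"] * (spec.n_orfs - n_tp)
    )
    rng.shuffle(organelles)

    mature_lengths = np.maximum(
        np.rint(
            rng.lognormal(math.log(spec.orf_length_median),
                          spec.orf_length_sigma, size=spec.n_orfs)
        ).astype(int),
        spec.min_mature_length,
    )
    mito_lengths = iter(
        sample_tp_lengths(rng, n_mito, spec.mito_tp_mean, spec.mito_tp_sd,
                          spec.tp_length_bounds)
    )
    chloro_lengths = iter(
        sample_tp_lengths(rng, n_chloro, spec.chloro_tp_mean, spec.chloro_tp_sd,
                          spec.tp_length_bounds)
    )

    peptides: list[Peptide] = []
    truth_rows = []
    for i, organelle in enumerate(organelles):
        orf_id = f"ORF{i + 1:05d}"
        if organelle == "other":
            seq = "M" + _draw_from_profile(rng, int(mature_lengths[i]) - 1, bg)
            tp_end, helix_class, segments = 0, "none", ()
        else:
            tp_len = int(next(mito_lengths if organelle == "mito"
                              else chloro_lengths))
            helix_class, segments = "none", ()
            helix_span = None
            h_lo, h_hi = spec.helix_length_range
            if (
                organelle == "mito"
                and tp_len >= h_lo + 2
                and rng.uniform() < spec.helix_fraction
            ):
                seg_len = int(rng.integers(h_lo, min(h_hi, tp_len - 2) + 1))
                start = int(rng.integers(2, tp_len - seg_len + 2))
                helix_span = (start, start + seg_len - 1)
                helix_class = "single_alpha"
                segments = (helix_span,)
            tp_seq = _make_tp(rng, tp_len, tp_profile, helix_span)
            mature = _draw_from_profile(rng, int(mature_lengths[i]), bg)
            seq = tp_seq + mature
            tp_end = tp_len
        peptides.append(Peptide(orf_id, seq))
        truth_rows.append(
            {
                "protein_id": orf_id,
                "organelle": organelle,
                "tp_end": tp_end,
                "helix_segments": format_segments(segments),
                "helix_class": helix_class,
            }
        )
    return peptides, pd.DataFrame(truth_rows)


def generate_overhangs(
    truth: pd.DataFrame,
    n_homologs: int = 5,
    noise_sd: float = 0.0,
    full_length_hit_rate: float = 0.0,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Homolog overhang rows emulating alignment output against each protein.

    Each protein gets `n_homologs` rows with
    ``query_aln_start = tp_end + 1 + round(Normal(0, noise_sd))`` floored at
    1; a `full_length_hit_rate` fraction of rows instead start at 1
    (spurious full-length conservation).
    """
    rng = rng or np.random.default_rng(seed)
    n = len(truth)
    tp_end = truth["tp_end"].to_numpy()[:, None]
    starts = tp_end + 1 + np.rint(
        rng.normal(0.0, noise_sd, size=(n, n_homologs))
    ).astype(int)
    starts = np.maximum(starts, 1)
    spurious = rng.uniform(size=(n, n_homologs)) < full_length_hit_rate
    starts[spurious] = 1
    rows = []
    for i, pid in enumerate(truth["protein_id"]):
        for j in range(n_homologs):
            rows.append((pid, f"{pid}_hom{j + 1}", int(starts[i, j])))
    return pd.DataFrame(rows, columns=["query_id", "homolog_id", "query_aln_start"])


# ---------------------------------------------------------------------------
# Truth-table fixture
# ---------------------------------------------------------------------------

def generate_truth_table() -> pd.DataFrame:
    """The 16-row in-vivo construct fixture (matches the shipped TSV).

    Rows: the native AAT 1-33 helix; the synTP arginine-count series
    (3R/2R/1R/0R and the lysine swap); the single-arginine scan at
    +2/+6/+8/+9/+12/+15/+21 (the +13 construct is the series 1R row); and the
    FMNL acidic-residue mutants E2A, E18A, E2A/E18A.
    """
    rows = [
        ("AAT_1-33", "4;13", 0, MITO),
        ("synTP_3R", "9;13;21", 0, MITO),
        ("synTP_2R", "13;21", 0, MITO),
        ("synTP_1R", "13", 0, MITO),
        ("synTP_0R", "", 0, CYTO),
        ("synTP_3K", "9K;13K;21K", 0, MITO),
        ("synTP_1R_R2", "2", 0, CYTO),
        ("synTP_1R_R6", "6", 0, MITO),
        ("synTP_1R_R8", "8", 0, MITO),
        ("synTP_1R_R9", "9", 0, MITO),
        ("synTP_1R_R12", "12", 0, MITO),
        ("synTP_1R_R15", "15", 0, MITO),
        ("synTP_1R_R21", "21", 0, MITO),
        ("FMNL_E2A", "7;12", 1, CYTO),
        ("FMNL_E18A", "7;12", 1, CYTO),
        ("FMNL_E2A_E18A", "7;12", 0, MITO),
    ]
    return pd.DataFrame(
        rows, columns=["label", "basic_positions", "n_acidic", "observed"]
    )


# ---------------------------------------------------------------------------
# Synthetic supplement stand-in
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSupplement:
    """Synthetic stand-in for a curated presequence supplement.

    Not real data: a generated dataset emulating the published study
    conditions (113 mitochondrial + 97 chloroplast presequences within the
    10-150 residue filter; 31 of the mitochondrial records carrying a single
    alpha-helix shorter than 25 residues).
    """

    mito_records: list[PresequenceRecord]
    chloro_records: list[PresequenceRecord]

    @property
    def helices(self) -> list[Peptide]:
        return select_single_helices(self.mito_records)


def synthetic_supplement(
    seed: int = 0,
    n_mito: int = 113,
    n_chloro: int = 97,
    n_helices: int = 31,
) -> SyntheticSupplement:
    """Generate the synthetic supplement stand-in (see SyntheticSupplement)."""
    rng = np.random.default_rng(seed)
    tp_profile = helix_profile(uniform_within_class=False)
    mito_lengths = sample_tp_lengths(rng, n_mito, 59.3, 23.4)
    chloro_lengths = sample_tp_lengths(rng, n_chloro, 78.4, 17.3)

    # Helix-bearing records need room for an 18-24 residue segment after Met.
    helix_seg_lengths = rng.integers(18, 25, size=n_helices)
    if helix_seg_lengths.max() < 24:
        helix_seg_lengths[int(rng.integers(0, n_helices))] = 24
    eligible = np.flatnonzero(mito_lengths >= helix_seg_lengths.max() + 2)
    if len(eligible) < n_helices:
        raise RuntimeError("too few long presequences to host helix segments")
    helix_hosts = rng.choice(eligible, size=n_helices, replace=False)
    host_seg = dict(zip(helix_hosts.tolist(), helix_seg_lengths.tolist()))

    def make_records(prefix, lengths, organelle):
        records = []
        for i, tp_len in enumerate(lengths):
            tp_len = int(tp_len)
            helix_span = None
            helix_class, segments = "none", ()
            if organelle == "mito" and i in host_seg:
                seg_len = int(host_seg[i])
                start = int(rng.integers(2, tp_len - seg_len + 2))
                helix_span = (start, start + seg_len - 1)
                helix_class, segments = "single_alpha", (helix_span,)
            seq = _make_tp(rng, tp_len, tp_profile, helix_span)
            records.append(
                PresequenceRecord(
                    protein_id=f"{prefix}{i + 1:03d}",
                    organelle=organelle,
                    tp_seq=Peptide(f"{prefix}{i + 1:03d}_TP", seq),
                    helix_class=helix_class,
                    helix_segments=segments,
                )
            )
        return records

    return SyntheticSupplement(
        mito_records=make_records("SMT", mito_lengths, "mito"),
        chloro_records=make_records("SCT", chloro_lengths, "chloro"),
    )
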