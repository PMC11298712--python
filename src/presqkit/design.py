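"""Consensus presequence design and systematic variant generation.

A synthetic targeting peptide (synTP) is designed by taking the modal residue
at each position of a left-anchored set of presequence alpha-helices, then
adjusting its charge toward the endogenous mean by substituting excess
arginines. Variant generators cover the experimental series used to probe
targeting requirements: the arginine-count series (3R -> 0R plus an all-K
swap), single-arginine positional scanning, and acidic-residue point mutants.
All operations are substitution-only: outputs always have the base length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd
from sklearn.base import BaseEstimator

from .peptide import Peptide, as_peptide
from .physchem import (
    PKA_PROTCALC,
    FrequencyMatrix,
    PkaSet,
    frequency_matrix,
    net_charge,
)

logger = logging.getLogger("presqkit")

#: Mean net charge of endogenous presequence helices at pH 7; the default
#: target for charge adjustment of a consensus design.
ENDOGENOUS_MEAN_CHARGE = 2.80

#: Positions probed in the single-arginine scan, relative to Met = 1.
DEFAULT_SCAN_POSITIONS = (2, 6, 8, 9, 12, 13, 15, 21)


@dataclass(frozen=True)
class VariantSpec:
    """A labelled set of point substitutions on a base peptide."""

    label: str
    base: Peptide
    substitutions: tuple[tuple[int, str], ...]

    def __post_init__(self) -> None:
        positions = [pos for pos, _ in self.substitutions]
        if len(set(positions)) != len(positions):
            raise ValueError(f"{self.label}: duplicate substitution positions")
        for pos, res in self.substitutions:
            if not 1 <= pos <= len(self.base):
                raise ValueError(
                    f"{self.label}: position {pos} outside 1..{len(self.base)}"
                )

    def apply(self) -> Peptide:
        seq = list(self.base.seq)
        for pos, res in self.substitutions:
            seq[pos - 1] = res
        return Peptide(self.label, "".join(seq))


@dataclass
class ConsensusResult:
    """A consensus peptide plus its per-position provenance.

    `per_position` has 1-based index and columns residue, frequency (winner
    frequency among covering sequences) and tie (True where the modal count
    was shared and the tie-break rule decided).
    """

    peptide: Peptide
    per_position: pd.DataFrame
    frequency_matrix: FrequencyMatrix


class ConsensusDesigner(BaseEstimator):
    """Fit a modal-residue consensus over a left-anchored helix set.

    Parameters
    ----------
    length : design length in residues (every position must be covered by at
        least one input sequence).
    tie_break : 'overall' resolves per-position ties by the residue with the
        higher total count across the whole input set, then alphabetically.

    Fitted attributes: ``frequency_matrix_``, ``consensus_`` (Peptide),
    ``result_`` (ConsensusResult with tie flags).
    """

    def __init__(self, length: int = 24, tie_break: str = "overall"):
        self.length = length
        self.tie_break = tie_break

    def fit(self, X: Sequence[Peptide | str], y=None) -> "ConsensusDesigner":
        helices = [as_peptide(p, id=f"helix_{i}") for i, p in enumerate(X)]
        if not helices:
            raise ValueError("consensus design requires at least one helix")
        if self.tie_break != "overall":
            raise ValueError(f"unknown tie_break {self.tie_break!r}")
        fm = frequency_matrix(helices, length=self.length)
        uncovered = fm.coverage[fm.coverage == 0]
        if len(uncovered):
            raise ValueError(
                f"no input sequence covers design position(s) "
                f"{list(uncovered.index)}"
            )
        overall = fm.counts.sum(axis=0)
        rows = []
        residues = []
        for position in fm.counts.index:
            counts = fm.counts.loc[position]
            top = counts.max()
            candidates = sorted(counts[counts == top].index)
            tie = len(candidates) > 1
            if tie:
                # Prefer the residue most frequent over the whole set, then
                # alphabetical; flagged so calibration stays auditable.
                candidates.sort(key=lambda aa: (-overall[aa], aa))
            winner = candidates[0]
            residues.append(winner)
            rows.append(
                {
                    "residue": winner,
                    "frequency": top / fm.coverage[position],
                    "tie": tie,
                }
            )
        self.frequency_matrix_ = fm
        self.consensus_ = Peptide("consensus", "".join(residues))
        self.result_ = ConsensusResult(
            peptide=self.consensus_,
            per_position=pd.DataFrame(rows, index=fm.counts.index),
            frequency_matrix=fm,
        )
        return self


def consensus_design(
    helices: Sequence[Peptide | str], length: int = 24, tie_break: str = "overall"
) -> ConsensusResult:
    """Modal-residue consensus of a helix set (see ConsensusDesigner)."""
    return ConsensusDesigner(length=length, tie_break=tie_break).fit(helices).result_


# ---------------------------------------------------------------------------
# Charge adjustment
# ---------------------------------------------------------------------------

def charge_adjust(
    consensus: ConsensusResult | Peptide,
    substitutions: Iterable[tuple[int, str]],
    label: str = "synTP",
) -> Peptide:
    """Apply explicit substitutions to a consensus peptide.

    Intended for replacing excess arginines to bring the design's net charge
    near the endogenous mean; substituting a position that does not hold R is
    allowed but logged as a warning.
    """
    base = consensus.peptide if isinstance(consensus, ConsensusResult) else consensus
    spec = VariantSpec(label, base, tuple(substitutions))
    for pos, _ in spec.substitutions:
        if base.residue(pos) != "R":
            logger.warning(
                "charge_adjust: position %d holds %s, not R", pos, base.residue(pos)
            )
    return spec.apply()


def suggest_charge_substitutions(
    consensus: ConsensusResult,
    target_charge: float = ENDOGENOUS_MEAN_CHARGE,
    pka: PkaSet = PKA_PROTCALC,
    ph: float = 7.0,
    max_substitutions: int | None = None,
) -> list[tuple[int, str]]:
    """Arginine substitutions bringing net charge closest to a target.

    Considers replacing each consensus arginine with the runner-up (non-basic)
    residue at its position, and returns the subset (any size up to
    `max_substitutions`) whose resulting peptide has net charge closest to
    `target_charge`; ties favour fewer substitutions, then N-terminal ones.
    """
    base = consensus.peptide
    arg_positions = [i for i, aa in enumerate(base.seq, start=1) if aa == "R"]
    replacements = {
        pos: _runner_up(consensus.frequency_matrix, pos, exclude="RKH")
        for pos in arg_positions
    }
    limit = len(arg_positions) if max_substitutions is None else max_substitutions
    best: tuple[float, int, tuple] | None = None
    best_subs: list[tuple[int, str]] = []
    for k in range(0, limit + 1):
        for subset in combinations(arg_positions, k):
            subs = [(pos, replacements[pos]) for pos in subset]
            candidate = VariantSpec("candidate", base, tuple(subs)).apply()
            err = abs(net_charge(candidate, pka, ph) - target_charge)
            key = (err, k, subset)
            if best is None or key < best:
                best = key
                best_subs = subs
    return best_subs


def _runner_up(fm: FrequencyMatrix, position: int, exclude: str = "") -> str:
    """Most frequent residue at a position outside an excluded alphabet."""
    counts = fm.counts.loc[position].drop(labels=list(exclude))
    top = counts.max()
    return sorted(counts[counts == top].index)[0]


# ---------------------------------------------------------------------------
# Variant series
# ---------------------------------------------------------------------------

def arg_series(
    base: Peptide | str,
    replacements: Mapping[int, str] | None = None,
    frequency_matrix: FrequencyMatrix | None = None,
    default_replacement: str = "L",
    removal_order: Sequence[int] | None = None,
) -> list[VariantSpec]:
    """The arginine-count series: R progressively removed, plus a K swap.

    From a base with n arginines, emits variants with n, n-1, ..., 0 arginines
    (labels ``<base>_<k>R``) and an all-R-to-K swap (``<base>_<n>K``).
    Replacement residues come from `replacements`, else the runner-up residue
    of a supplied frequency matrix, else a neutral nonpolar default. Arginines
    are removed N- to C-terminal unless `removal_order` lists positions.
    """
    base = as_peptide(base, id="synTP")
    arg_positions = [i for i, aa in enumerate(base.seq, start=1) if aa == "R"]
    if not arg_positions:
        raise ValueError("arg_series requires a base containing arginine")
    order = list(removal_order) if removal_order is not None else arg_positions
    if sorted(order) != sorted(arg_positions):
        raise ValueError("removal_order must list exactly the arginine positions")

    def replacement(pos: int) -> str:
        if replacements and pos in replacements:
            return replacements[pos]
        if frequency_matrix is not None:
            return _runner_up(frequency_matrix, pos, exclude="RKH")
        return default_replacement

    n = len(arg_positions)
    series = [VariantSpec(f"{base.id}_{n}R", base, ())]
    removed: list[tuple[int, str]] = []
    for k, pos in enumerate(order, start=1):
        removed.append((pos, replacement(pos)))
        series.append(VariantSpec(f"{base.id}_{n - k}R", base, tuple(removed)))
    k_swap = tuple((pos, "K") for pos in arg_positions)
    series.append(VariantSpec(f"{base.id}_{n}K", base, k_swap))
    return series


def arg_scan(
    base0r: Peptide | str,
    positions: Sequence[int] = DEFAULT_SCAN_POSITIONS,
) -> list[VariantSpec]:
    """Single-arginine scan: one variant per position, each with exactly one R.

    The base must be arginine-free so each variant's sole arginine is the
    scanned one.
    """
    base0r = as_peptide(base0r, id="synTP_0R")
    if "R" in base0r.seq:
        raise ValueError("arg_scan base must contain no arginine")
    if len(set(positions)) != len(positions):
        raise ValueError("duplicate scan positions")
    return [
        VariantSpec(f"{base0r.id}_R{pos}", base0r, ((pos, "R"),))
        for pos in positions
    ]


def point_mutants(
    base: Peptide | str,
    muts: Sequence[tuple[int, str, str]],
    combos: bool = True,
) -> list[VariantSpec]:
    """Point mutants like E2A, E18A and (with `combos`) their combinations.

    Each mutation is (position, from_residue, to_residue); `from_residue`
    must match the base sequence. Labels join single-mutant names with '/'.
    """
    base = as_peptide(base)
    for pos, from_res, _ in muts:
        actual = base.residue(pos)
        if actual != from_res:
            raise ValueError(
                f"base holds {actual} at position {pos}, expected {from_res}"
            )
    sizes = range(1, len(muts) + 1) if combos else [1]
    variants = []
    for size in sizes:
        for subset in combinations(muts, size):
            label = "/".join(f"{f}{pos}{t}" for pos, f, t in subset)
            variants.append(
                VariantSpec(label, base, tuple((pos, t) for pos, _, t in subset))
            )
    return variants
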