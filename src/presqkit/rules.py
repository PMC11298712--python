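"""Rule-based mitochondrial-targeting classifier.

Encodes the experimentally derived requirements for a functional N-terminal
targeting peptide in a reduced import system: within the N-terminal window a
peptide must carry at least one basic residue (R or K; the two were shown to
be exchangeable) outside the flanking positions {1, 2} (position 1 is the
initiator Met and a basic residue at +2 failed to target), and at most zero
acidic residues (either single remaining glutamate kept an otherwise
TP-like peptide cytosolic; removing both conferred targeting). Histidine is
not counted basic: only R and K were demonstrated. Amphiphilicity and net
charge are deliberately absent from the rule; they varied widely among
functional constructs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .io import data_path
from .peptide import Peptide, as_peptide

logger = logging.getLogger("presqkit")

MITO = "mitochondrion"
CYTO = "cytosol"

#: Scan positions the rule's flank exclusion was established on; calls that
#: hinge on other in-window positions are flagged as untested.
TESTED_POSITIONS = frozenset({2, 6, 8, 9, 12, 13, 15, 21})


@dataclass(frozen=True)
class LocalizationCall:
    """A targeting call with the rule outcomes that produced it."""

    call: str
    reasons: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.reasons:
            raise ValueError("a localization call must carry reasons")


@dataclass(frozen=True)
class ConstructFeatures:
    """A construct encoded by its targeting-relevant features.

    `basic_positions` holds (position, residue) pairs for basic residues in
    the window; `n_acidic` counts acidic residues in the window.
    """

    label: str
    basic_positions: tuple[tuple[int, str], ...]
    n_acidic: int


class PresequenceRuleClassifier(ClassifierMixin, BaseEstimator):
    """Classify N-terminal peptides as mitochondrion- or cytosol-destined.

    Parameters mirror the empirical rule: `window` (residues evaluated from
    the N-terminus), `min_basic` basic residues required outside
    `flank_excluded_positions`, `max_acidic` acidic residues tolerated in the
    window, and the residue sets counted as basic / acidic.

    Accepts either sequences (str / Peptide) or ConstructFeatures rows.
    `fit` validates parameters and sets ``classes_``; the rule itself has no
    learned state.
    """

    def __init__(
        self,
        window: int = 24,
        min_basic: int = 1,
        max_acidic: int = 0,
        flank_excluded_positions: tuple[int, ...] = (1, 2),
        basic_residues: str = "RK",
        acidic_residues: str = "DE",
    ):
        self.window = window
        self.min_basic = min_basic
        self.max_acidic = max_acidic
        self.flank_excluded_positions = flank_excluded_positions
        self.basic_residues = basic_residues
        self.acidic_residues = acidic_residues

    def fit(self, X: Sequence = (), y=None) -> "PresequenceRuleClassifier":
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.min_basic < 0 or self.max_acidic < 0:
            raise ValueError("min_basic and max_acidic must be >= 0")
        self.classes_ = np.array([CYTO, MITO])
        return self

    def _call_features(self, feats: ConstructFeatures) -> LocalizationCall:
        excluded = set(self.flank_excluded_positions)
        counted = [
            (pos, res)
            for pos, res in feats.basic_positions
            if pos <= self.window and pos not in excluded
            and res in set(self.basic_residues)
        ]
        reasons = [
            f"basic residues at non-flank window positions: "
            f"{len(counted)} (require >= {self.min_basic})",
            f"acidic residues in window: {feats.n_acidic} "
            f"(allow <= {self.max_acidic})",
        ]
        untested = [pos for pos, _ in counted if pos not in TESTED_POSITIONS]
        if untested:
            reasons.append(
                f"note: basic position(s) {untested} untested in vivo"
            )
        ok = (
            len(counted) >= self.min_basic
            and feats.n_acidic <= self.max_acidic
        )
        return LocalizationCall(MITO if ok else CYTO, tuple(reasons))

    def _features_from_peptide(self, p: Peptide) -> ConstructFeatures:
        if len(p) < self.window:
            logger.warning(
                "%s: length %d < window %d, evaluating available residues",
                p.id, len(p), self.window,
            )
        window_seq = p.seq[: self.window]
        basic = tuple(
            (i, aa)
            for i, aa in enumerate(window_seq, start=1)
            if aa in set(self.basic_residues)
        )
        n_acidic = sum(aa in set(self.acidic_residues) for aa in window_seq)
        return ConstructFeatures(p.id, basic, n_acidic)

    def call(self, x: "ConstructFeatures | Peptide | str") -> LocalizationCall:
        """Full call with reasons for one construct."""
        if not hasattr(self, "classes_"):
            self.fit()
        if not isinstance(x, ConstructFeatures):
            x = self._features_from_peptide(as_peptide(x))
        return self._call_features(x)

    def predict(self, X: Iterable) -> np.ndarray:
        return np.array([self.call(x).call for x in X])


def predict_targeting(
    p: "Peptide | str | ConstructFeatures",
    classifier: PresequenceRuleClassifier | None = None,
    **params,
) -> LocalizationCall:
    """One-shot targeting call with default (or overridden) rule parameters."""
    clf = classifier or PresequenceRuleClassifier(**params)
    return clf.call(p)


# ---------------------------------------------------------------------------
# Truth-table evaluation
# ---------------------------------------------------------------------------

def parse_basic_positions(text: str) -> tuple[tuple[int, str], ...]:
    """Parse '9;13K;21' into ((9,'R'), (13,'K'), (21,'R'))."""
    if not text or (isinstance(text, float) and pd.isna(text)):
        return ()
    out = []
    for token in str(text).split(";"):
        token = token.strip()
        if token.endswith(("K", "R", "H")):
            out.append((int(token[:-1]), token[-1]))
        else:
            out.append((int(token), "R"))
    return tuple(out)


def load_truth_table() -> pd.DataFrame:
    """The shipped in-vivo construct fixture (feature vectors + outcomes)."""
    df = pd.read_csv(
        data_path("truth_table.tsv"), sep="\t", comment="#",
        dtype={"label": str}, keep_default_na=False,
    )
    df["n_acidic"] = df["n_acidic"].astype(int)
    return df


def evaluate_truth_table(
    fixture: pd.DataFrame | None = None,
    classifier: PresequenceRuleClassifier | None = None,
) -> tuple[float, pd.DataFrame]:
    """Apply the rule to every fixture construct and report agreement.

    Returns (agreement fraction, per-construct report with predicted and
    observed calls, agreement flags and the rule reasons).
    """
    if fixture is None:
        fixture = load_truth_table()
    if fixture.empty:
        raise ValueError("truth-table fixture is empty")
    clf = classifier or PresequenceRuleClassifier()
    rows = []
    for row in fixture.itertuples(index=False):
        feats = ConstructFeatures(
            row.label,
            parse_basic_positions(row.basic_positions),
            int(row.n_acidic),
        )
        result = clf.call(feats)
        rows.append(
            {
                "label": row.label,
                "observed": row.observed,
                "predicted": result.call,
                "agree": result.call == row.observed,
                "reasons": " | ".join(result.reasons),
            }
        )
    report = pd.DataFrame(rows)
    return float(report["agree"].mean()), report
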