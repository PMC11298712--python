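"""Dataset-level summaries: composition tables, physicochemical aggregates,
and N-terminal-domain charges of receptor proteins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .peptide import AMINO_ACIDS, Peptide, as_peptide
from .physchem import (
    CLASS_NAMES,
    DEFAULT_CLASS_SCHEME,
    PKA_PROTCALC,
    PhyschemFeaturizer,
    PkaSet,
    class_composition,
    net_charge,
    validate_class_scheme,
)


@dataclass(frozen=True)
class CompositionReport:
    """Pooled-residue composition of a named peptide set."""

    name: str
    class_fractions: Mapping[str, float]
    residue_frequencies: pd.Series  # indexed by the 20 residues, sums to 1
    n_sequences: int
    n_residues: int


def composition_report(
    peptides: Sequence[Peptide | str],
    scheme: Mapping[str, str] | None = None,
    name: str = "set",
) -> CompositionReport:
    """Class fractions and the 20-residue frequency vector of a peptide set."""
    scheme = scheme or DEFAULT_CLASS_SCHEME
    validate_class_scheme(scheme)
    peps = [as_peptide(p) for p in peptides]
    if not peps:
        raise ValueError("composition_report requires at least one peptide")
    counts = pd.Series(0, index=list(AMINO_ACIDS))
    for p in peps:
        for aa in p.seq:
            counts[aa] += 1
    total = int(counts.sum())
    return CompositionReport(
        name=name,
        class_fractions=class_composition(peps, scheme),
        residue_frequencies=counts / total,
        n_sequences=len(peps),
        n_residues=total,
    )


def physchem_aggregate(
    peptides: Sequence[Peptide | str],
    featurizer: PhyschemFeaturizer | None = None,
) -> pd.DataFrame:
    """Mean and sample sd of per-peptide physicochemical properties.

    Rows: net_charge, mean_hydrophobicity, hydrophobic_moment, length;
    columns: mean, sd, n.
    """
    feat = featurizer or PhyschemFeaturizer()
    frame = feat.fit_transform(peptides)
    props = ["net_charge", "mean_hydrophobicity", "hydrophobic_moment", "length"]
    out = pd.DataFrame(
        {
            "mean": frame[props].mean(),
            "sd": frame[props].std(ddof=1).fillna(0.0),
            "n": len(frame),
        }
    )
    return out


def domain_charge(
    p: Peptide | str,
    domain_end: int,
    pka: PkaSet | str = PKA_PROTCALC,
    ph: float = 7.0,
    include_c_terminus: bool = False,
) -> float:
    """Net charge of the N-terminal domain 1..domain_end at a given pH.

    The free N-terminus is included; the C-terminal carboxylate is excluded
    by default because the domain continues into the rest of the protein
    (internal truncation). Used to compare the cytosolic N-terminal domains
    of presequence receptors such as TOM22 homologues.
    """
    p = as_peptide(p)
    if not 1 <= domain_end <= len(p):
        raise ValueError(f"domain_end {domain_end} outside 1..{len(p)}")
    domain = p.subsequence(1, domain_end)
    return net_charge(
        domain, pka, ph, n_terminus=True, c_terminus=include_c_terminus
    )
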