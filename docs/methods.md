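# Methods

## Scope and model

`presqkit` treats an organellar targeting peptide (TP) as a plain amino-acid
string over the 20 canonical residues, positions numbered 1-based from the
initiator methionine. Five computational layers operate on this object:
dataset delineation, physicochemistry, consensus design, proteome screening
and rule-based targeting prediction; a synthetic-data layer generates inputs
with the statistical structure the analyses assume. Ambiguity codes
(B/Z/X/U/O) are rejected at parse time rather than silently scored.

## Delineation of TP regions

Homology-based delineation takes, for each protein, the earliest aligned
query position across its homologs ("overhang table", produced by any
aligner) and sets `tp_end = aggregate(starts) − 1`; 0 means a fully conserved
N-terminus, i.e. no presequence. The aggregation is configurable (`median`,
`min`, `max`); the default is the *lower median*, which is robust to a
minority of spurious full-length alignments (which a `min` rule is not — see
`tests/test_dataset.py`) and always returns one of the observed integers, so
`min ≤ median ≤ max` holds exactly. Records with TP length outside the
inclusive band 10–150 residues are partitioned out before statistics.
Length summaries use the sample (n−1) standard deviation; a single-record
summary reports sd = 0 with a logged notice.

Single-helix extraction returns the annotated helix segment (not the whole
TP) of records classified `single_alpha` with exactly one segment, strictly
shorter than 25 residues by default.

## Physicochemistry

**Net charge** is a Henderson–Hasselbalch sum at the requested pH: positive
groups (free N-terminus, K, R, H) contribute `+1/(1+10^(pH−pKa))`, negative
groups (free C-terminus, D, E, C, Y) contribute `−1/(1+10^(pKa−pH))`. Two
pKa sets ship: `protcalc` (default; N-term 8.0, C-term 3.1, K 10.0, R 12.0,
H 6.5, D 4.4, E 4.4, C 8.5, Y 10.0), chosen to approximate the Protein
Calculator convention common in the presequence literature, and `emboss`.
Termini are included by default; for internally truncated domains
(`domain_charge`) the C-terminal carboxylate is excluded because the chain
continues in the real protein — switchable, since published domain-charge
values rarely state the convention.

**Hydrophobicity** uses the Fauchère–Pliska octanol/water scale (shipped as
a data file, alternative scales pluggable), as used by HELIQUEST. The
**hydrophobic moment** places residue *i* at angle (i−1)·δ with δ = 100°
(ideal α-helix) and reports the length-normalized magnitude of the vector
sum — the mean moment ⟨μH⟩, matching HELIQUEST's convention. It is computed
over the full peptide by default; an optional best-window mode (default
window 18) scans all windows and reports the maximum. The moment is
invariant under a uniform phase offset and vanishes for any homopolymer
whose length places the residues uniformly around the wheel (e.g. 18-mers
at δ = 100°).

**Composition** is pooled over all residues of a set, with the default class
scheme basic {K,R,H}, acidic {D,E}, polar uncharged {S,T,N,Q,C,Y}, nonpolar
{G,A,V,L,I,P,F,M,W} — the standard textbook grouping; the scheme is
configurable because published composition tables rarely print theirs.

## Consensus design and variants

The consensus designer anchors all helices at position 1, counts residues
per position (coverage = number of sequences reaching that position), and
takes the modal residue; every design position must be covered. Ties are
resolved by the residue's total frequency across the whole set, then
alphabetically, and are flagged per position so a design can be audited.

Charge adjustment substitutes explicit (position, residue) pairs — intended
for replacing excess arginines, warning if a position does not hold R.
Because which arginines to replace is a free choice, a helper enumerates
subsets of arginine positions (each replaced by the position's most frequent
non-basic residue) and returns the subset minimizing the distance of the
resulting net charge to a target (default +2.80 e, the endogenous helix
mean); ties prefer fewer substitutions. On generated helix sets this lands
on 24-mers retaining 3 arginines at ≈ +2.9 e.

Variant generators are substitution-only (no indels, output length always
equals input length): the arginine-count series removes arginines N- to
C-terminally (order configurable) with replacements from an explicit map, a
frequency-matrix runner-up, or a neutral nonpolar default, plus an all-R→K
swap; the arginine scan places a single R at each of the probed positions
(default +2/+6/+8/+9/+12/+13/+15/+21) of an arginine-free base; point
mutants validate the expected source residue and can emit all combinations
(E2A, E18A, E2A/E18A).

## Proteome screening

The screen scores the ungapped, unshifted sum of substitution-matrix entries
between a query and each ORF's N-terminal window (default k = 24, including
the initiator Met). ORFs shorter than k are skipped — padding would require
a gap score the method does not define. The shipped matrix is the published
NCBI BLOSUM30 (1/5-bit units); parsing validates symmetry and completeness
and drops the B/Z/X/* columns with a notice. Hits are sorted by descending
score with ORF id as a deterministic tiebreaker and dense-ranked, so output
is byte-for-byte reproducible.

## Targeting rule

The classifier encodes the minimal requirement observed in vivo in a
reduced-TOM system: within the N-terminal window (default 24),

* at least `min_basic` (default 1) basic residues — R or K; the two proved
  exchangeable — at positions **outside** the flank {1, 2} (position 1 is
  Met; a sole arginine at +2 failed to target while +6 and beyond succeeded);
* at most `max_acidic` (default 0) acidic residues (D/E) — either single
  remaining glutamate kept an otherwise TP-like peptide cytosolic, and only
  removing both conferred targeting.

Histidine is not counted basic (never demonstrated). Hydrophobic moment and
net charge are deliberately absent: both varied widely among functional
constructs. Calls carry machine-readable reasons, including a flag when a
decisive basic residue sits at a position (3–5, 22–24) never probed
experimentally. The default parameters reproduce all 16 construct outcomes
in the shipped truth table; the `max_acidic = 0` default is calibrated to
those constructs and is overridable, since endogenous TP helices do average
~3.6% acidic residues. The truth-table fixture encodes constructs as feature
vectors (basic-residue positions, acidic count) because the full construct
sequences are not part of the public record; representative positions are
documented in the fixture header.

## Synthetic data

The generator exists to exercise the pipeline under the study's stated
conditions, not to imitate real sequence detail.

* **Background ORFs**: residues i.i.d. from a class profile (11.2% basic,
  14.0% acidic, 22.2% polar uncharged, 52.5% nonpolar) spread uniformly
  within classes; mature lengths log-normal (median 280, σ = 0.45, a typical
  protein-length distribution), minimum 50; every ORF starts with Met.
  Default proteome: 4,803 ORFs, 14% carrying a TP, split evenly between
  mitochondrial and chloroplast.
* **TP lengths** follow truncated normals on [10, 150]. The parent (μ, σ)
  is solved numerically (scipy) so the *truncated* distribution has exactly
  the target moments (mito 59.3/23.4, chloro 78.4/17.3) — naive truncation
  of Normal(59.3, 23.4) would bias the mean upward by ≈ 1.1 residues.
  Lengths are rounded to integers.
* **Helix segments** use a two-step amphipathic model: residues are drawn
  i.i.d. from the helix profile — class fractions 17.3/3.6/26.2/52.9 with
  within-class weights emulating the reported abundance pattern (R-dominant
  basic content, S/T-rich polar, A/L/V-rich nonpolar, scarce D/E/P/I) — and
  then *permuted* so that hydrophobic residues cluster on one helical face:
  positions are ranked by cos((i−1)·100° − φ) with a random phase φ, residues
  by their hydrophobicity plus Gaussian noise of scale σ, and the ranks are
  matched. Because placement is a permutation of an i.i.d. draw, the
  composition marginal is exactly the profile at any σ. σ = 2.3 H-units was
  calibrated once so the mean moment of generated helices is ≈ 0.288 μH (the
  observed helix mean); the resulting per-helix spread (sd ≈ 0.12) and mean
  net charge (≈ +2.7 e at pH 7 with the default pKa set, vs 2.80 ± 1.76
  observed) follow from the model without further tuning. Helix segment
  lengths are uniform on 18–24 residues; generated sets include at least one
  full-length helix so a 24-position consensus is always defined.
* **Planted TPs** are Met + helix-profile residues with the amphipathic
  segment embedded at an annotated position (in 75% of mitochondrial TPs,
  matching the observed α-helical fraction) and are guaranteed at least one
  basic residue outside positions 1–2 (inserted if the draw lacks one, a
  rare event at these compositions).
* **Overhang tables** give each protein n homolog rows with
  `query_aln_start = tp_end + 1 + round(N(0, noise_sd))`, floored at 1, and
  a configurable fraction of spurious full-length hits starting at 1.
* **The synthetic supplement stand-in** (`synthetic_supplement`) bundles 113
  mitochondrial + 97 chloroplast presequence records, 31 of the
  mitochondrial ones hosting a single helix segment < 25 residues. It is a
  labelled synthetic surrogate for a curated presequence dataset: passing
  statistics on it demonstrate that the pipeline recovers the generator's
  planted parameters at the study's sample sizes, not that real data were
  re-analyzed.

What the generator does **not** emulate: real sequence motifs (cleavage-site
motifs such as R-2/R-3 arginines), position-specific composition along the
TP, codon-level structure, homology between proteins, or TargetP-style
predictor scores. Results on synthetic data therefore validate the
computational pipeline and its statistical behaviour, not biological
discovery claims.

## Numerical choices and problem sizes

* Tests and the reproduction script use modest problem sizes chosen for statistical
  resolution: parameter recovery at n = 2,000 TPs (2 s.e. ≈ 1.0 residue)
  and 10,000 helices (class-fraction s.e. < 0.1 pp); study-level
  reproduction averages 10 replicate stand-ins at the study's own n
  (113/97/31), with tolerance bands of two standard errors computed from
  the published population sd, plus the conventional 0.3 e allowance on mean
  net charge for pKa-set uncertainty.
* All randomness flows through `numpy.random.default_rng` seeded from one
  integer; identical seeds give byte-identical FASTA/TSV output.
* Frequencies at positions with zero coverage are NaN, not 0; consensus
  design refuses uncovered positions outright.
* `fsolve` moment matching for truncated normals is cached per parameter
  set; failure raises rather than falling back silently.

## Known limitations

* The rule classifier is a faithful encoding of a small construct series in
  one organism; positions 3–5 and 22–24 and `max_acidic > 0` regimes are
  extrapolations and are flagged as such in call reasons.
* The consensus of a synthetic helix set is composition-realistic but not
  sequence-identical to any published design; analyses that depend on a
  specific published synTP string should supply it as FASTA input.
* Charge calculations ignore sequence-context pKa shifts and phosphates;
  isoelectric points are out of scope.
* The screen is ungapped and N-anchored by design; it is not a substitute
  for alignment statistics (no E-values).
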