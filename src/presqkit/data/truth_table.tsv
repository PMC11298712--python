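# In-vivo construct truth table: localization of mVenus reporter fusions driven
# by native or engineered N-terminal peptides in C. merolae.
# Constructs are encoded as feature vectors over the 24-residue classifier
# window: 'basic_positions' lists the 1-based positions of basic residues
# (R or K; 'K' suffix marks lysine), 'n_acidic' counts acidic residues (D/E).
# Full construct sequences are not part of the public record, so positions for
# AAT, synTP and FMNL basic residues are representative non-flank positions
# consistent with the reported construct series (the R13 anchor comes from the
# 1-R strain label).
# Enumeration (16 rows): AAT 1-33; synTP R-series 3R/2R/1R/0R/3K; single-R scan
# at +2/+6/+8/+9/+12/+15/+21 (the +13 scan construct is the series 1R row);
# FMNL E2A, E18A, E2A/E18A. Folded constructs: FMNL wild-type 1-24 (two acidic
# residues; cytosolic, implied a fortiori by either single mutant) and RPSA 1-24
# (no acidics, basic residues at interior positions; mitochondrial,
# feature-identical to a passing scan row).
label	basic_positions	n_acidic	observed
AAT_1-33	4;13	0	mitochondrion
synTP_3R	9;13;21	0	mitochondrion
synTP_2R	13;21	0	mitochondrion
synTP_1R	13	0	mitochondrion
synTP_0R		0	cytosol
synTP_3K	9K;13K;21K	0	mitochondrion
synTP_1R_R2	2	0	cytosol
synTP_1R_R6	6	0	mitochondrion
synTP_1R_R8	8	0	mitochondrion
synTP_1R_R9	9	0	mitochondrion
synTP_1R_R12	12	0	mitochondrion
synTP_1R_R15	15	0	mitochondrion
synTP_1R_R21	21	0	mitochondrion
FMNL_E2A	7;12	1	cytosol
FMNL_E18A	7;12	1	cytosol
FMNL_E2A_E18A	7;12	0	mitochondrion
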