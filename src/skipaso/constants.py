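"""Central table of the procedure's documented constants.

Every threshold used by the pipeline lives here so that a single place
documents the geometry of the design windows, the NMD-evasion distances and
the oligo filter limits.  All of them can be overridden per call or via the
CLI; these are the defaults the procedure was built around.
"""

# ASO geometry ---------------------------------------------------------------
ASO_LENGTH = 25  # optimal morpholino length (nt)

# Acceptor-site windows span the intron|exon border.  Offsets are 1-based and
# signed: negative = intronic, positive = exonic, there is no position zero.
# The first window reaches 18 nt into the intron and 7 nt into the exon; the
# window then slides one nucleotide at a time toward the exon.
ACCEPTOR_WINDOWS = [(-18 + i, 7 + i) for i in range(7)]   # (-18,+7) .. (-12,+13)
# Donor-site windows span the exon|intron border, sliding toward the intron.
DONOR_WINDOWS = [(13 - i, -(12 + i)) for i in range(7)]   # (+13,-12) .. (+7,-18)

# A junction window needs at most 18 intronic nucleotides on its side.
MIN_FLANK_INTRON = 18
# and at most 13 exonic nucleotides.
MIN_EXON_FOR_JUNCTION = 13

# NMD evasion rules ----------------------------------------------------------
# A premature termination codon (PTC) evades NMD when it lies fewer than
# NMD_JUNCTION_RULE_NT nucleotides upstream of the last exon-exon junction
# (the "50-55 nt rule", stringent 55-nt variant), when it falls in the last
# exon, or when it sits within NMD_START_PROXIMAL_NT nucleotides of the
# start codon.  Distances are measured from the first nucleotide of the stop
# codon; at exactly 55 nt the transcript is NMD-competent, at exactly 150 nt
# from the start it still evades.
NMD_JUNCTION_RULE_NT = 55
NMD_START_PROXIMAL_NT = 150

# 20/20 mutation-pattern classification --------------------------------------
ONG_SCORE_CUTOFF = 20.0   # % gain-of-function mutations; strict >
TSG_SCORE_CUTOFF = 20.0   # % loss-of-function mutations; strict >
TSG_ONCOGENE_MAX = 5.0    # oncogene call additionally requires TSG score <= 5%

# Exon mutation ranking ------------------------------------------------------
TOP_K_EXONS = 10
TOP_GENE_FRACTION = 0.10

# Physicochemical filter thresholds ------------------------------------------
GC_MIN = 40.0             # % (inclusive)
GC_MAX = 60.0             # % (inclusive)
G_MAX = 36.0              # % (no more than 36% G)
MAX_G_RUN = 3             # no tetra-G
MAX_SELF_COMP = 16        # contiguous self-complementary base pairs
MISMATCH_BUDGET = 2       # genome-specificity search
REQUIRED_GENOME_MATCHES = 1

# Melting-temperature conditions ---------------------------------------------
NA_CONC_M = 1.0           # 1 M NaCl "standard conditions"
PRIMER_CONC_M = 50e-9     # 50 nM oligo, the usual web-calculator default
GAS_CONSTANT = 1.987      # cal / (mol K)
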