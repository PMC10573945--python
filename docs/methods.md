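# Methods

This note documents the models, conventions and numerical choices behind
`skipaso`, and what the synthetic test loci do and do not establish about
real data.

## Coordinate and sequence conventions

GFF3 is 1-based inclusive on disk and converted to 0-based half-open
intervals internally; every user-facing report converts back to 1-based.
Exons are strand-normalized at parse time: they are ordered 5'→3' in
transcript orientation (index 1 = most 5'), sequences are given on the
transcript strand (minus-strand features reverse-complemented), and each
exon carries its flanking intron sequences in the same orientation. The
"coding set" of a gene comprises transcripts with biotype
`protein_coding` and a resolved CDS; NMD/retained-intron and other
non-canonical biotypes are retained in the model but excluded from
analysis. A CDS length not divisible by 3 is flagged, not fatal, at parse
time (the synthetic generator refuses to emit one).

Exon coding status is derived from CDS overlap: an exon containing the
first (last) coding base is `contains_start` (`contains_stop`), an exon
fully covered by CDS is `fully_coding`, an exon with no CDS overlap is
`non_coding`. Skippable exons are the `fully_coding` ones — necessarily
strictly between the start- and stop-codon exons — so that skipping never
touches translation initiation or termination. Exon sequences are derived
from the genome FASTA (annotation sources sometimes ship separate cDNA
dumps; deriving from the genome keeps exon and intron sequences mutually
consistent).

## Skip simulation and NMD

Skipping excises one exon from the spliced transcript; the two junctions
flanking it merge into one, and junction coordinates are recomputed on
the skipped transcript. Frame is `IN` iff the exon length is a multiple
of 3. Translation proceeds codon-by-codon from the start codon (standard
genetic code); the PTC position is the transcript coordinate of the
first nucleotide of the first stop codon, reported only when that stop
differs from the annotated stop mapped onto the skipped transcript. A
product that reaches the 3' end without a stop is flagged `nonstop` and
given an indeterminate decay verdict rather than being treated as an NMD
substrate.

NMD is evaluated only for out-of-frame products carrying a PTC. The
three evasion rules use these distance conventions, chosen so that the
published thresholds are respectively the first degrading and the last
evading values (the sources give thresholds but not the inequality
direction at the exact boundary):

* **junction rule** (stringent 55-nt variant of the 50–55 nt rule):
  evades when `last_junction − ptc < 55`; a PTC exactly 55 nt upstream
  is NMD-competent;
* **last-exon rule**: evades when `ptc ≥ last_junction` (a transcript
  with no remaining junction is all last exon);
* **start-proximal rule**: evades when `ptc − cds_start ≤ 150`; 150 nt
  still evades, 151 does not.

`degraded = PTC exists ∧ no rule fires`. In-frame skips are never tested
for NMD even when translation reveals an incidental early stop; a
diagnostic warning is emitted in that case.

## 20/20 classification

The gain-of-function tally `x` counts missense substitutions and
in-frame indels (including complex in-frame deletions); the
loss-of-function tally `y` counts nonsense substitutions and frameshift
indels. Synonymous substitutions count toward the total (and toward the
per-exon point-mutation profile) but toward neither tally. The decision
grid uses strict inequalities; score pairs on a boundary (ONG exactly
20%, or TSG exactly 20% with ONG < 20%) match no row and yield
`unclassified` — a deliberate refusal to silently pick a label. The
plain tallies are the default because they are the only operational
formula published for the rule; an optional recurrence filter (count a
missense toward `x` only when its genomic position is hit in ≥ R
distinct samples) is available for the stricter "recurrent missense"
reading, disabled by default. "Patient" is operationalized as distinct
sample identifier; mutation sources may contain multiple samples per
patient, which is noted but not resolved. Per-exon burden is computed
per stable exon identifier (not per transcript), counting a sample at
most once per exon; the relative frequency divides by the distinct
samples with ≥1 point mutation in any exon of the gene.

## ASO design geometry

All candidates are 25-mers (the recommended morpholino length). Junction
offsets are signed and 1-based with no zero: −1 is the last intronic
base before an acceptor, +1 the first exonic base, symmetrically at the
donor. The acceptor set slides (−18,+7) → (−12,+13), the donor set
(+13,−12) → (+7,−18); 7 windows per site, 14 per exon whenever both
flanking introns provide ≥18 nt. (A published prose description of the
donor set as "+12 to −13 … +7 to −18" yields only six windows and
contradicts both the printed candidate names and the stated 7-per-site
count; the printed candidates win.) A flank shorter than 18 nt makes
that side junction-undesignable: its set is omitted with a warning
rather than an error. Exonic candidates are all windows fully inside the
exon that completely contain at least one positive-score ESE occurrence
("completely overlap" is read as site ⊆ window — the opposite
containment is impossible for motifs shorter than 25 nt); motif
occurrences are found by exact string scan, overlapping occurrences
included, and non-positive scores (silencers/neutral sites) are ignored.
ASO sequences are emitted uppercase RNA, 5'→3', antisense to the target
window. Names extend the Mann convention: `H{exon}A/D (o1, o2)` for
junctions (acceptor listing intronic then exonic offsets, donor the
reverse) and `H{exon}E (start, end)` with 1-based exon coordinates for
exonic windows; the exon index counts all exons of the transcript,
non-coding ones included.

## Evaluation

* **GC bounds are inclusive**: the reference donor set contains a
  passing candidate at exactly 40% GC, forcing `[40, 60]`.
* **Self-complementarity**: a 25-mer hairpin cannot stack more than 12
  pairs, so a 16-pair threshold can only be reached by the dimer of two
  copies of the molecule. The metric is therefore the longest contiguous
  complementary stretch (Watson–Crick plus G·U wobble, RNA context)
  over all antiparallel self-dimer registers, bounded below by the
  longest stacked helix of the ViennaRNA minimum-free-energy fold when
  the bindings are importable (they are optional; without them the dimer
  component alone decides, and for 25-mers it dominates). An alternative
  hydrogen-bond-weighted mode (A·U = 2, G·C = 3, G·U = 2) is exposed but
  carries no default threshold, since published guidance mixes "base
  pairs" and "H-bonds" for the same limit of 16.
* **Melting temperatures** are reported, not filtered on (no published
  threshold): basic `64.9 + 41(G+C−16.4)/N`; salt-adjusted
  `100.5 + 41(G+C)/N − 820/N + 16.6·log10[Na+]`; nearest-neighbor
  `(ΔH − 3.4 kcal/mol)/(ΔS + R·ln(1/[oligo])) + 16.6·log10[Na+]` in °C,
  with stacked ΔH/ΔS summed from the Sugimoto 1996 DNA or Xia 1998 RNA
  tables (both shipped via Biopython's tables, selectable; which table
  the original web calculator applies to RNA 25-mers is ambiguous, so
  neither is privileged). Standard conditions default to 1 M Na+ and a
  50 nM oligo, the usual web-calculator default, since no oligo
  concentration is published.
* **Specificity** is an ungapped both-strand Hamming scan of the 25-mer
  target (mismatches only, mirroring a `-v 2 -a` short-read-aligner
  search); unique means exactly one alignment at ≤2 mismatches — the
  on-target site itself. G·U wobble is not honored here (DNA context).
  Without a genome the criterion is skipped and flagged "not evaluated"
  rather than failed.

## Prioritization

Criterion (b) requires `OUT` for oncogenes and `IN` for tumor
suppressors; criterion (c) requires ≥1 passing candidate from *each*
strategy. Predicted NMD is reported alongside oncogene targets but is
not a criterion. The ranking percentage's denominator defaults to the
candidate exons (skippable ∩ top-10-mutated); an `all`-skippable-exons
denominator is configurable because the published description does not
pin the universe down. Unclassified genes are excluded from the ranking
(they appear in the assessment table with blank verdicts). Ties break by
absolute qualifying-exon count, then gene symbol, making the order
total and reproducible.

## Synthetic loci

The generator emulates the *structure* of the real inputs — GENCODE
attribute dialect, canonical GT..AG introns, COSMIC mutation-class
vocabulary, SpliceAid-style motif scores — with uniform-random sequence
and planted features. It does not emulate realistic base composition,
splice-site strength, mutational signatures, or patient/sample
structure; passing tests therefore establish the correctness of the
procedure's logic and arithmetic, not its biological yield on real
genomes. Design choices:

* One seed parameter drives all randomness; identical seeds give
  byte-identical files (verified by digest in the tests). Shipped
  default seeds: 7 (NRAS-like), 11 (VHL-like), 3 (NMD branches).
* The NRAS-like locus (7 exons, CDS in exons 2–5, internal coding exons
  of 103 and 160 nt — both frame-shifting) embeds the donor-junction
  context implied by the published NRAS exon-3 candidates; the VHL-like
  locus (two transcripts sharing a 123-nt frame-preserving exon 2)
  embeds both junction contexts implied by the published VHL exon-2
  set, so the design path regenerates all printed candidates verbatim.
* Hotspot mutations are planted at exact exonic positions with a chosen
  number of distinct samples; class-mix rows that force a 20/20 label
  are placed at intronic positions so exon patient counts remain
  exactly the planted ones.
* NMD-branch loci use poly-C exon bodies (no stop codon in any reading
  frame) with the start codon, annotated stop, and the decisive
  premature stop written explicitly at positions chosen relative to the
  55-nt and 150-nt windows; a repair pass replaces any accidental
  in-frame stop in random regions with C and refuses to touch pinned
  positions.
* Off-target planting copies a target window into the 3' flank with
  exactly k seeded substitutions; with a 25-mer and ≤600 nt of random
  flank, accidental extra matches at ≤2 mismatches are vanishingly
  unlikely and are not screened for.

## Problem sizes and determinism

All tests and the acceptance script run on loci of a few kilobases
(genomes ≤ ~3 kb, tens to hundreds of mutation rows), chosen as the
smallest sizes that exercise every branch; the whole suite completes in
a few seconds. The genome-scale figures of the motivating application
(a 72-gene cohort, thousands of patients per exon) require the real
COSMIC/GENCODE/SpliceAid/GRCh38 inputs and are intentionally out of
scope. Property tests (hypothesis) are derandomized; pipeline outputs
are pure functions of inputs and configuration, with every iteration
order fixed by sorting.

## Known limitations

No modeling of EJC deposition or quantitative NMD efficiency; no
intronic silencer/enhancer targeting; no multi-exon cocktails; no
RNA-space (transcriptome) off-target search or ΔG-based off-target
scoring; no cancer-type or allele-specific stratification; no handling
of trans-splicing or fusion transcripts. The specificity scan is exact
Hamming (no gapped alignments), appropriate for morpholino-length
oligos but not a general aligner replacement.
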