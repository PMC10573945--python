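# skipaso

In-silico design of exon-skipping antisense oligonucleotides (ASOs) for
cancer genes.

Many cancer driver genes — RAS-family oncogenes, TP53, VHL — are
"undruggable" by small molecules. Splice-switching ASOs offer an
alternative: a 25-mer morpholino-style oligo that masks a splice site or
an exonic splicing enhancer (ESE) can force the spliceosome to skip one
exon. Skipping a frame-shifting exon of an oncogene creates an
out-of-frame transcript (often degraded by nonsense-mediated decay, NMD),
knocking the protein down; skipping a frame-preserving exon of a tumor
suppressor can yield a shortened but partially functional protein.
`skipaso` implements the full computational procedure for exploring such
strategies, for computational biologists and ASO designers.

## What it computes

Given a GENCODE-style GFF3 annotation, a genome FASTA, a COSMIC-style
mutation export and a SpliceAid-style ESE motif table, the pipeline:

1. **Classifies the gene** with the 20/20 rule. With `x` = missense +
   in-frame-indel (gain-of-function) counts and `y` = nonsense +
   frameshift-indel (loss-of-function) counts over `N` annotated
   mutations, the scores are `ONG = 100·x/N` and `TSG = 100·y/N`:
   `ONG > 20 ∧ TSG ≤ 5` → oncogene; `ONG > 20 ∧ TSG > 5` or
   `ONG < 20 ∧ TSG > 20` → tumor suppressor; otherwise unclassified
   (boundaries are strict and never silently resolved).
2. **Selects skippable exons**: fully coding exons strictly between the
   start- and stop-codon exons of each protein-coding transcript.
3. **Simulates each skip**: frame (`IN` iff exon length ≡ 0 mod 3),
   in-silico translation, location of any premature termination codon
   (PTC), and NMD prediction for out-of-frame products via three evasion
   rules — last exon, <55 nt upstream of the last exon–exon junction,
   and ≤150 nt from the start codon; the transcript is predicted
   degraded exactly when a PTC exists and no rule fires.
4. **Ranks exons by mutation burden**: patients (distinct samples) with
   ≥1 point mutation per exon; the top 10 exons go forward.
5. **Designs 25-mer ASOs**: 7 windows across the acceptor junction
   ((−18,+7) … (−12,+13)) and 7 across the donor junction
   ((+13,−12) … (+7,−18)), plus every exonic window that completely
   contains ≥1 positive-score ESE. Candidates are named in the Mann
   convention (e.g. `H3D (13, -12)`) and emitted as antisense RNA.
6. **Evaluates and filters**: GC% in [40, 60], G% ≤ 36, no G-run > 3,
   self-complementarity ≤ 16 contiguous base pairs, and (optionally) a
   unique genome match at ≤2 mismatches on either strand. Three melting
   temperatures (basic, salt-adjusted, nearest-neighbor with Sugimoto
   1996 DNA or Xia 1998 RNA tables) are reported but not thresholded.
7. **Prioritizes genes** by the percentage of candidate exons that are
   top-10-mutated, frame-appropriate for the gene's cancer role, and
   coverable by at least one passing ASO of each design strategy.

A deterministic synthetic-locus generator (`skipaso.fixtures`) stands in
for the genome-scale inputs: it emits GFF3/FASTA/mutation-TSV/ESE-table
files for crafted loci, including an NRAS-like oncogene locus, a
VHL-like two-transcript tumor-suppressor locus (whose junction contexts
regenerate the published candidate sets verbatim), and a family of loci
that drive every NMD branch.

## Worked example

Generate the NRAS-like fixture and run the whole procedure:

```sh
skipaso fixtures --spec nras-like --out nras
skipaso run-all --gff3 nras/NRASL.gff3 --fasta nras/NRASL.fa \
    --mutations nras/NRASL.mutations.tsv --ese nras/NRASL.ese.tsv \
    --genome nras/NRASL.fa --out nras_run
```

`skipaso skip` reports the consequence of each eligible skip:

```
gene    transcript  exon_id    frame  protein_length  ptc_position  nonstop  nmd_degraded  nmd_rules
NRASL   NRASL-201   NRASL.E03  OUT    65              314           False    True
NRASL   NRASL-201   NRASL.E04  OUT    71              332           False    True
```

Both internal coding exons are frame-shifting (`OUT`), each skip creates
a PTC (transcript coordinate of the stop's first base), and no evasion
rule fires, so both products are predicted NMD substrates — the desired
outcome for an oncogene. The mutation ranking
(`nras_run/exon_mutation_ranking.tsv`) shows the planted hotspot
structure: exon 3 is mutated in 60 patients, 63% of all patients with a
point mutation in the gene:

```
gene    exon_id    rank  absolute_freq  relative_freq
NRASL   NRASL.E03  1     60             0.6316
NRASL   NRASL.E04  2     25             0.2632
NRASL   NRASL.E02  3     10             0.1053
```

Evaluating one designed candidate (the top donor-window ASO of exon 3):

```
$ skipaso evaluate --seq UGCUCCUAGUACCUGUAGAGGUUAA
aso_sequence               gc_percent  g_percent  max_g_run  max_self_comp  tm_basic  tm_salt  tm_nn  genome_matches  passed
UGCUCCUAGUACCUGUAGAGGUUAA  44.0        24.0       2          6              56.04     85.74    90.75  not evaluated   True
```

44% GC sits inside the [40, 60] band, 24% G is below the 36% cap, the
longest G-run (2) and self-dimer stretch (6 pairs) are well under their
limits, so the candidate passes; the three Tm values are reported for
reference (1 M Na+, 50 nM oligo).

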