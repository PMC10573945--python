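"""Design of 25-mer antisense oligonucleotides (ASOs) against a target exon.

Two complementary strategies are implemented, both with a 25-nt sliding
window on the pre-mRNA:

* splice-junction ASOs: 7 windows across the acceptor (intron|exon) border
  and 7 across the donor (exon|intron) border.  Window offsets are signed
  and 1-based with no zero: -1 is the last intronic base before an
  acceptor, +1 the first exonic base, and symmetrically at the donor.
  The acceptor set runs (-18,+7) .. (-12,+13); the donor set (+13,-12)
  .. (+7,-18).
* exonic ASOs: every 25-mer fully inside the exon, kept only when it
  completely contains at least one exonic-splicing-enhancer (ESE) site.

Candidates are named after the Mann convention, e.g. "H3D (13, -12)" for
a donor-site window on the third exon; exonic windows extend the scheme
as "H3E (start, end)" with 1-based exon coordinates.  ASO sequences are
emitted 5'->3' in the RNA alphabet, antisense to the target window.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .annotation import Exon
from .constants import (ACCEPTOR_WINDOWS, ASO_LENGTH, DONOR_WINDOWS,
                        MIN_EXON_FOR_JUNCTION, MIN_FLANK_INTRON)

log = logging.getLogger(__name__)

ACCEPTOR = "acceptor"
DONOR = "donor"
EXONIC = "exonic"


def dna_to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def antisense_rna(target: str) -> str:
    """5'->3' antisense RNA of a sense target window (DNA or RNA input)."""
    dna = target.upper().replace("U", "T")
    return dna_to_rna(str(Seq(dna).reverse_complement()))


@dataclass(frozen=True)
class SpliceWindow:
    site: str                     # acceptor / donor / exonic
    first_offset: int = 0         # signed, 1-based junction offsets
    second_offset: int = 0
    exon_start: int | None = None  # 0-based window start, exonic only
    length: int = ASO_LENGTH


@dataclass(frozen=True)
class EseMotif:
    motif: str
    protein: str
    score: int


@dataclass(frozen=True)
class EseSite:
    motif: str
    protein: str
    score: int
    start: int  # 0-based half-open within the exon
    end: int


@dataclass
class AsoCandidate:
    name: str
    exon_id: str
    window: SpliceWindow
    target_sequence: str  # sense pre-mRNA 25-mer, RNA alphabet
    aso_sequence: str     # antisense 25-mer, RNA alphabet, 5'->3'
    covered_ese_sites: list[EseSite] = field(default_factory=list)


# ---------------------------------------------------------------------------
# ESE annotation
# ---------------------------------------------------------------------------

def annotate_ese_sites(exon_sequence: str,
                       motifs: list[EseMotif]) -> list[EseSite]:
    """Exact occurrences of positive-score enhancer motifs in an exon.

    Overlapping and repeated occurrences are all reported; motifs with
    non-positive scores are silencers or neutral sites and are ignored.
    """
    if not motifs:
        log.warning("empty ESE motif set; no exonic sites will be annotated")
        return []
    seq = exon_sequence.upper().replace("U", "T")
    sites: list[EseSite] = []
    for m in motifs:
        if m.score <= 0:
            continue
        needle = m.motif.upper().replace("U", "T")
        start = seq.find(needle)
        while start != -1:
            sites.append(EseSite(motif=m.motif, protein=m.protein,
                                 score=m.score, start=start,
                                 end=start + len(needle)))
            start = seq.find(needle, start + 1)
    sites.sort(key=lambda s: (s.start, s.end, s.protein, s.motif))
    return sites


def read_ese_table(path) -> list[EseMotif]:
    """Read a motif/protein/score TSV (SpliceAid-style export)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"motif": str, "protein": str,
                                            "score": int})
    required = {"motif", "protein", "score"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"ESE table needs columns {sorted(required)}, "
            f"found {list(df.columns)}")
    return [EseMotif(r.motif, r.protein, int(r.score))
            for r in df.itertuples(index=False)]


# ---------------------------------------------------------------------------
# naming
# ---------------------------------------------------------------------------

def name_candidate(exon_index: int, window: SpliceWindow) -> str:
    """Mann-style candidate name ("H" = human)."""
    if window.site == ACCEPTOR:
        return f"H{exon_index}A ({window.first_offset}, {window.second_offset})"
    if window.site == DONOR:
        return f"H{exon_index}D ({window.first_offset}, {window.second_offset})"
    start_1 = window.exon_start + 1
    return f"H{exon_index}E ({start_1}, {window.exon_start + window.length})"


# ---------------------------------------------------------------------------
# junction design
# ---------------------------------------------------------------------------

def _junction_candidate(exon: Exon, site: str, offsets: tuple[int, int],
                        intron: str) -> AsoCandidate:
    if site == ACCEPTOR:
        intronic, exonic = -offsets[0], offsets[1]
        target = intron[-intronic:] + exon.sequence[:exonic]
    else:
        exonic, intronic = offsets[0], -offsets[1]
        target = exon.sequence[-exonic:] + intron[:intronic]
    assert len(target) == ASO_LENGTH
    window = SpliceWindow(site=site, first_offset=offsets[0],
                          second_offset=offsets[1])
    target_rna = dna_to_rna(target)
    return AsoCandidate(
        name=name_candidate(exon.index_in_transcript, window),
        exon_id=exon.id,
        window=window,
        target_sequence=target_rna,
        aso_sequence=antisense_rna(target_rna),
    )


def design_junction_asos(exon: Exon,
                         upstream_intron: str | None = None,
                         downstream_intron: str | None = None
                         ) -> list[AsoCandidate]:
    """The 14 junction candidates (7 acceptor + 7 donor) for one exon.

    Flanking introns default to the ones attached to the exon by the
    annotation model.  A flank shorter than 18 nt makes that side
    junction-undesignable: its set is omitted with a warning rather than
    raising, so the other side can still be designed.
    """
    if len(exon) < MIN_EXON_FOR_JUNCTION:
        raise ValueError(
            f"exon {exon.id} is {len(exon)} nt; junction windows need "
            f">= {MIN_EXON_FOR_JUNCTION} exonic nt")
    upstream = upstream_intron if upstream_intron is not None \
        else exon.upstream_intron
    downstream = downstream_intron if downstream_intron is not None \
        else exon.downstream_intron
    out: list[AsoCandidate] = []
    if upstream is not None and len(upstream) >= MIN_FLANK_INTRON:
        for offsets in ACCEPTOR_WINDOWS:
            out.append(_junction_candidate(exon, ACCEPTOR, offsets, upstream))
    else:
        log.warning("exon %s: upstream intron missing or < %d nt; "
                    "acceptor set omitted", exon.id, MIN_FLANK_INTRON)
    if downstream is not None and len(downstream) >= MIN_FLANK_INTRON:
        for offsets in DONOR_WINDOWS:
            out.append(_junction_candidate(exon, DONOR, offsets, downstream))
    else:
        log.warning("exon %s: downstream intron missing or < %d nt; "
                    "donor set omitted", exon.id, MIN_FLANK_INTRON)
    return out


# ---------------------------------------------------------------------------
# exonic design
# ---------------------------------------------------------------------------

def design_exonic_asos(exon: Exon,
                       ese_sites: list[EseSite]) -> list[AsoCandidate]:
    """All 25-mer exonic windows that completely contain >= 1 ESE site."""
    seq = exon.sequence
    if len(seq) < ASO_LENGTH:
        log.warning("exon %s is %d nt (< %d); no exonic candidates",
                    exon.id, len(seq), ASO_LENGTH)
        return []
    out: list[AsoCandidate] = []
    for start in range(len(seq) - ASO_LENGTH + 1):
        end = start + ASO_LENGTH
        covered = [s for s in ese_sites if start <= s.start and s.end <= end]
        if not covered:
            continue
        window = SpliceWindow(site=EXONIC, exon_start=start)
        target_rna = dna_to_rna(seq[start:end])
        out.append(AsoCandidate(
            name=name_candidate(exon.index_in_transcript, window),
            exon_id=exon.id,
            window=window,
            target_sequence=target_rna,
            aso_sequence=antisense_rna(target_rna),
            covered_ese_sites=covered,
        ))
    return out
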