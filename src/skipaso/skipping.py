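"""In-silico exon skipping: frame classification, translation, PTC
detection and nonsense-mediated decay (NMD) prediction.

Removing one internal, fully coding exon from a spliced transcript either
preserves the reading frame (exon length divisible by 3) or shifts it.
Out-of-frame products usually acquire a premature termination codon (PTC);
whether the PTC triggers NMD is predicted with three evasion rules:

* 50-55 nt rule (stringent 55-nt variant): a PTC fewer than 55 nt upstream
  of the last exon-exon junction escapes the surveillance complex;
* last-exon rule: a PTC in the terminal exon has no downstream junction
  and is read as a normal stop;
* start-proximal rule: a PTC within ~150 nt of the start codon is
  inefficiently recognized and the transcript escapes degradation.

A transcript is predicted degraded exactly when it carries a PTC and no
evasion rule fires.  NMD is only evaluated for out-of-frame products;
in-frame products keep their annotated stop and are not candidates for
PTC surveillance.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .annotation import FULLY_CODING, Exon, Transcript, select_skippable_exons
from .constants import NMD_JUNCTION_RULE_NT, NMD_START_PROXIMAL_NT

log = logging.getLogger(__name__)

IN_FRAME = "IN"
OUT_FRAME = "OUT"

RULE_LAST_EXON = "last_exon"
RULE_FIFTY_FIVE_NT = "fifty_five_nt"
RULE_START_PROXIMAL = "start_proximal"

STOP_CODONS = {"TAA", "TAG", "TGA", "UAA", "UAG", "UGA"}


@dataclass
class SkippedTranscript:
    """A spliced transcript with one exon excised (transcript coordinates)."""

    parent_id: str
    skipped_exon_id: str
    sequence: str
    junction_positions: list[int]  # first base of each downstream exon
    cds_start: int                 # first base of the start codon
    parent_stop_position: int      # first base of the annotated stop codon,
                                   # mapped onto the skipped transcript
    frame: str = OUT_FRAME         # IN / OUT


@dataclass
class NmdVerdict:
    ptc_position: int | None
    frame: str
    degraded: bool | None
    evasion_rules_fired: set[str] = field(default_factory=set)


@dataclass
class TranslationOutcome:
    protein: str
    ptc_position: int | None
    nonstop: bool = False


@dataclass
class SkippingOutcome:
    """Full consequence report for removing one exon."""

    transcript_id: str
    exon_id: str
    exon_index: int
    frame: str
    protein: str
    protein_length: int
    ptc_position: int | None
    nonstop: bool
    nmd: NmdVerdict | None


def classify_frame(exon: Exon) -> str:
    """IN when the exon length is a multiple of 3, else OUT."""
    if exon.coding_status != FULLY_CODING:
        raise ValueError(
            f"frame classification requires a fully coding exon; "
            f"{exon.id} is {exon.coding_status}")
    return IN_FRAME if len(exon) % 3 == 0 else OUT_FRAME


def skip_exon(transcript: Transcript, exon: Exon) -> SkippedTranscript:
    """Excise one skippable exon and rebuild the spliced transcript."""
    skippable = {e.id for e in select_skippable_exons(transcript)}
    if exon.id not in skippable:
        raise ValueError(
            f"exon {exon.id} is not skippable in transcript {transcript.id}")
    offsets = transcript.exon_offsets()
    keep = [e for e in transcript.exons if e.id != exon.id
            or e.index_in_transcript != exon.index_in_transcript]
    sequence = "".join(e.sequence for e in keep)
    junctions, pos = [], 0
    for e in keep[:-1]:
        pos += len(e)
        junctions.append(pos)
    cds_start = transcript.cds_start
    parent_stop = transcript.cds_end - 3
    exon_start = offsets[exon.index_in_transcript - 1]
    # the skipped exon lies strictly between start and stop codons
    assert cds_start < exon_start and exon_start + len(exon) <= parent_stop
    return SkippedTranscript(
        parent_id=transcript.id,
        skipped_exon_id=exon.id,
        sequence=sequence,
        junction_positions=junctions,
        cds_start=cds_start,
        parent_stop_position=parent_stop - len(exon),
        frame=classify_frame(exon),
    )


def translate_and_find_ptc(skipped: SkippedTranscript) -> TranslationOutcome:
    """Translate from the start codon and locate the first stop.

    The PTC position is the transcript coordinate (on the skipped
    transcript) of the first nucleotide of the first stop codon, reported
    only when that stop differs from the transcript's annotated stop.  A
    product that never reaches a stop codon is flagged nonstop.
    """
    cds = skipped.sequence[skipped.cds_start:]
    if len(cds) < 3:
        raise ValueError("coding sequence shorter than one codon")
    protein_chars: list[str] = []
    stop_at: int | None = None
    for i in range(0, len(cds) - 2, 3):
        codon = cds[i:i + 3].upper()
        if codon in STOP_CODONS:
            stop_at = skipped.cds_start + i
            break
        protein_chars.append(str(Seq(codon).translate()))
    protein = "".join(protein_chars)
    if stop_at is None:
        return TranslationOutcome(protein=protein, ptc_position=None,
                                  nonstop=True)
    ptc = stop_at if stop_at != skipped.parent_stop_position else None
    return TranslationOutcome(protein=protein, ptc_position=ptc)


def predict_nmd(skipped: SkippedTranscript,
                ptc_position: int,
                junction_rule_nt: int = NMD_JUNCTION_RULE_NT,
                start_proximal_nt: int = NMD_START_PROXIMAL_NT) -> NmdVerdict:
    """Apply the three NMD-evasion rules to one PTC.

    Distances use the first nucleotide of the stop codon.  A PTC exactly
    ``junction_rule_nt`` (55) nt upstream of the last junction is
    NMD-competent (< is strict); a PTC exactly ``start_proximal_nt``
    (150) nt downstream of the start codon still evades (<= inclusive).
    """
    if ptc_position is None:
        raise ValueError("no PTC to evaluate")
    if skipped.frame != OUT_FRAME:
        raise ValueError(
            "NMD prediction applies only to out-of-frame skipped products")
    fired: set[str] = set()
    if not skipped.junction_positions:
        fired.add(RULE_LAST_EXON)
    else:
        last_junction = skipped.junction_positions[-1]
        if ptc_position >= last_junction:
            fired.add(RULE_LAST_EXON)
        elif last_junction - ptc_position < junction_rule_nt:
            fired.add(RULE_FIFTY_FIVE_NT)
    if ptc_position - skipped.cds_start <= start_proximal_nt:
        fired.add(RULE_START_PROXIMAL)
    return NmdVerdict(ptc_position=ptc_position, frame=skipped.frame,
                      degraded=not fired, evasion_rules_fired=fired)


def simulate_skip(transcript: Transcript, exon: Exon) -> SkippingOutcome:
    """Skip one exon and report frame, protein, PTC and NMD verdict."""
    skipped = skip_exon(transcript, exon)
    tr_out = translate_and_find_ptc(skipped)
    nmd: NmdVerdict | None = None
    if skipped.frame == OUT_FRAME:
        if tr_out.nonstop:
            nmd = NmdVerdict(ptc_position=None, frame=OUT_FRAME,
                             degraded=None)
        elif tr_out.ptc_position is not None:
            nmd = predict_nmd(skipped, tr_out.ptc_position)
        else:
            # frameshift that happens to terminate at the annotated stop
            nmd = NmdVerdict(ptc_position=None, frame=OUT_FRAME,
                             degraded=False)
    elif tr_out.ptc_position is not None:
        log.warning(
            "in-frame skip of %s in %s nonetheless creates an early stop "
            "at %d; NMD not evaluated for in-frame products",
            exon.id, transcript.id, tr_out.ptc_position)
    return SkippingOutcome(
        transcript_id=transcript.id,
        exon_id=exon.id,
        exon_index=exon.index_in_transcript,
        frame=skipped.frame,
        protein=tr_out.protein,
        protein_length=len(tr_out.protein),
        ptc_position=tr_out.ptc_position,
        nonstop=tr_out.nonstop,
        nmd=nmd,
    )
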