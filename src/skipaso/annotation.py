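"""Gene/transcript/exon model built from GFF3 + genome FASTA.

Parses a GENCODE-dialect GFF3 (gene -> transcript -> exon/CDS) together with
a genome FASTA into a strand-normalized in-memory model: exons are ordered
5'->3' in transcript orientation, their sequences are given on the
transcript strand (minus-strand features reverse-complemented), and the
flanking intron sequences needed for splice-junction oligo design are
attached to every internal exon.

Coordinates follow standard GFF3 semantics on disk (1-based inclusive) and
are converted to 0-based half-open internally; see
:class:`skipaso.intervals.GenomicInterval`.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

from .constants import MIN_FLANK_INTRON
from .intervals import GenomicInterval

PROTEIN_CODING = "protein_coding"

# coding_status vocabulary
FULLY_CODING = "fully_coding"
CONTAINS_START = "contains_start"
CONTAINS_STOP = "contains_stop"
CONTAINS_START_AND_STOP = "contains_start_and_stop"
NON_CODING = "non_coding"


@dataclass
class Exon:
    """One exon in transcript orientation.

    ``index_in_transcript`` counts 5'->3' starting at 1 and includes
    non-coding exons.  ``sequence`` is the exon on the transcript strand.
    ``upstream_intron`` / ``downstream_intron`` are the full intron
    sequences flanking the exon in transcript orientation (None at the
    transcript ends): the upstream intron ends at this exon's acceptor
    site, the downstream intron starts at its donor site.
    """

    id: str
    interval: GenomicInterval
    index_in_transcript: int
    sequence: str
    coding_status: str = NON_CODING
    upstream_intron: str | None = None
    downstream_intron: str | None = None

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def acceptor_designable(self) -> bool:
        return (self.upstream_intron is not None
                and len(self.upstream_intron) >= MIN_FLANK_INTRON)

    @property
    def donor_designable(self) -> bool:
        return (self.downstream_intron is not None
                and len(self.downstream_intron) >= MIN_FLANK_INTRON)


@dataclass
class Transcript:
    id: str
    gene: str
    exons: list[Exon] = field(default_factory=list)
    biotype: str = ""
    cds_intervals: list[GenomicInterval] = field(default_factory=list)
    strand: str = "+"

    # ---- derived structure -------------------------------------------------
    @property
    def is_coding(self) -> bool:
        return self.biotype == PROTEIN_CODING and bool(self.cds_intervals)

    @property
    def spliced_sequence(self) -> str:
        return "".join(e.sequence for e in self.exons)

    def exon_offsets(self) -> list[int]:
        """Transcript coordinate of the first base of each exon."""
        offsets, pos = [], 0
        for e in self.exons:
            offsets.append(pos)
            pos += len(e)
        return offsets

    def junctions(self) -> list[int]:
        """Transcript coordinates of the exon-exon junctions.

        A junction is the coordinate of the first base of the downstream
        exon in the spliced transcript.
        """
        return self.exon_offsets()[1:]

    def _genomic_to_transcript(self, pos: int) -> int | None:
        """Map a 0-based genomic position to a spliced-transcript coordinate."""
        for e, off in zip(self.exons, self.exon_offsets()):
            iv = e.interval
            if iv.start <= pos < iv.end:
                if self.strand == "+":
                    return off + (pos - iv.start)
                return off + (iv.end - 1 - pos)
        return None

    @property
    def cds_start(self) -> int | None:
        """Transcript coordinate of the first base of the start codon."""
        if not self.cds_intervals:
            return None
        if self.strand == "+":
            g = min(iv.start for iv in self.cds_intervals)
        else:
            g = max(iv.end for iv in self.cds_intervals) - 1
        return self._genomic_to_transcript(g)

    @property
    def cds_end(self) -> int | None:
        """Transcript coordinate one past the last coding base (incl. stop)."""
        if not self.cds_intervals:
            return None
        if self.strand == "+":
            g = max(iv.end for iv in self.cds_intervals) - 1
        else:
            g = min(iv.start for iv in self.cds_intervals)
        t = self._genomic_to_transcript(g)
        return None if t is None else t + 1

    @property
    def cds_sequence(self) -> str:
        if not self.is_coding:
            return ""
        return self.spliced_sequence[self.cds_start:self.cds_end]

    @property
    def cds_length_valid(self) -> bool:
        return self.is_coding and len(self.cds_sequence) % 3 == 0

    def exon_by_id(self, exon_id: str) -> Exon:
        for e in self.exons:
            if e.id == exon_id:
                return e
        raise KeyError(f"exon {exon_id!r} not in transcript {self.id}")


@dataclass
class GeneModel:
    gene: str
    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def coding_transcripts(self) -> list[Transcript]:
        """The 'coding set': protein-coding biotype with a resolved CDS."""
        return [t for t in self.transcripts if t.is_coding]

    def all_exons(self) -> dict[str, list[tuple[Transcript, Exon]]]:
        """Exons grouped by stable exon id across transcripts."""
        out: dict[str, list[tuple[Transcript, Exon]]] = {}
        for t in self.transcripts:
            for e in t.exons:
                out.setdefault(e.id, []).append((t, e))
        return out


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def _read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def _slice(genome: dict[str, str], iv: GenomicInterval) -> str:
    if iv.chrom not in genome:
        raise ValueError(
            f"chromosome {iv.chrom!r} referenced by annotation is missing "
            f"from the FASTA (have: {sorted(genome)})"
        )
    chrom_seq = genome[iv.chrom]
    if iv.end > len(chrom_seq):
        raise ValueError(
            f"feature {iv.chrom}:{iv.start}-{iv.end} extends beyond "
            f"chromosome end ({len(chrom_seq)} nt)"
        )
    s = chrom_seq[iv.start:iv.end]
    return str(Seq(s).reverse_complement()) if iv.strand == "-" else s


def _first_attr(feat, *names: str) -> str | None:
    for n in names:
        if n in feat.attributes:
            return feat.attributes[n][0]
    return None


def _exon_coding_status(exon_iv: GenomicInterval,
                        cds: list[GenomicInterval],
                        strand: str) -> str:
    overlapping = [iv for iv in cds if iv.overlaps(exon_iv)]
    if not overlapping:
        return NON_CODING
    if strand == "+":
        first_base = min(iv.start for iv in cds)
        last_base = max(iv.end for iv in cds) - 1
    else:
        first_base = max(iv.end for iv in cds) - 1
        last_base = min(iv.start for iv in cds)
    has_start = exon_iv.start <= first_base < exon_iv.end
    has_stop = exon_iv.start <= last_base < exon_iv.end
    if has_start and has_stop:
        return CONTAINS_START_AND_STOP
    if has_start:
        return CONTAINS_START
    if has_stop:
        return CONTAINS_STOP
    covered = sum(min(iv.end, exon_iv.end) - max(iv.start, exon_iv.start)
                  for iv in overlapping)
    if covered == len(exon_iv):
        return FULLY_CODING
    # partially coding internal exon: treat as non-fully-coding
    return NON_CODING


def load_gene_models(gff3_path: str | Path,
                     fasta_path: str | Path) -> dict[str, GeneModel]:
    """Parse a GFF3 + genome FASTA into one :class:`GeneModel` per gene."""
    genome = _read_fasta(fasta_path)
    db = gffutils.create_db(str(gff3_path), ":memory:",
                            merge_strategy="create_unique", keep_order=True)
    models: dict[str, GeneModel] = {}
    for gene_feat in db.features_of_type("gene"):
        symbol = _first_attr(gene_feat, "gene_name", "Name") or gene_feat.id
        model = GeneModel(gene=symbol)
        for t_feat in db.children(gene_feat, featuretype=("transcript", "mRNA")):
            biotype = _first_attr(
                t_feat, "transcript_type", "transcript_biotype", "biotype") or ""
            strand = t_feat.strand
            tr = Transcript(id=t_feat.id, gene=symbol, biotype=biotype,
                            strand=strand)
            exon_feats = list(db.children(t_feat, featuretype="exon"))
            exon_feats.sort(key=lambda f: f.start, reverse=(strand == "-"))
            cds_ivs = [
                GenomicInterval.from_gff3(c.seqid, c.start, c.end, strand)
                for c in db.children(t_feat, featuretype=("CDS", "stop_codon"))
            ]
            tr.cds_intervals = cds_ivs
            intron_seqs: list[str | None] = []
            prev_iv: GenomicInterval | None = None
            exons: list[Exon] = []
            for i, f in enumerate(exon_feats, start=1):
                iv = GenomicInterval.from_gff3(f.seqid, f.start, f.end, strand)
                exon_id = _first_attr(f, "exon_id", "ID") or f"{t_feat.id}.exon{i}"
                exons.append(Exon(
                    id=exon_id, interval=iv, index_in_transcript=i,
                    sequence=_slice(genome, iv),
                    coding_status=_exon_coding_status(iv, cds_ivs, strand),
                ))
                if prev_iv is not None:
                    # intron between prev exon and this one, transcript strand
                    if strand == "+":
                        intron = GenomicInterval(iv.chrom, prev_iv.end,
                                                 iv.start, strand)
                    else:
                        intron = GenomicInterval(iv.chrom, iv.end,
                                                 prev_iv.start, strand)
                    intron_seqs.append(_slice(genome, intron))
                prev_iv = iv
            for i, e in enumerate(exons):
                e.upstream_intron = intron_seqs[i - 1] if i > 0 else None
                e.downstream_intron = (intron_seqs[i]
                                       if i < len(intron_seqs) else None)
            tr.exons = exons
            model.transcripts.append(tr)
        models[symbol] = model
    return models


def load_gene_model(gff3_path: str | Path, fasta_path: str | Path,
                    gene_symbol: str | None = None) -> GeneModel:
    """Load the model for one gene (the only gene, or ``gene_symbol``)."""
    models = load_gene_models(gff3_path, fasta_path)
    if gene_symbol is not None:
        if gene_symbol not in models:
            raise KeyError(
                f"gene {gene_symbol!r} not found (have: {sorted(models)})")
        return models[gene_symbol]
    if len(models) != 1:
        raise ValueError(
            f"annotation contains {len(models)} genes; pass gene_symbol "
            f"(one of {sorted(models)})")
    return next(iter(models.values()))


# ---------------------------------------------------------------------------
# skippable-exon selection
# ---------------------------------------------------------------------------

def select_skippable_exons(transcript: Transcript) -> list[Exon]:
    """Exons eligible for skipping in one protein-coding transcript.

    Eligible exons are fully coding and lie strictly between the exon
    carrying the start codon and the exon carrying the stop codon; exons
    containing either codon, and non-coding exons, are excluded so that
    translation initiation and termination stay untouched.
    """
    if not transcript.is_coding:
        raise ValueError(f"transcript {transcript.id} is not protein-coding")
    return [e for e in transcript.exons if e.coding_status == FULLY_CODING]


def skippable_exons_by_id(model: GeneModel) -> dict[str, dict]:
    """Gene-level skippable-exon report, one entry per stable exon id.

    An exon shared by several transcripts appears once, with the list of
    coding transcripts in which it is skippable.
    """
    report: dict[str, dict] = {}
    for tr in model.coding_transcripts:
        for e in select_skippable_exons(tr):
            entry = report.setdefault(e.id, {
                "exon_id": e.id, "gene": model.gene,
                "length": len(e), "transcripts": [],
            })
            entry["transcripts"].append(tr.id)
    return report


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def write_gff3(models: dict[str, GeneModel] | GeneModel,
               path: str | Path) -> None:
    """Serialize model(s) back to GENCODE-style GFF3 (round-trippable)."""
    if isinstance(models, GeneModel):
        models = {models.gene: models}
    lines = ["##gff-version 3"]
    for model in models.values():
        for tr in model.transcripts:
            ivs = [e.interval for e in tr.exons]
            chrom = ivs[0].chrom
            strand = tr.strand
            g_start = min(iv.start for iv in ivs) + 1
            g_end = max(iv.end for iv in ivs)
            gene_id = f"gene:{model.gene}"
            lines.append("\t".join([
                chrom, "skipaso", "gene", str(g_start), str(g_end), ".",
                strand, ".", f"ID={gene_id};gene_name={model.gene}"]))
            lines.append("\t".join([
                chrom, "skipaso", "transcript", str(g_start), str(g_end), ".",
                strand, ".",
                f"ID={tr.id};Parent={gene_id};gene_name={model.gene};"
                f"transcript_type={tr.biotype}"]))
            for e in tr.exons:
                s1, e1 = e.interval.to_gff3()
                lines.append("\t".join([
                    chrom, "skipaso", "exon", str(s1), str(e1), ".",
                    strand, ".",
                    f"ID=exonfeat:{tr.id}:{e.index_in_transcript};"
                    f"Parent={tr.id};exon_id={e.id};"
                    f"exon_number={e.index_in_transcript}"]))
            for j, iv in enumerate(sorted(tr.cds_intervals), start=1):
                s1, e1 = iv.to_gff3()
                lines.append("\t".join([
                    chrom, "skipaso", "CDS", str(s1), str(e1), ".",
                    strand, "0", f"ID=CDS:{tr.id}:{j};Parent={tr.id}"]))
    Path(path).write_text("\n".join(lines) + "\n")


def model_to_json(model: GeneModel) -> str:
    def exon_dict(e: Exon) -> dict:
        s1, e1 = e.interval.to_gff3()
        return {"id": e.id, "chrom": e.interval.chrom, "start": s1,
                "end": e1, "strand": e.interval.strand,
                "index": e.index_in_transcript,
                "coding_status": e.coding_status, "length": len(e)}

    return json.dumps({
        "gene": model.gene,
        "transcripts": [
            {"id": t.id, "biotype": t.biotype, "strand": t.strand,
             "coding": t.is_coding,
             "exons": [exon_dict(e) for e in t.exons]}
            for t in model.transcripts
        ],
    }, indent=2)
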