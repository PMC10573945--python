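"""Cancer mutation profiles: COSMIC-style parsing, 20/20 classification,
per-exon patient burden.

The 20/20 rule classifies a gene from the pattern of its annotated somatic
mutations: genes dominated by recurrent gain-of-function changes (missense
substitutions and in-frame indels) behave as oncogenes, genes dominated by
inactivating changes (nonsense substitutions and frameshift indels) as
tumor suppressors.  The oncogene (ONG) score is the percentage of
gain-of-function mutations among all annotated mutations, the tumor
suppressor (TSG) score the percentage of loss-of-function mutations:

    ONG > 20 and TSG <= 5   ->  oncogene
    ONG > 20 and TSG > 5    ->  tumor suppressor
    ONG < 20 and TSG > 20   ->  tumor suppressor
    ONG < 20 and TSG < 20   ->  unclassified

The inequalities are strict; a score landing exactly on a boundary matches
no row and the gene is left unclassified rather than silently assigned.
"""
from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass

import pandas as pd

from .annotation import GeneModel
from .constants import (ONG_SCORE_CUTOFF, TOP_GENE_FRACTION, TOP_K_EXONS,
                        TSG_ONCOGENE_MAX, TSG_SCORE_CUTOFF)
from .intervals import GenomicInterval

log = logging.getLogger(__name__)

ONCOGENE = "oncogene"
TUMOR_SUPPRESSOR = "tumor_suppressor"
UNCLASSIFIED = "unclassified"

# canonical mutation-class vocabulary
SUB_MISSENSE = "substitution_missense"
SUB_NONSENSE = "substitution_nonsense"
SUB_SYNONYMOUS = "substitution_synonymous"
DEL_INFRAME = "deletion_in_frame"
INS_INFRAME = "insertion_in_frame"
COMPLEX_DEL_INFRAME = "complex_deletion_in_frame"
DEL_FRAMESHIFT = "deletion_frameshift"
INS_FRAMESHIFT = "insertion_frameshift"
OTHER = "other"

GAIN_OF_FUNCTION = {SUB_MISSENSE, DEL_INFRAME, INS_INFRAME, COMPLEX_DEL_INFRAME}
LOSS_OF_FUNCTION = {SUB_NONSENSE, DEL_FRAMESHIFT, INS_FRAMESHIFT}
POINT_MUTATION_CLASSES = {SUB_MISSENSE, SUB_NONSENSE, SUB_SYNONYMOUS}

# COSMIC "Mutation Description" vocabulary -> canonical classes
_CLASS_MAP = {
    "substitution - missense": SUB_MISSENSE,
    "substitution - nonsense": SUB_NONSENSE,
    "substitution - coding silent": SUB_SYNONYMOUS,
    "substitution - synonymous": SUB_SYNONYMOUS,
    "deletion - in frame": DEL_INFRAME,
    "insertion - in frame": INS_INFRAME,
    "complex - deletion inframe": COMPLEX_DEL_INFRAME,
    "complex - deletion in frame": COMPLEX_DEL_INFRAME,
    "deletion - frameshift": DEL_FRAMESHIFT,
    "insertion - frameshift": INS_FRAMESHIFT,
}

DEFAULT_COLUMNS = {
    "gene": "Gene name",
    "sample": "ID_sample",
    "description": "Mutation Description",
    "position": "Mutation genome position",
}

_POS_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


def normalize_mutation_class(description: str) -> str:
    """Map a source vocabulary string to the canonical enumeration."""
    return _CLASS_MAP.get(description.strip().lower(), OTHER)


@dataclass(frozen=True)
class MutationRecord:
    gene: str
    sample_id: str
    mutation_class: str
    genomic_interval: GenomicInterval | None
    raw_description: str = ""


@dataclass(frozen=True)
class ClassificationScores:
    total_mutations: int
    x: int  # gain-of-function count
    y: int  # loss-of-function count
    ong_score: float  # percent
    tsg_score: float  # percent
    label: str


@dataclass(frozen=True)
class ExonMutationSummary:
    exon_id: str
    absolute_freq: int
    relative_freq: float
    rank: int = 0


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def parse_mutation_table(tsv_path, columns: dict[str, str] | None = None
                         ) -> list[MutationRecord]:
    """Read a COSMIC-style tab-separated mutation export.

    ``columns`` maps the logical names gene/sample/description/position to
    the file's header names (defaults follow the COSMIC export).  Rows
    whose genome position cannot be parsed are skipped with a warning.
    """
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(tsv_path, sep="\t", dtype=str, keep_default_na=False)
    missing = [v for v in cols.values() if v not in df.columns]
    if missing:
        raise ValueError(
            f"mutation table is missing required column(s) {missing}; "
            f"expected columns {sorted(cols.values())}, "
            f"found {list(df.columns)}")
    records: list[MutationRecord] = []
    n_skipped = 0
    for row in df.itertuples(index=False):
        row = dict(zip(df.columns, row))
        pos = row[cols["position"]].strip()
        interval = None
        if pos:
            m = _POS_RE.match(pos)
            if m is None:
                n_skipped += 1
                log.warning("unparseable genome position %r; row skipped", pos)
                continue
            start1, end1 = int(m["start"]), int(m["end"])
            if end1 < start1:
                n_skipped += 1
                log.warning("inverted genome position %r; row skipped", pos)
                continue
            interval = GenomicInterval.from_gff3(m["chrom"], start1, end1)
        desc = row[cols["description"]]
        records.append(MutationRecord(
            gene=row[cols["gene"]],
            sample_id=row[cols["sample"]],
            mutation_class=normalize_mutation_class(desc),
            genomic_interval=interval,
            raw_description=desc,
        ))
    if n_skipped:
        log.warning("%d rows skipped for unparseable coordinates", n_skipped)
    return records


# ---------------------------------------------------------------------------
# 20/20 classification
# ---------------------------------------------------------------------------

def classify_gene(records: list[MutationRecord],
                  recurrence_threshold: int | None = None
                  ) -> ClassificationScores:
    """Apply the 20/20 decision grid to one gene's mutation records.

    ``recurrence_threshold``, if given, counts a missense substitution
    toward the gain-of-function tally only when its genomic position is
    hit in at least that many distinct samples (recurrent-hotspot
    variant of the rule); by default every missense counts.
    """
    if not records:
        raise ValueError("no mutation annotations for gene")
    total = len(records)

    recurrent_ok = None
    if recurrence_threshold is not None:
        by_pos: dict[tuple, set[str]] = {}
        for r in records:
            if r.mutation_class == SUB_MISSENSE and r.genomic_interval:
                key = (r.genomic_interval.chrom, r.genomic_interval.start)
                by_pos.setdefault(key, set()).add(r.sample_id)
        recurrent_ok = {pos for pos, samples in by_pos.items()
                        if len(samples) >= recurrence_threshold}

    x = y = 0
    for r in records:
        if r.mutation_class in GAIN_OF_FUNCTION:
            if (recurrent_ok is not None
                    and r.mutation_class == SUB_MISSENSE):
                key = (r.genomic_interval.chrom, r.genomic_interval.start) \
                    if r.genomic_interval else None
                if key not in recurrent_ok:
                    continue
            x += 1
        elif r.mutation_class in LOSS_OF_FUNCTION:
            y += 1
    ong = 100.0 * x / total
    tsg = 100.0 * y / total

    if ong > ONG_SCORE_CUTOFF and tsg <= TSG_ONCOGENE_MAX:
        label = ONCOGENE
    elif ong > ONG_SCORE_CUTOFF and tsg > TSG_ONCOGENE_MAX:
        label = TUMOR_SUPPRESSOR
    elif ong < ONG_SCORE_CUTOFF and tsg > TSG_SCORE_CUTOFF:
        label = TUMOR_SUPPRESSOR
    elif ong < ONG_SCORE_CUTOFF and tsg < TSG_SCORE_CUTOFF:
        label = UNCLASSIFIED
    else:
        # boundary scores (ONG exactly 20, or TSG exactly 20 with ONG < 20)
        # match no grid row; never silently pick a label
        label = UNCLASSIFIED
    return ClassificationScores(total_mutations=total, x=x, y=y,
                                ong_score=ong, tsg_score=tsg, label=label)


# ---------------------------------------------------------------------------
# per-exon patient burden
# ---------------------------------------------------------------------------

def count_patients_per_exon(records: list[MutationRecord],
                            gene_model: GeneModel) -> list[ExonMutationSummary]:
    """Patients with >=1 point mutation per exon, by stable exon id.

    Only point mutations (substitution classes) are considered.  A sample
    contributes at most once to an exon however many mutations it carries
    there; the relative frequency divides by the number of distinct
    samples with at least one point mutation anywhere in the gene's exons.
    """
    point = [r for r in records
             if r.mutation_class in POINT_MUTATION_CLASSES
             and r.genomic_interval is not None]
    exon_samples: dict[str, set[str]] = {}
    gene_samples: set[str] = set()
    exon_ivs: dict[str, GenomicInterval] = {}
    for tr in gene_model.transcripts:
        for e in tr.exons:
            exon_ivs.setdefault(e.id, e.interval)
    for exon_id in exon_ivs:
        exon_samples[exon_id] = set()
    for r in point:
        iv = r.genomic_interval
        for exon_id, e_iv in exon_ivs.items():
            # strand-agnostic overlap: mutation coordinates are unstranded
            if (e_iv.chrom == iv.chrom and e_iv.start < iv.end
                    and iv.start < e_iv.end):
                exon_samples[exon_id].add(r.sample_id)
                gene_samples.add(r.sample_id)
    denom = len(gene_samples)
    summaries = [
        ExonMutationSummary(
            exon_id=exon_id,
            absolute_freq=len(samples),
            relative_freq=(len(samples) / denom) if denom else 0.0,
        )
        for exon_id, samples in exon_samples.items()
    ]
    return rank_exons_by_mutation(summaries, k=len(summaries))


def rank_exons_by_mutation(summaries: list[ExonMutationSummary],
                           k: int = TOP_K_EXONS) -> list[ExonMutationSummary]:
    """Top-k exons by absolute patient count.

    Ties break by relative frequency (descending) and then exon id
    (lexicographic ascending) so the ordering is total and reproducible.
    """
    ordered = sorted(summaries,
                     key=lambda s: (-s.absolute_freq, -s.relative_freq,
                                    s.exon_id))
    return [ExonMutationSummary(s.exon_id, s.absolute_freq, s.relative_freq,
                                rank=i + 1)
            for i, s in enumerate(ordered[:k])]


def select_top_fraction_genes(records: list[MutationRecord],
                              fraction: float = TOP_GENE_FRACTION
                              ) -> list[str]:
    """Most frequently mutated genes by distinct-patient count.

    Returns the ceil(fraction * n_genes) genes with the most distinct
    samples; genes tied with the last included count are all included.
    """
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    samples_by_gene: dict[str, set[str]] = {}
    for r in records:
        samples_by_gene.setdefault(r.gene, set()).add(r.sample_id)
    if not samples_by_gene:
        return []
    counts = sorted(((len(s), g) for g, s in samples_by_gene.items()),
                    key=lambda t: (-t[0], t[1]))
    n_keep = math.ceil(fraction * len(counts))
    threshold = counts[n_keep - 1][0]
    return [g for c, g in counts if c >= threshold]


def classification_table(records_by_gene: dict[str, list[MutationRecord]]
                         ) -> pd.DataFrame:
    """Per-gene 20/20 classification as a tidy table."""
    rows = []
    for gene, recs in sorted(records_by_gene.items()):
        s = classify_gene(recs)
        rows.append({"gene": gene, "total_mutations": s.total_mutations,
                     "gof": s.x, "lof": s.y,
                     "ong_score": round(s.ong_score, 2),
                     "tsg_score": round(s.tsg_score, 2), "label": s.label})
    return pd.DataFrame(rows)


def group_by_gene(records: list[MutationRecord]
                  ) -> dict[str, list[MutationRecord]]:
    out: dict[str, list[MutationRecord]] = {}
    for r in records:
        out.setdefault(r.gene, []).append(r)
    return out
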