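"""Exon suitability criteria and gene-level ranking.

An exon is a suitable exon-skipping target when it
(a) ranks among the gene's ten most frequently mutated exons,
(b) yields the therapeutically desired reading frame when skipped --
    out-of-frame for an oncogene (inactivation), in-frame for a tumor
    suppressor (partial functional rescue) -- and
(c) has at least one filter-passing ASO from each design strategy
    (splice-junction and exonic/ESE).

Genes are then ranked by the decreasing percentage of their candidate
exons that meet all three criteria.  Predicted NMD degradation is
reported alongside oncogene targets but is not itself a criterion.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

from .mutations import ONCOGENE, TUMOR_SUPPRESSOR, UNCLASSIFIED
from .skipping import IN_FRAME, OUT_FRAME, SkippingOutcome

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExonAssessment:
    exon_id: str
    in_top10_mutated: bool
    frame_matches_goal: bool
    has_aso_both_strategies: bool
    qualifies: bool
    nmd_predicted: bool = False
    frame: str = ""


@dataclass(frozen=True)
class GeneRanking:
    gene: str
    label: str
    n_candidate_exons: int
    n_qualifying: int
    percent_qualifying: float
    rank: int = 0


def desired_frame(gene_label: str) -> str:
    """OUT for oncogenes (degrade), IN for tumor suppressors (rescue)."""
    if gene_label == ONCOGENE:
        return OUT_FRAME
    if gene_label == TUMOR_SUPPRESSOR:
        return IN_FRAME
    raise ValueError(
        "classification required: gene must be labeled oncogene or "
        f"tumor_suppressor, got {gene_label!r}")


def assess_exon(exon_id: str,
                gene_label: str,
                skipping_outcome: SkippingOutcome,
                n_junction_pass: int,
                n_exonic_pass: int,
                top10_ids: set[str]) -> ExonAssessment:
    """Evaluate one exon against the three suitability criteria."""
    goal = desired_frame(gene_label)
    frame_ok = skipping_outcome.frame == goal
    both = n_junction_pass >= 1 and n_exonic_pass >= 1
    in_top = exon_id in top10_ids
    nmd = bool(skipping_outcome.nmd and skipping_outcome.nmd.degraded)
    return ExonAssessment(
        exon_id=exon_id,
        in_top10_mutated=in_top,
        frame_matches_goal=frame_ok,
        has_aso_both_strategies=both,
        qualifies=in_top and frame_ok and both,
        nmd_predicted=nmd,
        frame=skipping_outcome.frame,
    )


def rank_genes(assessments_by_gene: dict[str, tuple[str, list[ExonAssessment]]],
               denominator: str = "candidate") -> list[GeneRanking]:
    """Rank genes by the percentage of exons meeting all three criteria.

    ``assessments_by_gene`` maps gene -> (label, exon assessments).
    ``denominator`` chooses the exon universe of the percentage:
    ``"candidate"`` (default) counts only skippable exons that are also in
    the gene's top-10 mutated list; ``"all"`` counts every assessed
    skippable exon.  Unclassified genes and genes without candidate exons
    are excluded with a warning.  Ties break by the absolute number of
    qualifying exons, then by gene symbol, so the order is total.
    """
    if denominator not in ("candidate", "all"):
        raise ValueError(f"unknown denominator {denominator!r}")
    rankings: list[GeneRanking] = []
    for gene, (label, assessments) in assessments_by_gene.items():
        if label == UNCLASSIFIED:
            log.warning("gene %s is unclassified; excluded from ranking",
                        gene)
            continue
        if denominator == "candidate":
            universe = [a for a in assessments if a.in_top10_mutated]
        else:
            universe = list(assessments)
        if not universe:
            log.warning("gene %s has no candidate exons; excluded from "
                        "ranking", gene)
            continue
        n_q = sum(a.qualifies for a in universe)
        rankings.append(GeneRanking(
            gene=gene, label=label,
            n_candidate_exons=len(universe), n_qualifying=n_q,
            percent_qualifying=100.0 * n_q / len(universe)))
    rankings.sort(key=lambda r: (-r.percent_qualifying, -r.n_qualifying,
                                 r.gene))
    return [GeneRanking(r.gene, r.label, r.n_candidate_exons,
                        r.n_qualifying, r.percent_qualifying, rank=i + 1)
            for i, r in enumerate(rankings)]
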