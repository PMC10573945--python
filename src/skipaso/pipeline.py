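"""End-to-end orchestration: classify -> select exons -> simulate skips ->
rank mutated exons -> design ASOs -> evaluate -> prioritize.

Each stage writes one TSV into the output directory and the run ends with
a machine-readable JSON summary; outputs are pure functions of the inputs
and configuration, so re-running a stage from its persisted inputs
reproduces the files byte for byte.  A stage failure aborts the run with
the stage name; the outputs written so far are retained and a MANIFEST
records the incompleteness.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import annotation, design, evaluation, mutations, prioritize, skipping
from .constants import TOP_K_EXONS

log = logging.getLogger(__name__)

STAGE_FILES = {
    "classification": "classification.tsv",
    "skippable_exons": "skippable_exons.tsv",
    "skipping_outcomes": "skipping_outcomes.tsv",
    "exon_mutation_ranking": "exon_mutation_ranking.tsv",
    "aso_candidates": "aso_candidates.tsv",
    "aso_evaluation": "aso_evaluation.tsv",
    "exon_assessments": "exon_assessments.tsv",
    "gene_ranking": "gene_ranking.tsv",
}


@dataclass
class RunConfig:
    gff3: str
    fasta: str
    mutations: str
    ese: str
    out_dir: str
    genome: str | None = None   # specificity skipped when absent
    gene: str | None = None     # restrict to one gene symbol
    top_k_exons: int = TOP_K_EXONS
    thresholds: evaluation.FilterThresholds = field(
        default_factory=evaluation.FilterThresholds)
    ranking_denominator: str = "candidate"
    seed: int = 0
    column_map: dict[str, str] | None = None

    def validate(self) -> None:
        for name in ("gff3", "fasta", "mutations", "ese"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} input not found: {p}")
        if self.genome is not None and not Path(self.genome).exists():
            raise FileNotFoundError(f"genome input not found: {self.genome}")
        if self.top_k_exons < 1:
            raise ValueError("top_k_exons must be >= 1")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _write_tsv(df: pd.DataFrame, out_dir: Path, stage: str) -> None:
    df.to_csv(out_dir / STAGE_FILES[stage], sep="\t", index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full procedure; returns the JSON-serializable summary."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    completed: list[str] = []
    stage = "setup"
    summary: dict = {"genes": {}, "config": {
        k: v for k, v in dataclasses.asdict(config).items()
        if k != "thresholds"}}
    try:
        stage = "classification"
        records = mutations.parse_mutation_table(
            config.mutations, columns=config.column_map)
        by_gene = mutations.group_by_gene(records)
        if config.gene is not None:
            by_gene = {g: r for g, r in by_gene.items() if g == config.gene}
        cls_df = mutations.classification_table(by_gene)
        labels = dict(zip(cls_df.gene, cls_df.label)) if len(cls_df) else {}
        _write_tsv(cls_df, out_dir, stage)
        completed.append(stage)

        stage = "skippable_exons"
        models = annotation.load_gene_models(config.gff3, config.fasta)
        if config.gene is not None:
            models = {g: m for g, m in models.items() if g == config.gene}
        skippable_rows = []
        skippable_by_gene: dict[str, dict[str, dict]] = {}
        for gene in sorted(models):
            rep = annotation.skippable_exons_by_id(models[gene])
            skippable_by_gene[gene] = rep
            for exon_id in sorted(rep):
                e = rep[exon_id]
                skippable_rows.append({
                    "gene": gene, "exon_id": exon_id, "length": e["length"],
                    "transcripts": ",".join(e["transcripts"])})
        _write_tsv(pd.DataFrame(skippable_rows,
                                columns=["gene", "exon_id", "length",
                                         "transcripts"]),
                   out_dir, stage)
        completed.append(stage)

        stage = "skipping_outcomes"
        outcomes: dict[tuple[str, str], skipping.SkippingOutcome] = {}
        skip_rows = []
        for gene in sorted(models):
            model = models[gene]
            for tr in model.coding_transcripts:
                for exon in annotation.select_skippable_exons(tr):
                    key = (gene, exon.id)
                    if key in outcomes:
                        continue
                    out = skipping.simulate_skip(tr, exon)
                    outcomes[key] = out
                    nmd = out.nmd
                    skip_rows.append({
                        "gene": gene, "transcript": tr.id,
                        "exon_id": exon.id, "exon_index": out.exon_index,
                        "frame": out.frame,
                        "protein_length": out.protein_length,
                        "ptc_position": ("" if out.ptc_position is None
                                         else out.ptc_position),
                        "nonstop": out.nonstop,
                        "nmd_degraded": ("" if nmd is None or
                                         nmd.degraded is None
                                         else nmd.degraded),
                        "nmd_rules": ("" if nmd is None else
                                      ",".join(sorted(
                                          nmd.evasion_rules_fired))),
                    })
        _write_tsv(pd.DataFrame(skip_rows), out_dir, stage)
        completed.append(stage)

        stage = "exon_mutation_ranking"
        top_ids: dict[str, set[str]] = {}
        rank_rows = []
        for gene in sorted(models):
            recs = by_gene.get(gene, [])
            summaries = mutations.count_patients_per_exon(recs, models[gene])
            top = mutations.rank_exons_by_mutation(summaries,
                                                   k=config.top_k_exons)
            top_ids[gene] = {s.exon_id for s in top}
            for s in top:
                rank_rows.append({
                    "gene": gene, "exon_id": s.exon_id, "rank": s.rank,
                    "absolute_freq": s.absolute_freq,
                    "relative_freq": round(s.relative_freq, 4)})
        _write_tsv(pd.DataFrame(rank_rows), out_dir, stage)
        completed.append(stage)

        stage = "aso_candidates"
        motifs = design.read_ese_table(config.ese)
        cand_rows = []
        candidates: dict[tuple[str, str], list[design.AsoCandidate]] = {}
        for gene in sorted(models):
            model = models[gene]
            chosen = sorted(set(skippable_by_gene[gene])
                            & top_ids.get(gene, set()))
            for exon_id in chosen:
                tr_id = skippable_by_gene[gene][exon_id]["transcripts"][0]
                tr = next(t for t in model.coding_transcripts
                          if t.id == tr_id)
                exon = tr.exon_by_id(exon_id)
                sites = design.annotate_ese_sites(exon.sequence, motifs)
                cands = (design.design_junction_asos(exon)
                         + design.design_exonic_asos(exon, sites))
                candidates[(gene, exon_id)] = cands
                for c in cands:
                    cand_rows.append({
                        "gene": gene, "exon_id": exon_id, "name": c.name,
                        "site": c.window.site,
                        "target_sequence": c.target_sequence,
                        "aso_sequence": c.aso_sequence,
                        "n_covered_ese": len(c.covered_ese_sites)})
        _write_tsv(pd.DataFrame(cand_rows), out_dir, stage)
        completed.append(stage)

        stage = "aso_evaluation"
        genome = (evaluation._load_genome(config.genome)
                  if config.genome else None)
        eval_rows = []
        pass_counts: dict[tuple[str, str], dict[str, int]] = {}
        for (gene, exon_id), cands in sorted(candidates.items()):
            counts = {"junction": 0, "exonic": 0}
            for c in cands:
                rep = evaluation.apply_filters(
                    c.aso_sequence, thresholds=config.thresholds,
                    genome=genome)
                kind = ("exonic" if c.window.site == design.EXONIC
                        else "junction")
                if rep.passed:
                    counts[kind] += 1
                prof = rep.profile
                eval_rows.append({
                    "gene": gene, "exon_id": exon_id, "name": c.name,
                    "site": c.window.site,
                    "aso_sequence": c.aso_sequence,
                    "gc_percent": round(prof.gc_percent, 1),
                    "g_percent": round(prof.g_percent, 1),
                    "max_g_run": prof.max_g_run,
                    "max_self_comp": prof.max_self_comp_pairs,
                    "tm_basic": round(prof.tm_basic, 2),
                    "tm_salt": round(prof.tm_salt, 2),
                    "tm_nn": round(prof.tm_nn, 2),
                    "genome_matches": ("not evaluated"
                                       if rep.specificity is None
                                       else rep.specificity.match_count),
                    "passed": rep.passed,
                    "failed_criteria": ",".join(rep.failed_criteria)})
            pass_counts[(gene, exon_id)] = counts
        _write_tsv(pd.DataFrame(eval_rows), out_dir, stage)
        completed.append(stage)

        stage = "exon_assessments"
        assess_rows = []
        by_gene_assessments: dict[str, tuple[str, list]] = {}
        for gene in sorted(models):
            label = labels.get(gene, mutations.UNCLASSIFIED)
            assessments = []
            for exon_id in sorted(skippable_by_gene[gene]):
                key = (gene, exon_id)
                outcome = outcomes.get(key)
                if outcome is None:
                    continue
                counts = pass_counts.get(key, {"junction": 0, "exonic": 0})
                if label == mutations.UNCLASSIFIED:
                    assess_rows.append({
                        "gene": gene, "exon_id": exon_id,
                        "frame": outcome.frame,
                        "aso_j_pass": counts["junction"],
                        "aso_e_pass": counts["exonic"],
                        "in_top10": exon_id in top_ids.get(gene, set()),
                        "frame_matches_goal": "",
                        "nmd_predicted": "", "qualifies": ""})
                    continue
                a = prioritize.assess_exon(
                    exon_id, label, outcome,
                    n_junction_pass=counts["junction"],
                    n_exonic_pass=counts["exonic"],
                    top10_ids=top_ids.get(gene, set()))
                assessments.append(a)
                assess_rows.append({
                    "gene": gene, "exon_id": exon_id, "frame": a.frame,
                    "aso_j_pass": counts["junction"],
                    "aso_e_pass": counts["exonic"],
                    "in_top10": a.in_top10_mutated,
                    "frame_matches_goal": a.frame_matches_goal,
                    "nmd_predicted": a.nmd_predicted,
                    "qualifies": a.qualifies})
            if assessments:
                by_gene_assessments[gene] = (label, assessments)
        _write_tsv(pd.DataFrame(assess_rows), out_dir, stage)
        completed.append(stage)

        stage = "gene_ranking"
        rankings = prioritize.rank_genes(
            by_gene_assessments, denominator=config.ranking_denominator)
        _write_tsv(pd.DataFrame(
            [{"rank": r.rank, "gene": r.gene, "label": r.label,
              "n_candidate_exons": r.n_candidate_exons,
              "n_qualifying": r.n_qualifying,
              "percent_qualifying": round(r.percent_qualifying, 1)}
             for r in rankings],
            columns=["rank", "gene", "label", "n_candidate_exons",
                     "n_qualifying", "percent_qualifying"]),
            out_dir, stage)
        completed.append(stage)

        for gene in sorted(models):
            summary["genes"][gene] = {
                "label": labels.get(gene, mutations.UNCLASSIFIED),
                "n_skippable_exons": len(skippable_by_gene[gene]),
                "candidate_exons": {
                    exon_id: {
                        "frame": outcomes[(gene, exon_id)].frame,
                        "nmd_degraded": (
                            outcomes[(gene, exon_id)].nmd.degraded
                            if outcomes[(gene, exon_id)].nmd else None),
                        "aso_junction_pass": pass_counts.get(
                            (gene, exon_id), {}).get("junction", 0),
                        "aso_exonic_pass": pass_counts.get(
                            (gene, exon_id), {}).get("exonic", 0),
                    }
                    for exon_id in sorted(set(skippable_by_gene[gene])
                                          & top_ids.get(gene, set()))
                },
            }
        summary["ranking"] = [
            {"rank": r.rank, "gene": r.gene, "label": r.label,
             "percent_qualifying": round(r.percent_qualifying, 1)}
            for r in rankings]
        summary["specificity_evaluated"] = config.genome is not None
        (out_dir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n")
        (out_dir / "MANIFEST.json").write_text(json.dumps(
            {"complete": True, "stages": completed}, indent=2) + "\n")
        return summary
    except Exception as exc:
        (out_dir / "MANIFEST.json").write_text(json.dumps(
            {"complete": False, "failed_stage": stage,
             "error": str(exc), "stages": completed}, indent=2) + "\n")
        raise PipelineError(stage, exc) from exc
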