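"""End-to-end pipeline: enriched genes -> enriched peaks -> promoter and
distal motif enrichment -> TFRS design matrices -> scheme selection ->
predicted targets.

Stages communicate only via on-disk standard-format files, so any stage's
input can be swapped for output of the original external tools (e.g. a
count-based differential test or another motif scanner).  Every filter
logs its input/output counts and the run manifest records the config hash,
seed and stage list.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from . import __version__
from . import motifs as mo
from .expression import ExpressionTable, select_enriched_genes
from .genomics import (
    GeneModel,
    PeakSet,
    annotate_peaks,
    call_enriched_peaks,
    distal_window,
    read_bed,
    read_gene_annotation,
    write_bed,
)
from .model import select_scheme, predicted_targets
from .tfrs import DistalHit, PromoterHit, build_design_matrix

log = logging.getLogger(__name__)

STAGES = (
    "select_enriched_genes",
    "call_enriched_peaks",
    "annotate_peaks",
    "promoter_motif_enrichment",
    "distal_motif_enrichment",
    "candidate_tfs",
    "scheme_selection",
    "predicted_targets",
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Paths plus every threshold of the analysis (defaults as printed
    in the standard protocol: FC > 4, q < 0.001, FPKM > 1, peak q < 0.05,
    promoter +/- 3 kb, distal <= 1 Mb, promoter motif p < 1e-4, distal
    motif p < 1e-2, lambda in [0, 2] and alpha in [0, 1] with 0.1 steps,
    2-fold CV)."""

    genome_fasta: str = ""
    annotation_tsv: str = ""
    expression_tsv: str = ""
    pwms_jaspar: str = ""
    target_bed: str = ""
    reference_beds: list[str] = field(default_factory=list)
    target_cell_type: str = "target"
    reference_cell_types: list[str] = field(default_factory=list)

    fc_min: float = 4.0
    q_max: float = 0.001
    fpkm_min: float = 1.0
    dhs_q: float = 0.05
    promoter_bp: int = 3000
    distal_max_bp: int = 1_000_000
    promoter_motif_p: float = 1e-4
    distal_motif_p: float = 1e-2
    chunk_len: int = 200
    lambda_grid: list[float] = field(
        default_factory=lambda: [round(0.1 * i, 10) for i in range(21)]
    )
    alpha_grid: list[float] = field(
        default_factory=lambda: [round(0.1 * i, 10) for i in range(11)]
    )
    cv_folds: int = 2
    glmnet_compat: bool = False
    seed: int = 0

    def validate(self) -> None:
        for name in ("fc_min", "q_max", "fpkm_min", "dhs_q", "promoter_bp",
                     "distal_max_bp", "promoter_motif_p", "distal_motif_p",
                     "chunk_len", "cv_folds"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")


def validate_inputs(config: PipelineConfig) -> list[str]:
    """Pre-flight format and consistency report; returns issue strings."""
    issues: list[str] = []
    for path in [config.genome_fasta, config.annotation_tsv,
                 config.expression_tsv, config.pwms_jaspar,
                 config.target_bed, *config.reference_beds]:
        if path and not Path(path).exists():
            issues.append(f"missing input file: {path}")
    if issues:
        return issues
    genes = read_gene_annotation(config.annotation_tsv)
    expr = ExpressionTable.read_tsv(config.expression_tsv)
    expr_ids = set(expr.genes)
    for g in genes:
        if g.gene_id not in expr_ids:
            issues.append(f"gene {g.gene_id} absent from expression table")
    fasta = Fasta(config.genome_fasta)
    chroms = set(fasta.keys())
    for g in genes:
        if g.chrom not in chroms:
            issues.append(f"gene {g.gene_id}: chromosome {g.chrom} not in genome")
        elif g.tss >= len(fasta[g.chrom]):
            issues.append(f"gene {g.gene_id}: TSS {g.tss} beyond chromosome end")
    for bed in [config.target_bed, *config.reference_beds]:
        with open(bed) as fh:
            for lineno, line in enumerate(fh, start=1):
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 8:
                    issues.append(f"{bed}:{lineno}: expected 8 columns")
                    continue
                try:
                    start, end = int(fields[1]), int(fields[2])
                except ValueError:
                    issues.append(f"{bed}:{lineno}: non-integer coordinates")
                    continue
                if end <= start:
                    issues.append(f"{bed}:{lineno}: end <= start")
    return issues


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def _region_seq(fasta: Fasta, chrom: str, start: int, end: int) -> str:
    return str(fasta[chrom][max(start, 0): end]).upper()


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute the full analysis and write every intermediate to outdir.

    Returns a summary dict (also written as ``manifest.json``).
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"stages": [], "counts": {}}

    genes = read_gene_annotation(config.annotation_tsv)
    gene_by_id = {g.gene_id: g for g in genes}
    expr = ExpressionTable.read_tsv(config.expression_tsv)
    pwms = mo.read_jaspar(config.pwms_jaspar)
    fasta = Fasta(config.genome_fasta)
    target_expr = expr.slice(config.target_cell_type)
    ref_cts = config.reference_cell_types or [
        ct for ct in expr.cell_types if ct != config.target_cell_type
    ]

    # 1. cell-type-enriched genes -------------------------------------------
    @_stage("select_enriched_genes")
    def stage1():
        calls = select_enriched_genes(
            target_expr, [expr.slice(ct) for ct in ref_cts],
            fc_min=config.fc_min, q_max=config.q_max, fpkm_min=config.fpkm_min,
        )
        survivors = [c.gene_id for c in calls if c.passed]
        pd.DataFrame(
            [
                {"gene_id": c.gene_id, "passed": c.passed,
                 "min_log2_fc": float(np.min(c.log2_fc_per_reference)),
                 "q_value": c.q_value if c.q_value is not None else ""}
                for c in calls
            ]
        ).to_csv(outdir / "enriched_genes.tsv", sep="\t", index=False,
                 float_format="%.6g")
        return survivors

    enriched_genes = stage1()
    summary["stages"].append("select_enriched_genes")
    summary["counts"]["genes_total"] = len(expr.genes)
    summary["counts"]["genes_enriched"] = len(enriched_genes)
    log.info("enriched genes: %d of %d", len(enriched_genes), len(expr.genes))

    # 2. cell-type-enriched accessible regions ------------------------------
    @_stage("call_enriched_peaks")
    def stage2():
        target = read_bed(config.target_bed, q_threshold=config.dhs_q)
        refs = [read_bed(b, q_threshold=config.dhs_q) for b in config.reference_beds]
        enriched = call_enriched_peaks(target, refs)
        write_bed(enriched, outdir / "enriched_dhs.bed")
        return target, enriched

    target_peaks, enriched_peaks = stage2()
    summary["stages"].append("call_enriched_peaks")
    summary["counts"]["peaks_target"] = len(target_peaks)
    summary["counts"]["peaks_enriched"] = len(enriched_peaks)

    # 3. promoter / distal annotation ---------------------------------------
    @_stage("annotate_peaks")
    def stage3():
        annots = annotate_peaks(target_peaks, genes,
                                promoter_bp=config.promoter_bp,
                                distal_max_bp=config.distal_max_bp)
        from .genomics import write_annotations
        write_annotations(annots, outdir / "peak_annotation.tsv")
        return annots

    annotations = stage3()
    summary["stages"].append("annotate_peaks")
    summary["counts"]["peaks_promoter"] = sum(
        1 for a in annotations if a.category == "promoter"
    )

    # promoter peaks of each enriched gene (from the full target set);
    # a gene may own several and their scores later sum
    promoter_peaks: dict[str, list] = {}
    for a in annotations:
        if a.category == "promoter" and a.gene_id in set(enriched_genes):
            promoter_peaks.setdefault(a.gene_id, []).append(a.peak)
    modeled_genes = sorted(promoter_peaks)
    summary["counts"]["enriched_genes_with_promoter_dhs"] = len(modeled_genes)

    # 4. promoter motif enrichment ------------------------------------------
    @_stage("promoter_motif_enrichment")
    def stage4():
        bg_regions = [
            _region_seq(fasta, g.chrom, g.tss - config.promoter_bp,
                        g.tss + config.promoter_bp)
            for g in genes
        ]
        fg_pairs = [(gid, p) for gid in modeled_genes
                    for p in promoter_peaks[gid]]
        fg = [_region_seq(fasta, p.chrom, p.start, p.end) for _, p in fg_pairs]
        groups, hits = [], []
        for pwm in pwms:
            bg = mo.fit_background(bg_regions, pwm, chunk_len=config.chunk_len)
            group, per_region = mo.enrich(
                fg, pwm, bg,
                region_ids=[f"{gid}:{p.start}" for gid, p in fg_pairs],
                group_label="promoter_fg")
            groups.append(group)
            for res, (gid, peak) in zip(per_region, fg_pairs):
                hits.append(
                    PromoterHit(
                        tf_name=pwm.tf_name, gene_id=gid, p_value=res.p_value,
                        rpkm_dhs=peak.signal_rpkm,
                        distance_bp=abs(peak.midpoint - gene_by_id[gid].tss),
                    )
                )
        pd.DataFrame(
            [{"tf": g.tf_name, "n_regions": g.n_regions,
              "mean_log_affinity": g.affinity, "p_value": g.p_value}
             for g in groups]
        ).to_csv(outdir / "promoter_motifs.tsv", sep="\t", index=False,
                 float_format="%.6g")
        return groups, hits

    promoter_groups, promoter_hits = stage4()
    summary["stages"].append("promoter_motif_enrichment")

    # 5. distal motif enrichment --------------------------------------------
    @_stage("distal_motif_enrichment")
    def stage5():
        # null: target distal peaks that are NOT cell-type-enriched
        # (i.e. shared with the reference chromatin landscape)
        enriched_names = {(p.chrom, p.start) for p in enriched_peaks}
        distal_shared, distal_hits_map = [], {}
        for a in annotations:
            if a.category != "distal":
                continue
            if (a.peak.chrom, a.peak.start) not in enriched_names:
                distal_shared.append(_region_seq(fasta, a.peak.chrom,
                                                 a.peak.start, a.peak.end))
        fg_peaks = []  # enriched distal peaks within the window of a modeled gene
        for gid in modeled_genes:
            g = gene_by_id[gid]
            for p, d in distal_window(g, enriched_peaks,
                                      promoter_bp=config.promoter_bp,
                                      distal_max_bp=config.distal_max_bp):
                fg_peaks.append((gid, p, d))
        uniq = {}
        for gid, p, d in fg_peaks:
            uniq.setdefault((p.chrom, p.start, p.end), p)
        fg_seqs = {
            key: _region_seq(fasta, *key) for key in uniq
        }
        groups = []
        hits: list[DistalHit] = []
        if fg_peaks:
            for pwm in pwms:
                try:
                    bg = mo.fit_background(distal_shared, pwm,
                                           chunk_len=config.chunk_len)
                except ValueError as exc:
                    log.warning("distal background unavailable for %s: %s",
                                pwm.tf_name, exc)
                    continue
                keys = sorted(fg_seqs)
                group, per_region = mo.enrich(
                    [fg_seqs[k] for k in keys], pwm, bg,
                    region_ids=[f"{k[0]}:{k[1]}-{k[2]}" for k in keys],
                    group_label="distal_fg",
                )
                groups.append(group)
                p_by_key = {k: r.p_value for k, r in zip(keys, per_region)}
                for gid, p, d in fg_peaks:
                    key = (p.chrom, p.start, p.end)
                    hits.append(
                        DistalHit(
                            tf_name=pwm.tf_name, gene_id=gid,
                            dhs_index=f"{key[0]}:{key[1]}-{key[2]}",
                            p_value=p_by_key[key], rpkm_dhs=p.signal_rpkm,
                            distance_bp=float(d),
                        )
                    )
        pd.DataFrame(
            [{"tf": g.tf_name, "n_regions": g.n_regions,
              "mean_log_affinity": g.affinity, "p_value": g.p_value}
             for g in groups]
        ).to_csv(outdir / "distal_motifs.tsv", sep="\t", index=False,
                 float_format="%.6g")
        return groups, hits

    distal_groups, distal_hits = stage5()
    summary["stages"].append("distal_motif_enrichment")

    # 6. candidate TFs -------------------------------------------------------
    @_stage("candidate_tfs")
    def stage6():
        prom = mo.candidate_tfs(promoter_groups, target_expr,
                                p_max=config.promoter_motif_p,
                                fpkm_min=config.fpkm_min)
        dist = mo.candidate_tfs(distal_groups, target_expr,
                                p_max=config.distal_motif_p,
                                fpkm_min=config.fpkm_min)
        prom.to_csv(outdir / "candidate_tfs_promoter.tsv", sep="\t",
                    index=False, float_format="%.6g")
        dist.to_csv(outdir / "candidate_tfs_distal.tsv", sep="\t",
                    index=False, float_format="%.6g")
        return prom, dist

    prom_candidates, dist_candidates = stage6()
    summary["stages"].append("candidate_tfs")
    summary["counts"]["candidate_tfs_promoter"] = len(prom_candidates)
    summary["counts"]["candidate_tfs_distal"] = len(dist_candidates)

    # 7. TFRS design matrices + scheme selection -----------------------------
    @_stage("scheme_selection")
    def stage7():
        cand = list(prom_candidates["tf"])
        if not cand or len(modeled_genes) < max(2, config.cv_folds):
            log.warning("scheme selection skipped: %d candidate TFs, %d genes",
                        len(cand), len(modeled_genes))
            return None, {}, {}
        hits = [h for h in promoter_hits if h.tf_name in set(cand)]
        best, evals, matrices = select_scheme(
            hits, target_expr.loc[modeled_genes], genes=modeled_genes, tfs=cand,
            lambda_grid=config.lambda_grid, alpha_grid=config.alpha_grid,
            n_folds=config.cv_folds, seed=config.seed,
            glmnet_compat=config.glmnet_compat,
        )
        pd.DataFrame(
            [{"scheme": s, "best_lambda": e.best_lambda,
              "best_alpha": e.best_alpha, "cv_rmse": e.cv_rmse}
             for s, e in evals.items()]
        ).to_csv(outdir / "scheme_evaluation.tsv", sep="\t", index=False,
                 float_format="%.10g")
        for s, m in matrices.items():
            m.to_tsv(outdir / f"tfrs_{s}.tsv")
        return best, evals, matrices

    best_scheme, evals, matrices = stage7()
    summary["stages"].append("scheme_selection")
    summary["best_scheme"] = best_scheme

    # 8. per-TF predicted targets (winning scheme) ---------------------------
    @_stage("predicted_targets")
    def stage8():
        rows = []
        if best_scheme is not None:
            tfrs = matrices[best_scheme]
            for tf in tfrs.tfs:
                ranked = predicted_targets(tfrs, tf)
                for rank, rec in enumerate(ranked.itertuples(index=False), start=1):
                    rows.append({"tf": tf, "rank": rank,
                                 "gene_id": rec.gene_id, "score": rec.score})
        # distal TFRS matrix for distal candidates
        dist_tfs = list(dist_candidates["tf"])
        if dist_tfs and distal_hits:
            dhits = [h for h in distal_hits if h.tf_name in set(dist_tfs)]
            dmat = build_design_matrix(dhits, modeled_genes, dist_tfs, "distal")
            dmat.to_tsv(outdir / "tfrs_distal.tsv")
        pd.DataFrame(rows, columns=["tf", "rank", "gene_id", "score"]).to_csv(
            outdir / "predicted_targets.tsv", sep="\t", index=False,
            float_format="%.10g")
        return rows

    stage8()
    summary["stages"].append("predicted_targets")

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "stages": summary["stages"],
        "counts": summary["counts"],
        "best_scheme": best_scheme,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    summary["manifest"] = manifest
    return summary
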