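"""End-to-end orchestration: scoring files -> genotypes -> matching ->
scoring -> ancestry -> adjustment, with a run report.

Every stage is importable on its own; this module wires them together the
way the command-line ``run`` subcommand does, writing four artifacts into
the output directory:

* ``scores.tsv`` -- aggregated raw scores (sum, denom, avg, variants used);
* ``adjusted_scores.tsv`` -- the ancestry-normalized scales (when a
  reference panel is supplied);
* ``match_log.tsv.gz`` -- the per-variant matching audit log;
* ``report.json`` / ``report.txt`` -- match summaries, per-population score
  distribution summaries, assignment counts, and the configuration echo.

Outputs are byte-deterministic for identical inputs and configuration: no
timestamps in artifacts, pinned gzip headers, fixed float formatting.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import adjustment as adj
from . import ancestry as anc
from . import genotypes as gio
from . import matching as mat
from . import scoring as sco
from . import scoringfiles as sfio

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message carries the stage name."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run (mirrors the CLI flags)."""

    target_paths: list[str]
    scoring_paths: list[str]
    out_dir: str
    reference_vcf: str | None = None
    reference_labels: str | None = None
    target_build: str | None = None
    override_unknown_build: bool = False
    match_params: mat.MatchParams = field(default_factory=mat.MatchParams)
    K: int = 10
    min_pca_overlap: int = 100
    projection_method: str = "oadp"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.target_paths:
            raise PipelineError("config: at least one target path is required")
        if not self.scoring_paths:
            raise PipelineError("config: at least one scoring file is required")

    def echo(self) -> dict:
        return {
            "target_paths": [str(p) for p in self.target_paths],
            "scoring_paths": [str(p) for p in self.scoring_paths],
            "out_dir": str(self.out_dir),
            "reference_vcf": str(self.reference_vcf) if self.reference_vcf else None,
            "reference_labels": (
                str(self.reference_labels) if self.reference_labels else None
            ),
            "target_build": self.target_build,
            "override_unknown_build": self.override_unknown_build,
            "min_overlap": self.match_params.min_overlap,
            "keep_ambiguous": self.match_params.keep_ambiguous,
            "keep_multiallelic": self.match_params.keep_multiallelic,
            "K": self.K,
            "min_pca_overlap": self.min_pca_overlap,
            "projection_method": self.projection_method,
            "seed": self.seed,
        }


@dataclass
class RunResult:
    """In-memory view of a completed run plus the artifact paths."""

    scores: pd.DataFrame
    adjusted: pd.DataFrame | None
    match_results: list[mat.MatchResult]
    match_summaries: dict[str, mat.MatchSummary]
    assignments: dict[str, str] | None
    report: dict
    paths: dict[str, Path]


def _stage(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is not None:
                logger.error("stage %s: failed after %.2fs: %s", name, dt, exc)
                if not isinstance(exc, PipelineError):
                    raise PipelineError(f"stage {name}: {exc}") from exc
            logger.info("stage %s: done in %.2fs", name, dt)
            return False

    return _Timer()


def match_and_score(
    combined: pd.DataFrame,
    blocks: Sequence[gio.GenotypeBlock],
    params: mat.MatchParams,
    *,
    block_labels: Sequence[str] | None = None,
    raise_on_low_overlap: bool = True,
) -> tuple[list[mat.MatchResult], dict[str, mat.MatchSummary], list[sco.ScoreResult]]:
    """Match and score across one or more (per-chromosome) genotype blocks.

    Each combined-table row is matched inside the block covering its
    chromosome; rows on uncovered chromosomes are unmatched.  Per-block
    partial scores are aggregated, so split-per-chromosome input gives
    exactly the whole-file result.
    """
    if block_labels is None:
        block_labels = [f"block{i}" for i in range(len(blocks))]
    chrom_to_block: dict[str, int] = {}
    for bi, block in enumerate(blocks):
        for chrom in block.chromosomes():
            if chrom in chrom_to_block:
                raise gio.GenotypeError(f"chromosome {chrom} covered by two blocks")
            chrom_to_block[chrom] = bi

    global_results: list[mat.MatchResult | None] = [None] * len(combined)
    partials: list[sco.ScoreResult] = []
    row_block = np.array(
        [chrom_to_block.get(str(c), -1) for c in combined["chr_name"]], dtype=int
    )
    for bi, block in enumerate(blocks):
        rows = np.nonzero(row_block == bi)[0]
        sub = combined.iloc[rows]
        results, _ = mat.match_variants(
            sub, block, params, raise_on_low_overlap=False
        )
        for local_i, row_i in enumerate(rows):
            global_results[row_i] = results[local_i]
        plans = sco.build_scoring_plan(sub, results)
        partials.extend(sco.score_block(block, plans, block_label=block_labels[bi]))

    for row_i in np.nonzero(row_block == -1)[0]:
        row = combined.iloc[row_i]
        oa = row["other_allele"]
        global_results[row_i] = mat.MatchResult(
            chr_name=str(row["chr_name"]),
            chr_position=int(row["chr_position"]),
            effect_allele=row["effect_allele"],
            other_allele=oa if isinstance(oa, str) else None,
            target_index=None,
            match_class=mat.UNMATCHED,
            is_ambiguous=False,
            is_multiallelic=False,
            kept=False,
            exclusion_reason="unmatched",
        )

    results = [r for r in global_results if r is not None]
    assert len(results) == len(combined)

    # global per-score summaries over all blocks
    score_ids = [c for c in combined.columns if c not in sfio.COMBINED_KEY_COLUMNS]
    summaries: dict[str, mat.MatchSummary] = {}
    for sid in score_ids:
        has_weight = combined[sid].notna().to_numpy()
        total = int(has_weight.sum())
        class_counts: dict[str, int] = {}
        reason_counts: dict[str, int] = {}
        n_kept = 0
        for res, present in zip(results, has_weight):
            if not present:
                continue
            class_counts[res.match_class] = class_counts.get(res.match_class, 0) + 1
            if res.kept:
                n_kept += 1
                reason_counts["kept"] = reason_counts.get("kept", 0) + 1
            else:
                key = f"excluded_{res.exclusion_reason}"
                reason_counts[key] = reason_counts.get(key, 0) + 1
        rate = n_kept / total if total else 0.0
        summaries[sid] = mat.MatchSummary(
            score_id=sid,
            total=total,
            n_kept=n_kept,
            class_counts=class_counts,
            reason_counts=reason_counts,
            match_rate=rate,
            min_overlap=params.min_overlap,
            passed=rate >= params.min_overlap,
        )

    failing = [s for s in summaries.values() if not s.passed]
    if failing and raise_on_low_overlap:
        detail = ", ".join(
            f"{s.score_id}: {s.match_rate:.3f} < {s.min_overlap}" for s in failing
        )
        raise mat.LowMatchRateError(
            f"match rate below min_overlap for {len(failing)} score(s): {detail}",
            summaries,
        )

    aggregated = sco.aggregate_scores(partials)
    return results, summaries, aggregated


def _distribution_summary(values: np.ndarray) -> dict:
    qs = np.quantile(values, [0.05, 0.25, 0.5, 0.75, 0.95])
    return {
        "n": int(len(values)),
        "mean": float(np.mean(values)),
        "sd": float(np.std(values, ddof=1)) if len(values) > 1 else 0.0,
        "q05": float(qs[0]),
        "q25": float(qs[1]),
        "median": float(qs[2]),
        "q75": float(qs[3]),
        "q95": float(qs[4]),
    }


def run_pipeline(cfg: RunConfig) -> RunResult:
    """Execute the full pipeline and write all artifacts.

    Without a reference panel the ancestry and adjustment stages are
    skipped: raw SUM/AVG only, with the report noting that adjustment was
    unavailable.  Any hard stop (build mismatch, low match rate) propagates
    as an exception with the stage name attached.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    report: dict = {"config": cfg.echo()}

    with _stage("scoring_files"):
        files = []
        for p in cfg.scoring_paths:
            sf = sfio.parse_scoring_file(p, default_id=Path(p).stem)
            if cfg.target_build is not None:
                sfio.validate_build(
                    sf, cfg.target_build, override_unknown=cfg.override_unknown_build
                )
            files.append(sf)
        combined = sfio.combine_scoring_files(files)
        logger.info(
            "combined %d scores over %d variants", len(files), len(combined)
        )

    with _stage("genotype_io"):
        blocks = list(gio.iterate_chromosomes(cfg.target_paths))
        labels = [Path(p).name for p in cfg.target_paths]

    with _stage("matching_scoring"):
        results, summaries, aggregated = match_and_score(
            combined, blocks, cfg.match_params, block_labels=labels
        )
        paths["match_log"] = out_dir / "match_log.tsv.gz"
        mat.write_match_log(results, summaries, paths["match_log"])
        paths["scores"] = out_dir / "scores.tsv"
        sco.write_score_results(aggregated, paths["scores"])
        scores_df = sco.results_to_frame(aggregated)
        report["match_summaries"] = {
            sid: s.as_dict() for sid, s in summaries.items()
        }

    adjusted_df: pd.DataFrame | None = None
    assignments_map: dict[str, str] | None = None
    if cfg.reference_vcf is None:
        report["adjustment"] = "unavailable: no reference panel supplied"
    else:
        from .simulate import read_population_labels  # light circular-free import

        with _stage("ancestry"):
            if cfg.reference_labels is None:
                raise PipelineError(
                    "stage ancestry: reference_labels required with reference_vcf"
                )
            ref_block = gio.read_vcf(cfg.reference_vcf)
            panel = anc.ReferencePanel(
                block=ref_block,
                labels=read_population_labels(cfg.reference_labels),
            )
            target_all = gio.concatenate_blocks(blocks)
            overlap = anc.overlap_variants(
                panel, target_all, min_count=cfg.min_pca_overlap
            )
            panel_sub = panel.block.subset_variants(overlap.panel_indices)
            target_aligned = anc.aligned_target_dosages(target_all, overlap)
            pruned = anc.prune_ld(panel_sub.dosages)
            model = anc.fit_reference_pca(
                panel_sub.subset_variants(pruned),
                [overlap.keys[i] for i in pruned],
                K=cfg.K,
            )
            target_model_aligned = target_aligned[:, pruned][:, model.kept_mask]
            projections = anc.project_samples(
                model,
                target_model_aligned,
                target_all.sample_ids,
                method=cfg.projection_method,
            )
            assignments = anc.assign_populations(projections, model, panel.labels)
            assignments_map = {
                a.sample_id: a.most_similar_pop for a in assignments
            }
            counts: dict[str, int] = {}
            for a in assignments:
                counts[a.most_similar_pop] = counts.get(a.most_similar_pop, 0) + 1
            report["assignment_counts"] = dict(sorted(counts.items()))

        with _stage("adjustment"):
            # reference panel scored on exactly the target-kept variant set
            kept_rows = [i for i, r in enumerate(results) if r.kept]
            combined_kept = combined.iloc[kept_rows].reset_index(drop=True)
            ref_results, _, ref_scores = match_and_score(
                combined_kept,
                [panel.block],
                cfg.match_params,
                block_labels=["reference"],
                raise_on_low_overlap=False,
            )
            n_ref_unkept = sum(1 for r in ref_results if not r.kept)
            if n_ref_unkept:
                logger.warning(
                    "%d target-kept variants not scoreable in the reference "
                    "panel; reference distributions use the remainder",
                    n_ref_unkept,
                )
            ref_by_score: dict[str, dict[str, float]] = {}
            for r in ref_scores:
                ref_by_score.setdefault(r.score_id, {})[r.sample_id] = r.sum

            proj_map = {p.sample_id: p.coords for p in projections}
            adjusted_all: list[adj.AdjustedScore] = []
            report["adjustment_models"] = {}
            for sid in sorted(ref_by_score):
                sums = np.array(
                    [ref_by_score[sid][s] for s in model.sample_ids]
                )
                labels_ordered = [panel.labels[s] for s in model.sample_ids]
                amodel = adj.fit_adjustment_model(
                    sums, model.ref_coords, labels_ordered, score_id=sid
                )
                score_results = [
                    r for r in aggregated if r.score_id == sid
                ]
                adjusted_all.extend(
                    adj.adjust_scores(score_results, assignments_map, proj_map, amodel)
                )
                report["adjustment_models"][sid] = {
                    "resid_sd": amodel.resid_sd,
                    "var_floor": amodel.var_floor,
                    "ref_pop_means": {
                        p: st.mean for p, st in amodel.ref_pop_stats.items()
                    },
                    "ref_pop_sds": {
                        p: st.sd for p, st in amodel.ref_pop_stats.items()
                    },
                }
            adjusted_df = adj.adjusted_to_frame(adjusted_all)
            paths["adjusted_scores"] = out_dir / "adjusted_scores.tsv"
            adj.write_adjusted_scores(adjusted_all, paths["adjusted_scores"])

    with _stage("report"):
        dist: dict[str, dict] = {}
        for sid, grp in scores_df.groupby("score_id"):
            entry: dict = {"raw_sum": _distribution_summary(grp["sum"].to_numpy())}
            if adjusted_df is not None and assignments_map is not None:
                sub = adjusted_df[adjusted_df["score_id"] == sid]
                per_pop: dict[str, dict] = {}
                for pop, pgrp in sub.groupby("most_similar_pop"):
                    per_pop[pop] = {
                        "raw_sum": _distribution_summary(pgrp["sum_raw"].to_numpy()),
                        "Z_MostSimilarPop": _distribution_summary(
                            pgrp["Z_MostSimilarPop"].to_numpy()
                        ),
                        "Z_norm1": _distribution_summary(pgrp["Z_norm1"].to_numpy()),
                        "Z_norm2": _distribution_summary(pgrp["Z_norm2"].to_numpy()),
                    }
                entry["per_population"] = per_pop
            dist[sid] = entry
        report["score_distributions"] = dist

        paths["report_json"] = out_dir / "report.json"
        paths["report_json"].write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
        paths["report_text"] = out_dir / "report.txt"
        paths["report_text"].write_text(_render_text_report(report))

    return RunResult(
        scores=scores_df,
        adjusted=adjusted_df,
        match_results=results,
        match_summaries=summaries,
        assignments=assignments_map,
        report=report,
        paths=paths,
    )


def _render_text_report(report: dict) -> str:
    lines = ["pgskit run report", "=" * 40, ""]
    lines.append("Configuration:")
    for k, v in sorted(report["config"].items()):
        lines.append(f"  {k}: {v}")
    lines.append("")
    lines.append("Match summaries:")
    for sid, s in sorted(report.get("match_summaries", {}).items()):
        lines.append(
            f"  {sid}: {s['n_kept']}/{s['total']} kept "
            f"(rate {s['match_rate']:.4f}, "
            f"{'passed' if s['passed'] else 'FAILED'} vs {s['min_overlap']})"
        )
        for reason, count in sorted(s["reason_counts"].items()):
            lines.append(f"    {reason}: {count}")
    lines.append("")
    if "assignment_counts" in report:
        lines.append("Most-similar-population assignments:")
        for pop, count in sorted(report["assignment_counts"].items()):
            lines.append(f"  {pop}: {count}")
        lines.append("")
    if isinstance(report.get("adjustment"), str):
        lines.append(f"Adjustment: {report['adjustment']}")
        lines.append("")
    lines.append("Score distributions:")
    for sid, entry in sorted(report.get("score_distributions", {}).items()):
        raw = entry["raw_sum"]
        lines.append(
            f"  {sid}: raw SUM mean {raw['mean']:.4g}, sd {raw['sd']:.4g} "
            f"(n={raw['n']})"
        )
        for pop, stats in sorted(entry.get("per_population", {}).items()):
            lines.append(
                f"    {pop}: raw mean {stats['raw_sum']['mean']:.4g} | "
                f"Z_MostSimilarPop mean {stats['Z_MostSimilarPop']['mean']:.3f} "
                f"sd {stats['Z_MostSimilarPop']['sd']:.3f} | "
                f"Z_norm1 mean {stats['Z_norm1']['mean']:.3f} | "
                f"Z_norm2 sd {stats['Z_norm2']['sd']:.3f}"
            )
    return "\n".join(lines) + "\n"
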