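"""Polygenic score computation: weighted sums of effect-allele dosages.

A polygenic score is SUM = sum_j w_j * d_j over the kept, non-missing
variants j, where d_j is the effect-allele dosage.  Samples missing a
variant skip it, which shrinks that sample's denominator (DENOM = 2 x
variants used) rather than imputing -- scoring files carry no allele
frequencies, so mean imputation would be guesswork.  Both SUM and the
denominator-normalized AVG are reported; downstream normalization consumes
SUM.

Summation follows scoring-file row order so that results are bitwise
reproducible and chromosome-split runs aggregate to exactly the whole-file
answer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genotypes import GenotypeBlock
from .matching import MatchResult
from .scoringfiles import COMBINED_KEY_COLUMNS


class ScoringError(ValueError):
    """Inconsistent scoring inputs."""


def _chrom_key(chrom: str):
    return (0, int(chrom)) if chrom.isdigit() else (1, chrom)


# match classes whose effect dosage is the alt dosage; the rest reflect 2-d
_ALT_ORIENTED = {"altref", "altref_flip", "no_oa_alt"}
_REF_ORIENTED = {"refalt", "refalt_flip", "no_oa_ref"}


@dataclass(frozen=True)
class PlanEntry:
    """One kept variant of one score: where to read it and how to weight it."""

    target_index: int
    reverse: bool  # effect allele is the target ref: dosage reflects to 2-d
    effect_type: str
    weight: float


@dataclass
class ScoreResult:
    """One sample's result for one score (possibly a per-block partial)."""

    sample_id: str
    score_id: str
    sum: float
    denom: int
    n_variants_used: int
    block_label: str | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.sum):
            raise ScoringError(f"non-finite score sum for {self.sample_id}")
        if self.denom != 2 * self.n_variants_used:
            raise ScoringError("denom must equal 2 x variants used")

    @property
    def avg(self) -> float:
        return self.sum / self.denom if self.denom else 0.0


def effect_dosage(
    raw_alt_dosage: float,
    match_class: str,
    effect_type: str = "additive",
) -> float:
    """Effect-allele dosage from the stored alt-allele dosage.

    Orientation first (alt-oriented classes keep d, ref-oriented reflect to
    2-d), then the effect-type transform: dominant collapses to 1 at >= 0.5
    oriented copies, recessive at >= 1.5 -- thresholds chosen so hard calls
    reduce to the usual ">= 1 copy" / "2 copies" semantics while fractional
    imputed dosages still resolve.  Missing (nan) propagates.
    """
    if isinstance(raw_alt_dosage, float) and math.isnan(raw_alt_dosage):
        return float("nan")
    if match_class in _ALT_ORIENTED:
        orient = raw_alt_dosage
    elif match_class in _REF_ORIENTED:
        orient = 2.0 - raw_alt_dosage
    else:
        raise ScoringError(f"cannot score match class {match_class!r}")
    if effect_type == "additive":
        return orient
    if effect_type == "dominant":
        return 1.0 if orient >= 0.5 else 0.0
    if effect_type == "recessive":
        return 1.0 if orient >= 1.5 else 0.0
    raise ScoringError(f"unknown effect_type {effect_type!r}")


def build_scoring_plan(
    combined: pd.DataFrame,
    results: Sequence[MatchResult],
) -> dict[str, list[PlanEntry]]:
    """Turn kept match results into per-score ordered scoring plans.

    Entry order is combined-table row order, fixing the summation order.
    """
    if len(results) != len(combined):
        raise ScoringError(
            f"{len(results)} match results for {len(combined)} table rows"
        )
    score_ids = [c for c in combined.columns if c not in COMBINED_KEY_COLUMNS]
    plans: dict[str, list[PlanEntry]] = {sid: [] for sid in score_ids}
    effect_types = combined["effect_type"].tolist()
    for sid in score_ids:
        weights = combined[sid].to_numpy()
        for row_i, res in enumerate(results):
            if not res.kept or not np.isfinite(weights[row_i]):
                continue
            plans[sid].append(
                PlanEntry(
                    target_index=res.target_index,  # type: ignore[arg-type]
                    reverse=res.match_class in _REF_ORIENTED,
                    effect_type=effect_types[row_i],
                    weight=float(weights[row_i]),
                )
            )
    return plans


def score_block(
    block: GenotypeBlock,
    plans: dict[str, list[PlanEntry]],
    *,
    block_label: str | None = None,
) -> list[ScoreResult]:
    """Score every sample in the block for every score in the plans.

    Accumulates variant by variant, vectorized over samples, so each
    sample's sum has exactly the summation order of a per-sample loop.  The
    order is canonical -- chromosomes in natural order, file order within a
    chromosome, per-chromosome subtotals added in chromosome order -- which
    makes whole-file and split-per-chromosome runs bitwise identical.
    """
    n = block.n_samples
    out: list[ScoreResult] = []
    for sid, entries in plans.items():
        by_chrom: dict[str, list[PlanEntry]] = {}
        for e in entries:
            if not 0 <= e.target_index < block.n_variants:
                raise ScoringError(
                    f"plan entry references variant {e.target_index} outside block"
                )
            by_chrom.setdefault(block.variants[e.target_index].chrom, []).append(e)
        sums = np.zeros(n)
        used = np.zeros(n, dtype=int)
        for chrom in sorted(by_chrom, key=_chrom_key):
            chrom_sums = np.zeros(n)
            for e in by_chrom[chrom]:
                d = block.dosages[:, e.target_index]
                orient = 2.0 - d if e.reverse else d.copy()
                if e.effect_type == "dominant":
                    ed = np.where(orient >= 0.5, 1.0, 0.0)
                elif e.effect_type == "recessive":
                    ed = np.where(orient >= 1.5, 1.0, 0.0)
                else:
                    ed = orient
                ok = ~np.isnan(d)
                chrom_sums[ok] += e.weight * ed[ok]
                used[ok] += 1
            sums += chrom_sums
        for i, sample_id in enumerate(block.sample_ids):
            out.append(
                ScoreResult(
                    sample_id=sample_id,
                    score_id=sid,
                    sum=float(sums[i]),
                    denom=int(2 * used[i]),
                    n_variants_used=int(used[i]),
                    block_label=block_label,
                )
            )
    return out


def aggregate_scores(partials: Iterable[ScoreResult]) -> list[ScoreResult]:
    """Aggregate per-block partial scores: sums and denominators add.

    The same labelled block contributing twice to one (sample, score) is an
    error -- it would silently double-count a chromosome.  Output order is
    first-appearance order of (score, sample).
    """
    acc: dict[tuple[str, str], ScoreResult] = {}
    labels_seen: dict[tuple[str, str], set[str]] = {}
    order: list[tuple[str, str]] = []
    for p in partials:
        key = (p.score_id, p.sample_id)
        if key not in acc:
            acc[key] = ScoreResult(
                sample_id=p.sample_id,
                score_id=p.score_id,
                sum=p.sum,
                denom=p.denom,
                n_variants_used=p.n_variants_used,
                block_label=None,
            )
            labels_seen[key] = set()
            order.append(key)
        else:
            prev = acc[key]
            acc[key] = ScoreResult(
                sample_id=p.sample_id,
                score_id=p.score_id,
                sum=prev.sum + p.sum,
                denom=prev.denom + p.denom,
                n_variants_used=prev.n_variants_used + p.n_variants_used,
                block_label=None,
            )
        if p.block_label is not None:
            if p.block_label in labels_seen[key]:
                raise ScoringError(
                    f"block {p.block_label!r} contributed twice to "
                    f"({p.sample_id}, {p.score_id})"
                )
            labels_seen[key].add(p.block_label)
    return [acc[k] for k in order]


def results_to_frame(results: Sequence[ScoreResult]) -> pd.DataFrame:
    """Tabulate score results: sample_id, score_id, sum, denom, avg, n used."""
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "score_id": [r.score_id for r in results],
            "sum": [r.sum for r in results],
            "denom": [r.denom for r in results],
            "avg": [r.avg for r in results],
            "n_variants_used": [r.n_variants_used for r in results],
        }
    )


def write_score_results(results: Sequence[ScoreResult], path: str | Path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False, float_format="%.10g")
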