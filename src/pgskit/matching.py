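"""Matching scoring-file variants to target variants.

Each score variant is looked up by (chromosome, position) and every target
variant at that position is classified against it:

* ``altref`` / ``refalt`` -- effect allele equals the target alt / ref, with
  the other allele matching the opposite target allele;
* ``altref_flip`` / ``refalt_flip`` -- the same after reverse-complementing
  both score alleles (a strand flip between the score and the target);
* ``no_oa_alt`` / ``no_oa_ref`` -- scores published without an other
  allele, resolved on the effect allele only;
* ``unmatched`` -- no rule fires.

Palindromic allele pairs (A/T, C/G, and in general pairs mapped onto
themselves by reverse complement) make strand undecidable and are excluded
by default, as are matches to variants split from multi-allelic records.
Every decision lands in an auditable log: one row per score variant, with
rejected candidates preserved alongside.
"""

from __future__ import annotations

import gzip
import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Sequence

import pandas as pd

from .genotypes import GenotypeBlock, TargetVariant
from .scoringfiles import COMBINED_KEY_COLUMNS

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

# candidate preference: non-flipped before flipped, other-allele-resolved
# before effect-allele-only
MATCH_CLASSES = (
    "altref",
    "refalt",
    "altref_flip",
    "refalt_flip",
    "no_oa_alt",
    "no_oa_ref",
)
CLASS_RANK = {cls: i for i, cls in enumerate(MATCH_CLASSES)}
UNMATCHED = "unmatched"


class MatchError(ValueError):
    """Invalid matching inputs."""


class LowMatchRateError(RuntimeError):
    """A score's match rate fell below min_overlap; carries the summaries."""

    def __init__(self, message: str, summaries: dict[str, "MatchSummary"]):
        super().__init__(message)
        self.summaries = summaries


def reverse_complement(allele: str) -> str:
    """Reverse complement of an A/C/G/T allele string."""
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(allele.upper()))
    except KeyError as exc:
        raise MatchError(f"non-ACGT character in allele {allele!r}") from exc


def _revcomp_or_none(allele: str) -> str | None:
    try:
        return reverse_complement(allele)
    except MatchError:
        return None


def is_palindromic_pair(a: str, b: str) -> bool:
    """True when reverse-complementing maps the allele pair onto itself
    swapped (A/T, C/G, and longer strand-symmetric pairs): strand cannot be
    resolved for such a pair."""
    return _revcomp_or_none(a) == b


@dataclass(frozen=True)
class CandidateMatch:
    """Classification of one (score variant, target variant) pair."""

    match_class: str
    is_ambiguous: bool


@dataclass(frozen=True)
class MatchParams:
    """Matching policy knobs with conservative defaults."""

    keep_ambiguous: bool = False
    keep_multiallelic: bool = False
    min_overlap: float = 0.75

    def __post_init__(self) -> None:
        if not 0 < self.min_overlap <= 1:
            raise MatchError(f"min_overlap must be in (0, 1], got {self.min_overlap}")


@dataclass
class MatchResult:
    """Final matching decision for one score variant (one log row)."""

    chr_name: str
    chr_position: int
    effect_allele: str
    other_allele: str | None
    target_index: int | None
    match_class: str
    is_ambiguous: bool
    is_multiallelic: bool
    kept: bool
    exclusion_reason: str | None
    # audit trail of non-chosen candidates: (target_index, class, reason)
    candidate_log: list[tuple[int, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kept and (self.target_index is None or self.exclusion_reason):
            raise MatchError("kept results must have a target and no exclusion reason")
        if (self.match_class == UNMATCHED) != (self.target_index is None):
            raise MatchError("unmatched iff no target index")


@dataclass
class MatchSummary:
    """Per-score matching outcome versus the min_overlap threshold."""

    score_id: str
    total: int
    n_kept: int
    class_counts: dict[str, int]
    reason_counts: dict[str, int]
    match_rate: float
    min_overlap: float
    passed: bool

    def as_dict(self) -> dict:
        return {
            "score_id": self.score_id,
            "total": self.total,
            "n_kept": self.n_kept,
            "class_counts": dict(self.class_counts),
            "reason_counts": dict(self.reason_counts),
            "match_rate": self.match_rate,
            "min_overlap": self.min_overlap,
            "passed": self.passed,
        }


def classify_candidate(
    effect_allele: str,
    other_allele: str | None,
    target: TargetVariant,
) -> CandidateMatch:
    """Classify a score variant against one co-located target variant.

    Total function: anything unclassifiable is ``unmatched``.  Rules are
    tried in priority order -- direct orientations first, then the
    strand-flipped ones; with no other allele, only direct effect-allele
    equality is accepted (flipping a single allele is unverifiable).
    """
    ref, alt = target.ref, target.alt
    ea = effect_allele.upper()
    if other_allele is not None:
        oa = other_allele.upper()
        ambiguous = is_palindromic_pair(ea, oa)
        if ea == alt and oa == ref:
            return CandidateMatch("altref", ambiguous)
        if ea == ref and oa == alt:
            return CandidateMatch("refalt", ambiguous)
        rc_ea, rc_oa = _revcomp_or_none(ea), _revcomp_or_none(oa)
        if rc_ea is not None and rc_oa is not None:
            if rc_ea == alt and rc_oa == ref:
                return CandidateMatch("altref_flip", ambiguous)
            if rc_ea == ref and rc_oa == alt:
                return CandidateMatch("refalt_flip", ambiguous)
        return CandidateMatch(UNMATCHED, ambiguous)

    # effect-allele-only: ambiguous when the complement hits the other target
    # allele (palindromic target site)
    rc_ea = _revcomp_or_none(ea)
    if ea == alt:
        return CandidateMatch("no_oa_alt", rc_ea == ref)
    if ea == ref:
        return CandidateMatch("no_oa_ref", rc_ea == alt)
    return CandidateMatch(UNMATCHED, False)


def _build_position_index(block: GenotypeBlock) -> dict[tuple[str, int], list[int]]:
    index: dict[tuple[str, int], list[int]] = {}
    for i, tv in enumerate(block.variants):
        index.setdefault((tv.chrom, tv.pos), []).append(i)
    return index


def match_variants(
    combined: pd.DataFrame,
    block: GenotypeBlock,
    params: MatchParams = MatchParams(),
    *,
    raise_on_low_overlap: bool = True,
) -> tuple[list[MatchResult], dict[str, MatchSummary]]:
    """Match every combined-table variant against the target block.

    Per variant: classify all co-located targets, drop candidates forbidden
    by policy (ambiguous / multi-allelic-split) logging each, then keep the
    best remaining candidate by class preference; ties after preference
    ordering keep the first target in file order, the rest are logged as
    ``duplicate_best_match``.

    Returns one MatchResult per table row (in row order) and one
    MatchSummary per score column.  Raises :class:`LowMatchRateError` when
    any score's match rate falls below ``params.min_overlap`` (the summary
    travels with the exception), unless ``raise_on_low_overlap=False``.
    """
    score_ids = [c for c in combined.columns if c not in COMBINED_KEY_COLUMNS]
    pos_index = _build_position_index(block)

    results: list[MatchResult] = []
    for row in combined.itertuples(index=False):
        chrom = str(row.chr_name)
        pos = int(row.chr_position)
        ea = row.effect_allele
        oa = row.other_allele if isinstance(row.other_allele, str) else None

        candidates: list[tuple[int, CandidateMatch, bool]] = []
        for ti in pos_index.get((chrom, pos), []):
            tv = block.variants[ti]
            cand = classify_candidate(ea, oa, tv)
            if cand.match_class != UNMATCHED:
                candidates.append((ti, cand, tv.from_multiallelic))

        viable: list[tuple[int, CandidateMatch, bool]] = []
        rejected: list[tuple[int, CandidateMatch, bool, str]] = []
        for ti, cand, multi in candidates:
            if cand.is_ambiguous and not params.keep_ambiguous:
                rejected.append((ti, cand, multi, "ambiguous"))
            elif multi and not params.keep_multiallelic:
                rejected.append((ti, cand, multi, "multiallelic"))
            else:
                viable.append((ti, cand, multi))

        audit: list[tuple[int, str, str]] = [
            (ti, cand.match_class, reason) for ti, cand, _, reason in rejected
        ]

        if viable:
            order = sorted(
                range(len(viable)),
                key=lambda i: (CLASS_RANK[viable[i][1].match_class], viable[i][0]),
            )
            best_ti, best_cand, best_multi = viable[order[0]]
            best_rank = CLASS_RANK[best_cand.match_class]
            for i in order[1:]:
                ti, cand, _ = viable[i]
                reason = (
                    "duplicate_best_match"
                    if CLASS_RANK[cand.match_class] == best_rank
                    else "lower_priority_candidate"
                )
                audit.append((ti, cand.match_class, reason))
            results.append(
                MatchResult(
                    chr_name=chrom,
                    chr_position=pos,
                    effect_allele=ea,
                    other_allele=oa,
                    target_index=best_ti,
                    match_class=best_cand.match_class,
                    is_ambiguous=best_cand.is_ambiguous,
                    is_multiallelic=best_multi,
                    kept=True,
                    exclusion_reason=None,
                    candidate_log=audit,
                )
            )
        elif rejected:
            # best-ranked rejected candidate names the exclusion
            rejected.sort(key=lambda t: (CLASS_RANK[t[1].match_class], t[0]))
            ti, cand, multi, reason = rejected[0]
            audit = [a for a in audit if a[0] != ti]
            results.append(
                MatchResult(
                    chr_name=chrom,
                    chr_position=pos,
                    effect_allele=ea,
                    other_allele=oa,
                    target_index=ti,
                    match_class=cand.match_class,
                    is_ambiguous=cand.is_ambiguous,
                    is_multiallelic=multi,
                    kept=False,
                    exclusion_reason=reason,
                    candidate_log=audit,
                )
            )
        else:
            results.append(
                MatchResult(
                    chr_name=chrom,
                    chr_position=pos,
                    effect_allele=ea,
                    other_allele=oa,
                    target_index=None,
                    match_class=UNMATCHED,
                    is_ambiguous=False,
                    is_multiallelic=False,
                    kept=False,
                    exclusion_reason="unmatched",
                    candidate_log=audit,
                )
            )

    summaries: dict[str, MatchSummary] = {}
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
        summaries[sid] = MatchSummary(
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
        raise LowMatchRateError(
            f"match rate below min_overlap for {len(failing)} score(s): {detail}",
            summaries,
        )
    return results, summaries


LOG_COLUMNS = [
    "chr_name",
    "chr_position",
    "effect_allele",
    "other_allele",
    "match_class",
    "is_ambiguous",
    "is_multiallelic",
    "kept",
    "exclusion_reason",
    "target_id",
    "candidates",
]


def write_match_log(
    results: Sequence[MatchResult],
    summaries: dict[str, MatchSummary],
    sink: str | Path | IO,
) -> None:
    """Write the audit log: one TSV row per score variant, in file order,
    followed by a per-score summary block as ``#`` JSON lines.

    Byte-identical across reruns on identical inputs (gzip mtime pinned).
    """
    buf = io.StringIO()
    buf.write("\t".join(LOG_COLUMNS) + "\n")
    for r in results:
        target_id = "" if r.target_index is None else str(r.target_index)
        cand = json.dumps(r.candidate_log) if r.candidate_log else ""
        buf.write(
            "\t".join(
                [
                    r.chr_name,
                    str(r.chr_position),
                    r.effect_allele,
                    r.other_allele or "",
                    r.match_class,
                    str(r.is_ambiguous),
                    str(r.is_multiallelic),
                    str(r.kept),
                    r.exclusion_reason or "",
                    target_id,
                    cand,
                ]
            )
            + "\n"
        )
    for sid in sorted(summaries):
        buf.write("#summary\t" + json.dumps(summaries[sid].as_dict(), sort_keys=True) + "\n")

    text = buf.getvalue()
    if isinstance(sink, (str, Path)):
        path = Path(sink)
        if path.suffix == ".gz":
            # fileobj + pinned mtime: no filename/timestamp in the header,
            # so identical content is byte-identical
            with open(path, "wb") as raw, gzip.GzipFile(
                filename="", fileobj=raw, mode="wb", mtime=0
            ) as gz:
                gz.write(text.encode())
        else:
            path.write_text(text)
    else:
        sink.write(text)
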