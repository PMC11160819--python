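"""Reading target and reference genotypes into a dosage representation.

The in-memory container is :class:`GenotypeBlock`: an ordered sample list,
an ordered variant list, and a samples x variants matrix of alt-allele
dosages in [0, 2] with ``nan`` as the explicit missing marker (missingness
changes the scoring denominator, so it is never silently zero).

Multi-allelic VCF records are split into one biallelic variant per
alternate allele; each split carries ``from_multiallelic=True`` so the
matcher can apply its multi-allelic exclusion policy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from cyvcf2 import VCF


class GenotypeError(ValueError):
    """Malformed genotype input or inconsistent multi-file layout."""


@dataclass(frozen=True)
class TargetVariant:
    """A biallelic target variant (possibly split from a multi-allelic record).

    ``alts`` holds the full alternate-allele list of the originating record;
    dosages always count copies of ``alts[0]``.
    """

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    vid: str | None = None
    from_multiallelic: bool = False

    def __post_init__(self) -> None:
        if not self.alts:
            raise GenotypeError(f"variant {self.chrom}:{self.pos} has no alt alleles")
        if self.ref in self.alts:
            raise GenotypeError(
                f"variant {self.chrom}:{self.pos}: ref allele {self.ref} "
                "appears in alts"
            )

    @property
    def alt(self) -> str:
        """The alternate allele this variant's dosages count."""
        return self.alts[0]


@dataclass
class GenotypeBlock:
    """Samples x variants dosage matrix with nan marking missing calls."""

    sample_ids: list[str]
    variants: list[TargetVariant]
    dosages: np.ndarray  # float array, shape (n_samples, n_variants)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise GenotypeError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        finite = self.dosages[~np.isnan(self.dosages)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise GenotypeError("dosages must lie in [0, 2] or be nan")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def chromosomes(self) -> list[str]:
        """Distinct chromosome labels in variant order of first appearance."""
        seen: dict[str, None] = {}
        for v in self.variants:
            seen.setdefault(v.chrom, None)
        return list(seen)

    def subset_variants(self, indices: Sequence[int]) -> "GenotypeBlock":
        idx = list(indices)
        return GenotypeBlock(
            sample_ids=list(self.sample_ids),
            variants=[self.variants[i] for i in idx],
            dosages=self.dosages[:, idx],
        )


def read_vcf(path: str | Path) -> GenotypeBlock:
    """Read a VCF (plain or bgzipped) into a GenotypeBlock.

    Dosage precedence: the DS FORMAT field wins over GT at biallelic sites
    (it preserves imputation uncertainty); multi-allelic records are split
    per alternate allele with dosages computed as GT allele counts.  Missing
    and half-called genotypes become nan.
    """
    path = Path(path)
    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    n = len(sample_ids)
    if n == 0:
        raise GenotypeError(f"{path}: VCF has no samples")

    variants: list[TargetVariant] = []
    columns: list[np.ndarray] = []
    saw_usable_format = False

    for rec in vcf:
        alts = tuple(a.upper() for a in (rec.ALT or ()))
        if not alts:
            continue
        ref = rec.REF.upper()
        multi = len(alts) > 1

        ds = None
        if not multi:
            try:
                raw = rec.format("DS")
            except KeyError:
                raw = None
            if raw is not None:
                ds = np.asarray(raw, dtype=float).reshape(n, -1)[:, 0]
                ds = np.where(np.isfinite(ds), ds, np.nan)

        gt_counts: list[np.ndarray] | None = None
        try:
            gts = rec.genotypes  # list of [allele1, allele2, ..., phased]
        except Exception:  # cyvcf2 raises a bare Exception when GT is absent
            gts = None
        if gts is not None and len(gts) == n:
            per_alt = np.zeros((len(alts), n), dtype=float)
            missing = np.zeros(n, dtype=bool)
            for i, call in enumerate(gts):
                alleles = call[:-1]
                if len(alleles) == 0 or any(a < 0 for a in alleles):
                    missing[i] = True  # half-calls and no-calls are missing
                    continue
                for a in alleles:
                    if a > 0:
                        per_alt[a - 1, i] += 1.0
            per_alt[:, missing] = np.nan
            gt_counts = [per_alt[k] for k in range(len(alts))]

        if ds is None and gt_counts is None:
            raise GenotypeError(
                f"{path}: record {rec.CHROM}:{rec.POS} has neither GT nor DS"
            )
        saw_usable_format = True

        vid = rec.ID if rec.ID not in (None, ".") else None
        for k, alt in enumerate(alts):
            variants.append(
                TargetVariant(
                    chrom=str(rec.CHROM),
                    pos=int(rec.POS),
                    ref=ref,
                    alts=(alt,) + tuple(a for j, a in enumerate(alts) if j != k),
                    vid=vid,
                    from_multiallelic=multi,
                )
            )
            if not multi and ds is not None:
                columns.append(ds)
            else:
                assert gt_counts is not None
                columns.append(gt_counts[k])

    if variants and not saw_usable_format:
        raise GenotypeError(f"{path}: no usable GT or DS fields")

    dosages = (
        np.column_stack(columns) if columns else np.empty((n, 0), dtype=float)
    )
    return GenotypeBlock(sample_ids=sample_ids, variants=variants, dosages=dosages)


def iterate_chromosomes(paths: Sequence[str | Path]) -> Iterator[GenotypeBlock]:
    """Yield one GenotypeBlock per genotype file, in input order.

    Each file must cover a disjoint chromosome set, and sample IDs must
    agree across files both by identity and by position -- silent sample
    reordering would corrupt every score.  Downstream scoring is invariant
    to whether genotypes arrive whole or split per chromosome.
    """
    seen_chroms: dict[str, Path] = {}
    sample_ids: list[str] | None = None
    for raw in paths:
        path = Path(raw)
        block = read_vcf(path)
        if sample_ids is None:
            sample_ids = block.sample_ids
        elif block.sample_ids != sample_ids:
            raise GenotypeError(
                f"{path}: sample IDs differ from previous files "
                "(order and identity must match)"
            )
        for chrom in block.chromosomes():
            if chrom in seen_chroms:
                raise GenotypeError(
                    f"chromosome {chrom} appears in both {seen_chroms[chrom]} "
                    f"and {path}"
                )
            seen_chroms[chrom] = path
        yield block


def concatenate_blocks(blocks: Iterable[GenotypeBlock]) -> GenotypeBlock:
    """Concatenate per-chromosome blocks into one (sample order preserved)."""
    blocks = list(blocks)
    if not blocks:
        raise GenotypeError("no blocks to concatenate")
    first = blocks[0]
    for b in blocks[1:]:
        if b.sample_ids != first.sample_ids:
            raise GenotypeError("sample IDs differ across blocks")
    return GenotypeBlock(
        sample_ids=list(first.sample_ids),
        variants=[v for b in blocks for v in b.variants],
        dosages=np.concatenate([b.dosages for b in blocks], axis=1),
    )
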