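"""Synthetic reference panels, target cohorts and scoring files.

Population structure follows the Balding-Nichols model: each variant draws
an ancestral allele frequency p ~ Uniform(0.1, 0.9); each population draws
its own frequency from Beta(p(1-F)/F, (1-p)(1-F)/F), so F controls the
expected differentiation (F ~ F_ST); genotype dosages are Binomial(2,
p_pop).  Admixed target samples draw one allele from each of two parent
populations' frequencies.  The model has no linkage disequilibrium or
sequencing error -- it exists to create controllable population structure
and ancestry-confounded scores, not realistic haplotypes.

Generators emit real VCF text (plus population-label TSVs and scoring
files) so the I/O code paths are exercised, and everything is deterministic
given the seed.

:func:`inject_hazards` mutates a scoring file (and, where the hazard lives
in the target -- palindromic or multi-allelic sites -- the target block)
with the matching hazards a real scoring file exhibits, returning a ground
truth table of the match class and exclusion the matcher must produce.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .ancestry import ReferencePanel
from .genotypes import GenotypeBlock, TargetVariant
from .matching import reverse_complement
from .scoringfiles import ScoreVariant, ScoringFile


class SimulationError(ValueError):
    """Invalid simulation configuration."""


HAZARDS = (
    "strand_flip",
    "allele_swap",
    "drop_other_allele",
    "make_palindromic",
    "make_multiallelic",
    "unmatched",
)

_NON_PALINDROMIC_PAIRS = [
    (r, a)
    for r in "ACGT"
    for a in "ACGT"
    if r != a and reverse_complement(r) != a
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design knobs for one synthetic dataset."""

    n_pops: int = 3
    fst: float = 0.1
    n_ref_per_pop: int = 100
    n_target_per_pop: int = 100
    m_variants: int = 2000
    seed: int = 0
    admixed_fraction: float = 0.0
    palindromic_fraction: float = 0.0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_pops < 2:
            raise SimulationError("need >= 2 populations")
        if not 0 < self.fst < 1:
            raise SimulationError(f"fst must be in (0, 1), got {self.fst}")
        for name in ("n_ref_per_pop", "n_target_per_pop", "m_variants"):
            if getattr(self, name) < 1:
                raise SimulationError(f"{name} must be positive")
        for name in ("admixed_fraction", "palindromic_fraction", "missing_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise SimulationError(f"{name} must be in [0, 1]")


@dataclass
class SimulatedData:
    """A simulated reference panel + target cohort with generation truth."""

    panel: ReferencePanel
    target: GenotypeBlock
    target_labels: dict[str, str]  # generating population (truth)
    pop_names: list[str]
    pop_freqs: np.ndarray  # (n_pops, m)
    ancestral_freqs: np.ndarray  # (m,)


def _make_variants(cfg: SimulationConfig, rng: np.random.Generator) -> list[TargetVariant]:
    m = cfg.m_variants
    palindromic = rng.random(m) < cfg.palindromic_fraction
    variants = []
    for i in range(m):
        pool = _PALINDROMIC_PAIRS if palindromic[i] else _NON_PALINDROMIC_PAIRS
        ref, alt = pool[rng.integers(len(pool))]
        variants.append(
            TargetVariant(
                chrom=str((i % 22) + 1),
                pos=i + 1,
                ref=ref,
                alts=(alt,),
                vid=f"var{i + 1}",
            )
        )
    return variants


def simulate_panel(cfg: SimulationConfig) -> SimulatedData:
    """Simulate a labelled reference panel and a target cohort.

    Reference samples: ``n_ref_per_pop`` per population.  Targets:
    ``n_target_per_pop`` per population plus round(admixed_fraction x
    total) additional 50/50 admixed samples (labelled "POPi+POPj").
    Deterministic given cfg.seed.
    """
    rng = np.random.default_rng(cfg.seed)
    m = cfg.m_variants
    variants = _make_variants(cfg, rng)

    ancestral = rng.uniform(0.1, 0.9, size=m)
    F = cfg.fst
    a = ancestral * (1 - F) / F
    b = (1 - ancestral) * (1 - F) / F
    pop_freqs = rng.beta(a, b, size=(cfg.n_pops, m))
    pop_names = [f"POP{i + 1}" for i in range(cfg.n_pops)]

    ref_rows, ref_ids, labels = [], [], {}
    for k, pop in enumerate(pop_names):
        dosages = rng.binomial(2, pop_freqs[k], size=(cfg.n_ref_per_pop, m))
        ref_rows.append(dosages)
        for j in range(cfg.n_ref_per_pop):
            sid = f"ref_{pop}_{j + 1}"
            ref_ids.append(sid)
            labels[sid] = pop
    ref_block = GenotypeBlock(
        sample_ids=ref_ids,
        variants=list(variants),
        dosages=np.vstack(ref_rows).astype(float),
    )

    tgt_rows, tgt_ids = [], []
    target_labels: dict[str, str] = {}
    for k, pop in enumerate(pop_names):
        dosages = rng.binomial(2, pop_freqs[k], size=(cfg.n_target_per_pop, m))
        tgt_rows.append(dosages)
        for j in range(cfg.n_target_per_pop):
            sid = f"tgt_{pop}_{j + 1}"
            tgt_ids.append(sid)
            target_labels[sid] = pop

    n_admixed = round(cfg.admixed_fraction * cfg.n_pops * cfg.n_target_per_pop)
    for j in range(n_admixed):
        pa = j % cfg.n_pops
        pb = (j + 1) % cfg.n_pops
        # one allele draw from each parent population
        dosage = rng.binomial(1, pop_freqs[pa], size=m) + rng.binomial(
            1, pop_freqs[pb], size=m
        )
        tgt_rows.append(dosage[None, :])
        sid = f"tgt_admixed_{j + 1}"
        tgt_ids.append(sid)
        target_labels[sid] = f"{pop_names[pa]}+{pop_names[pb]}"

    tgt_dosages = np.vstack(tgt_rows).astype(float)
    if cfg.missing_rate > 0:
        mask = rng.random(tgt_dosages.shape) < cfg.missing_rate
        tgt_dosages[mask] = np.nan
    tgt_block = GenotypeBlock(
        sample_ids=tgt_ids, variants=list(variants), dosages=tgt_dosages
    )

    return SimulatedData(
        panel=ReferencePanel(block=ref_block, labels=labels),
        target=tgt_block,
        target_labels=target_labels,
        pop_names=pop_names,
        pop_freqs=pop_freqs,
        ancestral_freqs=ancestral,
    )


def simulate_scoring_file(
    variants: Sequence[TargetVariant],
    *,
    weight_sd: float = 0.1,
    seed: int = 0,
    pgs_id: str = "PGSSIM001",
    genome_build: str = "GRCh38",
    freq_gradient: np.ndarray | None = None,
) -> ScoringFile:
    """Random scoring file over the given target variants.

    Per variant, an alt-oriented weight ~ Normal(0, weight_sd) is drawn
    (plus ``freq_gradient`` if given, which tilts weights along e.g. a
    population frequency difference to build an ancestry-confounded score);
    the effect allele is then the target's alt or ref with equal
    probability, negating the stored weight in the ref case so the score's
    alt-dosage coefficient is the drawn weight regardless of orientation.
    Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    alt_weights = rng.normal(0.0, weight_sd, size=len(variants)) if weight_sd > 0 else np.zeros(len(variants))
    if freq_gradient is not None:
        if len(freq_gradient) != len(variants):
            raise SimulationError("freq_gradient length must match variants")
        alt_weights = alt_weights + np.asarray(freq_gradient, dtype=float)
    ea_is_alt = rng.random(len(variants)) < 0.5

    score_variants = []
    for i, tv in enumerate(variants):
        if ea_is_alt[i]:
            ea, oa, w = tv.alt, tv.ref, alt_weights[i]
        else:
            ea, oa, w = tv.ref, tv.alt, -alt_weights[i]
        score_variants.append(
            ScoreVariant(
                chr_name=tv.chrom,
                chr_position=tv.pos,
                effect_allele=ea,
                other_allele=oa,
                effect_weight=float(w),
            )
        )
    return ScoringFile(
        pgs_id=pgs_id,
        variants=score_variants,
        genome_build=genome_build,
        trait_label="simulated trait",
    )


@dataclass
class HazardInjection:
    """Mutated inputs plus the per-variant expected matcher verdicts."""

    scoring_file: ScoringFile
    target: GenotypeBlock
    truth: pd.DataFrame  # row, hazard, expected_class, expected_kept, expected_reason


def inject_hazards(
    sf: ScoringFile,
    target: GenotypeBlock,
    fractions: dict[str, float],
    seed: int = 0,
) -> HazardInjection:
    """Mutate a fraction of score variants per hazard, with ground truth.

    Hazards: ``strand_flip`` (reverse-complement both score alleles),
    ``allele_swap`` (exchange effect/other allele), ``drop_other_allele``,
    ``make_palindromic`` (the target site and score alleles become an A/T or
    C/G pair -- strand undecidable), ``make_multiallelic`` (a third allele
    appears at the target site), ``unmatched`` (score position perturbed off
    any target).  Disjoint variant subsets per hazard; fractions must sum to
    <= 1.
    """
    unknown = set(fractions) - set(HAZARDS)
    if unknown:
        raise SimulationError(f"unknown hazards: {sorted(unknown)}")
    if sum(fractions.values()) > 1 + 1e-9:
        raise SimulationError("hazard fractions sum to more than 1")
    if any(f < 0 for f in fractions.values()):
        raise SimulationError("hazard fractions must be non-negative")

    rng = np.random.default_rng(seed)
    n = len(sf.variants)
    order = rng.permutation(n)
    assignment = ["none"] * n
    cursor = 0
    for hazard in HAZARDS:  # fixed order for determinism
        frac = fractions.get(hazard, 0.0)
        count = round(frac * n)
        for i in order[cursor : cursor + count]:
            assignment[i] = hazard
        cursor += count

    tmap: dict[tuple[str, int], int] = {}
    for j, tv in enumerate(target.variants):
        tmap.setdefault((tv.chrom, tv.pos), j)

    new_targets = list(target.variants)
    new_cols: list[np.ndarray] = []
    new_variants: list[ScoreVariant] = []
    rows = []
    for i, sv in enumerate(sf.variants):
        hazard = assignment[i]
        ti = tmap.get((sv.chr_name, sv.chr_position))
        if ti is None:
            raise SimulationError(
                f"score variant {sv.chr_name}:{sv.chr_position} has no target site"
            )
        tv = new_targets[ti]
        ea_is_alt = sv.effect_allele == tv.alt
        base = "altref" if ea_is_alt else "refalt"
        out = sv
        expected_class, expected_kept, expected_reason = base, True, None

        if hazard == "strand_flip":
            out = dataclasses.replace(
                sv,
                effect_allele=reverse_complement(sv.effect_allele),
                other_allele=reverse_complement(sv.other_allele),
            )
            expected_class = base + "_flip"
        elif hazard == "allele_swap":
            out = dataclasses.replace(
                sv,
                effect_allele=sv.other_allele,
                other_allele=sv.effect_allele,
            )
            expected_class = "refalt" if ea_is_alt else "altref"
        elif hazard == "drop_other_allele":
            out = dataclasses.replace(sv, other_allele=None)
            expected_class = "no_oa_alt" if ea_is_alt else "no_oa_ref"
        elif hazard == "make_palindromic":
            ref, alt = _PALINDROMIC_PAIRS[rng.integers(len(_PALINDROMIC_PAIRS))]
            new_targets[ti] = dataclasses.replace(tv, ref=ref, alts=(alt,))
            ea, oa = (alt, ref) if ea_is_alt else (ref, alt)
            out = dataclasses.replace(sv, effect_allele=ea, other_allele=oa)
            expected_kept, expected_reason = False, "ambiguous"
        elif hazard == "make_multiallelic":
            third = next(
                b for b in "ACGT" if b not in (tv.ref, tv.alt)
            )
            new_targets[ti] = dataclasses.replace(tv, from_multiallelic=True)
            new_targets.append(
                dataclasses.replace(
                    tv, alts=(third, tv.alt), from_multiallelic=True
                )
            )
            new_cols.append(np.zeros(target.n_samples))
            expected_kept, expected_reason = False, "multiallelic"
        elif hazard == "unmatched":
            out = dataclasses.replace(sv, chr_position=sv.chr_position + 10_000_000)
            expected_class, expected_kept, expected_reason = (
                "unmatched",
                False,
                "unmatched",
            )

        new_variants.append(out)
        rows.append(
            {
                "row": i,
                "chr_name": out.chr_name,
                "chr_position": out.chr_position,
                "hazard": hazard,
                "expected_class": expected_class,
                "expected_kept": expected_kept,
                "expected_reason": expected_reason,
            }
        )

    dosages = target.dosages
    if new_cols:
        dosages = np.column_stack([dosages] + new_cols)
    mutated_target = GenotypeBlock(
        sample_ids=list(target.sample_ids), variants=new_targets, dosages=dosages
    )
    mutated_sf = ScoringFile(
        pgs_id=sf.pgs_id,
        variants=new_variants,
        genome_build=sf.genome_build,
        trait_label=sf.trait_label,
        header_meta=dict(sf.header_meta),
    )
    return HazardInjection(
        scoring_file=mutated_sf,
        target=mutated_target,
        truth=pd.DataFrame(rows),
    )


def _chrom_sort_key(chrom: str):
    return (0, int(chrom)) if chrom.isdigit() else (1, chrom)


def write_genotype_vcf(block: GenotypeBlock, path: str | Path) -> Path:
    """Write a GenotypeBlock as sorted VCF text (hard calls only).

    Variants split from one multi-allelic site are merged back into a
    single multi-allelic record; missing dosages become ``./.``.
    """
    path = Path(path)
    groups: dict[tuple[str, int, str], list[int]] = {}
    for i, tv in enumerate(block.variants):
        groups.setdefault((tv.chrom, tv.pos, tv.ref), []).append(i)

    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for chrom in sorted({c for c, _, _ in groups}, key=_chrom_sort_key):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(block.sample_ids)
    )

    for (chrom, pos, ref), idxs in sorted(
        groups.items(), key=lambda kv: (_chrom_sort_key(kv[0][0]), kv[0][1])
    ):
        alts = [block.variants[i].alt for i in idxs]
        vid = block.variants[idxs[0]].vid or "."
        cols = block.dosages[:, idxs]
        gts = []
        for s in range(block.n_samples):
            counts = cols[s]
            if np.any(np.isnan(counts)):
                gts.append("./.")
                continue
            if not np.allclose(counts, np.round(counts)):
                raise SimulationError(
                    f"cannot write fractional dosage at {chrom}:{pos} as GT"
                )
            alleles: list[int] = []
            for k, c in enumerate(np.round(counts).astype(int)):
                alleles.extend([k + 1] * c)
            total = sum(np.round(counts).astype(int))
            if total > 2:
                raise SimulationError(f"dosages exceed ploidy at {chrom}:{pos}")
            alleles = [0] * (2 - total) + alleles
            gts.append(f"{alleles[0]}/{alleles[1]}")
        lines.append(
            "\t".join(
                [chrom, str(pos), vid, ref, ",".join(alts), ".", "PASS", ".", "GT"]
                + gts
            )
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def write_genotype_vcfs_split(
    block: GenotypeBlock, out_dir: str | Path, prefix: str = "target"
) -> list[Path]:
    """Write one VCF per chromosome (enables the split-file code path)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for chrom in sorted(set(block.chromosomes()), key=_chrom_sort_key):
        idx = [i for i, v in enumerate(block.variants) if v.chrom == chrom]
        sub = block.subset_variants(idx)
        paths.append(write_genotype_vcf(sub, out_dir / f"{prefix}_chr{chrom}.vcf"))
    return paths


def write_population_labels(labels: dict[str, str], path: str | Path) -> Path:
    """Write the two-column sample -> population TSV."""
    path = Path(path)
    lines = ["sample_id\tpopulation"] + [
        f"{sid}\t{pop}" for sid, pop in labels.items()
    ]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_population_labels(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "population"} <= set(df.columns):
        raise SimulationError(f"{path}: expected columns sample_id, population")
    return dict(zip(df["sample_id"], df["population"]))


def weir_cockerham_fst(dosages: np.ndarray, pop_index: Sequence[int]) -> float:
    """Weir-Cockerham (1984) multi-population F_ST from hard-call dosages.

    ``pop_index`` assigns each sample (row) to a population 0..r-1.  The
    estimate is the ratio of summed among-population variance components to
    summed total components across variants (monomorphic variants
    contribute nothing).
    """
    pop_index = np.asarray(pop_index)
    pops = np.unique(pop_index)
    r = len(pops)
    if r < 2:
        raise SimulationError("F_ST needs >= 2 populations")

    n_i = np.array([(pop_index == p).sum() for p in pops], dtype=float)  # (r,)
    p_i = np.vstack(
        [np.nanmean(dosages[pop_index == p], axis=0) / 2.0 for p in pops]
    )  # (r, m)
    h_i = np.vstack(
        [np.nanmean(dosages[pop_index == p] == 1, axis=0) for p in pops]
    )  # (r, m)

    n_bar = n_i.mean()
    n_c = (r * n_bar - (n_i**2).sum() / (r * n_bar)) / (r - 1)
    p_bar = (n_i[:, None] * p_i).sum(axis=0) / (r * n_bar)
    s2 = (n_i[:, None] * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
    h_bar = (n_i[:, None] * h_i).sum(axis=0) / (r * n_bar)

    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
    )
    c = h_bar / 2

    denom = a + b + c
    ok = denom > 0
    if not ok.any():
        raise SimulationError("all variants monomorphic; F_ST undefined")
    return float(a[ok].sum() / denom[ok].sum())
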