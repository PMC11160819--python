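"""Reading, validating and combining polygenic scoring files.

A scoring file is the distributable definition of a polygenic score (PGS):
one row per variant giving its genomic coordinates, the effect allele whose
dosage is weighted, optionally the other allele, and the per-allele effect
weight (beta or log-odds-ratio scale).  The on-disk format is a
tab-separated table preceded by a ``#key=value`` header block, optionally
gzip-compressed -- the format the PGS Catalog distributes.

Two column dialects are accepted: the author dialect (``chr_name``,
``chr_position``, ``other_allele``) and the harmonized dialect (``hm_chr``,
``hm_pos``, ``hm_inferOtherAllele``).  Harmonized coordinates win when both
are present, because harmonized columns are the ones guaranteed to be on the
declared genome build.
"""

from __future__ import annotations

import gzip
import io
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

import pandas as pd

logger = logging.getLogger(__name__)

VALID_EFFECT_TYPES = ("additive", "dominant", "recessive")

_ALLELE_CHARS = set("ACGT")

_TRUEVALS = {"true", "1", "yes", "t"}
_FALSEVALS = {"false", "0", "no", "f", "", "na", "nan", "none"}


class ScoringFileError(ValueError):
    """Malformed or inconsistent scoring file."""


class BuildMismatchError(ScoringFileError):
    """Scoring file genome build does not match the target build."""


@dataclass(frozen=True)
class ScoreVariant:
    """One variant/weight pair of a polygenic score.

    ``effect_weight`` multiplies the dosage of ``effect_allele`` in the
    score sum.  ``other_allele`` may be absent (scores published with only
    the effect allele); matching then has to resolve orientation from a
    single allele.
    """

    chr_name: str
    chr_position: int
    effect_allele: str
    effect_weight: float
    other_allele: str | None = None
    effect_type: str = "additive"
    rsid: str | None = None

    def __post_init__(self) -> None:
        if self.chr_position < 1:
            raise ScoringFileError(
                f"chr_position must be >= 1, got {self.chr_position}"
            )
        if not self.effect_allele:
            raise ScoringFileError("effect_allele must be non-empty")
        if self.other_allele is not None and self.other_allele == self.effect_allele:
            raise ScoringFileError(
                f"effect_allele equals other_allele ({self.effect_allele}) at "
                f"{self.chr_name}:{self.chr_position}"
            )
        if not math.isfinite(self.effect_weight):
            raise ScoringFileError(
                f"non-finite effect_weight at {self.chr_name}:{self.chr_position}"
            )
        if self.effect_type not in VALID_EFFECT_TYPES:
            raise ScoringFileError(f"unknown effect_type {self.effect_type!r}")

    @property
    def key(self) -> tuple[str, int, str, str | None]:
        """Identity tuple: (chrom, pos, effect allele, other allele)."""
        return (self.chr_name, self.chr_position, self.effect_allele, self.other_allele)


@dataclass
class ScoringFile:
    """A parsed scoring file: metadata plus an ordered variant list."""

    pgs_id: str
    variants: list[ScoreVariant]
    genome_build: str | None = None
    trait_label: str | None = None
    header_meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.variants:
            raise ScoringFileError(f"scoring file {self.pgs_id!r} has no variants")
        seen: set[tuple] = set()
        for v in self.variants:
            if v.key in seen:
                raise ScoringFileError(
                    f"duplicate variant {v.key} in scoring file {self.pgs_id!r}"
                )
            seen.add(v.key)

    def __len__(self) -> int:
        return len(self.variants)


def _open_text(source: str | Path | IO) -> Iterator[str]:
    """Yield decoded lines from a path (gzip-aware) or a file-like object."""
    if isinstance(source, (str, Path)):
        path = Path(source)
        with open(path, "rb") as raw:
            magic = raw.read(2)
        opener = gzip.open if magic == b"\x1f\x8b" else open
        with opener(path, "rt") as fh:  # type: ignore[operator]
            yield from fh
    elif isinstance(source, io.TextIOBase) or hasattr(source, "read"):
        data = source.read()
        if isinstance(data, bytes):
            data = data.decode()
        yield from io.StringIO(data)
    else:  # iterable of lines
        yield from source


def _parse_bool(raw: str, line_no: int, colname: str) -> bool:
    low = raw.strip().lower()
    if low in _TRUEVALS:
        return True
    if low in _FALSEVALS:
        return False
    raise ScoringFileError(f"line {line_no}: cannot parse {colname}={raw!r} as boolean")


def parse_scoring_file(
    source: str | Path | IO | Iterable[str],
    *,
    default_id: str | None = None,
) -> ScoringFile:
    """Parse a scoring file from a path, file object, or iterable of lines.

    Harmonized coordinate columns (``hm_chr``/``hm_pos``) take precedence
    over ``chr_name``/``chr_position`` row-wise.  ``is_dominant`` /
    ``is_recessive`` flag columns map onto ``effect_type`` (both true in one
    row is an error).  A missing ``other_allele`` cell is recorded as absent,
    never as an empty string.

    Raises
    ------
    ScoringFileError
        On a missing ``effect_weight`` column, a non-numeric weight (the
        message names the offending line), a duplicated variant tuple, or an
        rsID-only file without positional coordinates.
    """
    header_meta: dict[str, str] = {}
    columns: list[str] | None = None
    rows: list[tuple[int, list[str]]] = []

    for line_no, line in enumerate(_open_text(source), start=1):
        line = line.rstrip("\n").rstrip("\r")
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                header_meta[key.strip()] = value.strip()
            continue
        if columns is None:
            columns = line.split("\t")
            continue
        rows.append((line_no, line.split("\t")))

    if columns is None:
        raise ScoringFileError("no column header line found")

    col_idx = {name: i for i, name in enumerate(columns)}

    if "effect_allele" not in col_idx:
        raise ScoringFileError("required column effect_allele is missing")
    if "effect_weight" not in col_idx:
        raise ScoringFileError("required column effect_weight is missing")

    has_pos = ("chr_name" in col_idx and "chr_position" in col_idx) or (
        "hm_chr" in col_idx and "hm_pos" in col_idx
    )
    if not has_pos:
        if "rsID" in col_idx or "rsid" in col_idx:
            raise ScoringFileError(
                "scoring file provides only rsIDs; positional coordinates "
                "(chr_name/chr_position or hm_chr/hm_pos) are required -- "
                "rsID-only matching is not supported"
            )
        raise ScoringFileError("no coordinate columns (chr_name/chr_position) found")

    def cell(fields: list[str], name: str) -> str | None:
        i = col_idx.get(name)
        if i is None or i >= len(fields):
            return None
        val = fields[i].strip()
        return val if val not in ("", ".", "NA", "nan", "None") else None

    variants: list[ScoreVariant] = []
    seen: set[tuple] = set()
    for line_no, fields in rows:
        # harmonized coordinates win over author-reported ones
        chrom = cell(fields, "hm_chr") or cell(fields, "chr_name")
        pos_raw = cell(fields, "hm_pos") or cell(fields, "chr_position")
        if chrom is None or pos_raw is None:
            raise ScoringFileError(f"line {line_no}: missing coordinates")
        try:
            pos = int(pos_raw)
        except ValueError:
            raise ScoringFileError(
                f"line {line_no}: non-integer position {pos_raw!r}"
            ) from None

        ea = cell(fields, "effect_allele")
        if ea is None:
            raise ScoringFileError(f"line {line_no}: missing effect_allele")
        oa = cell(fields, "other_allele")
        if oa is None:
            oa = cell(fields, "hm_inferOtherAllele")

        weight_raw = cell(fields, "effect_weight")
        if weight_raw is None:
            raise ScoringFileError(f"line {line_no}: missing effect_weight")
        try:
            weight = float(weight_raw)
        except ValueError:
            raise ScoringFileError(
                f"line {line_no}: non-numeric effect_weight {weight_raw!r}"
            ) from None

        dom = cell(fields, "is_dominant")
        rec = cell(fields, "is_recessive")
        is_dom = _parse_bool(dom, line_no, "is_dominant") if dom is not None else False
        is_rec = _parse_bool(rec, line_no, "is_recessive") if rec is not None else False
        if is_dom and is_rec:
            raise ScoringFileError(
                f"line {line_no}: variant flagged both dominant and recessive"
            )
        effect_type = "dominant" if is_dom else "recessive" if is_rec else "additive"

        rsid = cell(fields, "rsID") or cell(fields, "rsid")

        sv = ScoreVariant(
            chr_name=str(chrom),
            chr_position=pos,
            effect_allele=ea.upper(),
            other_allele=oa.upper() if oa is not None else None,
            effect_weight=weight,
            effect_type=effect_type,
            rsid=rsid,
        )
        if sv.key in seen:
            raise ScoringFileError(
                f"line {line_no}: duplicate variant tuple {sv.key}"
            )
        seen.add(sv.key)
        variants.append(sv)

    pgs_id = header_meta.get("pgs_id") or default_id
    if pgs_id is None:
        raise ScoringFileError("no pgs_id in header and no default_id given")

    build = header_meta.get("HmPOS_build") or header_meta.get("genome_build")
    if build in ("NR", "", None):
        build = None

    trait = header_meta.get("trait_reported") or header_meta.get("trait_mapped")

    return ScoringFile(
        pgs_id=pgs_id,
        variants=variants,
        genome_build=build,
        trait_label=trait,
        header_meta=header_meta,
    )


def write_scoring_file(sf: ScoringFile, sink: str | Path | IO) -> None:
    """Write a ScoringFile back to the on-disk format (round-trip safe)."""
    lines: list[str] = [f"#pgs_id={sf.pgs_id}"]
    if sf.genome_build is not None:
        lines.append(f"#genome_build={sf.genome_build}")
    if sf.trait_label is not None:
        lines.append(f"#trait_reported={sf.trait_label}")
    for key, value in sf.header_meta.items():
        if key in ("pgs_id", "genome_build", "HmPOS_build", "trait_reported"):
            continue
        lines.append(f"#{key}={value}")

    has_flags = any(v.effect_type != "additive" for v in sf.variants)
    has_rsid = any(v.rsid is not None for v in sf.variants)
    cols = ["chr_name", "chr_position", "effect_allele", "other_allele", "effect_weight"]
    if has_flags:
        cols += ["is_dominant", "is_recessive"]
    if has_rsid:
        cols.append("rsID")
    lines.append("\t".join(cols))

    for v in sf.variants:
        row = [
            v.chr_name,
            str(v.chr_position),
            v.effect_allele,
            v.other_allele if v.other_allele is not None else "",
            repr(v.effect_weight),
        ]
        if has_flags:
            row += [
                str(v.effect_type == "dominant"),
                str(v.effect_type == "recessive"),
            ]
        if has_rsid:
            row.append(v.rsid if v.rsid is not None else "")
        lines.append("\t".join(row))

    text = "\n".join(lines) + "\n"
    if isinstance(sink, (str, Path)):
        path = Path(sink)
        if path.suffix == ".gz":
            # fileobj + pinned mtime so identical content gives identical bytes
            with open(path, "wb") as raw, gzip.GzipFile(
                filename="", fileobj=raw, mode="wb", mtime=0
            ) as gz:
                gz.write(text.encode())
        else:
            path.write_text(text)
    else:
        sink.write(text)


def validate_build(
    sf: ScoringFile,
    target_build: str,
    *,
    override_unknown: bool = False,
) -> None:
    """Check the scoring file's genome build against the target's.

    An unknown build passes only with ``override_unknown`` (logged as a
    warning); any stated mismatch is a hard error, because scoring on wrong
    coordinates silently corrupts every downstream number.
    """
    if sf.genome_build is None:
        if override_unknown:
            logger.warning(
                "scoring file %s has unknown genome build; proceeding on user "
                "override assuming %s",
                sf.pgs_id,
                target_build,
            )
            return
        raise BuildMismatchError(
            f"scoring file {sf.pgs_id} has unknown genome build and target is "
            f"{target_build}; pass override to proceed"
        )
    if sf.genome_build != target_build:
        raise BuildMismatchError(
            f"genome build mismatch for {sf.pgs_id}: scoring file is "
            f"{sf.genome_build}, target is {target_build}"
        )


COMBINED_KEY_COLUMNS = [
    "chr_name",
    "chr_position",
    "effect_allele",
    "other_allele",
    "effect_type",
]


def combine_scoring_files(files: list[ScoringFile]) -> pd.DataFrame:
    """Union scoring files into one table keyed by variant, one weight
    column per score (named by pgs_id; NaN where a score lacks the variant).

    A variant shared by k scores appears once with k weights.  Two files
    with the same pgs_id are an error.
    """
    if not files:
        raise ScoringFileError("no scoring files to combine")
    ids = [sf.pgs_id for sf in files]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ScoringFileError(f"duplicate pgs_id across scoring files: {dupes}")

    # row order: first appearance across files, file order preserved
    index: dict[tuple, int] = {}
    records: list[dict] = []
    for sf in files:
        for v in sf.variants:
            key = (v.chr_name, v.chr_position, v.effect_allele, v.other_allele)
            if key not in index:
                index[key] = len(records)
                records.append(
                    {
                        "chr_name": v.chr_name,
                        "chr_position": v.chr_position,
                        "effect_allele": v.effect_allele,
                        "other_allele": v.other_allele,
                        "effect_type": v.effect_type,
                    }
                )
            else:
                prev = records[index[key]]
                if prev["effect_type"] != v.effect_type:
                    raise ScoringFileError(
                        f"conflicting effect_type for variant {key} across scores"
                    )
            records[index[key]][sf.pgs_id] = v.effect_weight

    df = pd.DataFrame.from_records(records)
    for pgs_id in ids:
        if pgs_id not in df.columns:
            df[pgs_id] = float("nan")
        df[pgs_id] = df[pgs_id].astype(float)
    return df[COMBINED_KEY_COLUMNS + ids]


def write_combined_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write the combined scoring table as TSV."""
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
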