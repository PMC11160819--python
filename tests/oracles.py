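"""Independent brute-force oracles the implementation is checked against.

These deliberately re-derive results from first principles -- literal
enumeration of orientation/strand combinations, nested-loop summation,
full-rank decompositions -- and share no code with the package internals
they verify.
"""

from __future__ import annotations

import math

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _rc(allele: str) -> str | None:
    try:
        return "".join(_COMP[b] for b in reversed(allele))
    except KeyError:
        return None


# the stated preference order: non-flipped before flipped, other-allele-
# resolved before effect-allele-only, alt-orientation before ref-orientation
PREFERENCE = ["altref", "refalt", "altref_flip", "refalt_flip", "no_oa_alt", "no_oa_ref"]


def classify_by_enumeration(ea: str, oa: str | None, ref: str, alt: str):
    """Try every orientation x strand arrangement in priority order; return
    (class, ambiguous) for the first that fires, or ("unmatched", amb)."""
    if oa is not None:
        ambiguous = _rc(ea) == oa
        arrangements = [
            ("altref", ea == alt and oa == ref),
            ("refalt", ea == ref and oa == alt),
            ("altref_flip", _rc(ea) == alt and _rc(oa) == ref),
            ("refalt_flip", _rc(ea) == ref and _rc(oa) == alt),
        ]
    else:
        if ea == alt:
            ambiguous = _rc(ea) == ref
        elif ea == ref:
            ambiguous = _rc(ea) == alt
        else:
            ambiguous = False
        arrangements = [
            ("no_oa_alt", ea == alt),
            ("no_oa_ref", ea == ref),
        ]
    for name, fires in arrangements:
        if fires:
            return name, ambiguous
    return "unmatched", ambiguous


def brute_force_match(combined, block, params):
    """Literal matcher: enumerate every (score variant, target variant)
    pair over the whole block, classify by enumeration, filter by policy,
    apply the preference order, first target wins ties.

    Returns a list of dicts (kept, match_class, exclusion_reason,
    target_index), one per combined-table row in order.
    """
    out = []
    for row in combined.itertuples(index=False):
        chrom, pos = str(row.chr_name), int(row.chr_position)
        ea = row.effect_allele
        oa = row.other_allele if isinstance(row.other_allele, str) else None

        candidates = []  # (rank, target_index, class, ambiguous, multi)
        for ti, tv in enumerate(block.variants):
            if tv.chrom != chrom or tv.pos != pos:
                continue
            cls, amb = classify_by_enumeration(ea, oa, tv.ref, tv.alts[0])
            if cls == "unmatched":
                continue
            candidates.append(
                (PREFERENCE.index(cls), ti, cls, amb, tv.from_multiallelic)
            )

        allowed = [
            c
            for c in candidates
            if (params.keep_ambiguous or not c[3])
            and (params.keep_multiallelic or not c[4])
        ]
        if allowed:
            allowed.sort(key=lambda c: (c[0], c[1]))
            rank, ti, cls, amb, multi = allowed[0]
            out.append(
                {
                    "kept": True,
                    "match_class": cls,
                    "exclusion_reason": None,
                    "target_index": ti,
                }
            )
        elif candidates:
            candidates.sort(key=lambda c: (c[0], c[1]))
            rank, ti, cls, amb, multi = candidates[0]
            reason = "ambiguous" if (amb and not params.keep_ambiguous) else "multiallelic"
            out.append(
                {
                    "kept": False,
                    "match_class": cls,
                    "exclusion_reason": reason,
                    "target_index": ti,
                }
            )
        else:
            out.append(
                {
                    "kept": False,
                    "match_class": "unmatched",
                    "exclusion_reason": "unmatched",
                    "target_index": None,
                }
            )
    return out


def nested_loop_score(block, plans):
    """Naive per-sample, per-variant scoring loop (file order).

    Returns {(score_id, sample_id): (sum, denom, n_used)}.
    """
    out = {}
    for sid, entries in plans.items():
        for i, sample_id in enumerate(block.sample_ids):
            total = 0.0
            used = 0
            for e in entries:
                d = block.dosages[i, e.target_index]
                if isinstance(d, float) and math.isnan(d):
                    continue
                x = 2.0 - d if e.reverse else d
                if e.effect_type == "dominant":
                    x = 1.0 if x >= 0.5 else 0.0
                elif e.effect_type == "recessive":
                    x = 1.0 if x >= 1.5 else 0.0
                total += e.weight * x
                used += 1
            out[(sid, sample_id)] = (total, 2 * used, used)
    return out


def full_pca_projection_oracle(model, z: np.ndarray) -> np.ndarray:
    """Coordinates of a new standardized sample from a *full-rank* PCA of
    the augmented (reference + sample) matrix, Procrustes-aligned back onto
    the model's reference coordinates.  Own Procrustes via the SVD of the
    cross-covariance."""
    A = np.vstack([model.ref_std, z[None, :]])
    U, S, _ = np.linalg.svd(A, full_matrices=False)
    coords = (U * S)[:, : model.K]
    X, Y = coords[:-1], model.ref_coords
    muX, muY = X.mean(axis=0), Y.mean(axis=0)
    X0, Y0 = X - muX, Y - muY
    Um, Sm, Vtm = np.linalg.svd(X0.T @ Y0)
    R = Um @ Vtm
    scale = Sm.sum() / (X0**2).sum()
    return scale * (coords[-1] - muX) @ R + muY
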