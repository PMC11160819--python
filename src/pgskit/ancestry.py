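"""Genetic-ancestry estimation against a labelled reference panel.

The pipeline: intersect panel and target variants (reconciling ref/alt
orientation and strand, dropping palindromic sites whose strand is
undecidable), LD-prune the overlap, fit a PCA of the standardized reference
dosages, project each target sample into that PC space, and report the
reference population each target is *most similar* to -- similarity, not an
ancestry label, because reference population labels are neither exhaustive
nor deterministic.

Projection offers two methods.  The naive projection (dosage vector times
loadings) is biased toward the origin when reference samples are far fewer
than variants (PCA shrinkage).  The OADP method (online augmentation,
decomposition and Procrustes) avoids this: the sample row is appended to
the standardized reference matrix, the augmented matrix is re-decomposed,
and a Procrustes transform (rotation + isotropic scale + translation)
mapping the augmented reference coordinates back onto the model's
coordinates is applied to the new sample's augmented coordinates.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.linalg import orthogonal_procrustes

from .genotypes import GenotypeBlock
from .matching import is_palindromic_pair, reverse_complement, _revcomp_or_none

logger = logging.getLogger(__name__)


class AncestryError(ValueError):
    """Invalid ancestry-analysis inputs."""


@dataclass
class ReferencePanel:
    """A genotyped reference panel with per-sample population labels."""

    block: GenotypeBlock
    labels: dict[str, str]

    def __post_init__(self) -> None:
        missing = [s for s in self.block.sample_ids if s not in self.labels]
        if missing:
            raise AncestryError(f"{len(missing)} panel samples lack labels: {missing[:5]}")
        counts: dict[str, int] = {}
        for s in self.block.sample_ids:
            counts[self.labels[s]] = counts.get(self.labels[s], 0) + 1
        if len(counts) < 2:
            raise AncestryError("reference panel needs >= 2 distinct populations")
        small = {p: c for p, c in counts.items() if c < 3}
        if small:
            raise AncestryError(f"populations with < 3 samples: {small}")

    def population_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for s in self.block.sample_ids:
            counts[self.labels[s]] = counts.get(self.labels[s], 0) + 1
        return counts


@dataclass
class VariantOverlap:
    """Panel/target variant intersection with orientation reconciliation.

    ``flip_target[i]`` means the target's alt is the panel's ref, so the
    target dosage must be reflected (2 - d) to count the same allele.
    """

    keys: list[tuple[str, int, str, str]]  # panel orientation (chrom,pos,ref,alt)
    panel_indices: np.ndarray
    target_indices: np.ndarray
    flip_target: np.ndarray

    def __len__(self) -> int:
        return len(self.keys)


def overlap_variants(
    panel: ReferencePanel,
    target: GenotypeBlock,
    *,
    min_count: int = 100,
) -> VariantOverlap:
    """Intersect panel and target variants by position and allele pair.

    Allele pairs are matched up to orientation (ref/alt swap) and strand
    (reverse complement); palindromic pairs are excluded unconditionally --
    a strand error here distorts the whole ancestry space.  Multi-allelic
    splits on either side are skipped.
    """
    tindex: dict[tuple[str, int], list[int]] = {}
    for j, tv in enumerate(target.variants):
        tindex.setdefault((tv.chrom, tv.pos), []).append(j)

    keys, p_idx, t_idx, flips = [], [], [], []
    for i, pv in enumerate(panel.block.variants):
        if pv.from_multiallelic or is_palindromic_pair(pv.ref, pv.alt):
            continue
        rc_ref = _revcomp_or_none(pv.ref)
        rc_alt = _revcomp_or_none(pv.alt)
        for j in tindex.get((pv.chrom, pv.pos), []):
            tv = target.variants[j]
            if tv.from_multiallelic:
                continue
            pair = (tv.ref, tv.alt)
            if pair == (pv.ref, pv.alt):
                flip = False
            elif pair == (pv.alt, pv.ref):
                flip = True
            elif rc_ref is not None and pair == (rc_ref, rc_alt):
                flip = False
            elif rc_ref is not None and pair == (rc_alt, rc_ref):
                flip = True
            else:
                continue
            keys.append((pv.chrom, pv.pos, pv.ref, pv.alt))
            p_idx.append(i)
            t_idx.append(j)
            flips.append(flip)
            break

    if len(keys) < min_count:
        raise AncestryError(
            f"only {len(keys)} overlapping variants between panel and target "
            f"(minimum {min_count})"
        )
    return VariantOverlap(
        keys=keys,
        panel_indices=np.asarray(p_idx, dtype=int),
        target_indices=np.asarray(t_idx, dtype=int),
        flip_target=np.asarray(flips, dtype=bool),
    )


def aligned_target_dosages(target: GenotypeBlock, overlap: VariantOverlap) -> np.ndarray:
    """Target dosage matrix aligned to the overlap (flips applied, nan kept)."""
    d = target.dosages[:, overlap.target_indices].copy()
    d[:, overlap.flip_target] = 2.0 - d[:, overlap.flip_target]
    return d


def prune_ld(
    dosages: np.ndarray,
    *,
    r2_threshold: float = 0.1,
    window: int = 250,
    step: int = 25,
) -> np.ndarray:
    """Greedy windowed LD pruning on a samples x variants dosage matrix.

    Windows of ``window`` variants are scanned in coordinate order,
    advancing by ``step``; whenever two still-kept variants in a window have
    squared Pearson correlation above the threshold, the later one is
    dropped.  Deterministic.  Returns the kept column indices.
    """
    m = dosages.shape[1]
    if m < 2:
        return np.arange(m)
    X = dosages.copy()
    mu = np.nanmean(X, axis=0)
    nan_mask = np.isnan(X)
    if nan_mask.any():
        X[nan_mask] = np.take(mu, np.nonzero(nan_mask)[1])

    keep = np.ones(m, dtype=bool)
    for start in range(0, m, step):
        stop = min(start + window, m)
        idx = np.nonzero(keep[start:stop])[0] + start
        if len(idx) < 2:
            if stop == m:
                break
            continue
        sub = X[:, idx]
        sd = sub.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(sub, rowvar=False)
        for a in range(len(idx)):
            if not keep[idx[a]]:
                continue
            for b in range(a + 1, len(idx)):
                if not keep[idx[b]]:
                    continue
                if sd[a] == 0 or sd[b] == 0:
                    continue
                if corr[a, b] ** 2 > r2_threshold:
                    keep[idx[b]] = False
        if stop == m:
            break
    return np.nonzero(keep)[0]


@dataclass
class PCAModel:
    """PCA of the standardized reference panel on the pruned overlap.

    Standardization is per variant: (d - mu) / sigma with mu the mean
    dosage (2 x allele frequency) and sigma the binomial scale
    sqrt(2 (mu/2)(1 - mu/2)).  ``loadings`` columns are orthonormal right
    singular vectors; ``ref_coords`` = U S are the reference sample
    coordinates.  ``ref_std`` (the standardized matrix) is retained for
    OADP augmentation.
    """

    variant_keys: list[tuple[str, int, str, str]]
    mu: np.ndarray
    sigma: np.ndarray
    loadings: np.ndarray  # (m, K)
    ref_coords: np.ndarray  # (n, K)
    singular_values: np.ndarray  # (K,)
    K: int
    sample_ids: list[str]
    ref_std: np.ndarray  # (n, m)
    kept_mask: np.ndarray  # bool over the variants the model was fit on

    def save(self, path: str | Path) -> None:
        """Serialize to a single .npz archive for reuse across runs."""
        np.savez_compressed(
            path,
            variant_keys=json.dumps([list(k) for k in self.variant_keys]),
            mu=self.mu,
            sigma=self.sigma,
            loadings=self.loadings,
            ref_coords=self.ref_coords,
            singular_values=self.singular_values,
            K=self.K,
            sample_ids=json.dumps(self.sample_ids),
            ref_std=self.ref_std,
            kept_mask=self.kept_mask,
        )

    @classmethod
    def load(cls, path: str | Path) -> "PCAModel":
        with np.load(path, allow_pickle=False) as z:
            return cls(
                variant_keys=[
                    (str(c), int(p), str(r), str(a))
                    for c, p, r, a in json.loads(str(z["variant_keys"]))
                ],
                mu=z["mu"],
                sigma=z["sigma"],
                loadings=z["loadings"],
                ref_coords=z["ref_coords"],
                singular_values=z["singular_values"],
                K=int(z["K"]),
                sample_ids=json.loads(str(z["sample_ids"])),
                ref_std=z["ref_std"],
                kept_mask=z["kept_mask"],
            )


@dataclass(frozen=True)
class Projection:
    """One sample's coordinates in the reference PC space."""

    sample_id: str
    coords: np.ndarray
    method: str

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coords)):
            raise AncestryError(f"non-finite projection for {self.sample_id}")


def fit_reference_pca(
    block: GenotypeBlock,
    keys: Sequence[tuple[str, int, str, str]],
    K: int = 10,
) -> PCAModel:
    """Fit the reference PCA on a (pruned-overlap) genotype block.

    Missing reference dosages are mean-filled before standardization;
    monomorphic variants (sigma = 0) are dropped and recorded in
    ``kept_mask``.  The sign convention -- each loading column's
    largest-magnitude entry positive -- makes refits reproducible.
    """
    X = block.dosages.copy()
    nan_mask = np.isnan(X)
    mu = np.nanmean(X, axis=0)
    if nan_mask.any():
        X[nan_mask] = np.take(mu, np.nonzero(nan_mask)[1])

    p = mu / 2.0
    sigma = np.sqrt(2.0 * p * (1.0 - p))
    kept = sigma > 0
    if kept.sum() < 2:
        raise AncestryError("fewer than 2 polymorphic variants for PCA")
    Xk = X[:, kept]
    muk, sigk = mu[kept], sigma[kept]
    Z = (Xk - muk) / sigk

    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    rank = int(np.sum(S > S[0] * 1e-9)) if S.size else 0
    if K > rank:
        raise AncestryError(f"K={K} exceeds the rank ({rank}) of the reference matrix")

    V = Vt[:K].T  # (m, K)
    # sign convention: largest-|entry| of each loading column is positive
    for k in range(K):
        j = int(np.argmax(np.abs(V[:, k])))
        if V[j, k] < 0:
            V[:, k] = -V[:, k]
            U[:, k] = -U[:, k]

    keys_kept = [keys[i] for i in np.nonzero(kept)[0]]
    return PCAModel(
        variant_keys=keys_kept,
        mu=muk,
        sigma=sigk,
        loadings=V,
        ref_coords=U[:, :K] * S[:K],
        singular_values=S[:K].copy(),
        K=K,
        sample_ids=list(block.sample_ids),
        ref_std=Z,
        kept_mask=kept,
    )


def standardize_sample(model: PCAModel, raw_dosages: np.ndarray) -> np.ndarray:
    """Standardize one sample's raw dosage vector (aligned to the model's
    variant keys) with the model's mu/sigma; missing entries become 0 --
    i.e. they are filled with the reference mean."""
    if raw_dosages.shape[-1] != len(model.variant_keys):
        raise AncestryError(
            f"vector length {raw_dosages.shape[-1]} != model variants "
            f"{len(model.variant_keys)}"
        )
    z = (raw_dosages - model.mu) / model.sigma
    return np.where(np.isnan(z), 0.0, z)


def project_naive(
    model: PCAModel,
    z: np.ndarray,
    sample_id: str = "",
) -> Projection:
    """Project a standardized sample vector directly onto the loadings.

    Fast but shrinkage-biased toward the origin when K is well below the
    variant count; the unbiased alternative is :func:`project_oadp`.
    """
    if z.shape[-1] != model.loadings.shape[0]:
        raise AncestryError("standardized vector length does not match loadings")
    return Projection(sample_id=sample_id, coords=z @ model.loadings, method="naive")


def _procrustes_map(X: np.ndarray, Y: np.ndarray):
    """Transform (rotation + isotropic scale + translation) minimizing
    ||f(X) - Y||_F; returns the mapping function."""
    muX, muY = X.mean(axis=0), Y.mean(axis=0)
    X0, Y0 = X - muX, Y - muY
    normX2 = float((X0**2).sum())
    if normX2 == 0:
        raise AncestryError("degenerate Procrustes problem: zero variance")
    R, s = orthogonal_procrustes(X0, Y0)
    scale = s / normX2

    def apply(P: np.ndarray) -> np.ndarray:
        return scale * ((P - muX) @ R) + muY

    return apply


def project_oadp(
    model: PCAModel,
    z: np.ndarray,
    sample_id: str = "",
    *,
    s_extra: int = 2,
) -> Projection:
    """Project a standardized sample vector with OADP.

    The sample row augments the standardized reference matrix; the top
    K + s_extra singular subspace of the augmented matrix is computed (a
    direct decomposition -- exact at this scale); the augmented reference
    coordinates in the top K dimensions are Procrustes-mapped onto the
    model's reference coordinates, and the same map is applied to the new
    row's coordinates.
    """
    if z.shape[-1] != model.loadings.shape[0]:
        raise AncestryError("standardized vector length does not match loadings")
    A = np.vstack([model.ref_std, z[None, :]])
    U, S, _ = np.linalg.svd(A, full_matrices=False)
    k2 = min(model.K + s_extra, len(S))
    coords_aug = U[:, :k2] * S[:k2]
    ref_aug = coords_aug[:-1, : model.K]
    x_aug = coords_aug[-1, : model.K]
    mapping = _procrustes_map(ref_aug, model.ref_coords)
    return Projection(
        sample_id=sample_id, coords=mapping(x_aug[None, :])[0], method="oadp"
    )


def project_samples(
    model: PCAModel,
    raw_matrix: np.ndarray,
    sample_ids: Sequence[str],
    *,
    method: str = "oadp",
    s_extra: int = 2,
) -> list[Projection]:
    """Project many samples (rows of a model-aligned raw dosage matrix)."""
    if method not in ("oadp", "naive"):
        raise AncestryError(f"unknown projection method {method!r}")
    out = []
    for i, sid in enumerate(sample_ids):
        z = standardize_sample(model, raw_matrix[i])
        if method == "oadp":
            out.append(project_oadp(model, z, sid, s_extra=s_extra))
        else:
            out.append(project_naive(model, z, sid))
    return out


@dataclass(frozen=True)
class AncestryAssignment:
    """Most-similar reference population with per-population distances."""

    sample_id: str
    most_similar_pop: str
    distances: dict[str, float]


def population_pc_stats(
    model: PCAModel, labels: dict[str, str], *, ridge: float = 1e-6
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-population (centroid, inverse covariance) in reference PC space.

    Covariances are ridge-regularized (+ ridge x I) so small populations
    stay invertible.
    """
    pops: dict[str, list[int]] = {}
    for i, sid in enumerate(model.sample_ids):
        pops.setdefault(labels[sid], []).append(i)
    stats: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for pop in sorted(pops):
        coords = model.ref_coords[pops[pop]]
        centroid = coords.mean(axis=0)
        cov = np.cov(coords, rowvar=False, ddof=1) + ridge * np.eye(model.K)
        try:
            inv = np.linalg.inv(cov)
        except np.linalg.LinAlgError as exc:
            raise AncestryError(
                f"population {pop} has singular PC covariance even after "
                "regularization"
            ) from exc
        stats[pop] = (centroid, inv)
    return stats


def assign_population(
    proj: Projection,
    model: PCAModel,
    labels: dict[str, str],
    *,
    stats: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
) -> AncestryAssignment:
    """Assign the most similar reference population by Mahalanobis distance
    to each population's PC centroid.  Exact ties break to the
    lexicographically first label (and are logged)."""
    if stats is None:
        stats = population_pc_stats(model, labels)
    distances: dict[str, float] = {}
    for pop in sorted(stats):
        centroid, inv = stats[pop]
        delta = proj.coords - centroid
        distances[pop] = float(np.sqrt(delta @ inv @ delta))
    best = min(sorted(distances), key=lambda p: distances[p])
    ties = [p for p in distances if distances[p] == distances[best] and p != best]
    if ties:
        logger.info(
            "sample %s equidistant to populations %s; keeping %s",
            proj.sample_id,
            [best] + ties,
            best,
        )
    return AncestryAssignment(
        sample_id=proj.sample_id, most_similar_pop=best, distances=distances
    )


def assign_populations(
    projections: Sequence[Projection],
    model: PCAModel,
    labels: dict[str, str],
) -> list[AncestryAssignment]:
    stats = population_pc_stats(model, labels)
    return [assign_population(p, model, labels, stats=stats) for p in projections]
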