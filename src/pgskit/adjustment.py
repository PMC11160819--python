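"""Normalizing raw polygenic scores onto ancestry-comparable relative scales.

Raw PGS sums are confounded by genetic ancestry: allele-frequency and LD
differences shift both the mean and the variance of the score distribution
between populations without implying any difference in risk.  Three
standard relative scales are produced for every sample, always together:

* ``Z_MostSimilarPop`` -- the empirical method: standardize against the
  score distribution of the sample's most similar reference population
  (also reported as a mid-rank percentile of that distribution);
* ``Z_norm1`` -- label-free mean correction: the residual of the score from
  an OLS regression of reference scores on the reference PCs, divided by
  the reference residual standard deviation;
* ``Z_norm2`` -- additionally corrects ancestry-dependent *variance*: the
  same residual divided by a predicted standard deviation from a second OLS
  regression of squared residuals on the PCs (floored to stay positive).

The reference panel must be scored with exactly the kept-variant set used
for the targets; a different match rate on the panel would silently shift
every reference distribution.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_EPS_SD = 1e-12


class AdjustmentError(ValueError):
    """Invalid adjustment inputs."""


@dataclass
class PopStats:
    """Reference score distribution of one population."""

    mean: float
    sd: float
    sorted_sums: np.ndarray

    @property
    def n(self) -> int:
        return len(self.sorted_sums)


@dataclass
class AdjustmentModel:
    """Fitted normalization model for one score.

    ``mean_coefs`` and ``var_coefs`` are length K+1 (intercept first) for
    E[SUM | PCs] and E[resid^2 | PCs]; ``var_floor`` keeps the predicted
    variance positive where the linear variance model goes negative.
    """

    score_id: str
    ref_pop_stats: dict[str, PopStats]
    mean_coefs: np.ndarray
    resid_sd: float
    var_coefs: np.ndarray
    var_floor: float
    K: int

    def __post_init__(self) -> None:
        for pop, st in self.ref_pop_stats.items():
            if not st.sd > 0:
                raise AdjustmentError(f"population {pop} has zero score sd")
        if not self.resid_sd > 0:
            raise AdjustmentError("resid_sd must be positive")


@dataclass
class AdjustedScore:
    """All relative-scale representations of one sample's score."""

    sample_id: str
    score_id: str
    sum_raw: float
    most_similar_pop: str
    percentile_MostSimilarPop: float
    Z_MostSimilarPop: float
    Z_norm1: float
    Z_norm2: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.percentile_MostSimilarPop <= 1.0:
            raise AdjustmentError("percentile must lie in [0, 1]")
        for z in (self.Z_MostSimilarPop, self.Z_norm1, self.Z_norm2):
            if not math.isfinite(z):
                raise AdjustmentError("adjusted Z values must be finite")


def _design(coords: np.ndarray) -> np.ndarray:
    coords = np.atleast_2d(coords)
    return np.column_stack([np.ones(len(coords)), coords])


def fit_adjustment_model(
    sums: np.ndarray,
    coords: np.ndarray,
    labels: Sequence[str],
    *,
    score_id: str = "score",
) -> AdjustmentModel:
    """Fit the normalization model on the scored reference panel.

    Pooled OLS of SUM on [1, PC1..PCK] over all reference samples gives the
    ancestry mean model; the residual sd and a second pooled OLS of squared
    residuals on the same design give the variance model.  Populations need
    >= 3 samples each for usable empirical distributions.
    """
    sums = np.asarray(sums, dtype=float)
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if len(sums) != len(coords) or len(sums) != len(labels):
        raise AdjustmentError("sums, coords and labels must align")
    K = coords.shape[1]

    counts: dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    small = {p: c for p, c in counts.items() if c < 3}
    if small:
        raise AdjustmentError(f"populations with < 3 reference samples: {small}")

    X = _design(coords)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise AdjustmentError("singular regression design (constant PC column?)")

    mean_coefs, *_ = np.linalg.lstsq(X, sums, rcond=None)
    resid = sums - X @ mean_coefs
    resid_sd = float(np.std(resid, ddof=1))
    if resid_sd <= _EPS_SD:
        logger.warning(
            "score %s: residual sd ~ 0 (score fully explained by PCs); "
            "guarding to epsilon",
            score_id,
        )
        resid_sd = _EPS_SD
    var_coefs, *_ = np.linalg.lstsq(X, resid**2, rcond=None)
    var_floor = 0.01 * resid_sd**2

    pop_stats: dict[str, PopStats] = {}
    labels_arr = np.asarray(labels)
    for pop in sorted(counts):
        vals = np.sort(sums[labels_arr == pop])
        sd = float(np.std(vals, ddof=1))
        if sd <= 0:
            raise AdjustmentError(f"population {pop} has constant reference scores")
        pop_stats[pop] = PopStats(mean=float(vals.mean()), sd=sd, sorted_sums=vals)

    return AdjustmentModel(
        score_id=score_id,
        ref_pop_stats=pop_stats,
        mean_coefs=mean_coefs,
        resid_sd=resid_sd,
        var_coefs=var_coefs,
        var_floor=var_floor,
        K=K,
    )


def empirical_adjust(
    sum_raw: float,
    most_similar_pop: str,
    model: AdjustmentModel,
) -> tuple[float, float]:
    """Empirical normalization against the most similar population.

    Returns (percentile, Z).  The percentile uses the mid-rank convention:
    ties count half, so reference samples' own percentiles are uniform.
    """
    if most_similar_pop not in model.ref_pop_stats:
        raise AdjustmentError(
            f"population {most_similar_pop!r} not in the reference model "
            f"(known: {sorted(model.ref_pop_stats)})"
        )
    st = model.ref_pop_stats[most_similar_pop]
    z = (sum_raw - st.mean) / st.sd
    below = int(np.searchsorted(st.sorted_sums, sum_raw, side="left"))
    equal = int(np.searchsorted(st.sorted_sums, sum_raw, side="right")) - below
    percentile = (below + 0.5 * equal) / st.n
    return percentile, z


def regression_adjust(
    sum_raw: float,
    coords: np.ndarray,
    model: AdjustmentModel,
) -> tuple[float, float]:
    """PC-regression normalization: returns (Z_norm1, Z_norm2).

    Z_norm1 removes the ancestry-predicted mean; Z_norm2 also divides by
    the ancestry-predicted sd, floored at var_floor so the result is always
    finite (a floored prediction is logged).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[-1] != model.K:
        raise AdjustmentError(f"coords length {coords.shape[-1]} != model K {model.K}")
    x = np.concatenate([[1.0], coords])
    pred_mean = float(x @ model.mean_coefs)
    resid = sum_raw - pred_mean
    z1 = resid / model.resid_sd
    pred_var = float(x @ model.var_coefs)
    if pred_var < model.var_floor:
        logger.debug(
            "predicted variance %.3g below floor %.3g; flooring",
            pred_var,
            model.var_floor,
        )
        pred_var = model.var_floor
    z2 = resid / math.sqrt(pred_var)
    return z1, z2


def adjust_scores(
    score_results: Sequence,
    assignments: dict[str, str],
    projections: dict[str, np.ndarray],
    model: AdjustmentModel,
) -> list[AdjustedScore]:
    """Adjust a batch of ScoreResults (same score) with one fitted model."""
    out: list[AdjustedScore] = []
    for res in score_results:
        pop = assignments[res.sample_id]
        pct, z_pop = empirical_adjust(res.sum, pop, model)
        z1, z2 = regression_adjust(res.sum, projections[res.sample_id], model)
        out.append(
            AdjustedScore(
                sample_id=res.sample_id,
                score_id=res.score_id,
                sum_raw=res.sum,
                most_similar_pop=pop,
                percentile_MostSimilarPop=pct,
                Z_MostSimilarPop=z_pop,
                Z_norm1=z1,
                Z_norm2=z2,
            )
        )
    return out


def adjusted_to_frame(adjusted: Sequence[AdjustedScore]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [a.sample_id for a in adjusted],
            "score_id": [a.score_id for a in adjusted],
            "sum_raw": [a.sum_raw for a in adjusted],
            "most_similar_pop": [a.most_similar_pop for a in adjusted],
            "percentile_MostSimilarPop": [a.percentile_MostSimilarPop for a in adjusted],
            "Z_MostSimilarPop": [a.Z_MostSimilarPop for a in adjusted],
            "Z_norm1": [a.Z_norm1 for a in adjusted],
            "Z_norm2": [a.Z_norm2 for a in adjusted],
        }
    )


def write_adjusted_scores(adjusted: Sequence[AdjustedScore], path: str | Path) -> None:
    adjusted_to_frame(adjusted).to_csv(path, sep="\t", index=False, float_format="%.10g")
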