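"""Bias-corrected, performance-weighted consensus bone age from a rater panel.

The reference rating is built in four steps:

1. **Initial consensus** — the unweighted mean of the available ratings per
   image.
2. **Exclusions** — images with any missing rating, or with any single
   rating deviating strictly more than a threshold (default 30 months) from
   the initial mean, are dropped.
3. **Rater profiles** — each rater's signed mean difference (SMD) against
   the initial mean is their additive bias; the mean absolute difference
   (MAD) of the *bias-corrected* rater against the initial mean measures
   their precision; consensus weights are proportional to 1/MAD and
   normalized to sum to 1.
4. **Weighted consensus** — per image, the weighted average of the
   bias-corrected ratings.

Both statistics are anchored to the initial, uncorrected mean in a single
pass; an optional iterative mode re-estimates them against the weighted
consensus until convergence but is off by default.

Leave-one-rater-out consensus re-runs the full pipeline on the reduced
panel, so a held-out rater (or the AI) can be benchmarked against the
consensus of the remaining raters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort

__all__ = [
    "RaterProfile",
    "ConsensusResult",
    "ConsensusError",
    "initial_consensus",
    "apply_exclusions",
    "fit_rater_profiles",
    "build_consensus",
    "consensus_pipeline",
    "leave_one_out_consensus",
]

REASON_MISSING = "missing_rating"
REASON_DEVIATION = "deviation_gt_threshold"


class ConsensusError(ValueError):
    pass


@dataclass(frozen=True)
class RaterProfile:
    """A rater's bias, precision, and normalized consensus weight."""

    rater_id: str
    smd_bias: float  # months, signed mean difference vs. initial consensus
    mad: float  # months, MAD of the bias-corrected rater vs. initial consensus
    weight: float  # unitless, in (0, 1]; proportional to 1/mad across the panel


@dataclass
class ConsensusResult:
    """Per-image consensus bone age plus the panel profiles and exclusions."""

    consensus: pd.Series  # months, indexed by image_id (included images only)
    profiles: tuple[RaterProfile, ...]
    excluded: tuple[tuple[str, str], ...]  # (image_id, reason)
    included_count: int
    rater_ids: tuple[str, ...]

    @property
    def weights(self) -> np.ndarray:
        return np.array([p.weight for p in self.profiles])


def _rater_indices(cohort: Cohort, raters: Sequence[str] | None) -> list[str]:
    if raters is None:
        return list(cohort.rater_ids)
    unknown = [r for r in raters if r not in cohort.rater_ids]
    if unknown:
        raise ConsensusError(f"unknown rater ids: {unknown}")
    return list(raters)


def initial_consensus(cohort: Cohort, raters: Sequence[str] | None = None) -> pd.Series:
    """Unweighted mean of the available ratings per image.

    Raises :class:`ConsensusError` naming the images for which no rating at
    all is available.
    """
    raters = _rater_indices(cohort, raters)
    matrix = cohort.frame[raters].to_numpy(dtype=float)
    counts = np.sum(~np.isnan(matrix), axis=1)
    if np.any(counts == 0):
        ids = list(cohort.frame.loc[counts == 0, "image_id"])
        raise ConsensusError(f"images without any rating: {ids}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(matrix, axis=1)
    return pd.Series(means, index=cohort.frame["image_id"].to_numpy(), name="initial_consensus")


def apply_exclusions(
    cohort: Cohort,
    initial: pd.Series,
    deviation_threshold: float = 30.0,
    drop_missing: bool = True,
    raters: Sequence[str] | None = None,
) -> tuple[Cohort, list[tuple[str, str]]]:
    """Drop images with missing ratings and gross single-rater deviations.

    An image is excluded when (a) any rating is missing (if ``drop_missing``)
    or (b) any rating's absolute deviation from the initial mean is
    *strictly* greater than ``deviation_threshold`` months.  Returns the
    filtered cohort and the list of ``(image_id, reason)`` pairs.
    """
    if deviation_threshold <= 0:
        raise ConsensusError("deviation_threshold must be > 0 months")
    raters = _rater_indices(cohort, raters)
    matrix = cohort.frame[raters].to_numpy(dtype=float)
    init = initial.reindex(cohort.frame["image_id"]).to_numpy(dtype=float)

    has_missing = np.isnan(matrix).any(axis=1)
    with np.errstate(invalid="ignore"):
        deviation = np.abs(matrix - init[:, None])
    max_dev = np.nanmax(np.where(np.isnan(deviation), -np.inf, deviation), axis=1)
    too_far = max_dev > deviation_threshold

    excluded: list[tuple[str, str]] = []
    ids = cohort.frame["image_id"].to_numpy()
    drop = np.zeros(len(ids), dtype=bool)
    for i, image_id in enumerate(ids):
        if drop_missing and has_missing[i]:
            excluded.append((str(image_id), REASON_MISSING))
            drop[i] = True
        elif too_far[i]:
            excluded.append((str(image_id), REASON_DEVIATION))
            drop[i] = True
    filtered = Cohort(
        cohort.frame.loc[~drop].copy(), list(cohort.rater_ids), dict(cohort.provenance)
    )
    return filtered, excluded


def fit_rater_profiles(
    cohort: Cohort,
    initial: pd.Series,
    raters: Sequence[str] | None = None,
    mad_floor: float = 1e-6,
) -> tuple[RaterProfile, ...]:
    """Per-rater SMD bias, MAD, and normalized 1/MAD weight.

    For rater *j* with ratings ``r_ij`` and initial means ``m_i``::

        smd_bias_j = mean_i(r_ij - m_i)
        mad_j      = mean_i(|r_ij - smd_bias_j - m_i|)
        weight_j   = (1 / mad_j) / sum_l (1 / mad_l)

    A rater in perfect agreement (MAD 0) receives the maximal finite weight
    through the configurable ``mad_floor`` (months); a warning is emitted.
    """
    raters = _rater_indices(cohort, raters)
    matrix = cohort.frame[raters].to_numpy(dtype=float)
    if np.isnan(matrix).any():
        raise ConsensusError("rater profiles require complete ratings; apply exclusions first")
    if matrix.shape[0] == 0:
        raise ConsensusError("cannot fit rater profiles on an empty cohort")
    init = initial.reindex(cohort.frame["image_id"]).to_numpy(dtype=float)

    diffs = matrix - init[:, None]
    smd = diffs.mean(axis=0)
    mad = np.abs(diffs - smd[None, :]).mean(axis=0)
    if np.any(mad < mad_floor):
        warnings.warn(
            "rater(s) in near-perfect agreement with the initial consensus; "
            f"flooring MAD at {mad_floor} months for weighting",
            RuntimeWarning,
            stacklevel=2,
        )
    inv = 1.0 / np.maximum(mad, mad_floor)
    weights = inv / inv.sum()
    return tuple(
        RaterProfile(rater_id=r, smd_bias=float(smd[j]), mad=float(mad[j]),
                     weight=float(weights[j]))
        for j, r in enumerate(raters)
    )


def build_consensus(
    cohort: Cohort,
    profiles: Sequence[RaterProfile],
    excluded: Sequence[tuple[str, str]] = (),
) -> ConsensusResult:
    """Performance-weighted average of the bias-corrected ratings.

    ``consensus_i = sum_j weight_j * (r_ij - smd_bias_j)``.
    """
    rater_ids = [p.rater_id for p in profiles]
    if set(rater_ids) - set(cohort.rater_ids):
        raise ConsensusError(
            "profiles refer to raters absent from the cohort: "
            f"{sorted(set(rater_ids) - set(cohort.rater_ids))}"
        )
    matrix = cohort.frame[rater_ids].to_numpy(dtype=float)
    if np.isnan(matrix).any():
        raise ConsensusError("consensus requires complete ratings; apply exclusions first")
    biases = np.array([p.smd_bias for p in profiles])
    weights = np.array([p.weight for p in profiles])
    values = (matrix - biases[None, :]) @ weights
    consensus = pd.Series(
        values, index=cohort.frame["image_id"].to_numpy(), name="consensus_ba_months"
    )
    return ConsensusResult(
        consensus=consensus,
        profiles=tuple(profiles),
        excluded=tuple((str(i), str(r)) for i, r in excluded),
        included_count=len(consensus),
        rater_ids=tuple(rater_ids),
    )


def consensus_pipeline(
    cohort: Cohort,
    deviation_threshold: float = 30.0,
    drop_missing: bool = True,
    mad_floor: float = 1e-6,
    raters: Sequence[str] | None = None,
    iterate: bool = False,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> ConsensusResult:
    """Full reference-rating pipeline: initial mean, exclusions, profiles,
    weighted consensus.

    ``raters`` restricts the panel to a subset (used for leave-one-out).
    ``iterate=True`` re-anchors biases and MADs to the weighted consensus
    until convergence (off by default; the standard procedure is one pass).
    """
    raters = _rater_indices(cohort, raters)
    if len(raters) < 2:
        raise ConsensusError("consensus building requires at least 2 raters")
    initial = initial_consensus(cohort, raters)
    filtered, excluded = apply_exclusions(
        cohort, initial, deviation_threshold, drop_missing, raters
    )
    if filtered.n_images == 0:
        raise ConsensusError("all images excluded; no consensus can be built")
    reference = initial.reindex(filtered.frame["image_id"].to_numpy())
    profiles = fit_rater_profiles(filtered, reference, raters, mad_floor)
    result = build_consensus(filtered, profiles, excluded)
    if iterate:
        for _ in range(max_iter):
            previous = result.consensus
            profiles = fit_rater_profiles(filtered, previous, raters, mad_floor)
            result = build_consensus(filtered, profiles, excluded)
            if np.max(np.abs(result.consensus.to_numpy() - previous.to_numpy())) < tol:
                break
    return result


def leave_one_out_consensus(
    cohort: Cohort,
    left_out: str,
    deviation_threshold: float = 30.0,
    drop_missing: bool = True,
    mad_floor: float = 1e-6,
) -> ConsensusResult:
    """Consensus of the panel with one rater removed.

    The entire pipeline (initial mean, exclusions, profiles, weights) is
    recomputed on the remaining ``k - 1`` raters, so the held-out rater and
    the AI can be scored against an independent reference.
    """
    if left_out not in cohort.rater_ids:
        raise ConsensusError(f"unknown rater id: {left_out!r}")
    if cohort.n_raters < 3:
        raise ConsensusError("leave-one-out requires a panel of at least 3 raters")
    remaining = [r for r in cohort.rater_ids if r != left_out]
    return consensus_pipeline(
        cohort,
        deviation_threshold=deviation_threshold,
        drop_missing=drop_missing,
        mad_floor=mad_floor,
        raters=remaining,
    )
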