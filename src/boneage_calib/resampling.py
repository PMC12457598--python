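"""Stratified train/test partitioning and bootstrap re-partitioning.

The calibration set is drawn by stratified sampling over age-bin-by-sex
cells (24-month bins by default), with largest-remainder rounding of the
per-stratum train counts; every image flagged with a known disorder is
assigned to the test set before sampling.

"Bootstrap" here means repeated re-partitioning of the same cohort into
fresh calibration/test splits (without replacement), refitting the
sex-specific calibration on each calibration set and re-evaluating the test
metrics — quantifying how much the calibration parameters and the measured
performance depend on the particular split.  Replicate seeds are derived
from the master seed by counter-keyed seed sequences, so any replicate can
be reproduced independently of the others.  Percentile summaries use
NumPy's linear-interpolation quantile convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationError, CalibrationModel, fit_calibration
from .cohort import SEXES, Cohort
from .consensus import ConsensusResult

__all__ = [
    "PartitionSpec",
    "BootstrapSummary",
    "ResamplingError",
    "stratified_split",
    "replicate_seed",
    "bootstrap_repartition",
    "correction_within_band",
    "DEFAULT_AGE_BINS",
]

#: 24-month stratification bins over the 0-18 year study range
DEFAULT_AGE_BINS: tuple[float, ...] = tuple(float(x) for x in range(0, 217, 24))

_PERCENTILES = (2.5, 50.0, 97.5)


class ResamplingError(ValueError):
    pass


@dataclass(frozen=True)
class PartitionSpec:
    """A single train/test split of a cohort."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    train_fraction: float
    age_bins: tuple[float, ...]
    seed: int


class _Stratification:
    """Precomputed age-bin x sex strata for repeated splitting.

    Splitting through this object is exactly equivalent to
    :func:`stratified_split`; the bootstrap reuses it to avoid rebuilding
    the strata for every replicate.
    """

    def __init__(self, frame: pd.DataFrame, age_bins: Sequence[float]):
        ids = frame["image_id"].to_numpy()
        ca = frame["ca_months"].to_numpy(dtype=float)
        sex = frame["sex"].to_numpy(dtype=object)
        disorder = frame["disorder"].to_numpy(dtype=bool)
        edges = np.asarray(age_bins, dtype=float)
        if len(edges) < 2 or np.any(np.diff(edges) <= 0):
            raise ResamplingError("age_bins must be strictly increasing with >= 2 edges")
        # right-open bins; ages at or past the last edge share the top bin
        bin_index = np.clip(np.digitize(ca, edges[1:-1], right=False), 0, len(edges) - 2)

        self.ids = ids
        self.disorder_ids = ids[disorder]
        self.age_bins = tuple(float(e) for e in edges)
        self.strata: list[tuple[tuple[str, int], np.ndarray]] = []
        keys = sorted(
            {(str(s), int(b)) for s, b in zip(sex[~disorder], bin_index[~disorder])}
        )
        eligible = ~disorder
        for key in keys:
            mask = eligible & (sex == key[0]) & (bin_index == key[1])
            self.strata.append((key, ids[mask]))

    def split(self, train_fraction: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
        if not 0.0 < train_fraction < 1.0:
            raise ResamplingError("train_fraction must lie strictly in (0, 1)")
        n_eligible = sum(len(members) for _, members in self.strata)
        total_train = int(round(train_fraction * n_eligible))

        quotas = np.array(
            [train_fraction * len(members) for _, members in self.strata]
        )
        base = np.floor(quotas).astype(int)
        remainders = quotas - base
        shortfall = total_train - int(base.sum())
        # largest-remainder rounding; ties broken by stratum order
        order = np.argsort(-remainders, kind="stable")
        counts = base.copy()
        for idx in order[:max(shortfall, 0)]:
            counts[idx] += 1

        rng = np.random.default_rng(seed)
        train_parts = []
        for (_, members), n_train in zip(self.strata, counts):
            chosen = rng.choice(len(members), size=int(n_train), replace=False)
            train_parts.append(members[np.sort(chosen)])
        train = set(np.concatenate(train_parts)) if train_parts else set()
        train_ids = tuple(i for i in self.ids if i in train)
        test_ids = tuple(i for i in self.ids if i not in train)
        return train_ids, test_ids


def stratified_split(
    cohort: Cohort,
    train_fraction: float = 1.0 / 3.0,
    age_bins: Sequence[float] | None = None,
    seed: int = 0,
) -> PartitionSpec:
    """Draw an age/sex-stratified train/test partition.

    Disorder-flagged images go to the test set unconditionally.  The
    remaining images are allocated to the train set per stratum at
    ``train_fraction`` with largest-remainder rounding.  Deterministic under
    a fixed seed.
    """
    bins = tuple(age_bins) if age_bins is not None else DEFAULT_AGE_BINS
    strat = _Stratification(cohort.frame, bins)
    train_ids, test_ids = strat.split(train_fraction, seed)
    return PartitionSpec(
        train_ids=tuple(str(i) for i in train_ids),
        test_ids=tuple(str(i) for i in test_ids),
        train_fraction=float(train_fraction),
        age_bins=strat.age_bins,
        seed=int(seed),
    )


def replicate_seed(master_seed: int, index: int) -> int:
    """Deterministic, order-independent per-replicate seed (< 2**31)."""
    state = np.random.SeedSequence((int(master_seed), int(index))).generate_state(1)[0]
    return int(state % (2**31))


@dataclass
class BootstrapSummary:
    """Per-replicate calibration parameters and test metrics with
    percentile summaries and correction-curve bands."""

    n_replicates: int
    replicates: pd.DataFrame  # one row per replicate
    metric_ci: Mapping[str, tuple[float, float, float]]  # (2.5, 50, 97.5)
    grid: np.ndarray  # raw-BA grid, months
    curves: Mapping[str, pd.DataFrame]  # per sex: raw, lower, median, upper
    master_seed: int
    train_fraction: float
    n_failed: int = 0
    age_bins: tuple[float, ...] = DEFAULT_AGE_BINS


def bootstrap_repartition(
    cohort: Cohort,
    consensus: ConsensusResult,
    n_replicates: int = 1000,
    train_fraction: float = 1.0 / 3.0,
    master_seed: int = 0,
    age_bins: Sequence[float] | None = None,
    grid: Sequence[float] | None = None,
    max_failure_fraction: float = 0.01,
) -> BootstrapSummary:
    """Re-partition, refit and re-evaluate ``n_replicates`` times.

    Each replicate draws a fresh stratified split (seeded by
    :func:`replicate_seed`), fits the sex-specific calibration of the raw AI
    against the consensus on the calibration part, and evaluates MAD, RMSE
    and 1-year accuracy of the calibrated AI on the test part.  Correction
    curves ``(slope - 1) * raw + intercept`` are evaluated per replicate on
    the raw-BA grid and summarized by 2.5/50/97.5 percentiles per sex.
    """
    if n_replicates < 1:
        raise ResamplingError("n_replicates must be >= 1")
    included = set(consensus.consensus.index)
    frame = cohort.frame[cohort.frame["image_id"].isin(included)].reset_index(drop=True)
    if len(frame) != len(included):
        raise ResamplingError("consensus does not cover all included cohort images")

    bins = tuple(age_bins) if age_bins is not None else DEFAULT_AGE_BINS
    strat = _Stratification(frame, bins)
    grid_arr = (
        np.asarray(grid, dtype=float) if grid is not None
        else np.arange(0.0, 217.0, 12.0)
    )

    ids = frame["image_id"].to_numpy()
    pos = {i: p for p, i in enumerate(ids)}
    sex = frame["sex"].to_numpy(dtype=object)
    ai_raw = frame["ai_ba_months"].to_numpy(dtype=float)
    ref = consensus.consensus.reindex(ids).to_numpy(dtype=float)
    sexes_present = [s for s in SEXES if (sex == s).any()]

    rows = []
    curve_samples = {s: np.full((n_replicates, len(grid_arr)), np.nan) for s in sexes_present}
    n_failed = 0
    for i in range(n_replicates):
        seed_i = replicate_seed(master_seed, i)
        train_ids, test_ids = strat.split(train_fraction, seed_i)
        train_idx = np.fromiter((pos[t] for t in train_ids), dtype=int, count=len(train_ids))
        test_idx = np.fromiter((pos[t] for t in test_ids), dtype=int, count=len(test_ids))
        row: dict = {"replicate": i, "seed": seed_i, "failed": False}
        try:
            model = fit_calibration(ai_raw[train_idx], ref[train_idx], sex[train_idx])
        except CalibrationError:
            n_failed += 1
            row["failed"] = True
            rows.append(row)
            continue
        calibrated = np.empty(len(test_idx))
        for s in sexes_present:
            mask = sex[test_idx] == s
            fit = model.fits[s]
            calibrated[mask] = fit.slope * ai_raw[test_idx][mask] + fit.intercept
            row[f"slope_{s}"] = fit.slope
            row[f"intercept_{s}"] = fit.intercept
            curve_samples[s][i] = (fit.slope - 1.0) * grid_arr + fit.intercept
        test_ref = ref[test_idx]
        diffs = calibrated - test_ref
        row["mad"] = float(np.mean(np.abs(diffs)))
        row["rmse"] = float(np.sqrt(np.mean(diffs**2)))
        row["one_year_accuracy"] = float(100.0 * np.mean(np.abs(diffs) <= 12.0))
        rows.append(row)

    if n_failed > max_failure_fraction * n_replicates:
        raise ResamplingError(
            f"{n_failed}/{n_replicates} replicates had singular calibration fits"
        )

    replicates = pd.DataFrame(rows)
    ok = ~replicates["failed"].to_numpy(dtype=bool)
    metric_ci: dict[str, tuple[float, float, float]] = {}
    metric_cols = ["mad", "rmse", "one_year_accuracy"] + [
        f"{p}_{s}" for s in sexes_present for p in ("slope", "intercept")
    ]
    for col in metric_cols:
        values = replicates.loc[ok, col].to_numpy(dtype=float)
        lo, med, hi = np.percentile(values, _PERCENTILES)
        metric_ci[col] = (float(lo), float(med), float(hi))

    curves: dict[str, pd.DataFrame] = {}
    for s in sexes_present:
        samples = curve_samples[s][ok]
        lo, med, hi = np.percentile(samples, _PERCENTILES, axis=0)
        curves[s] = pd.DataFrame(
            {"raw_ba": grid_arr, "lower": lo, "median": med, "upper": hi}
        )

    return BootstrapSummary(
        n_replicates=n_replicates,
        replicates=replicates,
        metric_ci=metric_ci,
        grid=grid_arr,
        curves=curves,
        master_seed=int(master_seed),
        train_fraction=float(train_fraction),
        n_failed=n_failed,
        age_bins=tuple(bins),
    )


def correction_within_band(
    model: CalibrationModel, summary: BootstrapSummary
) -> dict[str, dict]:
    """Check whether a fitted calibration lies inside the bootstrap band.

    For every sex in the bootstrap summary, evaluates the model's correction
    ``(slope - 1) * raw + intercept`` on the summary grid and reports whether
    it falls inside the 2.5-97.5 percentile band at every grid point, plus
    the fraction of grid points inside.
    """
    report: dict[str, dict] = {}
    for s, band in summary.curves.items():
        if s not in model.fits:
            raise ResamplingError(f"model has no fit for sex {s!r}")
        correction = np.asarray(model.correction(s, summary.grid), dtype=float)
        if len(correction) != len(band):
            raise ResamplingError("grid mismatch between model evaluation and band")
        inside = (correction >= band["lower"].to_numpy()) & (
            correction <= band["upper"].to_numpy()
        )
        report[s] = {
            "inside": bool(inside.all()),
            "coverage": float(np.mean(inside)),
        }
    return report
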