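"""Agreement statistics between a bone-age predictor and a reference.

All quantities are in months unless noted.  The confidence-interval
constructions follow the validation-study conventions implemented here:

* RMSE — chi-square interval assuming normal residuals, with the quantiles
  taken at *n* degrees of freedom:
  ``(sqrt(n * RMSE^2 / chi2_{0.975,n}), sqrt(n * RMSE^2 / chi2_{0.025,n}))``.
* SMD (signed mean difference, predictor minus reference) — t interval,
  ``dbar +/- t_{0.975,n-1} * sd / sqrt(n)`` with the n-1 sample SD.
* ICC(2,k) — two-way random effects, absolute agreement, average of k
  measurements (McGraw & Wong), with its F-based 95% CI.
* Bland-Altman — mean difference mu with limits mu +/- 1.96 * sigma and the
  percentage of differences inside the closed limits.
* Normality of the signed differences — Lilliefors-corrected one-sample
  Kolmogorov-Smirnov test (parameters estimated from the sample).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

from .cohort import SEXES

__all__ = [
    "AgreementReport",
    "mad",
    "rmse_with_ci",
    "rmse_ci_from_point",
    "smd_with_ci",
    "one_year_accuracy",
    "icc_2k",
    "bland_altman",
    "ks_normality",
    "ba_minus_ca_summary",
    "agreement_report",
]

ONE_YEAR_MONTHS = 12.0


def _paired(pred: Sequence[float], ref: Sequence[float], min_n: int) -> np.ndarray:
    p = np.asarray(pred, dtype=float)
    r = np.asarray(ref, dtype=float)
    if p.shape != r.shape or p.ndim != 1:
        raise ValueError("pred and ref must be 1-d arrays of equal length")
    if len(p) < min_n:
        raise ValueError(f"at least {min_n} paired values are required, got {len(p)}")
    return p - r


def mad(pred: Sequence[float], ref: Sequence[float]) -> float:
    """Mean absolute difference, months."""
    return float(np.mean(np.abs(_paired(pred, ref, 1))))


def rmse_ci_from_point(rmse: float, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Chi-square 95% CI for an RMSE given only the point value and n.

    Quantiles are taken at ``n`` degrees of freedom, so the interval can be
    reproduced exactly from a reported (RMSE, n) pair.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    lo = np.sqrt(n * rmse**2 / stats.chi2.ppf(1.0 - alpha / 2.0, df=n))
    hi = np.sqrt(n * rmse**2 / stats.chi2.ppf(alpha / 2.0, df=n))
    return float(lo), float(hi)


def rmse_with_ci(
    pred: Sequence[float], ref: Sequence[float], alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """Root mean squared error with its chi-square confidence interval."""
    diffs = _paired(pred, ref, 2)
    rmse = float(np.sqrt(np.mean(diffs**2)))
    return rmse, rmse_ci_from_point(rmse, len(diffs), alpha)


def smd_with_ci(
    pred: Sequence[float], ref: Sequence[float], alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """Signed mean difference (predictor minus reference) with its t CI."""
    diffs = _paired(pred, ref, 2)
    n = len(diffs)
    dbar = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    se = sd / np.sqrt(n)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df=n - 1)
    return dbar, (float(dbar - tcrit * se), float(dbar + tcrit * se))


def one_year_accuracy(
    pred: Sequence[float], ref: Sequence[float], threshold: float = ONE_YEAR_MONTHS
) -> float:
    """Percentage of cases with absolute error within ``threshold`` months
    (inclusive)."""
    diffs = _paired(pred, ref, 1)
    return float(100.0 * np.mean(np.abs(diffs) <= threshold))


def icc_2k(
    ratings: np.ndarray | pd.DataFrame, alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """ICC(2,k): two-way random effects, absolute agreement, average of the
    k sources (McGraw & Wong's ICC(A,k)).

    ``ratings`` is a complete image-by-source matrix (n >= 2 rows, k >= 2
    columns; no missing cells).  Returns the ICC and its F-based confidence
    interval, both at full precision.  The interval uses the
    Satterthwaite-approximated denominator degrees of freedom of the
    absolute-agreement case, with the single-measure bounds stepped up to
    the average-of-k scale.
    """
    matrix = np.asarray(ratings, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("ratings must be an (images x sources) matrix, both >= 2")
    if np.isnan(matrix).any():
        raise ValueError("ICC requires a complete-case matrix (no missing cells)")
    n, k = matrix.shape

    grand = matrix.mean()
    row_means = matrix.mean(axis=1)
    col_means = matrix.mean(axis=0)
    ss_rows = k * float(np.sum((row_means - grand) ** 2))
    ss_cols = n * float(np.sum((col_means - grand) ** 2))
    ss_total = float(np.sum((matrix - grand) ** 2))
    msr = ss_rows / (n - 1)  # between-image ("rows") mean square
    msc = ss_cols / (k - 1)  # between-source ("columns") mean square
    mse = (ss_total - ss_rows - ss_cols) / ((n - 1) * (k - 1))

    denom = msr + (msc - mse) / n
    if denom == 0.0:
        raise ValueError("degenerate matrix: no variance anywhere")
    icc = (msr - mse) / denom
    if mse == 0.0 and msc == 0.0:
        # perfect agreement: the interval collapses onto the estimate
        return float(icc), (float(icc), float(icc))

    # single-measure absolute agreement, for the CI construction
    icc_a1 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    fj = msc / mse
    df_err = (n - 1) * (k - 1)
    num = df_err * (k * icc_a1 * fj + n * (1 + (k - 1) * icc_a1) - k * icc_a1) ** 2
    den = (n - 1) * k**2 * icc_a1**2 * fj**2 + (
        n * (1 + (k - 1) * icc_a1) - k * icc_a1
    ) ** 2
    v = num / den
    f_upper = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_lower = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lo1 = n * (msr - f_upper * mse) / (
        f_upper * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    hi1 = n * (f_lower * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_lower * msr
    )
    lo = lo1 * k / (1 + lo1 * (k - 1))
    hi = hi1 * k / (1 + hi1 * (k - 1))
    return float(icc), (float(lo), float(hi))


@dataclass(frozen=True)
class BlandAltman:
    mu: float  # months, mean difference
    lower: float  # mu - 1.96 * sigma
    upper: float  # mu + 1.96 * sigma
    pct_within: float  # percent of differences inside the closed limits


def bland_altman(pred: Sequence[float], ref: Sequence[float]) -> BlandAltman:
    """Bland-Altman summary of predictor-minus-reference differences."""
    diffs = _paired(pred, ref, 2)
    mu = float(np.mean(diffs))
    sigma = float(np.std(diffs, ddof=1))
    lower, upper = mu - 1.96 * sigma, mu + 1.96 * sigma
    within = (diffs >= lower) & (diffs <= upper)
    return BlandAltman(mu=mu, lower=lower, upper=upper,
                       pct_within=float(100.0 * np.mean(within)))


def ks_normality(diffs: Sequence[float]) -> float:
    """p-value of a normality test on signed differences.

    Standardizes with the sample mean and SD and applies the Lilliefors
    correction to the Kolmogorov-Smirnov null distribution (the correct
    reference when the normal parameters are estimated from the data).  A
    degenerate sample (zero SD) returns p = 0 with a warning.
    """
    d = np.asarray(diffs, dtype=float)
    if len(d) < 5:
        raise ValueError("normality testing requires at least 5 values")
    if np.std(d, ddof=1) == 0.0:
        warnings.warn("degenerate (constant) differences; returning p = 0",
                      RuntimeWarning, stacklevel=2)
        return 0.0
    _, pvalue = lilliefors(d, dist="norm")
    return float(pvalue)


def ba_minus_ca_summary(
    ba: Sequence[float], ca: Sequence[float], sex: Sequence[str]
) -> pd.DataFrame:
    """Per-sex descriptive summary (n, mean, SD, quartiles) of BA - CA."""
    b = np.asarray(ba, dtype=float)
    c = np.asarray(ca, dtype=float)
    labels = np.asarray(sex, dtype=object)
    if not (len(b) == len(c) == len(labels)):
        raise ValueError("ba, ca and sex must have equal length")
    unknown = set(labels) - set(SEXES)
    if unknown:
        raise ValueError(f"unknown sex labels: {sorted(map(str, unknown))}")
    rows = []
    diffs = b - c
    for stratum in SEXES:
        mask = labels == stratum
        if not mask.any():
            continue
        d = diffs[mask]
        rows.append(
            {
                "sex": stratum,
                "n": int(mask.sum()),
                "mean": float(np.mean(d)),
                "sd": float(np.std(d, ddof=1)) if mask.sum() > 1 else 0.0,
                "q25": float(np.percentile(d, 25)),
                "median": float(np.percentile(d, 50)),
                "q75": float(np.percentile(d, 75)),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class AgreementReport:
    """All agreement statistics for one predictor-vs-reference comparison."""

    n: int
    mad: float
    rmse: float
    rmse_ci: tuple[float, float]
    smd: float
    smd_ci: tuple[float, float]
    smd_se: float
    diff_sd: float
    one_year_accuracy: float
    icc: float
    icc_ci: tuple[float, float]
    icc_mode: str  # "pair" (predictor vs reference) or "panel" (predictor vs raters)
    bland_altman: BlandAltman
    ks_p: float

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mad": self.mad,
            "rmse": self.rmse,
            "rmse_ci": list(self.rmse_ci),
            "smd": self.smd,
            "smd_ci": list(self.smd_ci),
            "smd_se": self.smd_se,
            "diff_sd": self.diff_sd,
            "one_year_accuracy": self.one_year_accuracy,
            "icc": self.icc,
            "icc_ci": list(self.icc_ci),
            "icc_mode": self.icc_mode,
            "bland_altman": {
                "mu": self.bland_altman.mu,
                "lower": self.bland_altman.lower,
                "upper": self.bland_altman.upper,
                "pct_within": self.bland_altman.pct_within,
            },
            "ks_p": self.ks_p,
        }


def agreement_report(
    pred: Sequence[float],
    ref: Sequence[float],
    panel: np.ndarray | None = None,
    icc_mode: str = "pair",
) -> AgreementReport:
    """Compute the full agreement report for one predictor.

    ``icc_mode="pair"`` computes the ICC on the (predictor, reference)
    two-column matrix; ``"panel"`` stacks the predictor next to the
    individual rater columns supplied in ``panel``.
    """
    p = np.asarray(pred, dtype=float)
    r = np.asarray(ref, dtype=float)
    diffs = _paired(p, r, 2)
    if icc_mode == "pair":
        matrix = np.column_stack([p, r])
    elif icc_mode == "panel":
        if panel is None:
            raise ValueError('icc_mode="panel" requires the rater panel matrix')
        matrix = np.column_stack([p, np.asarray(panel, dtype=float)])
    else:
        raise ValueError(f"unknown icc_mode: {icc_mode!r}")
    icc, icc_ci = icc_2k(matrix)
    rmse, rmse_ci = rmse_with_ci(p, r)
    smd, smd_ci = smd_with_ci(p, r)
    sd = float(np.std(diffs, ddof=1))
    return AgreementReport(
        n=len(diffs),
        mad=mad(p, r),
        rmse=rmse,
        rmse_ci=rmse_ci,
        smd=smd,
        smd_ci=smd_ci,
        smd_se=sd / float(np.sqrt(len(diffs))),
        diff_sd=sd,
        one_year_accuracy=one_year_accuracy(p, r),
        icc=icc,
        icc_ci=icc_ci,
        icc_mode=icc_mode,
        bland_altman=bland_altman(p, r),
        ks_p=ks_normality(diffs) if len(diffs) >= 5 else float("nan"),
    )
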