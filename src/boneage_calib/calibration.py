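"""Sex-specific linear recalibration of raw AI bone-age predictions.

The calibrated bone age is ``slope_sex * raw + intercept_sex``, with the
parameters obtained by ordinary least squares of the reference bone age
(response) on the raw AI prediction (predictor), fitted separately per sex.
95% confidence intervals come from the t distribution on the coefficient
standard errors.  Calibrated outputs are not clamped; a warning is recorded
when a calibrated value is negative.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .cohort import SEXES

__all__ = ["SexFit", "CalibrationModel", "CalibrationError", "fit_calibration",
           "apply_calibration"]


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class SexFit:
    """OLS fit of reference on raw for one sex stratum."""

    slope: float  # unitless
    intercept: float  # months
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    n_fit: int
    residual_sd: float  # months, sqrt(SSR / (n - 2))


@dataclass(frozen=True)
class CalibrationModel:
    """Per-sex linear maps from raw to calibrated bone age (months)."""

    fits: Mapping[str, SexFit]

    def __post_init__(self) -> None:
        for sex, fit in self.fits.items():
            if not np.isfinite(fit.slope):
                raise CalibrationError(f"non-finite slope for sex {sex!r}")

    def correction(self, sex: str, raw: np.ndarray | float) -> np.ndarray | float:
        """Calibrated minus raw: ``(slope - 1) * raw + intercept``."""
        fit = self._fit(sex)
        return (fit.slope - 1.0) * np.asarray(raw, dtype=float) + fit.intercept

    def _fit(self, sex: str) -> SexFit:
        try:
            return self.fits[sex]
        except KeyError:
            raise CalibrationError(f"model has no calibration for sex {sex!r}") from None

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            sex: {
                "slope": fit.slope,
                "intercept": fit.intercept,
                "slope_ci": list(fit.slope_ci),
                "intercept_ci": list(fit.intercept_ci),
                "n_fit": fit.n_fit,
                "residual_sd": fit.residual_sd,
            }
            for sex, fit in self.fits.items()
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "CalibrationModel":
        fits = {
            sex: SexFit(
                slope=float(d["slope"]),
                intercept=float(d["intercept"]),
                slope_ci=tuple(d["slope_ci"]),
                intercept_ci=tuple(d["intercept_ci"]),
                n_fit=int(d["n_fit"]),
                residual_sd=float(d["residual_sd"]),
            )
            for sex, d in data.items()
        }
        return cls(fits=fits)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "CalibrationModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _ols(x: np.ndarray, y: np.ndarray, alpha: float) -> SexFit:
    n = len(x)
    xbar = x.mean()
    ybar = y.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    if sxx <= 0.0:
        raise CalibrationError("zero variance in raw predictions; singular fit")
    sxy = float(np.sum((x - xbar) * (y - ybar)))
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = y - (slope * x + intercept)
    dof = n - 2
    sigma2 = float(resid @ resid) / dof
    se_slope = np.sqrt(sigma2 / sxx)
    se_intercept = np.sqrt(sigma2 * (1.0 / n + xbar**2 / sxx))
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, dof)
    return SexFit(
        slope=float(slope),
        intercept=float(intercept),
        slope_ci=(float(slope - tcrit * se_slope), float(slope + tcrit * se_slope)),
        intercept_ci=(
            float(intercept - tcrit * se_intercept),
            float(intercept + tcrit * se_intercept),
        ),
        n_fit=n,
        residual_sd=float(np.sqrt(sigma2)),
    )


def fit_calibration(
    raw_ba: Sequence[float],
    reference_ba: Sequence[float],
    sex: Sequence[str],
    alpha: float = 0.05,
    min_per_sex: int = 3,
) -> CalibrationModel:
    """Fit the sex-specific linear recalibration.

    Parameters
    ----------
    raw_ba, reference_ba : array-like, months
        Raw AI predictions (predictor) and reference bone ages (response).
    sex : array-like of {"female", "male"}
        Stratum labels; a separate line is fitted per sex present.
    """
    raw = np.asarray(raw_ba, dtype=float)
    ref = np.asarray(reference_ba, dtype=float)
    labels = np.asarray(sex, dtype=object)
    if not (len(raw) == len(ref) == len(labels)):
        raise CalibrationError("raw_ba, reference_ba and sex must have equal length")

    fits: dict[str, SexFit] = {}
    for stratum in SEXES:
        mask = labels == stratum
        if not mask.any():
            continue
        if mask.sum() < min_per_sex:
            raise CalibrationError(
                f"sex stratum {stratum!r} has only {int(mask.sum())} images; "
                f"at least {min_per_sex} are required"
            )
        fits[stratum] = _ols(raw[mask], ref[mask], alpha)
    if not fits:
        raise CalibrationError("no images in any recognized sex stratum")
    return CalibrationModel(fits=fits)


def apply_calibration(
    model: CalibrationModel,
    raw_ba: Sequence[float] | float,
    sex: Sequence[str] | str,
) -> np.ndarray | float:
    """Map raw predictions through the sex-specific line.

    Outputs are not clamped to the physiologic range; negative results
    trigger a ``RuntimeWarning`` but are returned as-is.
    """
    scalar = np.isscalar(raw_ba) and isinstance(sex, str)
    raw = np.atleast_1d(np.asarray(raw_ba, dtype=float))
    labels = np.atleast_1d(np.asarray(sex, dtype=object))
    if len(labels) == 1 and len(raw) > 1:
        labels = np.repeat(labels, len(raw))
    if len(raw) != len(labels):
        raise CalibrationError("raw_ba and sex must have equal length")

    out = np.empty_like(raw)
    for stratum in np.unique(labels):
        fit = model._fit(str(stratum))
        mask = labels == stratum
        out[mask] = fit.slope * raw[mask] + fit.intercept
    if np.any(out < 0):
        warnings.warn(
            f"{int(np.sum(out < 0))} calibrated bone age(s) are negative",
            RuntimeWarning,
            stacklevel=2,
        )
    return float(out[0]) if scalar else out
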