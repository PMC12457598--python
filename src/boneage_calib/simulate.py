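"""Synthetic cohort generation.

The generator produces cohorts with the statistical structure the analysis
pipeline assumes, so every downstream stage is testable with a known ground
truth:

* a true bone age per image, tied to a drawn chronological age
  (``BA_true = CA + N(0, ba_ca_sd)``, floored at 0 months);
* a panel of raters, each observing ``BA_true + bias_j + N(0, sd_j)``;
* a black-box AI whose raw output is a *linear distortion* of the truth,
  ``ai_raw = a_sex * BA_true + c_sex + N(0, ai_sd)``.

Because the distortion is modeled in the forward direction, the correct
linear recalibration is analytically known: slope ``1/a`` and intercept
``-c/a``.  The study-scale default configuration
(:func:`default_gbad_like_config`) emulates a cohort of 381 images rated by
7 clinicians in which the uncalibrated AI overestimates bone age by about
+2.85 months in girls and +5.35 months in boys relative to the panel
consensus, with per-rater biases spanning [-3.07, +1.55] months and a
disorder prevalence of 19/381.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import FEMALE, MALE, Cohort

__all__ = ["SyntheticConfig", "generate_cohort", "default_gbad_like_config"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic cohort generator.

    All ages are in months.  ``ai_slope``/``ai_offset`` define the global
    forward distortion of the AI; ``sex_specific_ai`` overrides them with
    per-sex ``(slope, offset)`` pairs.
    """

    n_images: int = 381
    sex_ratio: float = 184 / 381  # fraction female, as in the emulated cohort
    age_range: tuple[float, float] = (12.0, 216.0)
    age_sampler: str = "uniform"  # "uniform" | "truncnorm"
    age_mean: float = 114.0  # truncnorm only
    age_sd: float = 55.0  # truncnorm only
    ba_ca_sd: float = 12.0  # biological spread of bone age around CA
    n_raters: int = 7
    rater_biases: tuple[float, ...] = (0.0,) * 7
    rater_sds: tuple[float, ...] = (4.0,) * 7
    ai_slope: float = 1.0
    ai_offset: float = 0.0
    ai_sd: float = 2.0
    sex_specific_ai: Mapping[str, tuple[float, float]] | None = None
    disorder_rate: float = 0.0
    age_proportional_noise: bool = False  # scale rater SDs by BA_true / mean age
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_images < 0:
            raise ValueError("n_images must be >= 0")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must lie in [0, 1]")
        if not 0.0 <= self.disorder_rate <= 1.0:
            raise ValueError("disorder_rate must lie in [0, 1]")
        if len(self.rater_biases) != self.n_raters or len(self.rater_sds) != self.n_raters:
            raise ValueError("rater_biases and rater_sds must have length n_raters")
        if any(sd < 0 for sd in self.rater_sds) or self.ai_sd < 0 or self.ba_ca_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.age_sampler not in ("uniform", "truncnorm"):
            raise ValueError(f"unknown age_sampler: {self.age_sampler!r}")

    def ai_params(self, sex: str) -> tuple[float, float]:
        if self.sex_specific_ai is not None and sex in self.sex_specific_ai:
            slope, offset = self.sex_specific_ai[sex]
            return float(slope), float(offset)
        return self.ai_slope, self.ai_offset


def _draw_ages(config: SyntheticConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    lo, hi = config.age_range
    if config.age_sampler == "uniform":
        return rng.uniform(lo, hi, size=n)
    a = (lo - config.age_mean) / config.age_sd
    b = (hi - config.age_mean) / config.age_sd
    dist = stats.truncnorm(a, b, loc=config.age_mean, scale=config.age_sd)
    return dist.rvs(size=n, random_state=rng)


def generate_cohort(config: SyntheticConfig) -> tuple[Cohort, pd.Series]:
    """Generate a cohort and its per-image true bone ages.

    Returns ``(cohort, ground_truth)`` where ``ground_truth`` is a Series of
    true bone ages (months) indexed by image id.  The truth is returned
    separately and never written into the cohort table.  Identical configs
    (including the seed) yield bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_images

    n_female = int(round(n * config.sex_ratio))
    sexes = np.array([FEMALE] * n_female + [MALE] * (n - n_female), dtype=object)
    sexes = rng.permutation(sexes)

    ca = _draw_ages(config, rng, n)
    ba_true = np.clip(ca + rng.normal(0.0, config.ba_ca_sd, size=n), 0.0, None)

    biases = np.asarray(config.rater_biases, dtype=float)
    sds = np.asarray(config.rater_sds, dtype=float)
    noise = rng.standard_normal((n, config.n_raters)) * sds[None, :]
    if config.age_proportional_noise and n:
        scale = ba_true / max(np.mean(ba_true), 1e-9)
        noise *= scale[:, None]
    ratings = np.clip(ba_true[:, None] + biases[None, :] + noise, 0.0, None)

    ai_raw = np.empty(n)
    for sex in (FEMALE, MALE):
        mask = sexes == sex
        slope, offset = config.ai_params(sex)
        ai_raw[mask] = slope * ba_true[mask] + offset
    ai_raw = np.clip(ai_raw + rng.normal(0.0, config.ai_sd, size=n), 0.0, None)

    disorder = rng.random(n) < config.disorder_rate

    width = max(4, len(str(n)))
    image_ids = [f"img_{i + 1:0{width}d}" for i in range(n)]
    rater_ids = [f"rater_{j + 1}" for j in range(config.n_raters)]

    frame = pd.DataFrame({"image_id": image_ids, "sex": sexes, "ca_months": ca})
    for j, rater in enumerate(rater_ids):
        frame[rater] = ratings[:, j]
    frame["ai_ba_months"] = ai_raw
    frame["disorder"] = disorder

    provenance = {
        "source": "synthetic",
        "seed": config.seed,
        "n_images": n,
        "generator": "boneage_calib.simulate.generate_cohort",
    }
    cohort = Cohort(frame, rater_ids, provenance)
    truth = pd.Series(ba_true, index=pd.Index(image_ids, name="image_id"),
                      name="ba_true_months")
    return cohort, truth


def default_gbad_like_config(seed: int = 0) -> SyntheticConfig:
    """Study-scale default configuration.

    The AI offsets are derived so that the *expected* signed mean difference
    of the raw AI against the panel consensus equals the target
    overestimation (+2.85 months for girls, +5.35 for boys): the consensus
    inherits the panel's mean bias, so for forward distortion ``(a, c)``

        E[ai_raw - consensus] = (a - 1) * E[BA_true] + c - mean_bias,

    which is solved for ``c`` at the expectation of the default age sampler.
    Rater biases span [-3.07, +1.55] months and rater noise SDs rise from
    3.2 to 5.0 months across the panel, giving 1/MAD consensus weights with
    a spread comparable to an expert panel of seven.
    """
    rater_biases = (-3.07, -1.9, -1.0, -0.2, 0.6, 1.2, 1.55)
    rater_sds = (3.2, 3.5, 3.8, 4.1, 4.4, 4.7, 5.0)
    mean_bias = float(np.mean(rater_biases))

    age_range = (12.0, 216.0)
    mean_ba = 0.5 * (age_range[0] + age_range[1])

    # forward slopes are the inverses of the recalibration slopes 1.032 / 1.040
    slope_f = 1.0 / 1.032
    slope_m = 1.0 / 1.040
    target_smd = {FEMALE: 2.85, MALE: 5.35}
    offset_f = target_smd[FEMALE] + (1.0 - slope_f) * mean_ba + mean_bias
    offset_m = target_smd[MALE] + (1.0 - slope_m) * mean_ba + mean_bias

    return SyntheticConfig(
        n_images=381,
        sex_ratio=184 / 381,
        age_range=age_range,
        ba_ca_sd=12.0,
        n_raters=7,
        rater_biases=rater_biases,
        rater_sds=rater_sds,
        ai_sd=2.0,
        sex_specific_ai={FEMALE: (slope_f, offset_f), MALE: (slope_m, offset_m)},
        disorder_rate=19 / 381,
        seed=seed,
    )
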