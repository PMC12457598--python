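"""End-to-end study workflow and report rendering.

:func:`run_study` executes the whole validation pipeline on a cohort:
consensus reference construction (with exclusions), age/sex-stratified
train/test split (disorders forced to test), sex-specific calibration
fitted on the train part, agreement reports for the raw and calibrated AI
on the identical test image list (overall and per sex), a
leave-one-rater-out benchmarking table, bootstrap re-partitioning, and
per-sex summaries of bone age minus chronological age for every bone-age
source.  All randomness is controlled by the seeds in :class:`StudyConfig`
and recorded in the report's provenance block.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__ as _version
from .calibration import CalibrationModel, apply_calibration, fit_calibration
from .cohort import SEXES, Cohort
from .consensus import ConsensusResult, consensus_pipeline, leave_one_out_consensus
from .metrics import (
    AgreementReport,
    agreement_report,
    ba_minus_ca_summary,
    mad,
    rmse_with_ci,
)
from .resampling import (
    BootstrapSummary,
    bootstrap_repartition,
    correction_within_band,
    stratified_split,
)

__all__ = ["StudyConfig", "StudyReport", "run_study", "render_tables"]

logger = logging.getLogger("boneage_calib")


@dataclass(frozen=True)
class StudyConfig:
    """Settings for one full study run."""

    deviation_threshold: float = 30.0
    drop_missing: bool = True
    mad_floor: float = 1e-6
    train_fraction: float = 1.0 / 3.0
    age_bins: tuple[float, ...] | None = None
    split_seed: int = 0
    n_bootstrap: int = 1000
    bootstrap_seed: int = 0
    by_sex: bool = True
    leave_one_out: bool = True
    icc_mode: str = "pair"


@dataclass
class StudyReport:
    """Everything one study run computed, ready for serialization."""

    consensus: ConsensusResult
    model: CalibrationModel
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    uncalibrated: AgreementReport
    calibrated: AgreementReport
    uncalibrated_by_sex: dict[str, AgreementReport]
    calibrated_by_sex: dict[str, AgreementReport]
    leave_one_out_table: pd.DataFrame | None
    bootstrap: BootstrapSummary | None
    band_check: dict[str, dict] | None
    ba_minus_ca: dict[str, pd.DataFrame]
    provenance: dict

    def to_dict(self) -> dict:
        out: dict = {
            "provenance": self.provenance,
            "consensus": {
                "included_count": self.consensus.included_count,
                "excluded": [list(e) for e in self.consensus.excluded],
                "profiles": [asdict(p) for p in self.consensus.profiles],
            },
            "model": self.model.to_dict(),
            "train_ids": list(self.train_ids),
            "test_ids": list(self.test_ids),
            "uncalibrated": self.uncalibrated.to_dict(),
            "calibrated": self.calibrated.to_dict(),
            "uncalibrated_by_sex": {
                s: r.to_dict() for s, r in self.uncalibrated_by_sex.items()
            },
            "calibrated_by_sex": {
                s: r.to_dict() for s, r in self.calibrated_by_sex.items()
            },
            "ba_minus_ca": {
                source: frame.to_dict(orient="records")
                for source, frame in self.ba_minus_ca.items()
            },
        }
        if self.leave_one_out_table is not None:
            out["leave_one_out"] = self.leave_one_out_table.to_dict(orient="records")
        if self.bootstrap is not None:
            out["bootstrap"] = {
                "n_replicates": self.bootstrap.n_replicates,
                "n_failed": self.bootstrap.n_failed,
                "master_seed": self.bootstrap.master_seed,
                "train_fraction": self.bootstrap.train_fraction,
                "metric_ci": {k: list(v) for k, v in self.bootstrap.metric_ci.items()},
                "curves": {
                    s: frame.to_dict(orient="list")
                    for s, frame in self.bootstrap.curves.items()
                },
            }
        if self.band_check is not None:
            out["band_check"] = self.band_check
        return out

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True, default=_jsonify)
        if path is not None:
            Path(path).write_text(text)
        return text


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _sex_reports(
    pred: np.ndarray, ref: np.ndarray, sex: np.ndarray, icc_mode: str,
    panel: np.ndarray | None,
) -> dict[str, AgreementReport]:
    reports = {}
    for stratum in SEXES:
        mask = sex == stratum
        if mask.sum() < 2:
            continue
        reports[stratum] = agreement_report(
            pred[mask], ref[mask],
            panel=panel[mask] if panel is not None else None,
            icc_mode=icc_mode,
        )
    return reports


def _leave_one_out_table(
    cohort: Cohort,
    config: StudyConfig,
    model: CalibrationModel,
    test_ids: Sequence[str],
) -> pd.DataFrame:
    """Per left-out rater: manual vs. AI vs. calibrated-AI accuracy against
    the consensus of the remaining raters, on the test set."""
    rows = []
    test_set = set(test_ids)
    for rater in cohort.rater_ids:
        loo = leave_one_out_consensus(
            cohort,
            rater,
            deviation_threshold=config.deviation_threshold,
            drop_missing=config.drop_missing,
            mad_floor=config.mad_floor,
        )
        ids = [i for i in loo.consensus.index if i in test_set]
        sub = cohort.frame[cohort.frame["image_id"].isin(ids)]
        ref = loo.consensus.reindex(sub["image_id"]).to_numpy(dtype=float)
        manual = sub[rater].to_numpy(dtype=float)
        raw = sub["ai_ba_months"].to_numpy(dtype=float)
        cal = np.asarray(
            apply_calibration(model, raw, sub["sex"].to_numpy(dtype=object))
        )
        row: dict = {"left_out": rater, "n": len(ids)}
        for name, pred in (("manual", manual), ("ai", raw), ("calibrated", cal)):
            row[f"mad_{name}"] = mad(pred, ref)
            rmse, ci = rmse_with_ci(pred, ref)
            row[f"rmse_{name}"] = rmse
            row[f"rmse_{name}_lo"], row[f"rmse_{name}_hi"] = ci
        rows.append(row)
    return pd.DataFrame(rows)


def run_study(cohort: Cohort, config: StudyConfig | None = None) -> StudyReport:
    """Run the complete calibration-and-validation workflow on a cohort."""
    config = config or StudyConfig()

    logger.info("consensus: building reference rating for %d images", cohort.n_images)
    consensus = consensus_pipeline(
        cohort,
        deviation_threshold=config.deviation_threshold,
        drop_missing=config.drop_missing,
        mad_floor=config.mad_floor,
    )
    logger.info(
        "consensus: %d images included, %d excluded",
        consensus.included_count, len(consensus.excluded),
    )

    included = cohort.subset(list(consensus.consensus.index))
    split = stratified_split(
        included,
        train_fraction=config.train_fraction,
        age_bins=config.age_bins,
        seed=config.split_seed,
    )
    logger.info("split: %d train / %d test", len(split.train_ids), len(split.test_ids))

    frame = included.frame.set_index("image_id", drop=False)
    ref_all = consensus.consensus

    train = frame.loc[list(split.train_ids)]
    model = fit_calibration(
        train["ai_ba_months"].to_numpy(dtype=float),
        ref_all.reindex(train.index).to_numpy(dtype=float),
        train["sex"].to_numpy(dtype=object),
    )
    for sex, fit in model.fits.items():
        logger.info(
            "calibration[%s]: slope %.4f, intercept %.3f months (n=%d)",
            sex, fit.slope, fit.intercept, fit.n_fit,
        )

    test = frame.loc[list(split.test_ids)]
    test_sex = test["sex"].to_numpy(dtype=object)
    test_raw = test["ai_ba_months"].to_numpy(dtype=float)
    test_ref = ref_all.reindex(test.index).to_numpy(dtype=float)
    test_panel = test[included.rater_ids].to_numpy(dtype=float)
    test_cal = np.asarray(apply_calibration(model, test_raw, test_sex))

    panel = test_panel if config.icc_mode == "panel" else None
    uncal = agreement_report(test_raw, test_ref, panel=panel, icc_mode=config.icc_mode)
    cal = agreement_report(test_cal, test_ref, panel=panel, icc_mode=config.icc_mode)
    logger.info(
        "test: MAD %.2f -> %.2f months, SMD %.2f -> %.2f months",
        uncal.mad, cal.mad, uncal.smd, cal.smd,
    )

    uncal_by_sex = cal_by_sex = {}
    if config.by_sex:
        uncal_by_sex = _sex_reports(test_raw, test_ref, test_sex, config.icc_mode, panel)
        cal_by_sex = _sex_reports(test_cal, test_ref, test_sex, config.icc_mode, panel)

    loo_table = None
    if config.leave_one_out:
        loo_table = _leave_one_out_table(included, config, model, split.test_ids)

    bootstrap = band = None
    if config.n_bootstrap > 0:
        bootstrap = bootstrap_repartition(
            included,
            consensus,
            n_replicates=config.n_bootstrap,
            train_fraction=config.train_fraction,
            master_seed=config.bootstrap_seed,
            age_bins=config.age_bins,
        )
        band = correction_within_band(model, bootstrap)

    ca_all = frame["ca_months"].to_numpy(dtype=float)
    sex_all = frame["sex"].to_numpy(dtype=object)
    raw_all = frame["ai_ba_months"].to_numpy(dtype=float)
    cal_all = np.asarray(apply_calibration(model, raw_all, sex_all))
    ba_ca = {
        "consensus": ba_minus_ca_summary(ref_all.reindex(frame.index), ca_all, sex_all),
        "ai_raw": ba_minus_ca_summary(raw_all, ca_all, sex_all),
        "ai_calibrated": ba_minus_ca_summary(cal_all, ca_all, sex_all),
    }

    provenance = {
        "package_version": _version,
        "config": {
            **{k: (list(v) if isinstance(v, tuple) else v)
               for k, v in asdict(config).items()},
        },
        "cohort": dict(cohort.provenance),
        "n_images": cohort.n_images,
        "n_raters": cohort.n_raters,
        "n_included": consensus.included_count,
        "n_train": len(split.train_ids),
        "n_test": len(split.test_ids),
        "seeds": {"split": config.split_seed, "bootstrap": config.bootstrap_seed},
    }

    return StudyReport(
        consensus=consensus,
        model=model,
        train_ids=split.train_ids,
        test_ids=split.test_ids,
        uncalibrated=uncal,
        calibrated=cal,
        uncalibrated_by_sex=uncal_by_sex,
        calibrated_by_sex=cal_by_sex,
        leave_one_out_table=loo_table,
        bootstrap=bootstrap,
        band_check=band,
        ba_minus_ca=ba_ca,
        provenance=provenance,
    )


def render_tables(
    report: StudyReport, out_dir: str | Path, decimals: int = 2
) -> dict[str, Path]:
    """Write accuracy tables as CSV (and markdown).

    ``table1.csv`` compares the uncalibrated and calibrated AI on the test
    set (MAD, RMSE with CI).  ``table2.csv`` (when leave-one-out results are
    present) has one row per left-out rater with the manual, raw-AI and
    calibrated-AI accuracies against the reduced-panel consensus.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    rows = []
    for label, rep in (("uncalibrated", report.uncalibrated),
                       ("calibrated", report.calibrated)):
        rows.append(
            {
                "predictor": label,
                "n": rep.n,
                "mad": round(rep.mad, decimals),
                "rmse": round(rep.rmse, decimals),
                "rmse_lo": round(rep.rmse_ci[0], decimals),
                "rmse_hi": round(rep.rmse_ci[1], decimals),
                "one_year_accuracy": round(rep.one_year_accuracy, 1),
            }
        )
    table1 = pd.DataFrame(rows)
    path1 = out_dir / "table1.csv"
    table1.to_csv(path1, index=False)
    written["table1"] = path1
    (out_dir / "table1.md").write_text(table1.to_markdown(index=False) + "\n")

    if report.leave_one_out_table is not None:
        table2 = report.leave_one_out_table.copy()
        numeric = table2.select_dtypes(include=[float]).columns
        table2[numeric] = table2[numeric].round(decimals)
        path2 = out_dir / "table2.csv"
        table2.to_csv(path2, index=False)
        written["table2"] = path2
        (out_dir / "table2.md").write_text(table2.to_markdown(index=False) + "\n")
    return written
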