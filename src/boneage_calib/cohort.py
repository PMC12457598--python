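"""Cohort data model and rating-table CSV I/O.

A *cohort* is a table of hand-radiograph bone-age assessments: one row per
image, with the child's sex and chronological age, one bone-age rating per
rater on a fixed panel (missing ratings allowed), the raw prediction of a
black-box AI model, and a flag for known genetic disorders.  All ages and
bone ages are real numbers in months.

The CSV interchange format has one header row; column names are configurable
through :class:`ColumnSchema` (defaults: ``image_id``, ``sex``, ``ca_months``,
``rater_1`` .. ``rater_k``, ``ai_ba_months``, ``disorder``).  Missing rater
cells are empty strings and become NaN in memory, never zeros.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

FEMALE = "female"
MALE = "male"
SEXES = (FEMALE, MALE)

#: study age range, months (0-18 years)
AGE_RANGE = (0.0, 216.0)

_SEX_ALIASES = {"f": FEMALE, "female": FEMALE, "m": MALE, "male": MALE}
_TRUE_STRINGS = {"1", "true", "yes", "t", "y"}
_FALSE_STRINGS = {"0", "false", "no", "f", "n", ""}


class CohortError(Exception):
    """Base class for cohort I/O and validation failures."""


class CohortParseError(CohortError):
    """Malformed CSV input."""


class CohortValidationError(CohortError):
    """Structurally valid input violating a cohort invariant.

    Carries the offending image ids in :attr:`image_ids` when applicable.
    """

    def __init__(self, message: str, image_ids: Sequence[str] = ()):
        super().__init__(message)
        self.image_ids = list(image_ids)


def parse_sex(value: object) -> str:
    """Normalize a sex label to ``"female"``/``"male"`` (case-insensitive)."""
    key = str(value).strip().lower()
    try:
        return _SEX_ALIASES[key]
    except KeyError:
        raise CohortValidationError(f"unrecognized sex label: {value!r}") from None


def _parse_bool(value: object) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if isinstance(value, (int, float, np.integer, np.floating)) and not (
        isinstance(value, float) and math.isnan(value)
    ):
        return bool(value)
    key = str(value).strip().lower()
    if key in _TRUE_STRINGS:
        return True
    if key in _FALSE_STRINGS:
        return False
    raise CohortValidationError(f"unrecognized boolean flag: {value!r}")


@dataclass(frozen=True)
class ColumnSchema:
    """Column-name mapping between a rating-table CSV and the cohort model.

    Rater columns are either listed explicitly (``rater_columns``) or found
    by prefix (``rater_prefix``), preserving file order.
    """

    image_id: str = "image_id"
    sex: str = "sex"
    chronological_age: str = "ca_months"
    ai_ba: str = "ai_ba_months"
    disorder: str = "disorder"
    rater_prefix: str = "rater_"
    rater_columns: tuple[str, ...] | None = None
    disorder_style: str = "int"  # "int" (1/0) or "bool" (true/false) on write

    def resolve_raters(self, columns: Sequence[str]) -> list[str]:
        if self.rater_columns is not None:
            missing = [c for c in self.rater_columns if c not in columns]
            if missing:
                raise CohortParseError(f"missing rater columns: {missing}")
            return list(self.rater_columns)
        found = [c for c in columns if c.startswith(self.rater_prefix)]
        if not found:
            raise CohortParseError(
                f"no rater columns found with prefix {self.rater_prefix!r}"
            )
        return found

    @classmethod
    def from_file(cls, path: str | Path) -> "ColumnSchema":
        """Load a schema from a YAML (or JSON) mapping file."""
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, Mapping):
            raise CohortParseError(f"schema file {path} must contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise CohortParseError(f"unknown schema keys: {sorted(unknown)}")
        if "rater_columns" in data and data["rater_columns"] is not None:
            data = dict(data)
            data["rater_columns"] = tuple(data["rater_columns"])
        return cls(**data)


@dataclass(frozen=True)
class RatingRecord:
    """A single image's assessments.

    ``rater_ratings`` has one slot per panel rater; missing ratings are NaN.
    """

    image_id: str
    sex: str
    chronological_age: float
    rater_ratings: tuple[float, ...]
    ai_raw_ba: float
    disorder_flag: bool


@dataclass
class Cohort:
    """A rated cohort: records plus the ordered rater panel.

    ``frame`` holds canonical columns ``image_id``, ``sex``, ``ca_months``,
    one float column per entry of ``rater_ids``, ``ai_ba_months`` and a
    boolean ``disorder``.
    """

    frame: pd.DataFrame
    rater_ids: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frame = self.frame.reset_index(drop=True)
        self.validate()

    # -- structure ---------------------------------------------------------

    @property
    def n_images(self) -> int:
        return len(self.frame)

    @property
    def n_raters(self) -> int:
        return len(self.rater_ids)

    @property
    def image_ids(self) -> pd.Series:
        return self.frame["image_id"]

    @property
    def ratings(self) -> np.ndarray:
        """(n_images, n_raters) float matrix; NaN marks missing ratings."""
        return self.frame[self.rater_ids].to_numpy(dtype=float)

    def records(self) -> Iterator[RatingRecord]:
        for _, row in self.frame.iterrows():
            yield RatingRecord(
                image_id=str(row["image_id"]),
                sex=str(row["sex"]),
                chronological_age=float(row["ca_months"]),
                rater_ratings=tuple(float(row[r]) for r in self.rater_ids),
                ai_raw_ba=float(row["ai_ba_months"]),
                disorder_flag=bool(row["disorder"]),
            )

    def subset(self, image_ids: Sequence[str]) -> "Cohort":
        """Row subset, preserving original order."""
        keep = self.frame["image_id"].isin(set(image_ids))
        return Cohort(self.frame.loc[keep].copy(), list(self.rater_ids), dict(self.provenance))

    def drop_rater(self, rater_id: str) -> "Cohort":
        if rater_id not in self.rater_ids:
            raise CohortValidationError(f"unknown rater id: {rater_id!r}")
        remaining = [r for r in self.rater_ids if r != rater_id]
        return Cohort(
            self.frame.drop(columns=[rater_id]).copy(), remaining, dict(self.provenance)
        )

    # -- invariants --------------------------------------------------------

    def validate(self, relax_age_range: bool = True) -> None:
        frame = self.frame
        required = ["image_id", "sex", "ca_months", "ai_ba_months", "disorder"]
        missing = [c for c in required + list(self.rater_ids) if c not in frame.columns]
        if missing:
            raise CohortValidationError(f"cohort frame missing columns: {missing}")

        dup = frame["image_id"][frame["image_id"].duplicated()]
        if len(dup):
            raise CohortValidationError(
                f"duplicate image_id values: {sorted(set(dup))}", sorted(set(dup))
            )
        bad_sex = frame.loc[~frame["sex"].isin(SEXES), "image_id"]
        if len(bad_sex):
            raise CohortValidationError(
                f"unparsed sex labels for images: {list(bad_sex)}", list(bad_sex)
            )

        numeric = frame[["ca_months", "ai_ba_months"] + list(self.rater_ids)].to_numpy(
            dtype=float
        )
        neg = np.nansum(numeric < 0, axis=1) > 0
        if neg.any():
            ids = list(frame.loc[neg, "image_id"])
            raise CohortValidationError(
                f"negative ages or bone ages for images: {ids}", ids
            )
        ca = frame["ca_months"].to_numpy(dtype=float)
        if np.isnan(ca).any() or np.isnan(frame["ai_ba_months"].to_numpy(float)).any():
            ids = list(
                frame.loc[
                    np.isnan(ca) | np.isnan(frame["ai_ba_months"].to_numpy(float)),
                    "image_id",
                ]
            )
            raise CohortValidationError(
                f"missing chronological age or AI prediction for images: {ids}", ids
            )
        if not relax_age_range:
            out = (ca < AGE_RANGE[0]) | (ca > AGE_RANGE[1])
            if out.any():
                ids = list(frame.loc[out, "image_id"])
                raise CohortValidationError(
                    f"chronological age outside {AGE_RANGE} months for images: {ids}",
                    ids,
                )

    def config_hash(self) -> str:
        blob = json.dumps(self.provenance, sort_keys=True, default=str)
        import hashlib

        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def read_cohort(
    path: str | Path,
    schema: ColumnSchema | None = None,
    relax_age_range: bool = True,
) -> Cohort:
    """Read a rating-table CSV into a :class:`Cohort`.

    Missing rater cells become NaN.  Sex labels are parsed case-insensitively
    from {f, m, female, male}.  Raises :class:`CohortParseError` for malformed
    CSV and :class:`CohortValidationError` (listing offending image ids) for
    negative ages/ratings or duplicate ids.
    """
    schema = schema or ColumnSchema()
    path = Path(path)
    if not path.exists():
        raise CohortParseError(f"no such file: {path}")
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise CohortParseError(f"malformed CSV {path}: {exc}") from exc

    required = [schema.image_id, schema.sex, schema.chronological_age, schema.ai_ba]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise CohortParseError(f"{path} is missing required columns: {missing}")
    rater_cols = schema.resolve_raters(list(raw.columns))

    def _num(col: str, allow_missing: bool) -> np.ndarray:
        values = raw[col].str.strip()
        values = values.mask(values == "", other=None)
        try:
            # str -> float via the exact strtod path so values round-trip
            parsed = values.astype(float)
        except (ValueError, TypeError) as exc:
            raise CohortParseError(f"non-numeric value in column {col!r}: {exc}") from exc
        if not allow_missing and parsed.isna().any():
            lines = [str(i + 2) for i in parsed.index[parsed.isna()]]
            raise CohortParseError(
                f"empty cells in required column {col!r} at CSV lines {lines}"
            )
        return parsed.to_numpy(dtype=float)

    frame = pd.DataFrame({"image_id": raw[schema.image_id].str.strip()})
    frame["sex"] = [parse_sex(v) for v in raw[schema.sex]]
    frame["ca_months"] = _num(schema.chronological_age, allow_missing=False)
    for col in rater_cols:
        frame[col] = _num(col, allow_missing=True)
    frame["ai_ba_months"] = _num(schema.ai_ba, allow_missing=False)
    if schema.disorder in raw.columns:
        frame["disorder"] = [_parse_bool(v) for v in raw[schema.disorder]]
    else:
        frame["disorder"] = False

    cohort = Cohort(frame, rater_cols)
    cohort.validate(relax_age_range=relax_age_range)
    cohort.provenance.setdefault("source", str(path))
    return cohort


def write_cohort(
    cohort: Cohort, path: str | Path, schema: ColumnSchema | None = None
) -> None:
    """Write a cohort as CSV with stable column order; missing ratings as
    empty cells; the disorder flag serialized per ``schema.disorder_style``."""
    schema = schema or ColumnSchema()
    out = pd.DataFrame({schema.image_id: cohort.frame["image_id"]})
    out[schema.sex] = cohort.frame["sex"]
    out[schema.chronological_age] = cohort.frame["ca_months"]
    for rater in cohort.rater_ids:
        out[rater] = cohort.frame[rater]
    out[schema.ai_ba] = cohort.frame["ai_ba_months"]
    if schema.disorder_style == "bool":
        out[schema.disorder] = np.where(cohort.frame["disorder"], "true", "false")
    else:
        out[schema.disorder] = cohort.frame["disorder"].astype(int)
    try:
        out.to_csv(path, index=False, na_rep="")
    except OSError as exc:
        raise CohortError(f"cannot write cohort to {path}: {exc}") from exc
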