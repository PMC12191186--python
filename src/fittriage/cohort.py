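"""Patient-level cohort container, censored-FIT parsing and the urgent-conversion label.

Quantitative faecal immunochemical tests (FIT) report faecal haemoglobin in
µg Hb/g faeces.  Clinical laboratories censor results at assay detection
limits, so raw values arrive as e.g. ``"<7"``, ``"<10"`` or ``">400"`` depending
on the analyser in use at each site.  For modelling, censored results are
imputed to the limit itself (7, 10 or 400 µg/g) and exact results pass through
unchanged.

The binary outcome of the whole analysis is the *urgent-conversion* label: a
patient whose colonic findings would force a colon-capsule examination to be
converted to conventional colonoscopy (colorectal cancer, a large polyp, or a
high polyp count under configurable referral criteria).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Censoring",
    "FITMeasurement",
    "ColonicFindings",
    "ConversionCriteria",
    "PatientRecord",
    "CohortTable",
    "CompletenessReport",
    "CohortError",
    "FITParseError",
    "SchemaError",
    "parse_fit",
    "serialise_fit",
    "label_urgent",
    "load_cohort",
]

DEFAULT_LOWER_LIMITS: tuple[float, ...] = (7.0, 10.0)
DEFAULT_UPPER_LIMIT: float = 400.0

#: Plausible haemoglobin range in g/L; values outside are treated as unit errors
#: (e.g. g/dL entered instead of g/L).
HB_MIN_G_L = 30.0
HB_MAX_G_L = 250.0

MANDATORY_COLUMNS = (
    "id",
    "age",
    "sex",
    "haemoglobin_g_l",
    "fit_raw",
    "crc",
    "polyp_count",
    "max_polyp_size_mm",
)


class CohortError(ValueError):
    """Base class for cohort validation failures."""


class FITParseError(CohortError):
    """A raw FIT string could not be interpreted."""


class SchemaError(CohortError):
    """The input table does not match the documented column schema."""


class Censoring(str, enum.Enum):
    EXACT = "exact"
    BELOW_LOWER_LIMIT = "below_lower_limit"
    ABOVE_UPPER_LIMIT = "above_upper_limit"


@dataclass(frozen=True)
class FITMeasurement:
    """A single FIT result: the raw laboratory string plus its imputed value.

    ``raw`` is preserved verbatim so that serialising a parsed measurement is
    lossless; ``value`` is the numeric concentration used in every analysis
    (the detection limit itself for censored results).
    """

    raw: str
    censoring: Censoring
    value: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.value) and self.value > 0):
            raise FITParseError(f"FIT value must be positive and finite, got {self.value!r}")


@dataclass(frozen=True)
class ColonicFindings:
    """Colonic pathology relevant to capsule-to-colonoscopy conversion."""

    crc: bool = False
    polyp_count: int = 0
    max_polyp_size: float = 0.0  # mm, largest polyp
    other_findings: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.polyp_count < 0:
            raise CohortError(f"polyp_count must be non-negative, got {self.polyp_count}")
        if self.max_polyp_size < 0:
            raise CohortError(f"max_polyp_size must be non-negative, got {self.max_polyp_size}")
        if self.polyp_count == 0 and self.max_polyp_size != 0:
            raise CohortError("max_polyp_size must be 0 when polyp_count is 0")

    def advanced_polyp(self, size_threshold: float = 10.0) -> bool:
        """Advanced polyp: largest diameter at or above ``size_threshold`` mm."""
        return self.max_polyp_size >= size_threshold


@dataclass(frozen=True)
class ConversionCriteria:
    """Referral rule mapping colonic findings to an urgent-conversion label.

    The default — cancer, any polyp ≥ 10 mm, or ≥ 3 polyps — is a documented
    stand-in for capsule-to-colonoscopy referral criteria; every part is
    configurable because local pathways differ.
    """

    size_threshold: float = 10.0  # mm
    count_threshold: int = 3
    crc_always_urgent: bool = True
    extra_urgent_findings: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.size_threshold <= 0:
            raise CohortError("size_threshold must be positive")
        if self.count_threshold < 1:
            raise CohortError("count_threshold must be at least 1")


class BowelPrep(str, enum.Enum):
    ADEQUATE = "adequate"
    POOR = "poor"
    MISSING = "missing"


@dataclass(frozen=True)
class PatientRecord:
    id: str
    age: float
    sex: str  # "male" | "female"
    haemoglobin: float  # g/L
    fit: FITMeasurement
    findings: ColonicFindings
    urgent: bool
    bowel_prep: BowelPrep = BowelPrep.MISSING

    def __post_init__(self) -> None:
        if self.age < 18:
            raise CohortError(f"record {self.id}: age must be >= 18, got {self.age}")
        if self.haemoglobin <= 0:
            raise CohortError(f"record {self.id}: haemoglobin must be positive")
        if self.sex not in ("male", "female"):
            raise CohortError(f"record {self.id}: sex must be 'male' or 'female', got {self.sex!r}")


def parse_fit(
    raw: str,
    lower_limits: Sequence[float] = DEFAULT_LOWER_LIMITS,
    upper_limit: float = DEFAULT_UPPER_LIMIT,
) -> FITMeasurement:
    """Parse a laboratory FIT string, imputing censored results to the limit.

    ``"<7"`` and ``"<10"`` (the lower detection limits of the site assays) map to
    7 and 10 µg/g; ``">400"`` maps to 400 µg/g; plain numerics pass through.

    Raises
    ------
    FITParseError
        For empty input, non-numeric payloads, non-positive concentrations, or
        censoring markers whose limit is not one of the configured assay limits.
    """
    if raw is None or str(raw).strip() == "":
        raise FITParseError("empty FIT value")
    text = str(raw).strip()
    if text[0] in "<>":
        payload = text[1:].strip()
        try:
            limit = float(payload)
        except ValueError:
            raise FITParseError(f"unparseable FIT token {text!r}") from None
        if text[0] == "<":
            if not any(math.isclose(limit, lo) for lo in lower_limits):
                raise FITParseError(
                    f"unrecognised lower detection limit in {text!r}; expected one of {tuple(lower_limits)}"
                )
            return FITMeasurement(raw=text, censoring=Censoring.BELOW_LOWER_LIMIT, value=limit)
        if not math.isclose(limit, upper_limit):
            raise FITParseError(
                f"unrecognised upper detection limit in {text!r}; expected {upper_limit}"
            )
        return FITMeasurement(raw=text, censoring=Censoring.ABOVE_UPPER_LIMIT, value=limit)
    try:
        value = float(text)
    except ValueError:
        raise FITParseError(f"unparseable FIT token {text!r}") from None
    if not math.isfinite(value) or value <= 0:
        raise FITParseError(f"FIT concentration must be positive, got {text!r}")
    return FITMeasurement(raw=text, censoring=Censoring.EXACT, value=value)


def serialise_fit(measurement: FITMeasurement) -> str:
    """Inverse of :func:`parse_fit`: returns the raw string verbatim."""
    return measurement.raw


def label_urgent(findings: ColonicFindings, criteria: ConversionCriteria = ConversionCriteria()) -> bool:
    """Apply the conversion criteria to colonic findings.

    True iff cancer (when ``crc_always_urgent``), a polyp at or above the size
    threshold, a polyp count at or above the count threshold, or any finding in
    ``extra_urgent_findings``.  Monotone in both polyp size and count.
    """
    if criteria.crc_always_urgent and findings.crc:
        return True
    if findings.polyp_count > 0 and findings.max_polyp_size >= criteria.size_threshold:
        return True
    if findings.polyp_count >= criteria.count_threshold:
        return True
    return bool(findings.other_findings & criteria.extra_urgent_findings)


@dataclass(frozen=True)
class CompletenessReport:
    """Complete-case accounting: how many rows were excluded and why."""

    n_input: int
    n_valid: int
    n_missing_fit: int
    n_missing_findings: int
    n_invalid: int
    exclusions: tuple[tuple[int, str], ...]  # (row index, reason)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"{self.n_valid}/{self.n_input} rows valid "
            f"({self.n_missing_fit} missing FIT, {self.n_missing_findings} missing findings, "
            f"{self.n_invalid} invalid)"
        )


# Canonical column order of the analysis frame (and of serialised output).
_FRAME_COLUMNS = [
    "id", "age", "sex", "haemoglobin", "fit_raw", "fit_value", "fit_censoring",
    "crc", "polyp_count", "max_polyp_size", "bowel_prep", "urgent",
]


@dataclass
class CohortTable:
    """Validated cohort with imputed FIT values and derived urgent labels.

    Internally a pandas DataFrame in canonical column order; ``records``
    materialises :class:`PatientRecord` objects on demand.
    """

    frame: pd.DataFrame
    provenance: str = "unspecified"
    criteria: ConversionCriteria = field(default_factory=ConversionCriteria)
    completeness: CompletenessReport | None = None

    def __post_init__(self) -> None:
        if len(self.frame) == 0:
            raise CohortError("cohort must be non-empty")
        missing = [c for c in _FRAME_COLUMNS if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"cohort frame missing columns {missing}")
        ids = self.frame["id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise CohortError(f"duplicate patient id {dup!r}")
        if self.frame["fit_value"].isna().any() or not np.isfinite(self.frame["fit_value"]).all():
            raise CohortError("every record must carry a numeric imputed FIT value")
        extra = [c for c in self.frame.columns if c not in _FRAME_COLUMNS]
        self.frame = self.frame[_FRAME_COLUMNS + extra].reset_index(drop=True)

    # -- construction -----------------------------------------------------

    @classmethod
    def from_records(
        cls,
        records: Iterable[PatientRecord],
        provenance: str = "records",
        criteria: ConversionCriteria = ConversionCriteria(),
    ) -> "CohortTable":
        rows = []
        for r in records:
            rows.append(
                {
                    "id": r.id,
                    "age": r.age,
                    "sex": r.sex,
                    "haemoglobin": r.haemoglobin,
                    "fit_raw": r.fit.raw,
                    "fit_value": r.fit.value,
                    "fit_censoring": r.fit.censoring.value,
                    "crc": bool(r.findings.crc),
                    "polyp_count": int(r.findings.polyp_count),
                    "max_polyp_size": float(r.findings.max_polyp_size),
                    "bowel_prep": r.bowel_prep.value,
                    "urgent": bool(r.urgent),
                }
            )
        return cls(pd.DataFrame(rows), provenance=provenance, criteria=criteria)

    # -- accessors ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def fit_values(self) -> np.ndarray:
        return self.frame["fit_value"].to_numpy(dtype=float)

    @property
    def urgent(self) -> np.ndarray:
        return self.frame["urgent"].to_numpy(dtype=bool)

    def outcome(self, name: str) -> np.ndarray:
        """Binary outcome vector: 'urgent', 'crc' or 'polypoid' (polyp or CRC)."""
        if name == "urgent":
            return self.urgent
        if name == "crc":
            return self.frame["crc"].to_numpy(dtype=bool)
        if name == "polypoid":
            return (self.frame["crc"] | (self.frame["polyp_count"] > 0)).to_numpy(dtype=bool)
        raise KeyError(f"unknown outcome {name!r}; expected 'urgent', 'crc' or 'polypoid'")

    def records(self) -> Iterator[PatientRecord]:
        for row in self.frame.itertuples(index=False):
            findings = ColonicFindings(
                crc=bool(row.crc),
                polyp_count=int(row.polyp_count),
                max_polyp_size=float(row.max_polyp_size),
            )
            yield PatientRecord(
                id=str(row.id),
                age=float(row.age),
                sex=str(row.sex),
                haemoglobin=float(row.haemoglobin),
                fit=FITMeasurement(str(row.fit_raw), Censoring(row.fit_censoring), float(row.fit_value)),
                findings=findings,
                urgent=bool(row.urgent),
                bowel_prep=BowelPrep(row.bowel_prep),
            )

    def relabel(self, criteria: ConversionCriteria) -> "CohortTable":
        """Re-derive the urgent label under different conversion criteria."""
        frame = self.frame.copy()
        frame["urgent"] = [
            label_urgent(
                ColonicFindings(bool(c), int(k), float(s)), criteria
            )
            for c, k, s in zip(frame["crc"], frame["polyp_count"], frame["max_polyp_size"])
        ]
        return CohortTable(frame, provenance=self.provenance, criteria=criteria,
                           completeness=self.completeness)

    def to_csv(self, path) -> None:
        """Serialise in the documented input schema plus derived columns."""
        out = pd.DataFrame(
            {
                "id": self.frame["id"],
                "age": self.frame["age"],
                "sex": self.frame["sex"].map({"male": "M", "female": "F"}),
                "haemoglobin_g_l": self.frame["haemoglobin"],
                "fit_raw": self.frame["fit_raw"],
                "crc": self.frame["crc"].astype(int),
                "polyp_count": self.frame["polyp_count"],
                "max_polyp_size_mm": self.frame["max_polyp_size"],
                "bowel_prep": self.frame["bowel_prep"].replace("missing", ""),
                "fit_value": self.frame["fit_value"],
                "fit_censoring": self.frame["fit_censoring"],
                "urgent": self.frame["urgent"].astype(int),
            }
        )
        out.to_csv(path, index=False)


def load_cohort(
    path,
    criteria: ConversionCriteria = ConversionCriteria(),
    lower_limits: Sequence[float] = DEFAULT_LOWER_LIMITS,
    upper_limit: float = DEFAULT_UPPER_LIMIT,
) -> CohortTable:
    """Read and validate a cohort CSV (complete-case).

    Expected columns: ``id, age, sex {M,F}, haemoglobin_g_l, fit_raw, crc {0,1},
    polyp_count, max_polyp_size_mm`` and optionally ``bowel_prep
    {adequate,poor,<empty>}``.  Rows missing the FIT result, polyp count or
    largest polyp size are excluded and counted (complete-case rule); rows
    failing validation are rejected with row-indexed diagnostics in the
    attached :class:`CompletenessReport`.  The urgent label is (re-)derived
    from findings under ``criteria`` regardless of any pre-existing column, so
    reloading serialised output is idempotent.
    """
    raw = pd.read_csv(path, dtype={"fit_raw": str, "id": str}, keep_default_na=True)
    missing_cols = [c for c in MANDATORY_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise SchemaError(f"missing mandatory column(s) {missing_cols} in {path}")
    dup_mask = raw["id"].duplicated()
    if dup_mask.any():
        raise CohortError(f"duplicate patient id {raw['id'][dup_mask].iloc[0]!r} in {path}")

    rows = []
    exclusions: list[tuple[int, str]] = []
    n_missing_fit = n_missing_findings = n_invalid = 0
    sex_map = {"M": "male", "F": "female", "male": "male", "female": "female"}
    for idx, row in raw.iterrows():
        fit_raw = row["fit_raw"]
        if pd.isna(fit_raw) or str(fit_raw).strip() == "":
            n_missing_fit += 1
            exclusions.append((idx, "missing FIT"))
            continue
        if pd.isna(row["polyp_count"]) or pd.isna(row["max_polyp_size_mm"]):
            n_missing_findings += 1
            exclusions.append((idx, "missing polyp count or size"))
            continue
        try:
            fit = parse_fit(str(fit_raw), lower_limits=lower_limits, upper_limit=upper_limit)
            sex = sex_map.get(str(row["sex"]).strip())
            if sex is None:
                raise CohortError(f"unrecognised sex {row['sex']!r}")
            hb = float(row["haemoglobin_g_l"])
            if not (HB_MIN_G_L <= hb <= HB_MAX_G_L):
                raise CohortError(
                    f"haemoglobin {hb} g/L outside plausible range "
                    f"[{HB_MIN_G_L}, {HB_MAX_G_L}] (unit error?)"
                )
            prep_raw = row.get("bowel_prep", "")
            prep = (
                BowelPrep.MISSING
                if pd.isna(prep_raw) or str(prep_raw).strip() == ""
                else BowelPrep(str(prep_raw).strip())
            )
            findings = ColonicFindings(
                crc=bool(int(row["crc"])),
                polyp_count=int(row["polyp_count"]),
                max_polyp_size=float(row["max_polyp_size_mm"]),
            )
            record = PatientRecord(
                id=str(row["id"]),
                age=float(row["age"]),
                sex=sex,
                haemoglobin=hb,
                fit=fit,
                findings=findings,
                urgent=label_urgent(findings, criteria),
                bowel_prep=prep,
            )
        except (CohortError, ValueError) as exc:
            n_invalid += 1
            exclusions.append((idx, str(exc)))
            continue
        rows.append(record)

    if not rows:
        raise CohortError(f"no valid rows in {path} ({len(raw)} read, all excluded)")
    report = CompletenessReport(
        n_input=len(raw),
        n_valid=len(rows),
        n_missing_fit=n_missing_fit,
        n_missing_findings=n_missing_findings,
        n_invalid=n_invalid,
        exclusions=tuple(exclusions),
    )
    table = CohortTable.from_records(rows, provenance=str(path), criteria=criteria)
    table.completeness = report
    return table
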