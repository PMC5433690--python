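"""Patient-level data model and CSV I/O for ocular adnexal LPD cohorts.

The package models a three-group case series — reactive follicular
hyperplasia (RFH), atypical lymphoid hyperplasia (ALH) and extranodal
marginal-zone lymphoma (MALToma) — in which each subject carries clinical
covariates, CD23/IgD immunohistochemistry read-outs (five high-power fields
per marker per scorer, two independent scorers), an ordinal lymphoid-follicle
structure category, and an IgH-clonality result used as the molecular gold
standard.

Missing values are represented as *absent* (``None`` in memory, empty cells
on disk), never as zero: an unstained section and a section with 0% positive
cells are different observations.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Diagnosis",
    "Sex",
    "Laterality",
    "Site",
    "Symptom",
    "IghResult",
    "Marker",
    "IHCAssessment",
    "PatientRecord",
    "CohortTable",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "load_published_counts",
    "PublishedCounts",
    "COHORT_COLUMNS",
]

N_HPF = 5  # five high-power fields (x400) are averaged per section
AGE_WINDOW = (0.0, 120.0)  # plausibility window for age in years


class CohortValidationError(ValueError):
    """Raised when a record or CSV row violates the cohort schema."""


class Diagnosis(str, enum.Enum):
    RFH = "RFH"
    ALH = "ALH"
    MALTOMA = "MALToma"


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"


class Laterality(str, enum.Enum):
    UNILATERAL = "unilateral"
    BILATERAL = "bilateral"


class Site(str, enum.Enum):
    ORBITAL_SOFT_TISSUE = "orbital_soft_tissue"
    CONJUNCTIVA = "conjunctiva"
    LACHRYMAL_GLAND = "lachrymal_gland"
    EXTRAOCULAR_MUSCLE = "extraocular_muscle"
    OTHER = "other"  # eyelid, nasolacrimal duct and nerve, collapsed


class Symptom(str, enum.Enum):
    PERIORBITAL_SWELLING = "periorbital_swelling"
    PROPTOSIS = "proptosis"
    IMPAIRED_VISION = "impaired_vision"
    EPIPHORA = "epiphora"
    PAIN = "pain"
    MOTILITY_IMPAIRMENT = "motility_impairment"
    PTOSIS = "ptosis"


class IghResult(str, enum.Enum):
    CLONAL = "clonal"
    POLYCLONAL = "polyclonal"
    QC_FAILED = "qc_failed"  # degraded DNA template, excluded from denominators
    NOT_TESTED = "not_tested"


class Marker(str, enum.Enum):
    CD23 = "CD23"
    IGD = "IgD"


def _enum_error(value: object, enum_cls: type[enum.Enum], column: str) -> CohortValidationError:
    allowed = ", ".join(e.value for e in enum_cls)
    return CohortValidationError(
        f"column {column!r}: unknown value {value!r}; permitted values are {{{allowed}}}"
    )


def _parse_enum(value: str, enum_cls, column: str):
    try:
        return enum_cls(value)
    except ValueError:
        raise _enum_error(value, enum_cls, column) from None


@dataclass(frozen=True)
class IHCAssessment:
    """One scorer's read-out for one marker: five per-HPF percent-positive values."""

    marker: Marker
    scorer_id: str  # "A" or "B"
    hpf_values: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.scorer_id not in ("A", "B"):
            raise CohortValidationError(
                f"scorer_id must be 'A' or 'B', got {self.scorer_id!r}"
            )
        vals = tuple(float(v) for v in self.hpf_values)
        if len(vals) != N_HPF:
            raise CohortValidationError(
                f"{self.marker.value} scorer {self.scorer_id}: exactly {N_HPF} HPF "
                f"values are required (five high-power fields are counted per "
                f"section), got {len(vals)}"
            )
        for v in vals:
            if not (0.0 <= v <= 100.0) or math.isnan(v):
                raise CohortValidationError(
                    f"{self.marker.value} scorer {self.scorer_id}: HPF value {v!r} "
                    f"outside [0, 100]"
                )
        object.__setattr__(self, "hpf_values", vals)

    @property
    def mean_rate(self) -> float:
        """Arithmetic mean of the five HPF percent-positive values."""
        return float(sum(self.hpf_values) / N_HPF)


@dataclass(frozen=True)
class PatientRecord:
    """One subject of the cohort.

    ``cd23_a``/``cd23_b`` and ``igd_a``/``igd_b`` hold the two blinded
    scorers' assessments; either scorer (or a whole marker) may be absent.
    """

    patient_id: str
    diagnosis: Diagnosis
    age: float
    sex: Sex
    duration_months: float
    sites: frozenset[Site]
    laterality: Laterality
    symptoms: frozenset[Symptom] = frozenset()
    cd23_a: IHCAssessment | None = None
    cd23_b: IHCAssessment | None = None
    igd_a: IHCAssessment | None = None
    igd_b: IHCAssessment | None = None
    lf_category: int | None = None
    igh_result: IghResult = IghResult.NOT_TESTED

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise CohortValidationError("patient_id must be a non-empty string")
        lo, hi = AGE_WINDOW
        if not (lo <= float(self.age) <= hi):
            raise CohortValidationError(
                f"patient {self.patient_id}: age {self.age} outside plausibility "
                f"window [{lo}, {hi}]"
            )
        if not float(self.duration_months) > 0:
            raise CohortValidationError(
                f"patient {self.patient_id}: duration_months must be > 0, "
                f"got {self.duration_months}"
            )
        if not self.sites:
            raise CohortValidationError(
                f"patient {self.patient_id}: at least one anatomical site is required"
            )
        if self.lf_category is not None and self.lf_category not in (0, 1, 2, 3):
            raise CohortValidationError(
                f"patient {self.patient_id}: lf_category must be 0-3, "
                f"got {self.lf_category!r}"
            )
        object.__setattr__(self, "sites", frozenset(self.sites))
        object.__setattr__(self, "symptoms", frozenset(self.symptoms))

    def marker_rate(self, marker: Marker) -> float | None:
        """Panel-level percent-positive rate: mean of the available scorers."""
        pair = (self.cd23_a, self.cd23_b) if marker is Marker.CD23 else (self.igd_a, self.igd_b)
        rates = [a.mean_rate for a in pair if a is not None]
        if not rates:
            return None
        return float(sum(rates) / len(rates))


# ---------------------------------------------------------------------------
# CSV schema
# ---------------------------------------------------------------------------

_HPF_BLOCKS = {
    "cd23_a": [f"cd23_hpf{i}" for i in range(1, 6)],
    "igd_a": [f"igd_hpf{i}" for i in range(1, 6)],
    "cd23_b": [f"cd23_hpf{i}_b" for i in range(1, 6)],
    "igd_b": [f"igd_hpf{i}_b" for i in range(1, 6)],
}

COHORT_COLUMNS: tuple[str, ...] = (
    "patient_id",
    "diagnosis",
    "age",
    "sex",
    "duration_months",
    "sites",
    "laterality",
    "symptoms",
    *_HPF_BLOCKS["cd23_a"],
    *_HPF_BLOCKS["igd_a"],
    *_HPF_BLOCKS["cd23_b"],
    *_HPF_BLOCKS["igd_b"],
    "lf_category",
    "igh_result",
)

_BLOCK_MARKER = {
    "cd23_a": (Marker.CD23, "A"),
    "cd23_b": (Marker.CD23, "B"),
    "igd_a": (Marker.IGD, "A"),
    "igd_b": (Marker.IGD, "B"),
}


def _is_blank(v: object) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and math.isnan(v):
        return True
    return isinstance(v, str) and v.strip() == ""


@dataclass
class CohortTable:
    """An ordered cohort backed by a DataFrame in the on-disk column layout.

    ``records`` materializes validated :class:`PatientRecord` objects; the
    frame form is what vectorized generation, scoring and summarization use.
    """

    frame: pd.DataFrame
    provenance: str = "user_csv"  # published_counts | synthetic | user_csv

    def __post_init__(self) -> None:
        missing = [c for c in COHORT_COLUMNS if c not in self.frame.columns]
        if missing:
            raise CohortValidationError(f"missing columns: {missing}")
        ids = self.frame["patient_id"].astype(str)
        dup = ids[ids.duplicated()]
        if len(dup):
            raise CohortValidationError(
                f"duplicate patient_id values: {sorted(set(dup))}"
            )
        self.frame = self.frame.loc[:, list(COHORT_COLUMNS)].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    @property
    def records(self) -> list[PatientRecord]:
        return [_row_to_record(row) for _, row in self.frame.iterrows()]

    @classmethod
    def from_records(
        cls, records: Iterable[PatientRecord], provenance: str = "user_csv"
    ) -> "CohortTable":
        rows = [_record_to_row(r) for r in records]
        frame = pd.DataFrame(rows, columns=list(COHORT_COLUMNS))
        return cls(frame=frame, provenance=provenance)


def _row_to_record(row: Mapping[str, object]) -> PatientRecord:
    pid = str(row["patient_id"])

    def fail(column: str, value: object, why: str) -> CohortValidationError:
        return CohortValidationError(
            f"patient {pid!r}, column {column!r}, value {value!r}: {why}"
        )

    diagnosis = _parse_enum(str(row["diagnosis"]), Diagnosis, "diagnosis")
    sex = _parse_enum(str(row["sex"]), Sex, "sex")
    laterality = _parse_enum(str(row["laterality"]), Laterality, "laterality")
    try:
        age = float(row["age"])  # type: ignore[arg-type]
        duration = float(row["duration_months"])  # type: ignore[arg-type]
    except (TypeError, ValueError):
        raise fail("age/duration_months", row["age"], "not numeric") from None

    sites = frozenset(
        _parse_enum(tok, Site, "sites")
        for tok in str(row["sites"]).split(";")
        if tok.strip()
    )
    symptoms = frozenset(
        _parse_enum(tok, Symptom, "symptoms")
        for tok in str(row["symptoms"]).split(";")
        if not _is_blank(row["symptoms"]) and tok.strip()
    )

    assessments: dict[str, IHCAssessment | None] = {}
    for block, cols in _HPF_BLOCKS.items():
        vals = [row[c] for c in cols]
        blank = [_is_blank(v) for v in vals]
        if all(blank):
            assessments[block] = None
        elif any(blank):
            filled = sum(not b for b in blank)
            marker, scorer = _BLOCK_MARKER[block]
            raise fail(
                cols[blank.index(True)],
                "",
                f"{marker.value} scorer {scorer} has {filled} of {N_HPF} HPF values; "
                f"exactly {N_HPF} high-power fields must be counted per section "
                f"(leave all five blank if the marker was not assessed)",
            )
        else:
            marker, scorer = _BLOCK_MARKER[block]
            assessments[block] = IHCAssessment(
                marker=marker,
                scorer_id=scorer,
                hpf_values=tuple(float(v) for v in vals),
            )

    lf_raw = row["lf_category"]
    lf_category = None if _is_blank(lf_raw) else int(float(lf_raw))  # type: ignore[arg-type]

    igh_raw = row["igh_result"]
    igh = (
        IghResult.NOT_TESTED
        if _is_blank(igh_raw)
        else _parse_enum(str(igh_raw), IghResult, "igh_result")
    )

    return PatientRecord(
        patient_id=pid,
        diagnosis=diagnosis,
        age=age,
        sex=sex,
        duration_months=duration,
        sites=sites,
        laterality=laterality,
        symptoms=symptoms,
        cd23_a=assessments["cd23_a"],
        cd23_b=assessments["cd23_b"],
        igd_a=assessments["igd_a"],
        igd_b=assessments["igd_b"],
        lf_category=lf_category,
        igh_result=igh,
    )


def _record_to_row(r: PatientRecord) -> dict[str, object]:
    row: dict[str, object] = {
        "patient_id": r.patient_id,
        "diagnosis": r.diagnosis.value,
        "age": r.age,
        "sex": r.sex.value,
        "duration_months": r.duration_months,
        "sites": ";".join(sorted(s.value for s in r.sites)),
        "laterality": r.laterality.value,
        "symptoms": ";".join(sorted(s.value for s in r.symptoms)),
        "lf_category": "" if r.lf_category is None else r.lf_category,
        "igh_result": r.igh_result.value,
    }
    for block, cols in _HPF_BLOCKS.items():
        a: IHCAssessment | None = getattr(r, block)
        for i, c in enumerate(cols):
            row[c] = "" if a is None else a.hpf_values[i]
    return row


def read_cohort(path: str | Path) -> CohortTable:
    """Read a cohort CSV, validating every row eagerly.

    Raises :class:`CohortValidationError` naming the offending patient,
    column and value on the first malformed row.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise CohortValidationError(
            f"{path}: header is missing required columns {missing}"
        )
    table = CohortTable(frame=frame, provenance="user_csv")
    table.records  # eager row-level validation
    return table


def write_cohort(table: CohortTable, path: str | Path) -> None:
    """Write a cohort CSV; absent fields become empty cells, never zeros."""
    frame = table.frame.copy()
    # normalize absent markers to empty strings so NaN never reaches disk
    frame = frame.astype(object).where(~frame.isna(), "")
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Packaged fixture: printed group-level summary of the 125-patient cohort
# ---------------------------------------------------------------------------


class PublishedCounts:
    """Printed group-level counts and summaries of the 125-patient cohort.

    Exposes the published counts (group sizes, per-category counts, age
    mean/SD/range, clonality results) exactly as printed; no per-subject
    data exist, so percentages are always recomputed from counts.
    """

    _CATEGORICAL = ("sex", "laterality", "sites", "symptoms")

    def __init__(self, payload: Mapping[str, object]) -> None:
        self._d = dict(payload)
        self.groups = tuple(Diagnosis(g) for g in self._d["groups"])
        # integrity: binary-variable counts can never exceed group n
        for var in ("sites", "symptoms"):
            for cat, counts in self._d[var].items():  # type: ignore[union-attr]
                for g, c in counts.items():
                    if c > self._d["n"][g]:
                        raise CohortValidationError(
                            f"fixture count {var}/{cat}/{g} exceeds group size"
                        )

    def group_n(self, group: Diagnosis | str) -> int:
        return int(self._d["n"][Diagnosis(group).value])

    @property
    def total_n(self) -> int:
        return sum(self.group_n(g) for g in self.groups)

    def count(self, group: Diagnosis | str, **selector: str) -> int:
        """Count for one group and one category, e.g. ``count("RFH", sex="female")``.

        ``site=`` and ``symptom=`` select the per-category binary counts.
        """
        if len(selector) != 1:
            raise ValueError("exactly one selector keyword is required")
        (key, cat), = selector.items()
        g = Diagnosis(group).value
        table_key = {"sex": "sex", "laterality": "laterality",
                     "site": "sites", "symptom": "symptoms"}.get(key)
        if table_key is None:
            raise ValueError(f"unknown selector {key!r}")
        try:
            return int(self._d[table_key][cat][g])
        except KeyError:
            raise KeyError(f"unknown category {cat!r} for {key!r}") from None

    def percent(self, group: Diagnosis | str, **selector: str) -> float:
        return 100.0 * self.count(group, **selector) / self.group_n(group)

    def age_summary(self, group: Diagnosis | str) -> dict[str, float]:
        d = dict(self._d["age"][Diagnosis(group).value])
        d["n"] = self.group_n(group)
        return d

    def duration_range(self, group: Diagnosis | str) -> tuple[float, float]:
        lo, hi = self._d["duration_months_range"][Diagnosis(group).value]
        return float(lo), float(hi)

    def overall_count(self, key: str) -> int:
        return int(self._d["overall"][key])

    def overall_percent(self, key: str) -> float:
        return 100.0 * self.overall_count(key) / self.total_n

    def clonality(self, group: Diagnosis | str) -> dict[str, int]:
        g = Diagnosis(group).value
        return {
            "tested": int(self._d["clonality"]["tested"][g]),
            "clonal": int(self._d["clonality"]["clonal"][g]),
        }

    @property
    def qc_failed_total(self) -> int:
        return int(self._d["clonality"]["qc_failed_total"])

    def contingency(
        self,
        variable: str,
        groups: Sequence[Diagnosis | str] | None = None,
        categories: Sequence[str] | None = None,
    ) -> np.ndarray:
        """Groups x categories count matrix for a categorical variable.

        For binary site/symptom variables pass the variable name (e.g.
        ``"pain"``); the columns are (present, absent).
        """
        gs = [Diagnosis(g) for g in (groups or self.groups)]
        if variable in ("sex", "laterality"):
            cats = categories or list(self._d[variable].keys())
            rows = [[self.count(g, **{variable: c}) for c in cats] for g in gs]
            return np.asarray(rows, dtype=int)
        for key, sel in (("sites", "site"), ("symptoms", "symptom")):
            if variable in self._d[key]:
                rows = []
                for g in gs:
                    c = self.count(g, **{sel: variable})
                    rows.append([c, self.group_n(g) - c])
                return np.asarray(rows, dtype=int)
        raise KeyError(f"unknown categorical variable {variable!r}")

    def printed_p(self, variable: str, comparison: str = "overall") -> str | None:
        """Printed p-value string for a variable row, if transcribed."""
        return self._d.get("printed_p", {}).get(variable, {}).get(comparison)

    def variables(self) -> dict[str, list[str]]:
        return {
            "sex": list(self._d["sex"].keys()),
            "laterality": list(self._d["laterality"].keys()),
            "sites": list(self._d["sites"].keys()),
            "symptoms": list(self._d["symptoms"].keys()),
        }


def load_published_counts() -> PublishedCounts:
    """Load the packaged printed-count fixture for the 125-patient cohort."""
    text = resources.files("lpdscore.data").joinpath("published_counts.json").read_text("utf-8")
    return PublishedCounts(json.loads(text))
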