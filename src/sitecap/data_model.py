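"""Record types and CSV I/O for site-level VMMC service-delivery data.

A dataset is a pair of CSV files joined on ``site_name``:

* ``sites.csv`` — one row per service-delivery site (static descriptors);
* ``monthly.csv`` — one row per site per month (targets, staffing, beds,
  days of operation, and performance counts).

Per-age-band counts are stored as one column per band (``reached_10-14``,
``seeking_10-14``, ``vmmc_10-14``, ...); per-source counts as
``source_<name>``.  Absent optional values are written as ``""`` and load
as ``None`` — distinct from zero — so incompleteness in routine program
data propagates as "unknown" rather than "nothing happened".
"""

from __future__ import annotations

import calendar
import math
import re
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
from pydantic import (
    BaseModel,
    ConfigDict,
    Field,
    ValidationError,
    field_validator,
    model_validator,
)

#: Default age bands for VMMC program reporting.
AGE_BANDS: Tuple[str, ...] = (
    "10-14", "15-19", "20-24", "25-29", "30-34", "35-49", "50+",
)

#: Demand-creation information sources captured per month.
INFO_SOURCES: Tuple[str, ...] = (
    "TV", "radio", "friend", "family", "partner",
    "mobilizers", "community_leaders", "posters", "health_workers",
)

SCHEMA_VERSION = "1"

_MONTH_RE = re.compile(r"^\d{4}-(0[1-9]|1[0-2])$")


class SchemaError(Exception):
    """A CSV file's header does not match the published column dictionary."""


class DatasetValidationError(Exception):
    """One or more rows violate a type or invariant.

    ``errors`` is a list of ``(row_number, message)`` pairs; row numbers
    are 1-based data-row indices within the offending file (header = row 0).
    Validation is total: every malformed row is reported, and no partially
    loaded dataset is ever returned.
    """

    def __init__(self, errors: List[Tuple[int, str]], source: str = ""):
        self.errors = list(errors)
        self.source = source
        lines = [f"  row {r}: {m}" for r, m in self.errors]
        where = f" in {source}" if source else ""
        super().__init__(
            f"{len(self.errors)} validation error(s){where}:\n" + "\n".join(lines)
        )


class DuplicateRecordError(DatasetValidationError):
    """Duplicate site name or duplicate (site, month) key."""


def days_in_month(month: str) -> int:
    y, m = int(month[:4]), int(month[5:7])
    return calendar.monthrange(y, m)[1]


class SiteProfile(BaseModel):
    """Static descriptors of a VMMC service-delivery site.

    ``parent_fixed_site`` links an outreach site to the fixed site that
    staffs and manages it; it is required exactly when ``delivery_mode``
    is ``outreach``.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    site_name: str
    health_zone: str
    province: str
    region: Optional[str] = None  # falls back to province when absent
    urban_rural: str
    ownership: str
    dreams_status: bool = False
    agency: str = ""
    implementing_partner: str = ""
    delivery_mode: str
    pepfar_category: str
    vmmc_category: str
    task_sharing: bool = False
    task_shifting: bool = False
    opening_date: str  # ISO YYYY-MM-DD
    parent_fixed_site: Optional[str] = None

    @field_validator("site_name")
    @classmethod
    def _nonempty_name(cls, v: str) -> str:
        if not v or not v.strip():
            raise ValueError("site_name must be non-empty")
        return v

    @field_validator("urban_rural")
    @classmethod
    def _urban_rural(cls, v: str) -> str:
        if v not in ("rural", "urban"):
            raise ValueError(f"urban_rural must be rural|urban, got {v!r}")
        return v

    @field_validator("ownership")
    @classmethod
    def _ownership(cls, v: str) -> str:
        if v not in ("public", "private", "NGO"):
            raise ValueError(f"ownership must be public|private|NGO, got {v!r}")
        return v

    @field_validator("delivery_mode")
    @classmethod
    def _mode(cls, v: str) -> str:
        if v not in ("fixed", "mobile", "outreach"):
            raise ValueError(f"delivery_mode must be fixed|mobile|outreach, got {v!r}")
        return v

    @field_validator("pepfar_category")
    @classmethod
    def _pepfar(cls, v: str) -> str:
        allowed = ("attained", "scale-up aggressive", "scale-up saturation")
        if v not in allowed:
            raise ValueError(f"pepfar_category must be one of {allowed}, got {v!r}")
        return v

    @field_validator("vmmc_category")
    @classmethod
    def _vmmc_cat(cls, v: str) -> str:
        allowed = ("scale-up", "sustainability", "saturated")
        if v not in allowed:
            raise ValueError(f"vmmc_category must be one of {allowed}, got {v!r}")
        return v

    @field_validator("opening_date")
    @classmethod
    def _opening(cls, v: str) -> str:
        if not re.match(r"^\d{4}-\d{2}-\d{2}$", v):
            raise ValueError(f"opening_date must be YYYY-MM-DD, got {v!r}")
        return v

    @model_validator(mode="after")
    def _parent_iff_outreach(self) -> "SiteProfile":
        if self.delivery_mode == "outreach" and not self.parent_fixed_site:
            raise ValueError("outreach site requires parent_fixed_site")
        if self.delivery_mode != "outreach" and self.parent_fixed_site:
            raise ValueError("parent_fixed_site only allowed for outreach sites")
        return self


def _check_count_map(v: Optional[Dict[str, int]], what: str) -> Optional[Dict[str, int]]:
    if v is None:
        return None
    for k, n in v.items():
        if not isinstance(n, int) or isinstance(n, bool) or n < 0:
            raise ValueError(f"{what}[{k}] must be a non-negative integer, got {n!r}")
    return dict(v)


class MonthlyRecord(BaseModel):
    """One site-month of targets, staffing, beds and performance counts.

    Performance fields are optional: ``None`` means "not reported", which
    is distinct from zero and propagates as an undefined indicator rather
    than a perfect or empty one.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    site_name: str
    month: str  # ISO "YYYY-MM"
    target: int = Field(ge=0)
    providers: int = Field(ge=0)
    trained_assistants: int = Field(ge=0)
    other_nurses: int = Field(ge=0)
    mobilizers: int = Field(ge=0)
    counselors: int = Field(ge=0)
    beds: int = Field(ge=0)
    days_of_operation: int = Field(ge=0)
    reached_by_age: Optional[Dict[str, int]] = None
    seeking_by_age: Optional[Dict[str, int]] = None
    reached_by_source: Optional[Dict[str, int]] = None
    vmmc_by_age: Optional[Dict[str, int]] = None
    followup_48h: Optional[int] = Field(default=None, ge=0)
    followup_7d: Optional[int] = Field(default=None, ge=0)
    followup_6w: Optional[int] = Field(default=None, ge=0)
    ae_mild: Optional[int] = Field(default=None, ge=0)
    ae_moderate: Optional[int] = Field(default=None, ge=0)
    ae_severe: Optional[int] = Field(default=None, ge=0)
    sti_diagnosed: Optional[int] = Field(default=None, ge=0)
    sti_treated_circumcised: Optional[int] = Field(default=None, ge=0)
    hiv_tests: Optional[int] = Field(default=None, ge=0)
    hiv_pos_referred: Optional[int] = Field(default=None, ge=0)

    @field_validator("month")
    @classmethod
    def _month_format(cls, v: str) -> str:
        if not _MONTH_RE.match(v):
            raise ValueError(f"month must be ISO 'YYYY-MM', got {v!r}")
        return v

    @field_validator("reached_by_age", "seeking_by_age", "vmmc_by_age",
                     "reached_by_source")
    @classmethod
    def _maps_nonneg(cls, v, info):
        return _check_count_map(v, info.field_name)

    @property
    def performed(self) -> Optional[int]:
        """Total VMMCs performed this month (sum over age bands), or None."""
        if self.vmmc_by_age is None:
            return None
        return sum(self.vmmc_by_age.values())

    @property
    def reached(self) -> Optional[int]:
        if self.reached_by_age is None:
            return None
        return sum(self.reached_by_age.values())

    @property
    def seeking(self) -> Optional[int]:
        if self.seeking_by_age is None:
            return None
        return sum(self.seeking_by_age.values())

    @model_validator(mode="after")
    def _cross_field(self) -> "MonthlyRecord":
        if self.days_of_operation > days_in_month(self.month):
            raise ValueError(
                f"days_of_operation {self.days_of_operation} exceeds days in "
                f"{self.month} ({days_in_month(self.month)})"
            )
        if (self.reached_by_source is not None
                and set(self.reached_by_source) != set(INFO_SOURCES)):
            raise ValueError(
                f"reached_by_source keys must be exactly {INFO_SOURCES}")
        bands = [m for m in (self.reached_by_age, self.seeking_by_age,
                             self.vmmc_by_age) if m is not None]
        if bands:
            keys = set(bands[0])
            for m in bands[1:]:
                if set(m) != keys:
                    raise ValueError("age-band keys differ across "
                                     "reached/seeking/vmmc maps")
        performed = self.performed
        if performed is not None:
            for name in ("followup_48h", "followup_7d", "followup_6w",
                         "ae_mild", "ae_moderate", "ae_severe"):
                v = getattr(self, name)
                if v is not None and v > performed:
                    raise ValueError(
                        f"{name} ({v}) exceeds VMMCs performed ({performed})"
                    )
        return self


class CapacityParams:
    """Constants of the site-capacity model.

    The capacity model assumes each circumcision occupies one station
    (a provider, or a surgical bed) for ``minutes_per_procedure`` minutes
    within an operating day of ``operating_minutes_per_day`` minutes, so a
    station handles ``slots_per_station_per_day`` procedures per day
    (defaults: 30-minute procedure, 450-minute day, 15 slots).  The three
    quantities are kept consistent: setting any one recomputes
    ``slots_per_station_per_day = floor(operating_minutes / minutes)``;
    assigning ``slots_per_station_per_day`` directly rescales the
    operating day.

    ``task_shifting_factor`` / ``task_sharing_factor`` scale current
    capacity for sites operating under task shifting (whole procedure
    delegated to a nurse or clinical officer) or task sharing (parts
    delegated); both default to 1.0 — no published coefficient exists, so
    by default the flags have no numeric effect and are available for a
    program to encode its own adjustment.

    ``cap_current_at_beds`` optionally caps current capacity at
    ``beds × slots`` for sites with more providers than beds (off by
    default: current capacity is providers × slots, exactly the original
    spreadsheet formula).

    ``staffing_template`` is the normative per-bed staffing ratio used to
    compute additional staff needed for optimum operation.
    """

    DEFAULT_TEMPLATE: Dict[str, float] = {
        "providers": 1.0,
        "trained_assistants": 1.0,
        "other_nurses": 1.0,
        "counselors": 1.0,
    }

    def __init__(
        self,
        minutes_per_procedure: float = 30.0,
        operating_minutes_per_day: float = 450.0,
        task_shifting_factor: float = 1.0,
        task_sharing_factor: float = 1.0,
        cap_current_at_beds: bool = False,
        staffing_template: Optional[Dict[str, float]] = None,
    ):
        if minutes_per_procedure <= 0:
            raise ValueError("minutes_per_procedure must be > 0")
        if operating_minutes_per_day <= 0:
            raise ValueError("operating_minutes_per_day must be > 0")
        if task_shifting_factor <= 0 or task_sharing_factor <= 0:
            raise ValueError("task factors must be > 0")
        self._minutes = float(minutes_per_procedure)
        self._operating = float(operating_minutes_per_day)
        self.task_shifting_factor = float(task_shifting_factor)
        self.task_sharing_factor = float(task_sharing_factor)
        self.cap_current_at_beds = bool(cap_current_at_beds)
        self.staffing_template = dict(
            staffing_template if staffing_template is not None
            else self.DEFAULT_TEMPLATE
        )
        for role, ratio in self.staffing_template.items():
            if ratio < 0:
                raise ValueError(f"staffing_template[{role}] must be >= 0")

    @property
    def minutes_per_procedure(self) -> float:
        return self._minutes

    @minutes_per_procedure.setter
    def minutes_per_procedure(self, v: float) -> None:
        if v <= 0:
            raise ValueError("minutes_per_procedure must be > 0")
        self._minutes = float(v)

    @property
    def operating_minutes_per_day(self) -> float:
        return self._operating

    @operating_minutes_per_day.setter
    def operating_minutes_per_day(self, v: float) -> None:
        if v <= 0:
            raise ValueError("operating_minutes_per_day must be > 0")
        self._operating = float(v)

    @property
    def slots_per_station_per_day(self) -> int:
        return math.floor(self._operating / self._minutes)

    @slots_per_station_per_day.setter
    def slots_per_station_per_day(self, v: int) -> None:
        if v <= 0:
            raise ValueError("slots_per_station_per_day must be > 0")
        self._operating = float(v) * self._minutes

    def to_dict(self) -> Dict:
        return {
            "minutes_per_procedure": self._minutes,
            "operating_minutes_per_day": self._operating,
            "task_shifting_factor": self.task_shifting_factor,
            "task_sharing_factor": self.task_sharing_factor,
            "cap_current_at_beds": self.cap_current_at_beds,
            "staffing_template": dict(self.staffing_template),
        }

    @classmethod
    def from_dict(cls, d: Dict) -> "CapacityParams":
        return cls(**d)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"CapacityParams(minutes={self._minutes}, "
                f"operating={self._operating}, "
                f"slots={self.slots_per_station_per_day})")

    def __eq__(self, other) -> bool:
        return isinstance(other, CapacityParams) and self.to_dict() == other.to_dict()


# ---------------------------------------------------------------------------
# CSV schema


SITE_COLUMNS = [
    "site_name", "health_zone", "province", "region", "urban_rural",
    "ownership", "dreams_status", "agency", "implementing_partner",
    "delivery_mode", "pepfar_category", "vmmc_category", "task_sharing",
    "task_shifting", "opening_date", "parent_fixed_site",
]

_MONTHLY_SCALARS = [
    "site_name", "month", "target", "providers", "trained_assistants",
    "other_nurses", "mobilizers", "counselors", "beds", "days_of_operation",
]
_MONTHLY_TAIL = [
    "followup_48h", "followup_7d", "followup_6w",
    "ae_mild", "ae_moderate", "ae_severe",
    "sti_diagnosed", "sti_treated_circumcised",
    "hiv_tests", "hiv_pos_referred",
]


def monthly_columns(age_bands: Sequence[str] = AGE_BANDS) -> List[str]:
    """Column order of monthly.csv for the given age-band configuration."""
    cols = list(_MONTHLY_SCALARS)
    for prefix in ("reached", "seeking", "vmmc"):
        cols += [f"{prefix}_{b}" for b in age_bands]
    cols += [f"source_{s}" for s in INFO_SOURCES]
    cols += _MONTHLY_TAIL
    return cols


def _infer_age_bands(columns: Sequence[str]) -> List[str]:
    """Recover the age-band configuration from monthly.csv headers."""
    bands: Dict[str, List[str]] = {}
    for prefix in ("reached", "seeking", "vmmc"):
        bands[prefix] = [c[len(prefix) + 1:] for c in columns
                         if c.startswith(prefix + "_")]
    if not (bands["reached"] == bands["seeking"] == bands["vmmc"]):
        raise SchemaError(
            "age-band columns differ across reached_/seeking_/vmmc_ prefixes: "
            f"{bands}"
        )
    if not bands["reached"]:
        raise SchemaError("no age-band columns (reached_*/seeking_*/vmmc_*) found")
    return bands["reached"]


def _check_header(actual: Sequence[str], expected: Sequence[str],
                  filename: str) -> None:
    missing = [c for c in expected if c not in actual]
    extra = [c for c in actual if c not in expected]
    if missing or extra:
        parts = []
        if missing:
            parts.append(f"missing columns {missing}")
        if extra:
            parts.append(f"unexpected columns {extra}")
        raise SchemaError(f"{filename}: " + "; ".join(parts))


def _cell(row, col) -> Optional[str]:
    v = row.get(col)
    if v is None:
        return None
    s = str(v).strip()
    return s if s != "" else None


def _parse_int(s: Optional[str], col: str) -> Optional[int]:
    if s is None:
        return None
    try:
        f = float(s)
    except ValueError:
        raise ValueError(f"{col}: not a number: {s!r}")
    if f != int(f):
        raise ValueError(f"{col}: not an integer: {s!r}")
    return int(f)


def _parse_bool(s: Optional[str], col: str) -> bool:
    if s is None:
        return False
    low = s.lower()
    if low in ("true", "1", "yes"):
        return True
    if low in ("false", "0", "no"):
        return False
    raise ValueError(f"{col}: not a boolean: {s!r}")


def read_dataset(
    path, schema_version: str = SCHEMA_VERSION,
) -> Tuple[List[SiteProfile], List[MonthlyRecord]]:
    """Read and fully validate a dataset directory (sites.csv + monthly.csv).

    Raises :class:`SchemaError` for header problems,
    :class:`DuplicateRecordError` for duplicate keys, and
    :class:`DatasetValidationError` (listing every offending row) for type
    or invariant violations.  On success every record's ``site_name``
    resolves to a profile.
    """
    if schema_version != SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema_version {schema_version!r}; "
                          f"this reader supports {SCHEMA_VERSION!r}")
    path = Path(path)
    sites_path = path / "sites.csv"
    monthly_path = path / "monthly.csv"
    for p in (sites_path, monthly_path):
        if not p.exists():
            raise FileNotFoundError(p)

    sites_df = pd.read_csv(sites_path, dtype=str, keep_default_na=False)
    monthly_df = pd.read_csv(monthly_path, dtype=str, keep_default_na=False)

    _check_header(list(sites_df.columns), SITE_COLUMNS, "sites.csv")
    age_bands = _infer_age_bands(list(monthly_df.columns))
    _check_header(list(monthly_df.columns), monthly_columns(age_bands),
                  "monthly.csv")

    profiles: List[SiteProfile] = []
    errors: List[Tuple[int, str]] = []
    for i, row in enumerate(sites_df.to_dict("records"), start=1):
        try:
            profiles.append(SiteProfile(
                site_name=_cell(row, "site_name") or "",
                health_zone=_cell(row, "health_zone") or "",
                province=_cell(row, "province") or "",
                region=_cell(row, "region"),
                urban_rural=_cell(row, "urban_rural") or "",
                ownership=_cell(row, "ownership") or "",
                dreams_status=_parse_bool(_cell(row, "dreams_status"),
                                          "dreams_status"),
                agency=_cell(row, "agency") or "",
                implementing_partner=_cell(row, "implementing_partner") or "",
                delivery_mode=_cell(row, "delivery_mode") or "",
                pepfar_category=_cell(row, "pepfar_category") or "",
                vmmc_category=_cell(row, "vmmc_category") or "",
                task_sharing=_parse_bool(_cell(row, "task_sharing"),
                                         "task_sharing"),
                task_shifting=_parse_bool(_cell(row, "task_shifting"),
                                          "task_shifting"),
                opening_date=_cell(row, "opening_date") or "",
                parent_fixed_site=_cell(row, "parent_fixed_site"),
            ))
        except (ValidationError, ValueError) as e:
            errors.append((i, _squash(e)))
    if errors:
        raise DatasetValidationError(errors, "sites.csv")

    records: List[MonthlyRecord] = []
    for i, row in enumerate(monthly_df.to_dict("records"), start=1):
        try:
            records.append(_record_from_row(row, age_bands))
        except (ValidationError, ValueError) as e:
            errors.append((i, _squash(e)))
    if errors:
        raise DatasetValidationError(errors, "monthly.csv")

    validate_dataset(profiles, records)
    return profiles, records


def _squash(e: Exception) -> str:
    if isinstance(e, ValidationError):
        return "; ".join(
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            if err["loc"] else err["msg"]
            for err in e.errors()
        )
    return str(e)


def _map_from_row(row, prefix: str, keys: Sequence[str],
                  colname) -> Optional[Dict[str, int]]:
    cells = {k: _cell(row, colname(k)) for k in keys}
    if all(v is None for v in cells.values()):
        return None
    out: Dict[str, int] = {}
    for k, s in cells.items():
        if s is None:
            raise ValueError(
                f"{prefix}: partially filled group (blank {colname(k)}); "
                "leave all cells blank or fill all"
            )
        v = _parse_int(s, colname(k))
        assert v is not None
        out[k] = v
    return out


def _record_from_row(row, age_bands: Sequence[str]) -> MonthlyRecord:
    kwargs: Dict = {
        "site_name": _cell(row, "site_name") or "",
        "month": _cell(row, "month") or "",
    }
    for col in _MONTHLY_SCALARS[2:]:
        v = _parse_int(_cell(row, col), col)
        if v is None:
            raise ValueError(f"{col}: required value is blank")
        kwargs[col] = v
    kwargs["reached_by_age"] = _map_from_row(
        row, "reached_by_age", age_bands, lambda b: f"reached_{b}")
    kwargs["seeking_by_age"] = _map_from_row(
        row, "seeking_by_age", age_bands, lambda b: f"seeking_{b}")
    kwargs["vmmc_by_age"] = _map_from_row(
        row, "vmmc_by_age", age_bands, lambda b: f"vmmc_{b}")
    kwargs["reached_by_source"] = _map_from_row(
        row, "reached_by_source", INFO_SOURCES, lambda s: f"source_{s}")
    for col in _MONTHLY_TAIL:
        kwargs[col] = _parse_int(_cell(row, col), col)
    return MonthlyRecord(**kwargs)


def validate_dataset(profiles: Sequence[SiteProfile],
                     records: Sequence[MonthlyRecord]) -> None:
    """Cross-record invariants: unique keys and resolvable references."""
    dup_errors: List[Tuple[int, str]] = []
    names: Dict[str, int] = {}
    for i, p in enumerate(profiles, start=1):
        if p.site_name in names:
            dup_errors.append((i, f"duplicate site_name {p.site_name!r} "
                                  f"(first at row {names[p.site_name]})"))
        else:
            names[p.site_name] = i
    if dup_errors:
        raise DuplicateRecordError(dup_errors, "sites.csv")

    ref_errors: List[Tuple[int, str]] = []
    by_name = {p.site_name: p for p in profiles}
    for i, p in enumerate(profiles, start=1):
        if p.parent_fixed_site is not None:
            parent = by_name.get(p.parent_fixed_site)
            if parent is None:
                ref_errors.append(
                    (i, f"parent_fixed_site {p.parent_fixed_site!r} "
                        "does not exist"))
            elif parent.delivery_mode != "fixed":
                ref_errors.append(
                    (i, f"parent_fixed_site {p.parent_fixed_site!r} is not a "
                        "fixed site"))
    if ref_errors:
        raise DatasetValidationError(ref_errors, "sites.csv")

    seen: Dict[Tuple[str, str], int] = {}
    for i, r in enumerate(records, start=1):
        key = (r.site_name, r.month)
        if key in seen:
            dup_errors.append((i, f"duplicate (site, month) {key} "
                                  f"(first at row {seen[key]})"))
        else:
            seen[key] = i
    if dup_errors:
        raise DuplicateRecordError(dup_errors, "monthly.csv")

    for i, r in enumerate(records, start=1):
        if r.site_name not in by_name:
            ref_errors.append((i, f"site_name {r.site_name!r} has no profile"))
    if ref_errors:
        raise DatasetValidationError(ref_errors, "monthly.csv")


# ---------------------------------------------------------------------------
# Writing


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, bool):
        return "true" if v else "false"
    return str(v)


def write_dataset(profiles: Sequence[SiteProfile],
                  records: Sequence[MonthlyRecord],
                  path,
                  age_bands: Optional[Sequence[str]] = None) -> None:
    """Write sites.csv and monthly.csv under ``path`` (a directory).

    Round-trips exactly: ``read_dataset(write_dataset(x)) == x`` field for
    field, including the absent-vs-zero distinction.  ``age_bands`` defaults
    to the bands observed in the records (or :data:`AGE_BANDS` when no
    record carries an age map).
    """
    validate_dataset(profiles, records)
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    if age_bands is None:
        age_bands = next(
            (list(r.vmmc_by_age) for r in records if r.vmmc_by_age is not None),
            None,
        ) or next(
            (list(r.reached_by_age) for r in records
             if r.reached_by_age is not None),
            None,
        ) or list(AGE_BANDS)

    site_rows = []
    for p in profiles:
        d = p.model_dump()
        site_rows.append({c: _fmt(d[c]) for c in SITE_COLUMNS})
    pd.DataFrame(site_rows, columns=SITE_COLUMNS).to_csv(
        path / "sites.csv", index=False)

    cols = monthly_columns(age_bands)
    rec_rows = []
    for r in records:
        row = {c: "" for c in cols}
        for col in _MONTHLY_SCALARS + _MONTHLY_TAIL:
            row[col] = _fmt(getattr(r, col))
        for prefix, m in (("reached", r.reached_by_age),
                          ("seeking", r.seeking_by_age),
                          ("vmmc", r.vmmc_by_age)):
            if m is not None:
                if set(m) != set(age_bands):
                    raise ValueError(
                        f"record ({r.site_name}, {r.month}): {prefix} age "
                        f"bands {sorted(m)} do not match the dataset bands "
                        f"{sorted(age_bands)}")
                for b in age_bands:
                    row[f"{prefix}_{b}"] = _fmt(m[b])
        if r.reached_by_source is not None:
            for s in INFO_SOURCES:
                row[f"source_{s}"] = _fmt(r.reached_by_source[s])
        rec_rows.append(row)
    pd.DataFrame(rec_rows, columns=cols).to_csv(path / "monthly.csv",
                                                index=False)
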