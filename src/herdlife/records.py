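"""Life-history records: quality control, culling groups, longevity coding.

A cow's raw life history (birth, calvings, culling date and reason) is
turned into 14 yearly binary longevity codes covering ages 2 to 15 under
three definitions:

* ``TL``  -- traditional longevity: 1 while the cow is alive, 0 after
  culling.
* ``FLa`` -- functional longevity, no missing codes: 1 if the cow calved
  at that age, 0 otherwise (whether culled or merely not calving).
* ``FLb`` -- functional longevity with missing codes: 1 if calved, 0 for
  ages after culling, missing while alive without a recorded calving.

Ages are expressed in completed years: ``floor(age)``.  A calving at *m*
months is assigned to the yearly slot ``clamp(round(m / 12), 2, 15)``.
"""

from __future__ import annotations

import datetime as dt
import enum
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .basis import DEFAULT_GRID

__all__ = [
    "CowLifeRecord",
    "CullingGroup",
    "LongevityPanel",
    "QCReport",
    "apply_quality_control",
    "assign_culling_group",
    "build_longevity_panel",
    "summarize_life_histories",
    "read_records",
    "write_records",
]

MISSING = -1  # panel code for a missing entry

MIN_FIRST_CALVING_MONTHS = 19
MAX_FIRST_CALVING_MONTHS = 30
MIN_BIRTH_YEAR = 1990
MAX_CULLING_AGE_YEARS = 20.0


class CullingGroup(str, enum.Enum):
    NATURAL_DEATH = "natural_death"
    STRUCTURAL_PROBLEMS = "structural_problems"
    DISEASE = "disease"
    FERTILITY = "fertility"
    PERFORMANCE = "performance"
    MISCELLANEOUS = "miscellaneous"
    ALL_REASONS = "all_reasons"


#: raw culling-reason code -> specific culling group
REASON_GROUPS: dict[str, CullingGroup] = {
    "died_unknown": CullingGroup.NATURAL_DEATH,
    "eye_problem": CullingGroup.STRUCTURAL_PROBLEMS,
    "body_structure": CullingGroup.STRUCTURAL_PROBLEMS,
    "teat_udder_conformation": CullingGroup.STRUCTURAL_PROBLEMS,
    "rectal_prolapse": CullingGroup.STRUCTURAL_PROBLEMS,
    "vaginal_prolapse": CullingGroup.STRUCTURAL_PROBLEMS,
    "feet_conformation": CullingGroup.STRUCTURAL_PROBLEMS,
    "illness_disease": CullingGroup.DISEASE,
    "fertility": CullingGroup.FERTILITY,
    "missed_calving": CullingGroup.FERTILITY,
    "productivity_performance": CullingGroup.PERFORMANCE,
    "temperament": CullingGroup.PERFORMANCE,
    "miscellaneous": CullingGroup.MISCELLANEOUS,
    "sold_commercial": CullingGroup.MISCELLANEOUS,
    "unknown_reason": CullingGroup.MISCELLANEOUS,
}


def assign_culling_group(raw_code: str, culling_age: float) -> CullingGroup:
    """Map a raw culling-reason code and culling age to a culling group.

    A cow culled over 15 years old is classed as natural death regardless
    of the recorded code ("culled due to age"); cows with an unknown
    reason under 15 fall into miscellaneous.
    """
    if culling_age > 15.0:
        return CullingGroup.NATURAL_DEATH
    try:
        return REASON_GROUPS[raw_code]
    except KeyError:
        raise KeyError(
            f"unmapped culling reason code: {raw_code!r}; known codes: "
            f"{sorted(REASON_GROUPS)}"
        ) from None


@dataclass
class CowLifeRecord:
    """One cow's raw life history."""

    cow_id: object
    herd_id: object
    birth_date: dt.date | None
    first_calving_age: float | None  # months
    calving_ages: list  # months, strictly increasing
    culling_age: float | None  # years, fractional
    culling_reason: str | None
    embryo_transfer: bool = False
    sire_id: object = None

    @property
    def birth_year(self) -> int | None:
        return self.birth_date.year if self.birth_date else None

    @property
    def birth_season(self) -> int:
        """Two birth seasons per year: 1 = Jan-Jun, 2 = Jul-Dec."""
        if self.birth_date is None:
            return 0
        return 1 if self.birth_date.month <= 6 else 2

    @property
    def birth_year_season(self) -> str:
        return f"{self.birth_year}_{self.birth_season}"

    def herd_year_season(self) -> str:
        return f"{self.herd_id}_{self.birth_year}_{self.birth_season}"

    @property
    def completed_culling_age(self) -> int | None:
        return None if self.culling_age is None else int(math.floor(self.culling_age))

    def calving_age_slots(self, grid=DEFAULT_GRID) -> set:
        """Yearly age slots (2..15) the recorded calvings map into."""
        slots = set()
        for m in self.calving_ages:
            j = int(math.floor(m / 12.0 + 0.5))
            slots.add(min(max(j, grid.min_age), grid.max_age))
        return slots


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

QC_RULES = (
    "missing_fields",
    "duplicate_culling",
    "birth_before_1990",
    "first_calving_window",
    "culling_age_over_20",
)


@dataclass
class QCReport:
    n_input: int = 0
    removed: dict = field(default_factory=lambda: {r: 0 for r in QC_RULES})
    n_retained: int = 0
    parse_errors: list = field(default_factory=list)

    def check(self) -> None:
        total = self.n_retained + sum(self.removed.values())
        if total != self.n_input:
            raise AssertionError("QC accounting mismatch")

    def to_frame(self) -> pd.DataFrame:
        rows = [("input", self.n_input)]
        rows += [(f"removed_{k}", v) for k, v in self.removed.items()]
        rows.append(("retained", self.n_retained))
        return pd.DataFrame(rows, columns=["rule", "count"])

    def log_lines(self) -> list[str]:
        return [f"QC {r}: {c}" for r, c in
                self.to_frame().itertuples(index=False)]


def apply_quality_control(records: list[CowLifeRecord]):
    """Apply the phenotypic quality-control rules in a fixed order.

    Rules, in application order: missing required fields (birth date,
    herd, culling reason or date); more than one culling record for the
    same cow; born before 1990; first calving outside 19-30 months;
    culling age over 20 years.  Returns (kept records, QCReport).
    """
    report = QCReport(n_input=len(records))

    def has_missing(r: CowLifeRecord) -> bool:
        return (
            r.birth_date is None
            or r.herd_id is None
            or (isinstance(r.herd_id, float) and math.isnan(r.herd_id))
            or r.culling_reason is None
            or r.culling_age is None
        )

    stage = [r for r in records if not has_missing(r)]
    report.removed["missing_fields"] = len(records) - len(stage)

    counts = pd.Series([r.cow_id for r in stage]).value_counts() if stage else pd.Series(dtype=int)
    dupes = set(counts[counts > 1].index)
    nxt = [r for r in stage if r.cow_id not in dupes]
    report.removed["duplicate_culling"] = len(stage) - len(nxt)
    stage = nxt

    nxt = [r for r in stage if r.birth_year >= MIN_BIRTH_YEAR]
    report.removed["birth_before_1990"] = len(stage) - len(nxt)
    stage = nxt

    def fc_ok(r: CowLifeRecord) -> bool:
        return (
            r.first_calving_age is not None
            and MIN_FIRST_CALVING_MONTHS <= r.first_calving_age <= MAX_FIRST_CALVING_MONTHS
        )

    nxt = [r for r in stage if fc_ok(r)]
    report.removed["first_calving_window"] = len(stage) - len(nxt)
    stage = nxt

    nxt = [r for r in stage if r.culling_age <= MAX_CULLING_AGE_YEARS]
    report.removed["culling_age_over_20"] = len(stage) - len(nxt)
    stage = nxt

    report.n_retained = len(stage)
    report.check()
    return stage, report


# ---------------------------------------------------------------------------
# longevity panels
# ---------------------------------------------------------------------------


@dataclass
class LongevityPanel:
    """cow x 14-age matrix of {0, 1, missing} codes under one definition."""

    definition: str  # TL | FLa | FLb
    cow_ids: np.ndarray
    codes: np.ndarray  # int8, MISSING (-1) for missing
    culling_group: np.ndarray  # str per cow
    ages: np.ndarray = field(default_factory=lambda: DEFAULT_GRID.ages.copy())

    def __post_init__(self):
        if self.codes.shape != (len(self.cow_ids), len(self.ages)):
            raise ValueError("panel shape mismatch")

    @property
    def n_cows(self) -> int:
        return len(self.cow_ids)

    def subset_group(self, group) -> "LongevityPanel":
        """Panel restricted to one culling group ('all_reasons' keeps all)."""
        group = CullingGroup(group)
        if group is CullingGroup.ALL_REASONS:
            return self
        mask = self.culling_group == group.value
        return LongevityPanel(self.definition, self.cow_ids[mask],
                              self.codes[mask], self.culling_group[mask],
                              self.ages)

    def to_long_frame(self) -> pd.DataFrame:
        n, m = self.codes.shape
        df = pd.DataFrame(
            {
                "cow_id": np.repeat(self.cow_ids, m),
                "age": np.tile(self.ages, n),
                "code": self.codes.ravel().astype(object),
            }
        )
        df.loc[df["code"] == MISSING, "code"] = pd.NA
        return df

    def write(self, path) -> None:
        self.to_long_frame().to_csv(path, index=False, na_rep="NA")


def build_longevity_panel(
    records: list[CowLifeRecord], definition: str, grid=DEFAULT_GRID
) -> LongevityPanel:
    """Code QC-passed records into a 14-column binary longevity panel."""
    if definition not in ("TL", "FLa", "FLb"):
        raise ValueError(f"unknown longevity definition: {definition}")
    ages = grid.ages
    n = len(records)
    codes = np.zeros((n, len(ages)), dtype=np.int8)
    groups = np.empty(n, dtype=object)
    for i, r in enumerate(records):
        if r.culling_age is None:
            raise ValueError(f"cow {r.cow_id} lacks a culling age (QC leak)")
        cy = r.completed_culling_age
        calved = r.calving_age_slots(grid)
        groups[i] = assign_culling_group(r.culling_reason, r.culling_age).value
        for k, j in enumerate(ages):
            if definition == "TL":
                codes[i, k] = 1 if cy >= j else 0
            elif definition == "FLa":
                codes[i, k] = 1 if j in calved else 0
            else:  # FLb
                if j in calved:
                    codes[i, k] = 1
                elif j > cy:
                    codes[i, k] = 0
                else:
                    codes[i, k] = MISSING
    return LongevityPanel(definition, np.array([r.cow_id for r in records]),
                          codes, groups.astype(str), ages.copy())


def summarize_life_histories(records: list[CowLifeRecord]) -> dict:
    """Descriptive statistics per culling group.

    Returns ``by_group`` (n, mean/SD culling age, mean calvings) and
    ``cumulative`` (cow counts by completed culling age) frames.
    """
    rows = []
    for r in records:
        rows.append(
            {
                "group": assign_culling_group(r.culling_reason, r.culling_age).value,
                "culling_age": r.culling_age,
                "n_calvings": len(r.calving_ages),
                "completed_age": r.completed_culling_age,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return {"by_group": pd.DataFrame(), "cumulative": pd.DataFrame()}
    by_group = (
        df.groupby("group")
        .agg(
            n=("culling_age", "size"),
            mean_culling_age=("culling_age", "mean"),
            sd_culling_age=("culling_age", lambda s: s.std(ddof=1)),
            mean_calvings=("n_calvings", "mean"),
        )
        .reset_index()
    )
    overall = pd.DataFrame(
        [{
            "group": CullingGroup.ALL_REASONS.value,
            "n": len(df),
            "mean_culling_age": df["culling_age"].mean(),
            "sd_culling_age": df["culling_age"].std(ddof=1),
            "mean_calvings": df["n_calvings"].mean(),
        }]
    )
    by_group = pd.concat([by_group, overall], ignore_index=True)
    cumulative = (
        df.groupby("completed_age").size().sort_index().cumsum()
        .rename("n_culled_by_age").reset_index()
    )
    return {"by_group": by_group, "cumulative": cumulative}


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------

RECORD_COLUMNS = [
    "cow_id", "herd_id", "birth_date", "first_calving_age", "calving_ages",
    "culling_age", "culling_reason", "embryo_transfer", "sire_id",
]


def write_records(records: list[CowLifeRecord], path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "cow_id": r.cow_id,
                "herd_id": r.herd_id,
                "birth_date": r.birth_date.isoformat() if r.birth_date else "",
                "first_calving_age": r.first_calving_age,
                "calving_ages": ";".join(str(m) for m in r.calving_ages),
                "culling_age": r.culling_age,
                "culling_reason": r.culling_reason or "",
                "embryo_transfer": int(r.embryo_transfer),
                "sire_id": r.sire_id if r.sire_id is not None else "",
            }
        )
    pd.DataFrame(rows, columns=RECORD_COLUMNS).to_csv(path, index=False)


def read_records(path) -> tuple[list[CowLifeRecord], list[str]]:
    """Parse a delimited records file; unparseable rows are collected,
    not silently dropped."""
    df = pd.read_csv(path, dtype={"culling_reason": str})
    records, errors = [], []
    for idx, row in df.iterrows():
        try:
            bd = row.get("birth_date")
            birth = (dt.date.fromisoformat(str(bd))
                     if isinstance(bd, str) and bd else None)
            calv = [float(m) for m in str(row.get("calving_ages", "")).split(";")
                    if m not in ("", "nan")]
            fca = row.get("first_calving_age")
            reason = row.get("culling_reason")
            records.append(
                CowLifeRecord(
                    cow_id=row["cow_id"],
                    herd_id=row["herd_id"] if not pd.isna(row["herd_id"]) else None,
                    birth_date=birth,
                    first_calving_age=None if pd.isna(fca) else float(fca),
                    calving_ages=calv,
                    culling_age=(None if pd.isna(row.get("culling_age"))
                                 else float(row["culling_age"])),
                    culling_reason=None if pd.isna(reason) else str(reason),
                    embryo_transfer=bool(int(row.get("embryo_transfer", 0) or 0)),
                    sire_id=(None if pd.isna(row.get("sire_id"))
                             else row.get("sire_id")),
                )
            )
        except Exception as exc:  # noqa: BLE001 - report, do not drop silently
            errors.append(f"row {idx}: {exc}")
    return records, errors
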