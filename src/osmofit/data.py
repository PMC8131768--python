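"""Experimental data model for salinity-tolerance and common-garden studies.

Two record types are supported:

* :class:`TolCensus` — one replicate box of an acute salinity-tolerance
  bioassay: ten-ish adults exposed to a fixed salinity, censused at 48, 72
  and 96 hours.  Dead individuals are removed at census, so the counts are
  cumulative survivors.
* :class:`GardenBox` — one common-garden box: adults of known origin
  (freshwater "FW" or brackish "BW") transplanted to a salinity treatment,
  censused daily by sex over a 30-day adult window, with box-level egg
  totals, F1 offspring counts and individual F1 longevity records followed
  to day 90.

Datasets are read and written as plain UTF-8 comma-separated tables with a
single header row.  Daily censuses and F1 longevity are stored long
(box_id, day, ...) in sidecar files next to the wide box table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger("osmofit")

EXPOSURE_HOURS = (48, 72, 96)
GARDEN_TREATMENTS = (0.0, 1.0, 3.0, 5.0, 11.0)
ADULT_WINDOW_DAYS = 30
F1_WINDOW_DAYS = 90


class SchemaError(ValueError):
    """A required column is missing or mis-typed in an input table."""


class ValidationError(ValueError):
    """A record violates a structural invariant of its type."""


@dataclass(frozen=True)
class Violation:
    """One invariant violation found by :func:`validate_dataset`."""

    record_id: str
    rule: str
    detail: str = ""

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.record_id}: {self.rule} ({self.detail})"


@dataclass
class TolCensus:
    """One replicate box of the acute tolerance bioassay."""

    replicate_id: str
    salinity: float
    n_initial: int
    alive_at: dict[int, int]  # exposure hour -> survivors
    population: str = ""

    def survivors(self, hour: int) -> int:
        if hour not in self.alive_at:
            raise KeyError(f"no census at {hour} hr for replicate {self.replicate_id}")
        return self.alive_at[hour]

    def deaths(self, hour: int) -> int:
        return self.n_initial - self.survivors(hour)

    def violations(self) -> list[Violation]:
        out: list[Violation] = []
        if self.salinity < 0:
            out.append(Violation(self.replicate_id, "negative_salinity", str(self.salinity)))
        if self.n_initial <= 0:
            out.append(Violation(self.replicate_id, "nonpositive_n_initial", str(self.n_initial)))
        prev = self.n_initial
        for hr in sorted(self.alive_at):
            n = self.alive_at[hr]
            if n < 0 or n > self.n_initial:
                out.append(Violation(self.replicate_id, "count_out_of_range", f"{hr} hr: {n}"))
            if n > prev:
                out.append(
                    Violation(self.replicate_id, "nonmonotone_survivors", f"{hr} hr: {n} > {prev}")
                )
            prev = n
        return out


@dataclass
class GardenBox:
    """One common-garden box (the independent experimental unit)."""

    box_id: str
    origin: str  # "FW" or "BW"
    treatment: float  # ppt; 0 denotes the freshwater treatment
    n_males: int
    n_females: int
    daily_alive: dict[str, list[int]]  # sex ("M"/"F") -> survivors at day 0..D
    eggs_total: int
    days_observed: int = ADULT_WINDOW_DAYS
    n_offspring: int = 0
    f1_longevity: list[tuple[int, bool]] = field(default_factory=list)
    # each F1 record: (day of death or last observation <= 90, True if death)

    @property
    def n_initial(self) -> int:
        return self.n_males + self.n_females

    def alive_on(self, day: int, sex: str | None = None) -> int:
        sexes = [sex] if sex else ["M", "F"]
        total = 0
        for s in sexes:
            series = self.daily_alive[s]
            if day >= len(series):
                raise ValidationError(
                    f"box {self.box_id}: no census recorded for day {day} (sex {s})"
                )
            total += series[day]
        return total

    def violations(self) -> list[Violation]:
        out: list[Violation] = []
        if self.eggs_total < 0:
            out.append(Violation(self.box_id, "negative_eggs", str(self.eggs_total)))
        if not (1 <= self.days_observed <= ADULT_WINDOW_DAYS):
            out.append(Violation(self.box_id, "days_observed_out_of_range", str(self.days_observed)))
        init = {"M": self.n_males, "F": self.n_females}
        for sex, series in self.daily_alive.items():
            if not series:
                out.append(Violation(self.box_id, "empty_daily_series", sex))
                continue
            if series[0] != init.get(sex, -1):
                out.append(
                    Violation(
                        self.box_id, "day0_mismatch", f"sex {sex}: {series[0]} != {init.get(sex)}"
                    )
                )
            for d in range(1, len(series)):
                if series[d] > series[d - 1]:
                    out.append(
                        Violation(self.box_id, "nonmonotone_daily_alive", f"sex {sex}, day {d}")
                    )
                    break
        for day, _ in self.f1_longevity:
            if not (1 <= day <= F1_WINDOW_DAYS):
                out.append(Violation(self.box_id, "f1_day_out_of_range", str(day)))
        return out


@dataclass
class Dataset:
    """Homogeneous collection of experiment records plus free-form metadata."""

    records: list
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def record_type(self) -> type | None:
        return type(self.records[0]) if self.records else None

    def ids(self) -> list[str]:
        if not self.records:
            return []
        attr = "replicate_id" if isinstance(self.records[0], TolCensus) else "box_id"
        return [getattr(r, attr) for r in self.records]


def validate_dataset(ds: Dataset) -> list[Violation]:
    """Collect every invariant violation in *ds* (empty list == valid).

    Violations are data, not exceptions: loaders raise, this reports.
    """
    out: list[Violation] = []
    seen: set[str] = set()
    for rec, rid in zip(ds.records, ds.ids()):
        if rid in seen:
            out.append(Violation(rid, "duplicate_id"))
        seen.add(rid)
        out.extend(rec.violations())
    if ds.records:
        kinds = {type(r) for r in ds.records}
        if len(kinds) > 1:
            out.append(Violation("<dataset>", "mixed_record_types", str(sorted(k.__name__ for k in kinds))))
    return out


def _require_columns(df: pd.DataFrame, cols: Iterable[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}; found {list(df.columns)}")


# ---------------------------------------------------------------------------
# Tolerance tables
# ---------------------------------------------------------------------------

TOL_COLUMNS = ("replicate_id", "population", "salinity", "n_initial", "alive_48", "alive_72", "alive_96")


def load_tolerance_table(path, schema: Mapping[str, str] | None = None) -> Dataset:
    """Read an acute-tolerance census CSV into a validated Dataset.

    *schema* maps logical column names (``replicate_id``, ``salinity``,
    ``n_initial``, ``alive_48`` ...) to the file's actual headers.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    _require_columns(df, [c for c in TOL_COLUMNS if c != "population"], path)
    if "population" not in df.columns:
        df["population"] = ""
    records = []
    for _, row in df.iterrows():
        rec = TolCensus(
            replicate_id=str(row["replicate_id"]),
            salinity=float(row["salinity"]),
            n_initial=int(row["n_initial"]),
            alive_at={hr: int(row[f"alive_{hr}"]) for hr in EXPOSURE_HOURS},
            population=str(row["population"]),
        )
        records.append(rec)
    if not records:
        logger.warning("%s: header-only file, loaded 0 records", path)
    ds = Dataset(records, metadata=_read_sidecar(path))
    _raise_on_violations(ds)
    if len(ds) != len(df):
        raise ValidationError(f"{path}: loaded {len(ds)} records from {len(df)} data rows")
    return ds


def write_tolerance_table(ds: Dataset, path) -> None:
    path = Path(path)
    rows = [
        {
            "replicate_id": r.replicate_id,
            "population": r.population,
            "salinity": r.salinity,
            "n_initial": r.n_initial,
            **{f"alive_{hr}": r.alive_at[hr] for hr in EXPOSURE_HOURS},
        }
        for r in ds.records
    ]
    pd.DataFrame(rows, columns=list(TOL_COLUMNS)).to_csv(path, index=False)
    _write_sidecar(path, ds.metadata)


# ---------------------------------------------------------------------------
# Common-garden tables
# ---------------------------------------------------------------------------

BOX_COLUMNS = (
    "box_id", "origin", "treatment", "n_males", "n_females",
    "eggs_total", "days_observed", "n_offspring",
)
DAILY_COLUMNS = ("box_id", "day", "sex", "n_alive")
F1_COLUMNS = ("box_id", "day", "event")


def _garden_paths(box_path) -> tuple[Path, Path, Path]:
    box_path = Path(box_path)
    stem = box_path.with_suffix("")
    return box_path, Path(f"{stem}_daily.csv"), Path(f"{stem}_f1.csv")


def load_garden_table(
    path,
    daily_path=None,
    f1_path=None,
    schema: Mapping[str, str] | None = None,
    strict: bool = True,
) -> Dataset:
    """Read a common-garden dataset (wide box table + long sidecars).

    The daily census and F1 longevity files default to ``<stem>_daily.csv``
    and ``<stem>_f1.csv`` next to the box table.  ``strict=False`` downgrades
    range errors (e.g. a treatment level outside the design) to warnings.
    """
    box_path, default_daily, default_f1 = _garden_paths(path)
    daily_path = Path(daily_path) if daily_path else default_daily
    f1_path = Path(f1_path) if f1_path else default_f1

    boxes = pd.read_csv(box_path)
    if schema:
        boxes = boxes.rename(columns={v: k for k, v in schema.items()})
    _require_columns(boxes, BOX_COLUMNS, box_path)
    daily = pd.read_csv(daily_path) if daily_path.exists() else pd.DataFrame(columns=DAILY_COLUMNS)
    if not daily.empty:
        _require_columns(daily, DAILY_COLUMNS, daily_path)
    f1 = pd.read_csv(f1_path) if f1_path.exists() else pd.DataFrame(columns=F1_COLUMNS)
    if not f1.empty:
        _require_columns(f1, F1_COLUMNS, f1_path)

    dup = boxes["box_id"].astype(str)[boxes["box_id"].astype(str).duplicated()].tolist()
    if dup:
        raise ValidationError(f"{box_path}: duplicate box_id(s) {sorted(set(dup))}")

    daily_by_box = dict(tuple(daily.groupby("box_id"))) if not daily.empty else {}
    f1_by_box = dict(tuple(f1.groupby("box_id"))) if not f1.empty else {}

    records = []
    for _, row in boxes.iterrows():
        bid = str(row["box_id"])
        treatment = float(row["treatment"])
        if treatment not in GARDEN_TREATMENTS:
            msg = f"box {bid}: treatment {treatment} ppt outside the design levels {GARDEN_TREATMENTS}"
            if strict:
                raise ValidationError(msg)
            warnings.warn(msg)
        sub = daily_by_box.get(row["box_id"])
        daily_alive: dict[str, list[int]] = {}
        if sub is not None:
            for sex, g in sub.groupby("sex"):
                g = g.sort_values("day")
                days = g["day"].tolist()
                if days != list(range(len(days))):
                    raise ValidationError(f"box {bid}: daily census days for sex {sex} are not 0..D")
                daily_alive[str(sex)] = g["n_alive"].astype(int).tolist()
        else:
            # no census sidecar: assume only day 0 known
            daily_alive = {"M": [int(row["n_males"])], "F": [int(row["n_females"])]}
        fsub = f1_by_box.get(row["box_id"])
        f1_events = (
            [(int(d), bool(e)) for d, e in zip(fsub["day"], fsub["event"])] if fsub is not None else []
        )
        records.append(
            GardenBox(
                box_id=bid,
                origin=str(row["origin"]),
                treatment=treatment,
                n_males=int(row["n_males"]),
                n_females=int(row["n_females"]),
                daily_alive=daily_alive,
                eggs_total=int(row["eggs_total"]),
                days_observed=int(row["days_observed"]),
                n_offspring=int(row["n_offspring"]),
                f1_longevity=f1_events,
            )
        )
    if not records:
        logger.warning("%s: header-only file, loaded 0 records", box_path)
    ds = Dataset(records, metadata=_read_sidecar(box_path))
    if strict:
        _raise_on_violations(ds)
    else:
        for v in validate_dataset(ds):
            warnings.warn(str(v))
    return ds


def write_garden_table(ds: Dataset, path, daily_path=None, f1_path=None) -> None:
    box_path, default_daily, default_f1 = _garden_paths(path)
    daily_path = Path(daily_path) if daily_path else default_daily
    f1_path = Path(f1_path) if f1_path else default_f1

    box_rows, daily_rows, f1_rows = [], [], []
    for b in ds.records:
        box_rows.append(
            {
                "box_id": b.box_id, "origin": b.origin, "treatment": b.treatment,
                "n_males": b.n_males, "n_females": b.n_females,
                "eggs_total": b.eggs_total, "days_observed": b.days_observed,
                "n_offspring": b.n_offspring,
            }
        )
        for sex, series in sorted(b.daily_alive.items()):
            for day, n in enumerate(series):
                daily_rows.append({"box_id": b.box_id, "day": day, "sex": sex, "n_alive": n})
        for day, event in b.f1_longevity:
            f1_rows.append({"box_id": b.box_id, "day": day, "event": int(event)})

    pd.DataFrame(box_rows, columns=list(BOX_COLUMNS)).to_csv(box_path, index=False)
    pd.DataFrame(daily_rows, columns=list(DAILY_COLUMNS)).to_csv(daily_path, index=False)
    pd.DataFrame(f1_rows, columns=list(F1_COLUMNS)).to_csv(f1_path, index=False)
    _write_sidecar(box_path, ds.metadata)


# ---------------------------------------------------------------------------
# Metadata sidecars
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".meta.yaml")


def _read_sidecar(path: Path) -> dict:
    sp = _sidecar_path(path)
    if sp.exists():
        with open(sp) as fh:
            return yaml.safe_load(fh) or {}
    return {}


def _write_sidecar(path: Path, metadata: dict) -> None:
    if metadata:
        with open(_sidecar_path(path), "w") as fh:
            yaml.safe_dump(metadata, fh, sort_keys=True)


def _raise_on_violations(ds: Dataset) -> None:
    violations = validate_dataset(ds)
    if violations:
        lines = "; ".join(str(v) for v in violations[:10])
        raise ValidationError(f"{len(violations)} validation error(s): {lines}")
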