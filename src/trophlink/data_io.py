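"""Schema-validated readers and writers for the survey tables.

All tables are plain CSV (UTF-8, "." decimal separator, ISO-8601 dates and
timestamps). Depths are metres, positive down; depth strata elsewhere in the
package are half-open ``[lower, upper)`` intervals. Unknown columns are
ignored with a logged warning so that extended tables keep loading.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

logger = logging.getLogger("trophlink")

DielPeriod = Literal["day", "night", "twilight"]
SizeClass = Literal["small", "large"]
IsotopeGroup = Literal[
    "consumer-small",
    "consumer-large",
    "prey",
    "epipelagic-predator",
    "bathypelagic-predator",
    "LTL",
    "POM",
]
LengthConvention = Literal[
    "SL-fish", "eye-to-telson-decapod", "rostrum-to-telson-euphausiid"
]


class SchemaError(ValueError):
    """A CSV row violated the declared schema (names file, row, column)."""


class StationRecord(BaseModel):
    station_id: str
    latitude: float = Field(ge=-90, le=90)
    longitude: float = Field(ge=-180, le=180)
    date: dt.date
    sunrise: dt.time
    sunset: dt.time

    @model_validator(mode="after")
    def _solar_order(self) -> "StationRecord":
        if self.sunrise >= self.sunset:
            raise ValueError(f"station {self.station_id}: sunrise must precede sunset")
        return self


class TrawlEvent(BaseModel):
    trawl_id: str
    station_id: str
    start_time: dt.datetime
    end_time: dt.datetime
    depth_min_m: float = Field(ge=0)
    depth_max_m: float
    mouth_area_m2: float = Field(gt=0)
    diel_period: Optional[DielPeriod] = None

    @model_validator(mode="after")
    def _ordering(self) -> "TrawlEvent":
        if self.end_time <= self.start_time:
            raise ValueError(f"trawl {self.trawl_id}: end_time must follow start_time")
        if self.depth_max_m <= self.depth_min_m:
            raise ValueError(f"trawl {self.trawl_id}: depth_min_m must be < depth_max_m")
        return self

    @property
    def duration_h(self) -> float:
        return (self.end_time - self.start_time).total_seconds() / 3600.0

    @property
    def midpoint_depth_m(self) -> float:
        return 0.5 * (self.depth_min_m + self.depth_max_m)


class SpecimenRecord(BaseModel):
    specimen_id: str
    trawl_id: str
    taxon: str
    standard_length_cm: float = Field(gt=0)
    total_weight_g: float = Field(gt=0)
    size_class: Optional[SizeClass] = None


class PreyItem(BaseModel):
    category: str
    count: int = Field(ge=1)
    weight_g: float = Field(ge=0)
    prey_length_mm: Optional[float] = None
    length_convention: Optional[LengthConvention] = None


class StomachRecord(BaseModel):
    specimen_id: str
    is_empty: bool
    items: list[PreyItem] = Field(default_factory=list)

    @model_validator(mode="after")
    def _empty_consistent(self) -> "StomachRecord":
        if self.is_empty != (len(self.items) == 0):
            raise ValueError(
                f"stomach {self.specimen_id}: is_empty flag inconsistent with items"
            )
        return self


class IsotopeSample(BaseModel):
    sample_id: str
    taxon: str
    group: IsotopeGroup
    d13C: float
    d15N: float
    CN_mass: Optional[float] = None
    lipid_corrected: bool = False
    d13C_raw: Optional[float] = None

    @field_validator("CN_mass")
    @classmethod
    def _cn_positive(cls, v: Optional[float]) -> Optional[float]:
        if v is not None and v <= 0:
            raise ValueError("CN_mass must be > 0 when present")
        return v

    @model_validator(mode="after")
    def _raw_when_corrected(self) -> "IsotopeSample":
        if self.lipid_corrected and self.d13C_raw is None:
            raise ValueError(f"sample {self.sample_id}: corrected sample lacks d13C_raw")
        return self


class CTDProfile(BaseModel):
    station_id: str
    depth_m: list[float]
    temperature_C: list[float]
    oxygen_ml_l: list[float]
    salinity: list[float]
    fluorescence: list[float]

    @model_validator(mode="after")
    def _grid(self) -> "CTDProfile":
        n = len(self.depth_m)
        for name in ("temperature_C", "oxygen_ml_l", "salinity", "fluorescence"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"profile {self.station_id}: {name} length mismatch")
        if any(b <= a for a, b in zip(self.depth_m, self.depth_m[1:])):
            raise ValueError(f"profile {self.station_id}: depth_m must strictly increase")
        return self


@dataclass
class Dataset:
    """The fully linked survey: one object per table, list-of-records style."""

    stations: list[StationRecord] = field(default_factory=list)
    trawls: list[TrawlEvent] = field(default_factory=list)
    specimens: list[SpecimenRecord] = field(default_factory=list)
    stomachs: list[StomachRecord] = field(default_factory=list)
    isotopes: list[IsotopeSample] = field(default_factory=list)
    ctd: list[CTDProfile] = field(default_factory=list)

    def specimen_by_id(self) -> dict[str, SpecimenRecord]:
        return {s.specimen_id: s for s in self.specimens}

    def trawl_by_id(self) -> dict[str, TrawlEvent]:
        return {t.trawl_id: t for t in self.trawls}

    def station_by_id(self) -> dict[str, StationRecord]:
        return {s.station_id: s for s in self.stations}


@dataclass
class ValidationIssue:
    severity: Literal["error", "warning"]
    table: str
    record_id: str
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def is_clean(self) -> bool:
        return not self.issues

    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "error"]

    def add(self, severity: str, table: str, record_id: str, message: str) -> None:
        self.issues.append(ValidationIssue(severity, table, record_id, message))  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# Reading

_EXPECTED_COLUMNS = {
    "stations": ["station_id", "latitude", "longitude", "date", "sunrise", "sunset"],
    "trawls": [
        "trawl_id", "station_id", "start_time", "end_time",
        "depth_min_m", "depth_max_m", "mouth_area_m2", "diel_period",
    ],
    "specimens": [
        "specimen_id", "trawl_id", "taxon",
        "standard_length_cm", "total_weight_g", "size_class",
    ],
    "stomachs": [
        "specimen_id", "is_empty", "category", "count",
        "weight_g", "prey_length_mm", "length_convention",
    ],
    "isotopes": [
        "sample_id", "taxon", "group", "d13C", "d15N",
        "CN_mass", "lipid_corrected", "d13C_raw",
    ],
    "ctd": [
        "station_id", "depth_m", "temperature_C",
        "oxygen_ml_l", "salinity", "fluorescence",
    ],
}

_REQUIRED_COLUMNS = {
    "stations": _EXPECTED_COLUMNS["stations"],
    "trawls": _EXPECTED_COLUMNS["trawls"][:-1],
    "specimens": _EXPECTED_COLUMNS["specimens"][:-1],
    "stomachs": ["specimen_id", "is_empty"],
    "isotopes": ["sample_id", "taxon", "group", "d13C", "d15N"],
    "ctd": _EXPECTED_COLUMNS["ctd"],
}


def _read_table(path: Path, table: str) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(f"{table} table not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS[table] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    unknown = [c for c in df.columns if c not in _EXPECTED_COLUMNS[table]]
    if unknown:
        logger.warning("%s: ignoring unknown column(s) %s", path, unknown)
        df = df.drop(columns=unknown)
    return df


def _opt(value: str) -> Optional[str]:
    return value if value not in ("", "NA", "nan", "None") else None


def _build(model, table: str, path: Path, row_ix: int, **kwargs):
    try:
        return model(**kwargs)
    except Exception as exc:  # pydantic ValidationError or ValueError
        raise SchemaError(f"{path}, row {row_ix + 2}: {exc}") from exc


def load_dataset(paths: Mapping[str, str | Path]) -> Dataset:
    """Load all survey tables into a linked :class:`Dataset`.

    ``paths`` maps table names (``stations``, ``trawls``, ``specimens``,
    ``stomachs``, ``isotopes``, ``ctd``) to CSV files; tables may be omitted
    and then load empty. Schema violations raise :class:`SchemaError` naming
    file and row; broken foreign keys raise after loading via
    :func:`validate` semantics (a stomach row pointing at an unknown specimen
    is reported with its row number).
    """
    ds = Dataset()
    p = {k: Path(v) for k, v in paths.items()}

    if "stations" in p:
        for i, row in _read_table(p["stations"], "stations").iterrows():
            ds.stations.append(_build(
                StationRecord, "stations", p["stations"], i,
                station_id=row["station_id"], latitude=row["latitude"],
                longitude=row["longitude"], date=row["date"],
                sunrise=row["sunrise"], sunset=row["sunset"]))
    if "trawls" in p:
        for i, row in _read_table(p["trawls"], "trawls").iterrows():
            ds.trawls.append(_build(
                TrawlEvent, "trawls", p["trawls"], i,
                trawl_id=row["trawl_id"], station_id=row["station_id"],
                start_time=row["start_time"], end_time=row["end_time"],
                depth_min_m=row["depth_min_m"], depth_max_m=row["depth_max_m"],
                mouth_area_m2=row["mouth_area_m2"],
                diel_period=_opt(row.get("diel_period", ""))))
    if "specimens" in p:
        for i, row in _read_table(p["specimens"], "specimens").iterrows():
            ds.specimens.append(_build(
                SpecimenRecord, "specimens", p["specimens"], i,
                specimen_id=row["specimen_id"], trawl_id=row["trawl_id"],
                taxon=row["taxon"],
                standard_length_cm=row["standard_length_cm"],
                total_weight_g=row["total_weight_g"],
                size_class=_opt(row.get("size_class", ""))))
    if "stomachs" in p:
        ds.stomachs.extend(_load_stomachs(p["stomachs"]))
    if "isotopes" in p:
        for i, row in _read_table(p["isotopes"], "isotopes").iterrows():
            ds.isotopes.append(_build(
                IsotopeSample, "isotopes", p["isotopes"], i,
                sample_id=row["sample_id"], taxon=row["taxon"],
                group=row["group"], d13C=row["d13C"], d15N=row["d15N"],
                CN_mass=_opt(row.get("CN_mass", "")),
                lipid_corrected=row.get("lipid_corrected", "False") in ("True", "true", "1"),
                d13C_raw=_opt(row.get("d13C_raw", ""))))
    if "ctd" in p:
        ds.ctd.extend(_load_ctd(p["ctd"]))

    known_specimens = {s.specimen_id for s in ds.specimens}
    if ds.specimens or not ds.stomachs:
        for st in ds.stomachs:
            if st.specimen_id not in known_specimens:
                raise SchemaError(
                    f"{p.get('stomachs')}: stomach row references unknown specimen "
                    f"'{st.specimen_id}'")
    return ds


def _load_stomachs(path: Path) -> list[StomachRecord]:
    df = _read_table(path, "stomachs")
    records: list[StomachRecord] = []
    for spec_id, grp in df.groupby("specimen_id", sort=False):
        is_empty = grp["is_empty"].iloc[0] in ("True", "true", "1")
        items = []
        if not is_empty:
            for i, row in grp.iterrows():
                items.append(_build(
                    PreyItem, "stomachs", path, i,
                    category=row["category"], count=row["count"],
                    weight_g=row["weight_g"],
                    prey_length_mm=_opt(row.get("prey_length_mm", "")),
                    length_convention=_opt(row.get("length_convention", ""))))
        records.append(StomachRecord(specimen_id=str(spec_id), is_empty=is_empty, items=items))
    return records


def _load_ctd(path: Path) -> list[CTDProfile]:
    df = _read_table(path, "ctd").astype({
        "depth_m": float, "temperature_C": float, "oxygen_ml_l": float,
        "salinity": float, "fluorescence": float})
    profiles = []
    for sid, grp in df.groupby("station_id", sort=False):
        grp = grp.sort_values("depth_m")
        profiles.append(CTDProfile(
            station_id=str(sid),
            depth_m=grp["depth_m"].tolist(),
            temperature_C=grp["temperature_C"].tolist(),
            oxygen_ml_l=grp["oxygen_ml_l"].tolist(),
            salinity=grp["salinity"].tolist(),
            fluorescence=grp["fluorescence"].tolist()))
    return profiles


# ---------------------------------------------------------------------------
# Validation

def validate(ds: Dataset) -> ValidationReport:
    """Report every invariant violation; never raises.

    The report is empty iff the dataset is clean. Severity is ``error`` for
    violations that would corrupt downstream statistics (broken links,
    non-positive measurements) and ``warning`` for recoverable oddities.
    """
    rep = ValidationReport()

    def dupes(ids: Sequence[str], table: str) -> None:
        seen: set[str] = set()
        for x in ids:
            if x in seen:
                rep.add("error", table, x, "duplicate primary id")
            seen.add(x)

    dupes([s.station_id for s in ds.stations], "stations")
    dupes([t.trawl_id for t in ds.trawls], "trawls")
    dupes([s.specimen_id for s in ds.specimens], "specimens")
    dupes([s.sample_id for s in ds.isotopes], "isotopes")
    dupes([s.specimen_id for s in ds.stomachs], "stomachs")

    stations = {s.station_id for s in ds.stations}
    trawls = {t.trawl_id for t in ds.trawls}
    specimens = {s.specimen_id for s in ds.specimens}

    for t in ds.trawls:
        if t.station_id not in stations:
            rep.add("error", "trawls", t.trawl_id, f"unknown station '{t.station_id}'")
        if t.depth_min_m >= t.depth_max_m:
            rep.add("error", "trawls", t.trawl_id, "depth_min_m >= depth_max_m")
    for s in ds.specimens:
        if s.trawl_id not in trawls:
            rep.add("error", "specimens", s.specimen_id, f"unknown trawl '{s.trawl_id}'")
        if s.standard_length_cm <= 0:
            rep.add("error", "specimens", s.specimen_id, "non-positive standard length")
        if s.total_weight_g <= 0:
            rep.add("error", "specimens", s.specimen_id, "non-positive total weight")
    for st in ds.stomachs:
        if st.specimen_id not in specimens:
            rep.add("error", "stomachs", st.specimen_id, "unknown specimen")
        if st.is_empty != (len(st.items) == 0):
            rep.add("error", "stomachs", st.specimen_id, "is_empty flag inconsistent")
    for prof in ds.ctd:
        if prof.station_id not in stations:
            rep.add("warning", "ctd", prof.station_id, "profile at unknown station")
    return rep


# ---------------------------------------------------------------------------
# Writing

def _records_frame(ds: Dataset, table: str) -> pd.DataFrame:
    if table == "stations":
        rows = [s.model_dump() for s in ds.stations]
    elif table == "trawls":
        rows = [t.model_dump() for t in ds.trawls]
    elif table == "specimens":
        rows = [s.model_dump() for s in ds.specimens]
    elif table == "isotopes":
        rows = [s.model_dump() for s in ds.isotopes]
    elif table == "stomachs":
        rows = []
        for st in ds.stomachs:
            if st.is_empty:
                rows.append({"specimen_id": st.specimen_id, "is_empty": True,
                             "category": "", "count": "", "weight_g": "",
                             "prey_length_mm": "", "length_convention": ""})
            else:
                for it in st.items:
                    rows.append({"specimen_id": st.specimen_id, "is_empty": False,
                                 **it.model_dump()})
    elif table == "ctd":
        rows = []
        for prof in ds.ctd:
            for k in range(len(prof.depth_m)):
                rows.append({
                    "station_id": prof.station_id, "depth_m": prof.depth_m[k],
                    "temperature_C": prof.temperature_C[k],
                    "oxygen_ml_l": prof.oxygen_ml_l[k],
                    "salinity": prof.salinity[k],
                    "fluorescence": prof.fluorescence[k]})
    else:  # pragma: no cover
        raise KeyError(table)
    return pd.DataFrame(rows, columns=_EXPECTED_COLUMNS[table])


def write_dataset(ds: Dataset, outdir: str | Path) -> dict[str, Path]:
    """Write the six survey CSVs; returns table -> path. Inverse of load."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}
    for table in _EXPECTED_COLUMNS:
        df = _records_frame(ds, table)
        path = outdir / f"{table}.csv"
        df.to_csv(path, index=False)
        written[table] = path
    return written


def write_results(bundle: Mapping[str, pd.DataFrame], outdir: str | Path,
                  config: Optional[Mapping] = None,
                  seed: Optional[int] = None) -> dict:
    """Write one CSV per result table plus a JSON run manifest.

    Re-running with the same inputs and seed reproduces byte-identical CSVs:
    tables are written with a fixed dialect and the manifest records a sha256
    checksum per file.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "config": dict(config) if config else {},
                      "files": {}}
    for name, df in bundle.items():
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False, lineterminator="\n")
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        manifest["files"][f"{name}.csv"] = digest
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    return manifest
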