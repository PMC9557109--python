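"""Domain types, CSV schemas, validation and loading of a complete trial dataset.

A *trial dataset* bundles everything a multi-year maize hybrid comparison
measures: daily weather, phenology dates, per-plant organ dry masses at
silking (R1) and physiological maturity (R6), leaf-area-index and ear-leaf
gas-exchange observations, ¹³C pulse-label samples, and plot-level yield
components.  One CSV file per table, ISO-8601 dates, units fixed per column
and documented in the headers; design metadata (planting density, replicate
count) travels in a small YAML sidecar.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

__all__ = [
    "WeatherDay",
    "StageRecord",
    "PlantSample",
    "LAIObservation",
    "GasExchangeObservation",
    "IsotopeSample",
    "YieldPlot",
    "TrialDataset",
    "Violation",
    "ValidationReport",
    "SchemaError",
    "RowParseError",
    "DatasetValidationError",
    "DomainError",
    "InvariantError",
    "read_trial_dataset",
    "write_trial_dataset",
    "validate_dataset",
    "STAGE_ORDER",
    "ORGANS",
]


class DomainError(ValueError):
    """An argument lies outside the physical/mathematical domain of an operation."""


class InvariantError(ValueError):
    """A data invariant (e.g. tmax >= tmin) is violated."""


class SchemaError(ValueError):
    """A CSV table is missing a required column."""


class RowParseError(ValueError):
    """A CSV row holds an unparsable date or number."""


class DatasetValidationError(ValueError):
    """Raised by read_trial_dataset when the loaded dataset violates invariants."""

    def __init__(self, report: "ValidationReport"):
        self.report = report
        super().__init__("dataset failed validation:\n" + str(report))


STAGE_ORDER = ("sowing", "v6", "v12", "r1", "r3", "r5", "r6")
ORGANS = ("grain", "other", "stalk", "leaf")


# ---------------------------------------------------------------------------
# Record types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WeatherDay:
    """One day of weather: calendar date, daily maximum and minimum air temperature (°C)."""

    date: _dt.date
    tmax: float
    tmin: float


@dataclass(frozen=True)
class StageRecord:
    """Phenology dates for one year x hybrid.

    R5 is defined operationally as 45 days after silking; R6 is physiological
    maturity (kernel black layer).
    """

    year: str
    hybrid: str
    sowing: _dt.date
    v6: _dt.date
    v12: _dt.date
    r1: _dt.date
    r3: _dt.date
    r5: _dt.date
    r6: _dt.date

    def dates_in_order(self) -> tuple[_dt.date, ...]:
        return tuple(getattr(self, s) for s in STAGE_ORDER)


@dataclass(frozen=True)
class PlantSample:
    """Per-plant organ dry masses (g plant⁻¹) at stage R1 or R6.

    grain and other (bract + cob) exist only at R6 and are None at R1.
    """

    year: str
    hybrid: str
    replicate: int
    stage: str  # "R1" | "R6"
    leaf: float
    stalk: float
    grain: float | None = None
    other: float | None = None

    def total(self) -> float:
        return self.leaf + self.stalk + (self.grain or 0.0) + (self.other or 0.0)


@dataclass(frozen=True)
class LAIObservation:
    """Leaf area index (m² leaf per m² ground) at a stage; time axis is days after silking."""

    year: str
    hybrid: str
    stage: str
    days_after_silking: float
    lai: float


@dataclass(frozen=True)
class GasExchangeObservation:
    """Ear-leaf gas exchange: Pn (µmol CO₂ m⁻² s⁻¹), Gs (mol m⁻² s⁻¹), Ci (µmol mol⁻¹); optional SPAD."""

    year: str
    hybrid: str
    stage: str
    days_after_silking: float
    pn: float
    gs: float
    ci: float
    spad: float | None = None


@dataclass(frozen=True)
class IsotopeSample:
    """One organ of one pulse-labeled (or unlabeled reference) plant: dry mass and ¹³C atom-%."""

    year: str
    hybrid: str
    plant_id: str
    labeled: bool
    organ: str  # grain | other | stalk | leaf
    mass_g: float
    atom_pct_13c: float


@dataclass(frozen=True)
class YieldPlot:
    """Plot-level yield components; yield standardized to 14% kernel moisture (kg ha⁻¹)."""

    year: str
    hybrid: str
    replicate: int
    ears_per_ha: float
    grains_per_ear: float
    thousand_grain_g: float
    moisture: float
    yield_kg_ha: float


@dataclass
class TrialDataset:
    """A complete trial: weather per year plus all measurement tables and design metadata."""

    weather: dict[str, list[WeatherDay]] = field(default_factory=dict)
    stages: list[StageRecord] = field(default_factory=list)
    plant_samples: list[PlantSample] = field(default_factory=list)
    lai: list[LAIObservation] = field(default_factory=list)
    gas_exchange: list[GasExchangeObservation] = field(default_factory=list)
    isotope: list[IsotopeSample] = field(default_factory=list)
    yield_plots: list[YieldPlot] = field(default_factory=list)
    density_plants_ha: float = 75_000.0
    replicates: int = 3

    # -- convenience frames used by the analysis layers ---------------------

    def plant_samples_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(r) for r in self.plant_samples])

    def lai_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(r) for r in self.lai])

    def gas_exchange_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(r) for r in self.gas_exchange])

    def isotope_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(r) for r in self.isotope])

    def yield_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(r) for r in self.yield_plots])

    def year_hybrids(self) -> list[tuple[str, str]]:
        return [(s.year, s.hybrid) for s in self.stages]

    def stage_record(self, year: str, hybrid: str) -> StageRecord:
        for s in self.stages:
            if s.year == year and s.hybrid == hybrid:
                return s
        raise KeyError(f"no StageRecord for year={year!r} hybrid={hybrid!r}")


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Violation:
    severity: str  # "error" | "warning"
    table: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.severity}] {self.table}: {self.message}"


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not any(v.severity == "error" for v in self.violations)

    def errors(self) -> list[Violation]:
        return [v for v in self.violations if v.severity == "error"]

    def __str__(self) -> str:
        if not self.violations:
            return "no violations"
        return "\n".join(str(v) for v in self.violations)


def validate_dataset(ds: TrialDataset) -> ValidationReport:
    """Check every type invariant and cross-table reference; report, never raise.

    An empty report means the dataset satisfies all invariants.  Replicate
    imbalance is a warning (ANOVA raises separately where balance is required).
    """
    out: list[Violation] = []

    def err(table: str, msg: str) -> None:
        out.append(Violation("error", table, msg))

    def warn(table: str, msg: str) -> None:
        out.append(Violation("warning", table, msg))

    for year, days in ds.weather.items():
        seen: set[_dt.date] = set()
        for d in days:
            if d.tmax < d.tmin:
                err("weather", f"{year} {d.date.isoformat()}: tmax {d.tmax} < tmin {d.tmin}")
            if d.date in seen:
                err("weather", f"{year}: duplicate date {d.date.isoformat()}")
            seen.add(d.date)

    known = set()
    for s in ds.stages:
        key = (s.year, s.hybrid)
        if key in known:
            err("phenology", f"duplicate StageRecord for {key}")
        known.add(key)
        dates = s.dates_in_order()
        for a, b, na, nb in zip(dates, dates[1:], STAGE_ORDER, STAGE_ORDER[1:]):
            if not a < b:
                err("phenology", f"{s.year} {s.hybrid}: stage {nb} ({b}) not after {na} ({a})")
        if (dates[-1] - dates[0]).days > 365:
            err("phenology", f"{s.year} {s.hybrid}: season longer than one year")

    for p in ds.plant_samples:
        tbl = "plant_samples"
        if (p.year, p.hybrid) not in known:
            err(tbl, f"{p.year} {p.hybrid}: no matching StageRecord")
        for organ in ("leaf", "stalk", "grain", "other"):
            m = getattr(p, organ)
            if m is not None and m < 0:
                err(tbl, f"{p.year} {p.hybrid} rep {p.replicate} {p.stage}: negative {organ} mass {m}")
        if p.stage == "R1" and ((p.grain or 0.0) != 0.0 or (p.other or 0.0) != 0.0):
            err(tbl, f"{p.year} {p.hybrid} rep {p.replicate}: grain/other mass present at R1")
        if p.stage not in ("R1", "R6"):
            err(tbl, f"{p.year} {p.hybrid} rep {p.replicate}: unknown stage {p.stage!r}")

    for o in ds.lai:
        if (o.year, o.hybrid) not in known:
            err("lai", f"{o.year} {o.hybrid}: no matching StageRecord")
        if o.lai < 0:
            err("lai", f"{o.year} {o.hybrid} {o.stage}: negative LAI {o.lai}")

    for g in ds.gas_exchange:
        if (g.year, g.hybrid) not in known:
            err("gas_exchange", f"{g.year} {g.hybrid}: no matching StageRecord")
        for name in ("pn", "gs", "ci"):
            v = getattr(g, name)
            if v is not None and v < 0:
                err("gas_exchange", f"{g.year} {g.hybrid} {g.stage}: negative {name} {v}")

    iso_cohorts: dict[tuple[str, str], dict[bool, int]] = {}
    for i in ds.isotope:
        if (i.year, i.hybrid) not in known:
            err("isotope", f"{i.year} {i.hybrid}: no matching StageRecord")
        if not (0.0 < i.atom_pct_13c < 100.0):
            err("isotope", f"{i.year} {i.hybrid} plant {i.plant_id}: atom-% {i.atom_pct_13c} outside (0, 100)")
        if i.organ not in ORGANS:
            err("isotope", f"{i.year} {i.hybrid} plant {i.plant_id}: unknown organ {i.organ!r}")
        if i.mass_g < 0:
            err("isotope", f"{i.year} {i.hybrid} plant {i.plant_id}: negative mass {i.mass_g}")
        cohort = iso_cohorts.setdefault((i.year, i.hybrid), {True: 0, False: 0})
        cohort[i.labeled] += 1
    for (year, hybrid), counts in iso_cohorts.items():
        if counts[True] and not counts[False]:
            err("isotope", f"{year} {hybrid}: labeled plants without reference plants")

    for yp in ds.yield_plots:
        tbl = "yield"
        if (yp.year, yp.hybrid) not in known:
            err(tbl, f"{yp.year} {yp.hybrid}: no matching StageRecord")
        for name in ("ears_per_ha", "grains_per_ear", "thousand_grain_g", "yield_kg_ha"):
            if getattr(yp, name) <= 0:
                err(tbl, f"{yp.year} {yp.hybrid} rep {yp.replicate}: non-positive {name}")
        if not (0.0 < yp.moisture < 0.40):
            err(tbl, f"{yp.year} {yp.hybrid} rep {yp.replicate}: moisture {yp.moisture} outside (0, 0.40)")

    # replicate balance (warning only)
    counts: dict[tuple[str, str], int] = {}
    for yp in ds.yield_plots:
        counts[(yp.year, yp.hybrid)] = counts.get((yp.year, yp.hybrid), 0) + 1
    if counts and len(set(counts.values())) > 1:
        warn("yield", f"unbalanced replicate counts across cells: {sorted(set(counts.values()))}")

    return ValidationReport(out)


# ---------------------------------------------------------------------------
# CSV schemas
# ---------------------------------------------------------------------------

_SCHEMAS: dict[str, list[str]] = {
    "weather": ["year", "date", "tmax_c", "tmin_c"],
    "phenology": ["year", "hybrid", "sowing", "v6", "v12", "r1", "r3", "r5", "r6"],
    "plant_samples": ["year", "hybrid", "replicate", "stage", "leaf_g", "stalk_g", "grain_g", "other_g"],
    "lai": ["year", "hybrid", "stage", "days_after_silking", "lai"],
    "gas_exchange": ["year", "hybrid", "stage", "days_after_silking", "pn", "gs", "ci", "spad"],
    "isotope": ["year", "hybrid", "plant_id", "labeled", "organ", "mass_g", "atom_pct_13c"],
    "yield": ["year", "hybrid", "replicate", "ears_per_ha", "grains_per_ear",
              "thousand_grain_g", "moisture_frac", "yield_kg_ha_14pct"],
}

_META_FILE = "meta.yaml"


def default_paths(directory: str | Path) -> dict[str, Path]:
    """Standard one-file-per-table layout inside a directory."""
    d = Path(directory)
    return {name: d / f"{name}.csv" for name in _SCHEMAS}


def _check_schema(df: pd.DataFrame, table: str) -> None:
    for col in _SCHEMAS[table]:
        if col not in df.columns:
            raise SchemaError(f"table {table!r}: missing required column {col!r}")


def _parse_date(value, table: str, line: int) -> _dt.date:
    try:
        return _dt.date.fromisoformat(str(value).strip())
    except ValueError as exc:
        raise RowParseError(f"table {table!r} line {line}: unparsable date {value!r}") from exc


def _parse_float(value, table: str, line: int, optional: bool = False) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or str(value).strip() == "":
        if optional:
            return None
        raise RowParseError(f"table {table!r} line {line}: missing numeric value")
    try:
        return float(value)
    except (TypeError, ValueError) as exc:
        raise RowParseError(f"table {table!r} line {line}: unparsable number {value!r}") from exc


def read_trial_dataset(paths: Mapping[str, str | Path] | str | Path,
                       validate: bool = True) -> TrialDataset:
    """Load a trial dataset from CSV tables.

    ``paths`` is either a mapping of table name to file path or a directory
    holding the standard layout (weather.csv, phenology.csv, ...).  Missing
    optional tables (isotope, gas_exchange) yield empty collections; weather
    and phenology are required.  With ``validate=True`` (default) the loaded
    dataset is checked and a :class:`DatasetValidationError` is raised on any
    error-severity violation.
    """
    if isinstance(paths, (str, Path)):
        directory = Path(paths)
        paths = default_paths(directory)
        meta_path = directory / _META_FILE
    else:
        paths = {k: Path(v) for k, v in paths.items()}
        meta_path = next(iter(paths.values())).parent / _META_FILE

    ds = TrialDataset()

    if meta_path.exists():
        meta = yaml.safe_load(meta_path.read_text()) or {}
        ds.density_plants_ha = float(meta.get("density_plants_ha", ds.density_plants_ha))
        ds.replicates = int(meta.get("replicates", ds.replicates))

    def load(table: str, required: bool) -> pd.DataFrame | None:
        p = paths.get(table)
        if p is None or not Path(p).exists():
            if required:
                raise SchemaError(f"required table {table!r} not found")
            return None
        df = pd.read_csv(p)
        _check_schema(df, table)
        return df

    wdf = load("weather", required=True)
    for idx, row in wdf.iterrows():
        line = int(idx) + 2  # header is line 1
        ds.weather.setdefault(str(row["year"]), []).append(WeatherDay(
            date=_parse_date(row["date"], "weather", line),
            tmax=_parse_float(row["tmax_c"], "weather", line),
            tmin=_parse_float(row["tmin_c"], "weather", line),
        ))

    pdf = load("phenology", required=True)
    for idx, row in pdf.iterrows():
        line = int(idx) + 2
        ds.stages.append(StageRecord(
            year=str(row["year"]), hybrid=str(row["hybrid"]),
            **{s: _parse_date(row[s], "phenology", line) for s in STAGE_ORDER},
        ))

    sdf = load("plant_samples", required=False)
    if sdf is not None:
        for idx, row in sdf.iterrows():
            line = int(idx) + 2
            ds.plant_samples.append(PlantSample(
                year=str(row["year"]), hybrid=str(row["hybrid"]),
                replicate=int(row["replicate"]), stage=str(row["stage"]),
                leaf=_parse_float(row["leaf_g"], "plant_samples", line),
                stalk=_parse_float(row["stalk_g"], "plant_samples", line),
                grain=_parse_float(row["grain_g"], "plant_samples", line, optional=True),
                other=_parse_float(row["other_g"], "plant_samples", line, optional=True),
            ))

    ldf = load("lai", required=False)
    if ldf is not None:
        for idx, row in ldf.iterrows():
            line = int(idx) + 2
            ds.lai.append(LAIObservation(
                year=str(row["year"]), hybrid=str(row["hybrid"]), stage=str(row["stage"]),
                days_after_silking=_parse_float(row["days_after_silking"], "lai", line),
                lai=_parse_float(row["lai"], "lai", line),
            ))

    gdf = load("gas_exchange", required=False)
    if gdf is not None:
        for idx, row in gdf.iterrows():
            line = int(idx) + 2
            ds.gas_exchange.append(GasExchangeObservation(
                year=str(row["year"]), hybrid=str(row["hybrid"]), stage=str(row["stage"]),
                days_after_silking=_parse_float(row["days_after_silking"], "gas_exchange", line),
                pn=_parse_float(row["pn"], "gas_exchange", line),
                gs=_parse_float(row["gs"], "gas_exchange", line),
                ci=_parse_float(row["ci"], "gas_exchange", line),
                spad=_parse_float(row["spad"], "gas_exchange", line, optional=True),
            ))

    idf = load("isotope", required=False)
    if idf is not None:
        for idx, row in idf.iterrows():
            line = int(idx) + 2
            ds.isotope.append(IsotopeSample(
                year=str(row["year"]), hybrid=str(row["hybrid"]), plant_id=str(row["plant_id"]),
                labeled=str(row["labeled"]).strip().lower() in ("1", "true", "yes"),
                organ=str(row["organ"]),
                mass_g=_parse_float(row["mass_g"], "isotope", line),
                atom_pct_13c=_parse_float(row["atom_pct_13c"], "isotope", line),
            ))

    ydf = load("yield", required=False)
    if ydf is not None:
        for idx, row in ydf.iterrows():
            line = int(idx) + 2
            ds.yield_plots.append(YieldPlot(
                year=str(row["year"]), hybrid=str(row["hybrid"]), replicate=int(row["replicate"]),
                ears_per_ha=_parse_float(row["ears_per_ha"], "yield", line),
                grains_per_ear=_parse_float(row["grains_per_ear"], "yield", line),
                thousand_grain_g=_parse_float(row["thousand_grain_g"], "yield", line),
                moisture=_parse_float(row["moisture_frac"], "yield", line),
                yield_kg_ha=_parse_float(row["yield_kg_ha_14pct"], "yield", line),
            ))

    if validate:
        report = validate_dataset(ds)
        if not report.ok:
            raise DatasetValidationError(report)
    return ds


def write_trial_dataset(ds: TrialDataset, directory: str | Path) -> dict[str, Path]:
    """Write the dataset as one CSV per table plus meta.yaml; inverse of read_trial_dataset."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = default_paths(d)

    def frame(rows: Iterable[tuple], cols: list[str]) -> pd.DataFrame:
        return pd.DataFrame(list(rows), columns=cols)

    frame(((y, w.date.isoformat(), w.tmax, w.tmin)
           for y in sorted(ds.weather) for w in ds.weather[y]),
          _SCHEMAS["weather"]).to_csv(paths["weather"], index=False)

    frame(((s.year, s.hybrid, *(getattr(s, n).isoformat() for n in STAGE_ORDER))
           for s in ds.stages), _SCHEMAS["phenology"]).to_csv(paths["phenology"], index=False)

    frame(((p.year, p.hybrid, p.replicate, p.stage, p.leaf, p.stalk,
            "" if p.grain is None else p.grain, "" if p.other is None else p.other)
           for p in ds.plant_samples), _SCHEMAS["plant_samples"]).to_csv(paths["plant_samples"], index=False)

    frame(((o.year, o.hybrid, o.stage, o.days_after_silking, o.lai) for o in ds.lai),
          _SCHEMAS["lai"]).to_csv(paths["lai"], index=False)

    frame(((g.year, g.hybrid, g.stage, g.days_after_silking, g.pn, g.gs, g.ci,
            "" if g.spad is None else g.spad) for g in ds.gas_exchange),
          _SCHEMAS["gas_exchange"]).to_csv(paths["gas_exchange"], index=False)

    frame(((i.year, i.hybrid, i.plant_id, int(i.labeled), i.organ, i.mass_g, i.atom_pct_13c)
           for i in ds.isotope), _SCHEMAS["isotope"]).to_csv(paths["isotope"], index=False)

    frame(((y.year, y.hybrid, y.replicate, y.ears_per_ha, y.grains_per_ear,
            y.thousand_grain_g, y.moisture, y.yield_kg_ha) for y in ds.yield_plots),
          _SCHEMAS["yield"]).to_csv(paths["yield"], index=False)

    (d / _META_FILE).write_text(yaml.safe_dump({
        "density_plants_ha": ds.density_plants_ha,
        "replicates": ds.replicates,
    }))
    return paths
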