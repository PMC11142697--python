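"""Domain containers and delimited-text I/O for yield and climate series.

Yield tables are tidy (long) comma-delimited text, one row per observation,
with header columns ``year, crop, kind, yield[, country]``; climate tables
carry ``year, temperature, precipitation``.  Yields are in kg/ha, global mean
temperature in deg C, annual land precipitation in mm.  Internally values are
kept at full float precision; report files round yields to 0.1 kg/ha.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import pandas as pd

from ._util import round_half_up

CROPS = ("rice", "wheat", "maize", "soybean")
KINDS = ("average", "top")

__all__ = [
    "CROPS",
    "KINDS",
    "ValidationError",
    "YieldSeries",
    "ClimateSeries",
    "ProjectionReport",
    "read_yield_table",
    "write_yield_table",
    "read_climate_table",
    "write_climate_table",
    "write_report",
    "read_report",
]


class ValidationError(ValueError):
    """An input table or container violates a stated invariant."""


def _check_contiguous(years, what: str) -> list[int]:
    ys = sorted(int(y) for y in years)
    if not ys:
        raise ValidationError(f"{what}: empty series")
    expected = list(range(ys[0], ys[-1] + 1))
    if ys != expected:
        missing = sorted(set(expected) - set(ys))
        raise ValidationError(f"{what}: years must be contiguous; missing {missing}")
    return ys


@dataclass(frozen=True)
class YieldSeries:
    """Annual yields (kg/ha) of one crop, either the world average or the
    top national yield, over a contiguous span of calendar years.

    ``top_country`` optionally labels, for a top series, which country held
    the world-top yield in each year.
    """

    crop: str
    kind: str
    values: Mapping[int, float]
    top_country: Mapping[int, str] | None = None

    def __post_init__(self):
        if self.crop not in CROPS:
            raise ValidationError(f"unknown crop {self.crop!r}; expected one of {CROPS}")
        if self.kind not in KINDS:
            raise ValidationError(f"unknown kind {self.kind!r}; expected one of {KINDS}")
        _check_contiguous(self.values, f"{self.crop}/{self.kind}")
        for y, v in self.values.items():
            if not v > 0:
                raise ValidationError(
                    f"{self.crop}/{self.kind}: non-positive yield {v} in {y}"
                )
        if self.top_country is not None:
            if self.kind != "top":
                raise ValidationError("top_country labels only apply to kind='top'")
            extra = set(self.top_country) - set(self.values)
            if extra:
                raise ValidationError(f"top_country labels for unobserved years {sorted(extra)}")

    @property
    def years(self) -> list[int]:
        return sorted(self.values)

    @property
    def first_year(self) -> int:
        return min(self.values)

    @property
    def last_year(self) -> int:
        return max(self.values)

    def window(self, start: int, end: int) -> "YieldSeries":
        """Restrict to calendar years ``start..end`` (inclusive)."""
        vals = {y: v for y, v in self.values.items() if start <= y <= end}
        tc = None
        if self.top_country is not None:
            tc = {y: c for y, c in self.top_country.items() if start <= y <= end}
        return replace(self, values=vals, top_country=tc)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "year": self.years,
                "crop": self.crop,
                "kind": self.kind,
                "yield": [self.values[y] for y in self.years],
            }
        )
        if self.top_country:
            df["country"] = [self.top_country.get(y, "") for y in self.years]
        return df


@dataclass(frozen=True)
class ClimateSeries:
    """Global mean temperature (deg C) and annual land precipitation (mm)
    over a contiguous span of calendar years."""

    temperature: Mapping[int, float]
    precipitation: Mapping[int, float]

    def __post_init__(self):
        _check_contiguous(self.temperature, "temperature")
        _check_contiguous(self.precipitation, "precipitation")
        for y, t in self.temperature.items():
            if not 10.0 < t < 20.0:
                raise ValidationError(
                    f"temperature {t} deg C in {y} outside the plausible (10, 20) band"
                )
        for y, p in self.precipitation.items():
            if not p > 0:
                raise ValidationError(f"non-positive precipitation {p} mm in {y}")

    @property
    def years(self) -> list[int]:
        return sorted(self.temperature)


@dataclass
class ProjectionReport:
    """Serializable record of one crop/kind projection.

    ``holdout`` maps a held-out year to ``(actual, projected, percent
    difference)``; the sign convention is (projected - actual)/actual x 100.
    """

    crop: str
    kind: str
    model_id: str
    equation: str
    projections: dict[int, float]
    holdout: dict[int, tuple[float, float, float]] = field(default_factory=dict)
    ratio_table: dict[int, float] | None = None


def _validate_pairing(series: dict[tuple[str, str], YieldSeries]) -> None:
    for crop in CROPS:
        avg = series.get((crop, "average"))
        top = series.get((crop, "top"))
        if avg is None or top is None:
            continue
        for y in sorted(set(avg.values) & set(top.values)):
            if top.values[y] < avg.values[y]:
                raise ValidationError(
                    f"{crop}: top yield {top.values[y]} below average "
                    f"{avg.values[y]} in {y}"
                )


def read_yield_table(path) -> dict[tuple[str, str], YieldSeries]:
    """Read a tidy yield table into one :class:`YieldSeries` per (crop, kind).

    Checks contiguity, positivity, duplicate rows and the top >= average
    invariant for every crop present with both kinds.
    """
    df = pd.read_csv(path)
    required = {"year", "crop", "kind", "yield"}
    if not required <= set(df.columns):
        raise ValidationError(f"yield table needs columns {sorted(required)}")
    dup = df.duplicated(subset=["year", "crop", "kind"])
    if dup.any():
        rows = df.loc[dup, ["year", "crop", "kind"]].values.tolist()
        raise ValidationError(f"duplicate (year, crop, kind) rows: {rows}")
    out: dict[tuple[str, str], YieldSeries] = {}
    for (crop, kind), grp in df.groupby(["crop", "kind"], sort=False):
        values = dict(zip(grp["year"].astype(int), grp["yield"].astype(float)))
        tc = None
        if kind == "top" and "country" in grp.columns:
            labels = {
                int(y): str(c)
                for y, c in zip(grp["year"], grp["country"])
                if isinstance(c, str) and c.strip()
            }
            tc = labels or None
        out[(crop, kind)] = YieldSeries(crop=crop, kind=kind, values=values, top_country=tc)
    _validate_pairing(out)
    return out


def write_yield_table(series, path) -> None:
    """Write an iterable (or dict) of :class:`YieldSeries` back to tidy CSV."""
    if isinstance(series, dict):
        series = series.values()
    frames = [s.to_frame() for s in series]
    df = pd.concat(frames, ignore_index=True)
    if "country" in df.columns:
        df["country"] = df["country"].fillna("")
    df.to_csv(path, index=False)


def read_climate_table(path) -> ClimateSeries:
    df = pd.read_csv(path)
    required = {"year", "temperature", "precipitation"}
    if not required <= set(df.columns):
        raise ValidationError(f"climate table needs columns {sorted(required)}")
    if df["year"].duplicated().any():
        raise ValidationError("duplicate years in climate table")
    years = df["year"].astype(int)
    return ClimateSeries(
        temperature=dict(zip(years, df["temperature"].astype(float))),
        precipitation=dict(zip(years, df["precipitation"].astype(float))),
    )


def write_climate_table(climate: ClimateSeries, path) -> None:
    years = climate.years
    pd.DataFrame(
        {
            "year": years,
            "temperature": [climate.temperature[y] for y in years],
            "precipitation": [climate.precipitation[y] for y in years],
        }
    ).to_csv(path, index=False)


def write_report(report: ProjectionReport, path) -> None:
    """Write a projection report as CSV (yields at 0.1 kg/ha) plus a JSON
    sidecar holding the full-precision numbers; :func:`read_report` on the
    sidecar round-trips projections exactly."""
    if not report.projections:
        raise ValidationError("report has an empty projection horizon")
    path = Path(path)
    years = sorted(report.projections)
    rows = {"year": years, "projection": [round_half_up(report.projections[y], 1) for y in years]}
    if report.holdout:
        rows["actual"] = [
            report.holdout[y][0] if y in report.holdout else "" for y in years
        ]
        rows["percent_difference"] = [
            report.holdout[y][2] if y in report.holdout else "" for y in years
        ]
    if report.ratio_table:
        rows["ratio_pct"] = [report.ratio_table.get(y, "") for y in years]
    pd.DataFrame(rows).to_csv(path, index=False)
    sidecar = {
        "crop": report.crop,
        "kind": report.kind,
        "model_id": report.model_id,
        "equation": report.equation,
        "projections": {str(y): report.projections[y] for y in years},
        "holdout": {str(y): list(v) for y, v in report.holdout.items()},
        "ratio_table": (
            {str(y): v for y, v in report.ratio_table.items()} if report.ratio_table else None
        ),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_report(path) -> ProjectionReport:
    """Rebuild a :class:`ProjectionReport` from the JSON sidecar written by
    :func:`write_report` (pass either the CSV or the JSON path)."""
    path = Path(path)
    if path.suffix != ".json":
        path = path.with_suffix(".json")
    d = json.loads(path.read_text())
    return ProjectionReport(
        crop=d["crop"],
        kind=d["kind"],
        model_id=d["model_id"],
        equation=d["equation"],
        projections={int(y): v for y, v in d["projections"].items()},
        holdout={int(y): tuple(v) for y, v in d["holdout"].items()},
        ratio_table=(
            {int(y): v for y, v in d["ratio_table"].items()} if d["ratio_table"] else None
        ),
    )
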