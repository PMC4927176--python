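"""Climatic drivers per sub-region and year, and the lagged design matrix.

Four drivers feed the calf-proportion models:

rain_anom
    Wet-season (November-April) rainfall total for the sub-region minus the
    mean wet-season total over the 30 preceding seasons.  Seasons are
    labeled by the calendar year of their January-April part.
SOI
    Mean November-February Southern Oscillation Index, labeled by the
    January/February year.  Positive values mark La Nina.
NINO34
    Mean November-February NINO 3.4 sea-surface-temperature index, same
    labeling.  Positive values mark El Nino.
TC
    Number of tropical cyclones whose track, interpolated onto a 1 x 1
    degree grid, came within 5 degrees (degree-space distance) of the
    sub-region's coastline during the season.

Each driver is then lagged 1-4 years relative to the survey year and the
lagged columns standardized to mean 0, sd 1 across the fitted survey rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point

from .surveys import SubregionRegistry, SurveyTable

__all__ = [
    "DRIVERS",
    "CoverageError",
    "DegenerateColumnError",
    "MonthlySeries",
    "CycloneTrack",
    "CovariateTable",
    "LaggedDesign",
    "wet_season_rainfall_anomaly",
    "seasonal_enso_index",
    "interpolate_track",
    "cell_center",
    "cyclone_season_year",
    "cyclone_counts",
    "build_covariate_table",
    "build_lagged_design",
]

DRIVERS = ("rain_anom", "SOI", "NINO34", "TC")

#: Wet-season months: November, December of the preceding calendar year,
#: then January-April of the labeling year.
WET_SEASON_MONTHS = ((-1, 11), (-1, 12), (0, 1), (0, 2), (0, 3), (0, 4))

#: ENSO index window: November-February, labeled by the Jan/Feb year.
ENSO_MONTHS = ((-1, 11), (-1, 12), (0, 1), (0, 2))


class CoverageError(ValueError):
    """A series does not cover a window required by a computation."""


class DegenerateColumnError(ValueError):
    """A lagged design column has zero variance and cannot be standardized."""


class MonthlySeries:
    """A monthly climate series: (year, month) -> value.

    ``variable`` is one of rainfall / SOI / NINO34; ``subregion`` is set for
    rainfall only (the ENSO indices are basin-scale).
    """

    def __init__(self, variable: str, values: Mapping[tuple[int, int], float],
                 subregion: str | None = None):
        self.variable = variable
        self.subregion = subregion
        idx = pd.MultiIndex.from_tuples(sorted(values), names=["year", "month"])
        self._series = pd.Series([values[k] for k in sorted(values)], index=idx,
                                 name=variable, dtype=float)
        months = self._series.index.get_level_values("month")
        if len(months) and (months.min() < 1 or months.max() > 12):
            raise ValueError("months must lie in 1..12")
        # plain-dict mirror: value() is on the hot path of anomaly baselines
        self._values = {(int(y), int(m)): float(v) for (y, m), v in values.items()}

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, variable: str,
                   subregion: str | None = None) -> "MonthlySeries":
        """Build from a long frame with columns year, month, value."""
        values = {
            (int(r.year), int(r.month)): float(r.value) for r in frame.itertuples()
        }
        return cls(variable, values, subregion=subregion)

    @property
    def series(self) -> pd.Series:
        return self._series.copy()

    def __len__(self) -> int:
        return len(self._series)

    def value(self, year: int, month: int) -> float:
        try:
            return self._values[(year, month)]
        except KeyError:
            label = self.variable if self.subregion is None else f"{self.variable}[{self.subregion}]"
            raise CoverageError(f"{label} has no value for {year}-{month:02d}") from None

    def window_sum(self, year: int, months: Sequence[tuple[int, int]]) -> float:
        return sum(self.value(year + dy, m) for dy, m in months)

    def window_mean(self, year: int, months: Sequence[tuple[int, int]]) -> float:
        return self.window_sum(year, months) / len(months)


@dataclass(frozen=True)
class CycloneTrack:
    """One storm: id, season label and time-ordered (timestamp, lat, lon) fixes."""

    storm_id: str
    season: str
    fixes: tuple[tuple[pd.Timestamp, float, float], ...]

    def __post_init__(self) -> None:
        if len(self.fixes) < 1:
            raise ValueError(f"track {self.storm_id} has no fixes")
        times = [f[0] for f in self.fixes]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError(f"track {self.storm_id} fixes are not time-ordered")

    @property
    def path(self) -> np.ndarray:
        """(n, 2) array of (lat, lon)."""
        return np.array([[f[1], f[2]] for f in self.fixes], dtype=float)


class CovariateTable:
    """Driver values per (subregion, year): rain_anom, SOI, NINO34, TC."""

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        required = {"subregion", "year", *DRIVERS}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"covariate table missing columns: {sorted(missing)}")
        frame["year"] = frame["year"].astype(int)
        frame["TC"] = frame["TC"].astype(int)
        if (frame["TC"] < 0).any():
            raise ValueError("cyclone counts must be non-negative")
        # Basin-scale indices must not vary across sub-regions within a year.
        for col in ("SOI", "NINO34"):
            spread = frame.groupby("year")[col].agg(lambda v: v.max() - v.min())
            if (spread > 1e-9).any():
                bad = spread.index[spread > 1e-9].tolist()
                raise ValueError(f"{col} differs across sub-regions in years {bad}")
        self._frame = frame.set_index(["subregion", "year"]).sort_index()

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame.reset_index()

    def value(self, subregion: str, year: int, driver: str) -> float:
        if driver not in DRIVERS:
            raise KeyError(f"unknown driver {driver!r}")
        try:
            return float(self._frame.loc[(subregion, year), driver])
        except KeyError:
            raise CoverageError(
                f"no covariate value for ({subregion}, {year})"
            ) from None

    def years(self, subregion: str) -> list[int]:
        return sorted(self._frame.loc[subregion].index.tolist())

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CovariateTable":
        return cls(pd.read_csv(path))


# ---------------------------------------------------------------------------
# Driver construction
# ---------------------------------------------------------------------------

def wet_season_rainfall_anomaly(series: MonthlySeries, year: int,
                                baseline_years: int = 30) -> float:
    """Wet-season rainfall total minus the mean over the preceding seasons.

    The season labeled ``year`` spans Nov(year-1)-Apr(year); the baseline is
    the mean wet-season total of the ``baseline_years`` seasons immediately
    before it.
    """
    if series.variable != "rainfall":
        raise ValueError(f"expected a rainfall series, got {series.variable!r}")
    total = series.window_sum(year, WET_SEASON_MONTHS)
    baseline = [
        series.window_sum(y, WET_SEASON_MONTHS)
        for y in range(year - baseline_years, year)
    ]
    return total - float(np.mean(baseline))


def seasonal_enso_index(series: MonthlySeries, year: int) -> float:
    """Mean Nov-Feb index value, labeled by the January/February year."""
    if series.variable not in ("SOI", "NINO34"):
        raise ValueError(f"expected an ENSO index series, got {series.variable!r}")
    return series.window_mean(year, ENSO_MONTHS)


# ---------------------------------------------------------------------------
# Cyclone exposure
# ---------------------------------------------------------------------------

def _cell_of(lat: float, lon: float, grid: float) -> tuple[int, int]:
    return (math.floor(lat / grid), math.floor(lon / grid))


def cell_center(cell: tuple[int, int], grid_deg: float = 1.0) -> tuple[float, float]:
    """(lat, lon) center of a grid cell index pair."""
    return ((cell[0] + 0.5) * grid_deg, (cell[1] + 0.5) * grid_deg)


def interpolate_track(track: CycloneTrack, grid_deg: float = 1.0) -> set[tuple[int, int]]:
    """Grid cells traversed by the piecewise-linear track path.

    Cells are half-open squares ``[i*g, (i+1)*g)`` in latitude and
    longitude.  Each segment is walked exactly: boundary-crossing parameters
    are enumerated and the cell of each inter-crossing midpoint recorded, so
    the result is independent of any sampling density.
    """
    path = track.path
    cells: set[tuple[int, int]] = {_cell_of(lat, lon, grid_deg) for lat, lon in path}
    for (lat0, lon0), (lat1, lon1) in zip(path[:-1], path[1:]):
        ts = {0.0, 1.0}
        for a0, a1 in ((lat0, lat1), (lon0, lon1)):
            if a0 == a1:
                continue
            lo, hi = sorted((a0, a1))
            k = math.ceil(lo / grid_deg)
            while k * grid_deg < hi:
                ts.add((k * grid_deg - a0) / (a1 - a0))
                k += 1
        tsort = sorted(ts)
        for ta, tb in zip(tsort[:-1], tsort[1:]):
            tm = 0.5 * (ta + tb)
            cells.add(_cell_of(lat0 + tm * (lat1 - lat0),
                               lon0 + tm * (lon1 - lon0), grid_deg))
    return cells


def cyclone_season_year(track: CycloneTrack) -> int:
    """Season label of a storm: the January year of its Nov-Apr season.

    A storm first observed in July-December belongs to the following
    January's season; January-June storms to the current one.  This matches
    the Nov-Feb labeling of the ENSO indices, keeping lag arithmetic
    uniform across drivers.
    """
    first = track.fixes[0][0]
    return first.year + 1 if first.month >= 7 else first.year


def cyclone_counts(tracks: Iterable[CycloneTrack], registry: SubregionRegistry,
                   radius_deg: float = 5.0, grid_deg: float = 1.0) -> pd.DataFrame:
    """Count storms within ``radius_deg`` of each sub-region coastline.

    A storm increments the count of every sub-region whose coastline
    polyline comes within ``radius_deg`` (Euclidean distance in degree
    space) of any of the storm's gridded track points; it is counted at
    most once per sub-region per season-year.  Returns a long frame with
    columns ``subregion, year, TC`` covering every (sub-region, season)
    pair seen, zeros included.
    """
    coastlines = {
        entry.name: LineString([(lon, lat) for lat, lon in entry.coastline])
        for entry in registry
    }
    counted: set[tuple[str, str, int]] = set()
    tracks = list(tracks)
    seasons = sorted({cyclone_season_year(t) for t in tracks})
    counts = {(name, yr): 0 for name in coastlines for yr in seasons}
    for track in tracks:
        year = cyclone_season_year(track)
        centers = [cell_center(c, grid_deg) for c in interpolate_track(track, grid_deg)]
        for name, line in coastlines.items():
            if (track.storm_id, name, year) in counted:
                continue
            if any(line.distance(Point(lon, lat)) <= radius_deg for lat, lon in centers):
                counts[(name, year)] += 1
                counted.add((track.storm_id, name, year))
    rows = [
        {"subregion": name, "year": yr, "TC": counts[(name, yr)]}
        for name in coastlines for yr in seasons
    ]
    return pd.DataFrame(rows, columns=["subregion", "year", "TC"])


# ---------------------------------------------------------------------------
# Covariate table and lagged design
# ---------------------------------------------------------------------------

def build_covariate_table(
    rainfall: Mapping[str, MonthlySeries],
    soi: MonthlySeries,
    nino34: MonthlySeries,
    tc_counts: pd.DataFrame,
    years: Iterable[int],
    baseline_years: int = 30,
) -> CovariateTable:
    """Assemble the per-(subregion, year) driver table.

    ``tc_counts`` is the long frame produced by :func:`cyclone_counts`;
    seasons absent from it count as zero storms.
    """
    tc = tc_counts.set_index(["subregion", "year"])["TC"] if len(tc_counts) else None
    rows = []
    for year in sorted(set(int(y) for y in years)):
        soi_val = seasonal_enso_index(soi, year)
        nino_val = seasonal_enso_index(nino34, year)
        for name, rain_series in rainfall.items():
            count = 0
            if tc is not None and (name, year) in tc.index:
                count = int(tc.loc[(name, year)])
            rows.append(
                {
                    "subregion": name,
                    "year": year,
                    "rain_anom": wet_season_rainfall_anomaly(
                        rain_series, year, baseline_years=baseline_years
                    ),
                    "SOI": soi_val,
                    "NINO34": nino_val,
                    "TC": count,
                }
            )
    return CovariateTable(pd.DataFrame(rows))


@dataclass(frozen=True)
class LaggedDesign:
    """Standardized lag-1..4 driver columns aligned to the survey rows.

    ``frame`` holds the standardized columns ``<driver>_lag<k>``; ``raw``
    the unscaled values; ``scaling`` maps column name -> (mean, sd), so
    ``standardized * sd + mean`` recovers the raw series.
    """

    frame: pd.DataFrame
    raw: pd.DataFrame
    scaling: dict[str, tuple[float, float]]
    lags: tuple[int, ...]
    drivers: tuple[str, ...] = DRIVERS

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    def back_transform(self, column: str) -> np.ndarray:
        mean, sd = self.scaling[column]
        return self.frame[column].to_numpy() * sd + mean


def build_lagged_design(cov: CovariateTable, surveys: SurveyTable,
                        lags: Iterable[int] = (1, 2, 3, 4),
                        drivers: Sequence[str] = DRIVERS) -> LaggedDesign:
    """Lag each driver 1..4 years behind every survey row, then standardize.

    The lag-k column of a survey in year t holds the driver value at year
    t - k for that survey's sub-region.  Columns are scaled to mean 0 and
    sd 1 across the survey rows; the scaling constants are retained.
    """
    lags = tuple(sorted(set(int(k) for k in lags)))
    if not lags or any(k < 0 for k in lags):
        raise ValueError(f"lags must be a non-empty set of non-negative ints, got {lags}")
    frame = surveys.frame
    raw_cols: dict[str, list[float]] = {}
    for driver in drivers:
        for k in lags:
            col = f"{driver}_lag{k}"
            vals = []
            for row in frame.itertuples():
                try:
                    vals.append(cov.value(row.subregion, row.year - k, driver))
                except CoverageError:
                    raise CoverageError(
                        f"missing {driver} for ({row.subregion}, year "
                        f"{row.year - k}) needed at lag {k}"
                    ) from None
            raw_cols[col] = vals
    raw = pd.DataFrame(raw_cols, index=frame.index)
    scaling: dict[str, tuple[float, float]] = {}
    std = {}
    for col in raw.columns:
        mean = float(raw[col].mean())
        sd = float(raw[col].std(ddof=1))
        if not np.isfinite(sd) or sd == 0.0:
            raise DegenerateColumnError(
                f"column {col} has zero variance across survey rows"
            )
        scaling[col] = (mean, sd)
        std[col] = (raw[col] - mean) / sd
    return LaggedDesign(frame=pd.DataFrame(std, index=frame.index), raw=raw,
                        scaling=scaling, lags=lags, drivers=tuple(drivers))
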