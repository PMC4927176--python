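"""Aerial-survey records, sub-region registry and calf-proportion bookkeeping.

The observational unit throughout the package is one aerial survey of one
coastal sub-region in one year: the number of dugongs sighted (``total``)
and the number of those classified as dependent calves (``calves``).  The
modelled response is the proportion ``calves / total``.

Five Queensland sub-regions are indexed 1..5 in their north-to-south order:
Torres Strait, Northern Great Barrier Reef, Southern Great Barrier Reef,
Hervey Bay and Moreton Bay.  The bundled registry carries synthetic
coastline polylines that approximate each sub-region's coast; they exist so
that cyclone-exposure counting has geometry to work against, not to
reproduce any real shoreline.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SEASONS",
    "SurveyRecord",
    "SubregionInfo",
    "SubregionRegistry",
    "SurveyTable",
    "SurveyFormatError",
    "SurveyValidationError",
    "read_survey_table",
    "write_survey_table",
    "compute_proportion",
    "default_registry",
    "table1_survey_years",
]

SEASONS = ("spring_summer", "autumn")

SURVEY_COLUMNS = ["subregion", "year", "season", "total", "calves"]


class SurveyFormatError(ValueError):
    """The file does not have the expected survey-table layout."""


class SurveyValidationError(ValueError):
    """A row violates a survey-record invariant (reported with its row index)."""


@dataclass(frozen=True)
class SurveyRecord:
    """One aerial survey: counts, location, timing.

    ``time_value`` is the survey year on the model's standardized time
    scale, ``(year - mean(survey years)) / sd(survey years)``, computed once
    per dataset by :class:`SurveyTable`.
    """

    subregion_id: str
    year: int
    season: str
    total_count: int
    calf_count: int
    time_value: float = float("nan")

    def __post_init__(self) -> None:
        if self.season not in SEASONS:
            raise SurveyValidationError(
                f"unknown season {self.season!r}; expected one of {SEASONS}"
            )
        if self.total_count < 0 or self.calf_count < 0:
            raise SurveyValidationError(
                f"negative count in {self.subregion_id} {self.year}"
            )
        if self.calf_count > self.total_count:
            raise SurveyValidationError(
                f"calves ({self.calf_count}) exceed total ({self.total_count}) "
                f"in {self.subregion_id} {self.year}"
            )


@dataclass(frozen=True)
class SubregionInfo:
    """Registry entry: name, model index l in 1..5, coastline polyline, area."""

    name: str
    index: int
    coastline: tuple[tuple[float, float], ...]  # (lat, lon) decimal degrees
    area_km2: float

    def __post_init__(self) -> None:
        if len(self.coastline) < 2:
            raise ValueError(f"coastline of {self.name} needs >= 2 vertices")


class SubregionRegistry:
    """The five survey sub-regions with unique indices 1..5."""

    def __init__(self, entries: Iterable[SubregionInfo]):
        entries = list(entries)
        if len(entries) != 5:
            raise ValueError(f"registry needs exactly 5 sub-regions, got {len(entries)}")
        indices = sorted(e.index for e in entries)
        if indices != [1, 2, 3, 4, 5]:
            raise ValueError(f"sub-region indices must be 1..5 unique, got {indices}")
        self._by_name = {e.name: e for e in entries}
        if len(self._by_name) != 5:
            raise ValueError("duplicate sub-region names")

    def __iter__(self):
        return iter(sorted(self._by_name.values(), key=lambda e: e.index))

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> list[str]:
        return [e.name for e in self]

    def get(self, name: str) -> SubregionInfo:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown sub-region {name!r}; known: {self.names}") from None

    def index_of(self, name: str) -> int:
        return self.get(name).index


class SurveyTable:
    """Ordered, validated collection of survey records.

    Uniqueness is enforced on ``(subregion, year, season)``; two surveys of
    the same sub-region and year are allowed only when they carry different
    season tags (the design permits an autumn and a spring/summer survey in
    the same calendar year).
    """

    def __init__(self, frame: pd.DataFrame, source: str | None = None):
        frame = frame.reset_index(drop=True)
        missing = [c for c in SURVEY_COLUMNS if c not in frame.columns]
        if missing:
            raise SurveyFormatError(f"missing survey columns: {missing}")
        frame = frame[SURVEY_COLUMNS].copy()
        frame["year"] = frame["year"].astype(int)
        frame["total"] = frame["total"].astype(int)
        frame["calves"] = frame["calves"].astype(int)
        for i, row in frame.iterrows():
            if row["season"] not in SEASONS:
                raise SurveyValidationError(f"row {i}: unknown season {row['season']!r}")
            if row["calves"] < 0 or row["total"] < 0:
                raise SurveyValidationError(f"row {i}: negative count")
            if row["calves"] > row["total"]:
                raise SurveyValidationError(
                    f"row {i}: calves ({row['calves']}) exceed total ({row['total']}) "
                    f"for {row['subregion']} {row['year']}"
                )
        dup = frame.duplicated(subset=["subregion", "year", "season"])
        if dup.any():
            raise SurveyValidationError(
                f"duplicate (subregion, year, season) at rows {list(frame.index[dup])}"
            )
        years = frame["year"].to_numpy(float)
        self.year_mean = float(years.mean()) if len(years) else 0.0
        sd = float(years.std(ddof=1)) if len(years) > 1 else 0.0
        self.year_sd = sd if sd > 0 else 1.0
        frame["time_value"] = (years - self.year_mean) / self.year_sd
        self._frame = frame
        self.source = source

    # -- construction -----------------------------------------------------

    @classmethod
    def from_records(cls, records: Iterable[SurveyRecord], source: str | None = None):
        rows = [
            {
                "subregion": r.subregion_id,
                "year": r.year,
                "season": r.season,
                "total": r.total_count,
                "calves": r.calf_count,
            }
            for r in records
        ]
        return cls(pd.DataFrame(rows, columns=SURVEY_COLUMNS), source=source)

    # -- views ------------------------------------------------------------

    def __len__(self) -> int:
        return len(self._frame)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SurveyTable):
            return NotImplemented
        return self._frame.equals(other._frame)

    @property
    def frame(self) -> pd.DataFrame:
        """The table as a DataFrame (copy), with the derived ``time_value``."""
        return self._frame.copy()

    @property
    def records(self) -> list[SurveyRecord]:
        return [
            SurveyRecord(
                subregion_id=row.subregion,
                year=int(row.year),
                season=row.season,
                total_count=int(row.total),
                calf_count=int(row.calves),
                time_value=float(row.time_value),
            )
            for row in self._frame.itertuples()
        ]

    @property
    def years(self) -> np.ndarray:
        return self._frame["year"].to_numpy(int)

    @property
    def time_values(self) -> np.ndarray:
        return self._frame["time_value"].to_numpy(float)

    def time_for_years(self, years) -> np.ndarray:
        """Map calendar years onto this table's standardized time scale."""
        return (np.asarray(years, dtype=float) - self.year_mean) / self.year_sd

    @property
    def totals(self) -> np.ndarray:
        return self._frame["total"].to_numpy(int)

    @property
    def calves(self) -> np.ndarray:
        return self._frame["calves"].to_numpy(int)

    @property
    def subregions(self) -> list[str]:
        return self._frame["subregion"].tolist()

    def proportions(self) -> pd.Series:
        """Observed calf proportion per record; NaN where total is zero."""
        total = self._frame["total"]
        with np.errstate(invalid="ignore", divide="ignore"):
            p = self._frame["calves"] / total.where(total > 0)
        return p.rename("proportion")

    def model_rows(self) -> "SurveyTable":
        """Records usable in the likelihood: total_count > 0."""
        keep = self._frame["total"] > 0
        if keep.all():
            return self
        return SurveyTable(self._frame.loc[keep, SURVEY_COLUMNS], source=self.source)

    def checksum(self) -> str:
        payload = self._frame[SURVEY_COLUMNS].to_csv(index=False).encode()
        return hashlib.sha256(payload).hexdigest()


def compute_proportion(record: SurveyRecord) -> float:
    """Observed calf proportion for one survey.

    Raises :class:`SurveyValidationError` when ``total_count == 0``: the
    proportion is undefined and such records carry no binomial information.
    """
    if record.total_count == 0:
        raise SurveyValidationError(
            f"proportion undefined for zero-total survey "
            f"{record.subregion_id} {record.year}"
        )
    return record.calf_count / record.total_count


def read_survey_table(path: str | Path) -> SurveyTable:
    """Read a survey CSV (columns ``subregion,year,season,total,calves``)."""
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # pragma: no cover - malformed CSV
        raise SurveyFormatError(f"{path}: {exc}") from exc
    return SurveyTable(frame, source=str(path))


def write_survey_table(table: SurveyTable, path: str | Path) -> None:
    table.frame[SURVEY_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Study design constants
# ---------------------------------------------------------------------------

#: Survey years per sub-region in the five-sub-region Queensland design
#: (44 sub-region-years, 1974-2013).
_TABLE1_YEARS: dict[str, tuple[int, ...]] = {
    "torres_strait": (1991, 1996, 2001, 2006, 2011, 2013),
    "northern_gbr": (1978, 1984, 1985, 1990, 1995, 2000, 2006, 2013),
    "southern_gbr": (1974, 1975, 1976, 1977, 1978, 1979, 1986, 1992, 1994, 1999, 2005, 2011),
    "hervey_bay": (1979, 1988, 1992, 1993, 1994, 1999, 2001, 2005, 2011),
    "moreton_bay": (1976, 1977, 1979, 1995, 1999, 2000, 2001, 2005, 2011),
}

#: Sub-region-years that additionally had an autumn survey in the study design.
_TABLE1_AUTUMN_EXTRA: tuple[tuple[str, int], ...] = (
    ("hervey_bay", 2001),
    ("moreton_bay", 2001),
)


def table1_survey_years() -> dict[str, tuple[int, ...]]:
    """Survey years per sub-region for the standard 44-record study design."""
    return dict(_TABLE1_YEARS)


def default_registry() -> SubregionRegistry:
    """Registry of the five sub-regions with *synthetic* coastline polylines.

    Vertices are coarse straight-line approximations of the Queensland coast
    (decimal degrees, south negative); areas follow the published survey
    sub-region areas.  Adequate for degree-space distance computations in
    cyclone-exposure counting, not for mapping.
    """
    return SubregionRegistry(
        [
            SubregionInfo(
                "torres_strait", 1,
                ((-10.2, 142.0), (-10.5, 142.4), (-10.7, 142.9)),
                29764.0,
            ),
            SubregionInfo(
                "northern_gbr", 2,
                ((-11.5, 142.9), (-13.5, 143.6), (-15.5, 145.3)),
                20132.0,
            ),
            SubregionInfo(
                "southern_gbr", 3,
                ((-15.5, 145.3), (-19.3, 147.0), (-21.1, 149.2), (-24.5, 151.8)),
                33676.0,
            ),
            SubregionInfo(
                "hervey_bay", 4,
                ((-24.8, 152.4), (-25.3, 152.9), (-25.8, 153.1)),
                6156.0,
            ),
            SubregionInfo(
                "moreton_bay", 5,
                ((-27.0, 153.2), (-27.5, 153.4), (-28.0, 153.5)),
                2192.0,
            ),
        ]
    )
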