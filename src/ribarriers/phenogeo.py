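"""Flowering-phenology overlap and occurrence-record sympatry.

Phenological isolation treats overlapping flowering days as the shared
factor: ``RI = 1 - overlap / focal season length`` with both day counts
inclusive of their endpoints.  Geographic isolation classifies each focal
occurrence record as sympatric when at least one heterospecific record
lies within a distance threshold (7 km by default) and returns the
allopatric fraction.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .components import ri_cooccurrence
from .errors import SchemaError, UndefinedBarrierError

__all__ = [
    "FlowerSeason",
    "OccurrenceRecord",
    "overlap_days",
    "ri_phenology",
    "haversine_km",
    "ri_geographic",
    "elevation_summary",
    "duplicate_coordinates",
    "read_seasons_csv",
    "read_occurrences_csv",
    "write_occurrences_csv",
]

EARTH_RADIUS_KM = 6371.0
SYMPATRY_RADIUS_KM = 7.0


@dataclass(frozen=True)
class FlowerSeason:
    """One species' flowering interval (endpoints inclusive)."""

    species: str
    start: dt.date
    end: dt.date

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise SchemaError(
                f"{self.species}: season start {self.start} after end "
                f"{self.end}"
            )

    @property
    def length_days(self) -> int:
        """Inclusive day count of the season."""
        return (self.end - self.start).days + 1


@dataclass(frozen=True)
class OccurrenceRecord:
    """One georeferenced occurrence of a species."""

    species: str
    latitude: float
    longitude: float
    elevation_m: float | None = None

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise SchemaError(f"latitude out of range: {self.latitude}")
        if not -180.0 <= self.longitude <= 180.0:
            raise SchemaError(f"longitude out of range: {self.longitude}")
        if self.elevation_m is not None and self.elevation_m < 0:
            raise SchemaError(f"negative elevation: {self.elevation_m}")


def _check_same_year(a: FlowerSeason, b: FlowerSeason) -> None:
    years = {a.start.year, a.end.year, b.start.year, b.end.year}
    if len(years) != 1:
        raise SchemaError(
            "seasons must fall within a single calendar year; "
            f"got years {sorted(years)}"
        )


def overlap_days(a: FlowerSeason, b: FlowerSeason) -> int:
    """Inclusive day count of the intersection of two seasons; 0 if disjoint."""
    _check_same_year(a, b)
    start = max(a.start, b.start)
    end = min(a.end, b.end)
    return max(0, (end - start).days + 1)


def ri_phenology(focal: FlowerSeason, other: FlowerSeason) -> float:
    """Phenological RI for the focal species.

    ``1 - S/(S+U)`` with ``S`` the inclusive flowering-overlap day count
    and ``S + U`` the focal species' inclusive season length, so the value
    is 0 exactly when the focal season lies entirely inside the overlap.
    """
    shared = overlap_days(focal, other)
    length = focal.length_days
    if length == 0:  # unreachable given inclusive counting, kept for safety
        raise UndefinedBarrierError("zero-length focal season")
    return ri_cooccurrence(shared, length - shared)


def haversine_km(p: OccurrenceRecord, q: OccurrenceRecord) -> float:
    """Great-circle distance between two records on a 6371-km sphere."""
    lat1, lon1, lat2, lon2 = map(
        np.radians, (p.latitude, p.longitude, q.latitude, q.longitude)
    )
    h = (
        np.sin((lat2 - lat1) / 2) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    )
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h)))


def _coords(records: Sequence[OccurrenceRecord]) -> np.ndarray:
    return np.radians(
        [[r.latitude, r.longitude] for r in records], dtype=float
    )


def _pairwise_km(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    lat1 = a[:, 0][:, None]
    lon1 = a[:, 1][:, None]
    lat2 = b[:, 0][None, :]
    lon2 = b[:, 1][None, :]
    h = (
        np.sin((lat2 - lat1) / 2) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h))


def ri_geographic(
    records_focal: Sequence[OccurrenceRecord],
    records_other: Sequence[OccurrenceRecord],
    radius_km: float = SYMPATRY_RADIUS_KM,
) -> float:
    """Geographic RI: allopatric fraction of focal occurrence records.

    A focal record is sympatric iff at least one heterospecific record lies
    within ``radius_km`` (inclusive).  With no heterospecific records every
    focal record is allopatric and the RI is 1.
    """
    if not records_focal:
        raise UndefinedBarrierError("no focal occurrence records")
    if not records_other:
        return 1.0
    d = _pairwise_km(_coords(records_focal), _coords(records_other))
    sympatric = int((d.min(axis=1) <= radius_km).sum())
    return ri_cooccurrence(sympatric, len(records_focal) - sympatric)


def elevation_summary(
    records: Sequence[OccurrenceRecord],
) -> tuple[float, float, float, int]:
    """(mean, min, max, n) over records carrying an elevation."""
    elevations = [r.elevation_m for r in records if r.elevation_m is not None]
    if not elevations:
        raise UndefinedBarrierError("no records with elevation")
    return (
        float(np.mean(elevations)),
        float(min(elevations)),
        float(max(elevations)),
        len(elevations),
    )


def duplicate_coordinates(
    records: Sequence[OccurrenceRecord],
) -> list[tuple[int, int]]:
    """Index pairs of records with exactly equal coordinates.

    De-duplication itself is left to the caller (repeated herbarium
    collections are a data-curation decision, not a geometry one).
    """
    seen: dict[tuple[float, float], int] = {}
    dupes = []
    for i, r in enumerate(records):
        key = (r.latitude, r.longitude)
        if key in seen:
            dupes.append((seen[key], i))
        else:
            seen[key] = i
    return dupes


def read_seasons_csv(path: str | Path) -> dict[str, FlowerSeason]:
    """Read ``species,start_date,end_date`` (ISO-8601 dates) into seasons."""
    df = pd.read_csv(path, dtype=str)
    required = ["species", "start_date", "end_date"]
    if list(df.columns) != required:
        raise SchemaError(
            f"season CSV header must be {required}, got {list(df.columns)}"
        )
    seasons = {}
    for r in df.itertuples():
        seasons[r.species] = FlowerSeason(
            r.species,
            dt.date.fromisoformat(r.start_date),
            dt.date.fromisoformat(r.end_date),
        )
    return seasons


def read_occurrences_csv(path: str | Path) -> list[OccurrenceRecord]:
    """Read ``species,latitude,longitude,elevation_m`` occurrence records.

    ``elevation_m`` is optional (column may be absent or blank per row).
    """
    df = pd.read_csv(path)
    required = ["species", "latitude", "longitude"]
    if list(df.columns[:3]) != required:
        raise SchemaError(
            f"occurrence CSV must start with columns {required}, "
            f"got {list(df.columns)}"
        )
    has_elev = "elevation_m" in df.columns
    records = []
    for r in df.itertuples():
        elev = getattr(r, "elevation_m", None) if has_elev else None
        if elev is not None and pd.isna(elev):
            elev = None
        records.append(
            OccurrenceRecord(
                str(r.species), float(r.latitude), float(r.longitude),
                None if elev is None else float(elev),
            )
        )
    return records


def write_occurrences_csv(
    records: Iterable[OccurrenceRecord], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {
                "species": r.species,
                "latitude": r.latitude,
                "longitude": r.longitude,
                "elevation_m": r.elevation_m,
            }
            for r in records
        ],
        columns=["species", "latitude", "longitude", "elevation_m"],
    ).to_csv(path, index=False)
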