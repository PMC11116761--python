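"""Photo-identification data model, I/O and dataset-restriction filters.

The unit of observation is the *sighting*: a spatio-temporally bounded set
of photographs of identified individuals, taken either from shore (chained
photo bursts within one bay) or from a fishing vessel (one longline-set
haul).  Photographic effort — the number of photographs taken during a
sighting — drives the probability that individuals present were actually
identified, and is banded into five categorical levels used downstream as
a random term in the occurrence model.

Input dialects (delimited text, comma by default):

``photos.csv``
    photo_id, timestamp (ISO-8601), platform (shore|vessel), vessel_id,
    site_or_set_id, lon, lat, individual_ids ("A;B;C")
``sightings.csv``
    sighting_id, platform, start_time, end_time, vessel_id, site_or_set_id,
    lon, lat, n_photos, individual_ids

All timestamps are stored timezone-aware in UTC; a "day" anywhere in the
package means the UTC calendar date.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SHORE = "shore"
VESSEL = "vessel"
PLATFORMS = (SHORE, VESSEL)

#: Effort bands (label, inclusive lower bound on n_photos); upper bounds are
#: implied by the next band.  very_low <25, low 25–49, medium 50–124,
#: high 125–249, very_high >=250.
EFFORT_LEVELS = ("very_low", "low", "medium", "high", "very_high")
_EFFORT_BOUNDS = (1, 25, 50, 125, 250)


def effort_category(n_photos: int) -> str:
    """Band a sighting's photo count into the five-level effort category."""
    if n_photos < 1:
        raise ValueError(f"n_photos must be >= 1, got {n_photos}")
    idx = int(np.searchsorted(_EFFORT_BOUNDS, n_photos, side="right")) - 1
    return EFFORT_LEVELS[idx]


@dataclass(frozen=True)
class Photograph:
    """One photograph with the individuals identified in it."""

    photo_id: str
    timestamp: pd.Timestamp
    platform: str
    vessel_id: str | None
    site_or_set_id: str
    lon: float
    lat: float
    individual_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise ValueError(f"unknown platform {self.platform!r}")
        if self.platform == VESSEL and not self.vessel_id:
            raise ValueError(f"photo {self.photo_id}: vessel photo without vessel_id")
        if self.platform == VESSEL and not self.site_or_set_id:
            raise ValueError(f"photo {self.photo_id}: vessel photo without set id")
        if not (-90.0 <= self.lat <= 90.0 and -180.0 <= self.lon <= 180.0):
            raise ValueError(f"photo {self.photo_id}: coordinates out of range")


@dataclass(frozen=True)
class Sighting:
    sighting_id: str
    platform: str
    start_time: pd.Timestamp
    end_time: pd.Timestamp
    lon: float
    lat: float
    n_photos: int
    individual_ids: frozenset[str]
    vessel_id: str | None = None
    site_or_set_id: str | None = None

    def __post_init__(self) -> None:
        if self.end_time < self.start_time:
            raise ValueError(f"sighting {self.sighting_id}: end before start")
        if self.n_photos < 1:
            raise ValueError(f"sighting {self.sighting_id}: n_photos < 1")

    @property
    def effort_category(self) -> str:
        return effort_category(self.n_photos)

    @property
    def year(self) -> int:
        return int(self.start_time.year)

    @property
    def date(self):
        """UTC calendar date (the sampling 'day')."""
        return self.start_time.tz_convert("UTC").date()


@dataclass(frozen=True)
class Individual:
    individual_id: str
    years_photographed: frozenset[int]

    @property
    def first_year(self) -> int:
        return min(self.years_photographed)

    @property
    def last_year(self) -> int:
        return max(self.years_photographed)


@dataclass
class Dataset:
    """A collection of sightings plus the derived individual catalogue."""

    sightings: list[Sighting]
    provenance: dict = field(default_factory=dict)

    @property
    def individuals(self) -> dict[str, Individual]:
        years: dict[str, set[int]] = {}
        for s in self.sightings:
            for ind in s.individual_ids:
                years.setdefault(ind, set()).add(s.year)
        return {
            i: Individual(i, frozenset(y)) for i, y in sorted(years.items())
        }

    @property
    def individual_ids(self) -> list[str]:
        return sorted({i for s in self.sightings for i in s.individual_ids})

    def counts_by_platform(self) -> dict[str, int]:
        out = {p: 0 for p in PLATFORMS}
        for s in self.sightings:
            out[s.platform] += 1
        return out

    def subset(self, platform: str) -> "Dataset":
        return Dataset([s for s in self.sightings if s.platform == platform],
                       dict(self.provenance, platform=platform))

    def __len__(self) -> int:
        return len(self.sightings)


# ---------------------------------------------------------------------------
# Sighting construction from photo logs
# ---------------------------------------------------------------------------

def _to_utc(ts) -> pd.Timestamp:
    t = pd.Timestamp(ts)
    if t is pd.NaT:
        raise ValueError("unparseable timestamp")
    return t.tz_localize("UTC") if t.tzinfo is None else t.tz_convert("UTC")


def _aggregate(photos: Sequence[Photograph], sighting_id: str) -> Sighting:
    times = [p.timestamp for p in photos]
    ids = frozenset().union(*(p.individual_ids for p in photos))
    return Sighting(
        sighting_id=sighting_id,
        platform=photos[0].platform,
        start_time=min(times),
        end_time=max(times),
        lon=float(np.mean([p.lon for p in photos])),
        lat=float(np.mean([p.lat for p in photos])),
        n_photos=len(photos),
        individual_ids=ids,
        vessel_id=photos[0].vessel_id,
        site_or_set_id=photos[0].site_or_set_id,
    )


def build_shore_sightings(photos: Iterable[Photograph],
                          gap_hours: float = 1.0) -> list[Sighting]:
    """Chain shore photographs into sightings.

    Photographs from the same bay are merged into one sighting whenever
    consecutive photographs (in time order) are less than ``gap_hours``
    apart; the chain breaks at the first gap >= ``gap_hours``.
    """
    photos = list(photos)
    bad = [p.photo_id for p in photos if p.platform != SHORE]
    if bad:
        raise ValueError(f"build_shore_sightings got non-shore photos: {bad[:5]}")
    gap = pd.Timedelta(hours=gap_hours)
    out: list[Sighting] = []
    by_bay: dict[str, list[Photograph]] = {}
    for p in photos:
        by_bay.setdefault(p.site_or_set_id, []).append(p)
    for bay in sorted(by_bay):
        chrono = sorted(by_bay[bay], key=lambda p: (p.timestamp, p.photo_id))
        chain: list[Photograph] = []
        for p in chrono:
            if chain and (p.timestamp - chain[-1].timestamp) >= gap:
                out.append(_aggregate(chain, f"SH-{bay}-{len(out):04d}"))
                chain = []
            chain.append(p)
        if chain:
            out.append(_aggregate(chain, f"SH-{bay}-{len(out):04d}"))
    out.sort(key=lambda s: (s.start_time, s.sighting_id))
    return [replace(s, sighting_id=f"SH{k:05d}") for k, s in enumerate(out)]


def build_vessel_sightings(photos: Iterable[Photograph]) -> list[Sighting]:
    """One sighting per (vessel, longline-set) haul."""
    photos = list(photos)
    bad = [p.photo_id for p in photos if p.platform != VESSEL]
    if bad:
        raise ValueError(f"build_vessel_sightings got non-vessel photos: {bad[:5]}")
    by_haul: dict[tuple[str, str], list[Photograph]] = {}
    for p in photos:
        if not p.site_or_set_id:
            raise ValueError(f"photo {p.photo_id}: missing longline-set id")
        by_haul.setdefault((p.vessel_id, p.site_or_set_id), []).append(p)
    out = [
        _aggregate(ps, f"VS-{v}-{h}") for (v, h), ps in sorted(by_haul.items())
    ]
    out.sort(key=lambda s: (s.start_time, s.sighting_id))
    return out


# ---------------------------------------------------------------------------
# Dataset restriction
# ---------------------------------------------------------------------------

def restrict_dataset(ds: Dataset,
                     min_years: int = 6,
                     min_last_year: int = 2019,
                     min_photos_per_sighting: int = 42) -> Dataset:
    """Apply the tenure and photographic-effort restriction filters.

    Keeps sightings with at least ``min_photos_per_sighting`` photographs,
    then keeps individuals photographed in at least ``min_years`` distinct
    calendar years whose last year is strictly after ``min_last_year``
    (both computed from the retained sightings), and finally drops
    sightings left with no retained individual.  Applied in this order the
    operation is idempotent.
    """
    if min_photos_per_sighting < 1:
        raise ValueError("min_photos_per_sighting must be >= 1")
    kept = [s for s in ds.sightings if s.n_photos >= min_photos_per_sighting]
    tmp = Dataset(kept)
    ok = {
        i for i, ind in tmp.individuals.items()
        if len(ind.years_photographed) >= min_years and ind.last_year > min_last_year
    }
    out: list[Sighting] = []
    for s in kept:
        ids = frozenset(s.individual_ids & ok)
        if ids:
            out.append(replace(s, individual_ids=ids))
    if not out:
        raise ValueError("dataset is empty after filtering")
    res = Dataset(out, dict(ds.provenance,
                            filters=dict(min_years=min_years,
                                         min_last_year=min_last_year,
                                         min_photos=min_photos_per_sighting)))
    logger.info("restrict_dataset: %d -> %d sightings, %d individuals, %s",
                len(ds), len(res), len(res.individuals),
                res.counts_by_platform())
    return res


@dataclass(frozen=True)
class ThresholdSuggestion:
    suggested: int
    mean_individuals_per_sighting: float
    sd_individuals_per_sighting: float
    median_n_photos: float


def suggest_photo_threshold(ds: Dataset, multiplier: float = 3.0) -> ThresholdSuggestion:
    """Advisory photo threshold: ceil(multiplier x mean individuals/sighting).

    Also reports the median photo count per sighting (the minimum number of
    photographs taken during 50% of sightings) as a cross-check.  The
    operative threshold used by :func:`restrict_dataset` comes from config,
    not from this suggestion.
    """
    if not ds.sightings:
        raise ValueError("empty dataset")
    n_ind = np.array([len(s.individual_ids) for s in ds.sightings], dtype=float)
    n_photos = np.array([s.n_photos for s in ds.sightings], dtype=float)
    mean = float(n_ind.mean())
    return ThresholdSuggestion(
        suggested=math.ceil(multiplier * mean),
        mean_individuals_per_sighting=mean,
        sd_individuals_per_sighting=float(n_ind.std()),
        median_n_photos=float(np.median(n_photos)),
    )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_photos(path, sep: str = ",") -> list[Photograph]:
    df = pd.read_csv(path, sep=sep, dtype=str)
    required = {"photo_id", "timestamp", "platform", "lon", "lat"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"photos file missing columns: {sorted(missing)}")
    out = []
    for idx, row in df.iterrows():
        try:
            ts = _to_utc(row["timestamp"])
        except ValueError as e:
            raise ValueError(f"row {idx} (photo {row['photo_id']}): {e}") from None
        ids = row.get("individual_ids")
        inds = frozenset() if pd.isna(ids) or not str(ids).strip() else frozenset(
            s.strip() for s in str(ids).split(";") if s.strip())
        out.append(Photograph(
            photo_id=str(row["photo_id"]),
            timestamp=ts,
            platform=str(row["platform"]),
            vessel_id=None if pd.isna(row.get("vessel_id")) else str(row["vessel_id"]),
            site_or_set_id="" if pd.isna(row.get("site_or_set_id")) else str(row["site_or_set_id"]),
            lon=float(row["lon"]),
            lat=float(row["lat"]),
            individual_ids=inds,
        ))
    return out


def sightings_to_frame(sightings: Iterable[Sighting]) -> pd.DataFrame:
    rows = []
    for s in sightings:
        rows.append(dict(
            sighting_id=s.sighting_id,
            platform=s.platform,
            start_time=s.start_time.isoformat(),
            end_time=s.end_time.isoformat(),
            vessel_id=s.vessel_id or "",
            site_or_set_id=s.site_or_set_id or "",
            lon=s.lon, lat=s.lat, n_photos=s.n_photos,
            individual_ids=";".join(sorted(s.individual_ids)),
        ))
    return pd.DataFrame(rows)


def write_sightings(sightings: Iterable[Sighting], path, sep: str = ",") -> None:
    sightings_to_frame(sightings).to_csv(path, sep=sep, index=False)


def read_sightings(path, sep: str = ",") -> Dataset:
    df = pd.read_csv(path, sep=sep, dtype=str)
    out = []
    for idx, row in df.iterrows():
        ids = row["individual_ids"]
        inds = frozenset() if pd.isna(ids) or not str(ids).strip() else frozenset(
            str(ids).split(";"))
        try:
            start, end = _to_utc(row["start_time"]), _to_utc(row["end_time"])
        except ValueError as e:
            raise ValueError(f"row {idx} (sighting {row['sighting_id']}): {e}") from None
        out.append(Sighting(
            sighting_id=str(row["sighting_id"]),
            platform=str(row["platform"]),
            start_time=start, end_time=end,
            lon=float(row["lon"]), lat=float(row["lat"]),
            n_photos=int(row["n_photos"]),
            individual_ids=inds,
            vessel_id=(None if pd.isna(row.get("vessel_id")) or not str(row.get("vessel_id"))
                       else str(row["vessel_id"])),
            site_or_set_id=(None if pd.isna(row.get("site_or_set_id")) or not str(row.get("site_or_set_id"))
                            else str(row["site_or_set_id"])),
        ))
    return Dataset(out, provenance={"source": str(path)})
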