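"""Lake and visit domain model.

The analysis operates on two tables: a lake attribute table (one row per
water body, with coordinates, physical/chemical traits and a trophic class)
and a visit table (one row per observation of a marked juvenile on a
non-natal lake).  This module defines the in-memory types, the trophic
taxonomy, trait conventions (shape index, completeness), suitability
filtering, and CSV I/O for both tables.

Missing trait values are loaded and flagged, never silently dropped;
filtering to trait-complete records is an explicit, reported step.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from datetime import date as Date
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

log = logging.getLogger(__name__)

#: The five basic quantitative lake traits used throughout the analysis.
BASIC_TRAITS: tuple[str, ...] = ("area_ha", "max_depth", "shape_index", "secchi", "ph")

#: Trophic codes attainable by classification of a lake:
#: {Complex,Simple} x {Cool,Warm} x {Clear,Dark}, plus two-story (TS) lakes,
#: whose vertical stratification supports both warm- and cold-water fish
#: communities and overrides the clarity/temperature split.
LAKE_TROPHIC_CODES: tuple[str, ...] = (
    "CCC", "CCD", "CWC", "CWD", "SCC", "SCD", "SWC", "SWD", "TS",
)

#: Water-body categories present in regional trophic datasets but never
#: suitable loon habitat; they close the 12-code taxonomy.
NON_LAKE_TROPHIC_CODES: tuple[str, ...] = ("RIVER", "TROUT_POND", "SPRING_POND")

TROPHIC_CODES: tuple[str, ...] = LAKE_TROPHIC_CODES + NON_LAKE_TROPHIC_CODES

DEFAULT_EXCLUDED_CLASSES: frozenset[str] = frozenset(NON_LAKE_TROPHIC_CODES)

#: Classes treated as trophically complex (diverse sportfish community).
COMPLEX_CODES: frozenset[str] = frozenset({"CCC", "CCD", "CWC", "CWD", "TS"})


def normalize_trophic_code(code: str) -> str:
    """Normalize a free-text class label (e.g. ``"trout pond"``) to code form."""
    return code.strip().upper().replace(" ", "_").replace("-", "_")


@dataclass(frozen=True)
class TrophicClass:
    """A discrete trophic lake category.

    The taxonomy combines sportfish richness (Complex/Simple), temperature
    (Warm/Cool), water clarity (Clear/Dark) and stratification (two-story);
    the code is a deterministic function of the components.
    """

    code: str
    complexity: Optional[str] = None  # "Complex" | "Simple"
    temperature: Optional[str] = None  # "Warm" | "Cool"
    clarity: Optional[str] = None  # "Clear" | "Dark"
    two_story: bool = False

    def __post_init__(self) -> None:
        if self.code not in TROPHIC_CODES:
            raise ValueError(
                f"unknown trophic code {self.code!r}; expected one of {TROPHIC_CODES}"
            )

    @property
    def is_complex(self) -> bool:
        return self.code in COMPLEX_CODES


def classify_trophic(
    sportfish_species_count: int,
    temperature: str,
    clarity: str,
    two_story: bool = False,
    complex_threshold: int = 4,
) -> TrophicClass:
    """Assign a trophic class from its defining components.

    Lakes with at least ``complex_threshold`` sportfish species are Complex,
    fewer are Simple (the boundary count is assigned to Complex; the
    threshold is exposed because the verbal rule is ambiguous at the
    boundary).  Two-story lakes take the TS code regardless of clarity.
    """
    if sportfish_species_count < 0:
        raise ValueError("sportfish_species_count must be >= 0")
    if temperature not in ("Warm", "Cool"):
        raise ValueError(f"temperature must be 'Warm' or 'Cool', got {temperature!r}")
    if clarity not in ("Clear", "Dark"):
        raise ValueError(f"clarity must be 'Clear' or 'Dark', got {clarity!r}")
    complexity = "Complex" if sportfish_species_count >= complex_threshold else "Simple"
    if two_story:
        code = "TS"
    else:
        code = complexity[0] + temperature[0] + clarity[0]
    return TrophicClass(
        code=code,
        complexity=complexity,
        temperature=temperature,
        clarity=clarity,
        two_story=two_story,
    )


def compute_shape_index(perimeter_km: float, area_ha: float) -> float:
    """Shoreline development index: perimeter (km) / sqrt(area (ha)).

    With these units a circular lake of 100 ha scores ~0.354, the practical
    minimum for real lakes; the index is invariant under uniform linear
    rescaling of the outline (perimeter scales by k, area by k**2).
    """
    if perimeter_km <= 0:
        raise ValueError(f"perimeter_km must be > 0, got {perimeter_km}")
    if area_ha <= 0:
        raise ValueError(f"area_ha must be > 0, got {area_ha}")
    return perimeter_km / math.sqrt(area_ha)


@dataclass
class Lake:
    """One water body with coordinates, traits and trophic class.

    Trait fields are ``None`` when missing in the source table; ``area_ha``
    in hectares, ``perimeter_km`` in kilometres, ``max_depth`` and ``secchi``
    in the source's units (metres assumed, stored as given, never converted).
    """

    lake_id: str
    name: str = ""
    lat: float = 0.0
    lon: float = 0.0
    area_ha: Optional[float] = None
    perimeter_km: Optional[float] = None
    shape_index: Optional[float] = None
    max_depth: Optional[float] = None
    secchi: Optional[float] = None
    ph: Optional[float] = None
    trophic_class: Optional[str] = None
    loon_suitable: bool = True

    def __post_init__(self) -> None:
        if not self.lake_id:
            raise ValueError("lake_id must be non-empty")
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"lake {self.lake_id}: lat {self.lat} out of [-90, 90]")
        if not (-180.0 <= self.lon <= 180.0):
            raise ValueError(f"lake {self.lake_id}: lon {self.lon} out of [-180, 180]")
        if self.area_ha is not None and self.area_ha <= 0:
            raise ValueError(f"lake {self.lake_id}: area_ha must be > 0")
        if self.ph is not None and not (0.0 < self.ph < 14.0):
            raise ValueError(f"lake {self.lake_id}: ph {self.ph} out of (0, 14)")
        if self.shape_index is not None and self.shape_index <= 0:
            raise ValueError(f"lake {self.lake_id}: shape_index must be > 0")
        if self.trophic_class is not None:
            self.trophic_class = normalize_trophic_code(self.trophic_class)

    @property
    def has_basic_traits(self) -> bool:
        """True when all five basic quantitative traits are present."""
        return all(getattr(self, t) is not None for t in BASIC_TRAITS)

    def get_trait(self, trait: str) -> Optional[float]:
        if trait not in BASIC_TRAITS:
            raise KeyError(f"unknown trait {trait!r}; expected one of {BASIC_TRAITS}")
        return getattr(self, trait)


@dataclass(frozen=True)
class VisitRecord:
    """One observation of a marked juvenile on a non-natal lake."""

    juvenile_id: str
    natal_lake_id: str
    destination_lake_id: str
    date: Optional[Date] = None

    def __post_init__(self) -> None:
        if self.natal_lake_id == self.destination_lake_id:
            raise ValueError(
                f"visit by {self.juvenile_id}: natal and destination lake are both "
                f"{self.natal_lake_id}"
            )


# ---------------------------------------------------------------------------
# CSV I/O

LAKE_COLUMNS = (
    "lake_id", "name", "lat", "lon", "area_ha", "perimeter_km", "shape_index",
    "max_depth", "secchi", "ph", "trophic_code", "suitable",
)
VISIT_COLUMNS = ("juvenile_id", "natal_lake_id", "destination_lake_id", "date")

_LAKE_FLOAT_FIELDS = {
    "lat": "lat", "lon": "lon", "area_ha": "area_ha",
    "perimeter_km": "perimeter_km", "shape_index": "shape_index",
    "max_depth": "max_depth", "secchi": "secchi", "ph": "ph",
}


@dataclass
class LoadReport:
    """Summary of a lake-table load: completeness of the five basic traits."""

    n_rows: int = 0
    n_complete: int = 0
    n_incomplete: int = 0
    missing_by_field: dict[str, int] = field(default_factory=dict)

    def __str__(self) -> str:
        return f"{self.n_complete} complete, {self.n_incomplete} incomplete"


@dataclass
class VisitFilterReport:
    """Summary of a visit-table load and optional completeness filter."""

    n_rows: int = 0
    n_valid: int = 0
    n_after_completeness: Optional[int] = None
    rejections: list[str] = field(default_factory=list)

    def __str__(self) -> str:
        if self.n_after_completeness is None:
            return f"{self.n_rows} rows -> {self.n_valid} visits"
        return f"{self.n_valid} -> {self.n_after_completeness}"


def _parse_float(
    raw: str, column: str, row_label: str, required: bool = False
) -> Optional[float]:
    raw = raw.strip()
    if raw == "":
        if required:
            raise ValueError(f"row {row_label}: missing required value for {column}")
        return None
    try:
        return float(raw)
    except ValueError as exc:
        raise ValueError(
            f"row {row_label}: unparseable {column} value {raw!r}"
        ) from exc


def read_lake_table(path: str | Path) -> tuple[list[Lake], LoadReport]:
    """Read a lake CSV into ``Lake`` records plus a completeness report.

    Rows with missing trait values load with those fields ``None`` and are
    counted incomplete.  Duplicate ids and unparseable coordinates raise.
    """
    path = Path(path)
    lakes: list[Lake] = []
    seen: set[str] = set()
    report = LoadReport()
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "lake_id" not in reader.fieldnames:
            raise ValueError(f"{path}: header row with a 'lake_id' column required")
        for i, row in enumerate(reader, start=2):  # 1-based incl. header
            lake_id = (row.get("lake_id") or "").strip()
            if not lake_id:
                raise ValueError(f"row {i}: empty lake_id")
            if lake_id in seen:
                raise ValueError(f"duplicate lake_id {lake_id!r} at row {i}")
            seen.add(lake_id)
            kwargs: dict = {"lake_id": lake_id, "name": (row.get("name") or "").strip()}
            for col, attr in _LAKE_FLOAT_FIELDS.items():
                required = col in ("lat", "lon")
                kwargs[attr] = _parse_float(row.get(col, ""), col, f"{i} ({lake_id})",
                                            required=required)
            code = (row.get("trophic_code") or "").strip()
            kwargs["trophic_class"] = code or None
            suit = (row.get("suitable") or "").strip().lower()
            kwargs["loon_suitable"] = suit not in ("false", "0", "no", "n")
            lake = Lake(**kwargs)
            lakes.append(lake)
            report.n_rows += 1
            if lake.has_basic_traits:
                report.n_complete += 1
            else:
                report.n_incomplete += 1
                for t in BASIC_TRAITS:
                    if getattr(lake, t) is None:
                        report.missing_by_field[t] = report.missing_by_field.get(t, 0) + 1
    return lakes, report


def write_lake_table(lakes: Iterable[Lake], path: str | Path) -> None:
    """Write lakes as CSV; floats use shortest-repr so re-reading is exact."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(LAKE_COLUMNS)
        for lake in lakes:
            writer.writerow([
                lake.lake_id, lake.name,
                repr(lake.lat), repr(lake.lon),
                *("" if getattr(lake, a) is None else repr(getattr(lake, a))
                  for a in ("area_ha", "perimeter_km", "shape_index",
                            "max_depth", "secchi", "ph")),
                lake.trophic_class or "",
                "true" if lake.loon_suitable else "false",
            ])


def read_visit_table(
    path: str | Path,
    lakes: Sequence[Lake],
    require_complete_traits: bool = False,
    months: Optional[Sequence[int]] = None,
) -> tuple[list[VisitRecord], VisitFilterReport]:
    """Read a visit CSV, validating lake references.

    Visits referencing unknown lakes, or whose natal and destination lake
    coincide, are rejected with a reason naming the offending id; rejections
    are collected in the report rather than aborting the load.  With
    ``require_complete_traits`` only visits whose natal AND destination lakes
    carry all five basic traits are returned (the before/after counts go in
    the report).  ``months`` optionally restricts to observation months
    (e.g. ``(9, 10)`` for the September-October fledging window).
    """
    path = Path(path)
    by_id = {lake.lake_id: lake for lake in lakes}
    visits: list[VisitRecord] = []
    report = VisitFilterReport()
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "natal_lake_id" not in reader.fieldnames:
            raise ValueError(f"{path}: header row with visit columns required")
        for i, row in enumerate(reader, start=2):
            report.n_rows += 1
            jid = (row.get("juvenile_id") or "").strip()
            natal = (row.get("natal_lake_id") or "").strip()
            dest = (row.get("destination_lake_id") or "").strip()
            raw_date = (row.get("date") or "").strip()
            reason = None
            if natal not in by_id:
                reason = f"row {i}: unknown natal lake {natal!r}"
            elif dest not in by_id:
                reason = f"row {i}: unknown destination lake {dest!r}"
            elif natal == dest:
                reason = f"row {i}: natal and destination are the same lake {natal!r}"
            if reason is None and raw_date:
                try:
                    parsed_date: Optional[Date] = Date.fromisoformat(raw_date)
                except ValueError:
                    reason = f"row {i}: unparseable date {raw_date!r}"
            else:
                parsed_date = None
            if reason is None and months is not None and parsed_date is not None \
                    and parsed_date.month not in months:
                reason = f"row {i}: date {raw_date} outside months {tuple(months)}"
            if reason is not None:
                report.rejections.append(reason)
                continue
            visits.append(VisitRecord(jid, natal, dest, parsed_date))
            report.n_valid += 1
    if require_complete_traits:
        kept = [
            v for v in visits
            if by_id[v.natal_lake_id].has_basic_traits
            and by_id[v.destination_lake_id].has_basic_traits
        ]
        report.n_after_completeness = len(kept)
        visits = kept
    return visits, report


def write_visit_table(visits: Iterable[VisitRecord], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(VISIT_COLUMNS)
        for v in visits:
            writer.writerow([
                v.juvenile_id, v.natal_lake_id, v.destination_lake_id,
                v.date.isoformat() if v.date else "",
            ])


def filter_loon_suitable(
    lakes: Iterable[Lake],
    min_area_ha: float = 10.0,
    excluded_classes: frozenset[str] | set[str] = DEFAULT_EXCLUDED_CLASSES,
) -> list[Lake]:
    """Drop water bodies unusable by loons: below the area threshold or in an
    excluded class (rivers, trout ponds, ...).  Removal counts are logged per
    reason.  Lakes with unknown area are removed whenever an area threshold
    applies, since the threshold cannot be verified.
    """
    excluded = {normalize_trophic_code(c) for c in excluded_classes}
    kept: list[Lake] = []
    removed: dict[str, int] = {}
    for lake in lakes:
        if lake.trophic_class is not None and lake.trophic_class in excluded:
            removed["excluded_class"] = removed.get("excluded_class", 0) + 1
            continue
        if min_area_ha > 0:
            if lake.area_ha is None:
                removed["missing_area"] = removed.get("missing_area", 0) + 1
                continue
            if lake.area_ha < min_area_ha:
                removed["below_min_area"] = removed.get("below_min_area", 0) + 1
                continue
        kept.append(lake)
    if removed:
        log.info("filter_loon_suitable removed %s", removed)
    return kept


def lakes_by_id(lakes: Iterable[Lake]) -> dict[str, Lake]:
    """Index lakes by id, enforcing uniqueness."""
    out: dict[str, Lake] = {}
    for lake in lakes:
        if lake.lake_id in out:
            raise ValueError(f"duplicate lake_id {lake.lake_id!r}")
        out[lake.lake_id] = lake
    return out
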