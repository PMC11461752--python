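"""Domain types and CSV input/output for citizen-science observation records.

An observation is one record from a platform export (e.g. an iNaturalist
CSV): a species name, a date, WGS84 coordinates with a positional-accuracy
radius in metres, a human assessment of the attached media, the platform's
own quality grade, and — when expert verification has been done — an
accuracy label (correct / incorrect / uncertain).

Absence is meaningful throughout: a blank coordinate cell becomes ``None``,
never zero, because missing georeferencing is a scoring stop condition while
a zero coordinate is a (bad) datum.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence


class ObsConfError(Exception):
    """Base class for package errors."""


class DataError(ObsConfError):
    """Malformed or inconsistent input data."""


class ConfigError(ObsConfError):
    """Invalid rubric or run configuration."""


class QualityGrade(str, enum.Enum):
    """iNaturalist's internal data-quality tier."""

    CASUAL = "casual"
    NEEDS_ID = "needs_id"
    RESEARCH_GRADE = "research_grade"


class AccuracyLabel(str, enum.Enum):
    """Expert verdict on an observation's identification."""

    INCORRECT = "incorrect"
    UNCERTAIN = "uncertain"
    CORRECT = "correct"


class MediaClarity(str, enum.Enum):
    CLEAR = "clear"
    MODERATE = "moderate"
    POOR = "poor"
    UNUSABLE = "unusable"


class FeaturesShown(str, enum.Enum):
    ALL = "all"
    MOST = "most"
    SOME = "some"
    NONE = "none"


class DiagnosticVisibility(str, enum.Enum):
    EASY_TO_SEE = "easy_to_see"
    VISIBLE_WITH_DIFFICULTY = "visible_with_difficulty"
    REQUIRES_DISSECTION_OR_MOLECULAR = "requires_dissection_or_molecular"


@dataclass(frozen=True)
class MediaAssessment:
    """Human (or upstream-tool) judgement of the uploaded media.

    ``clarity == UNUSABLE`` and ``diagnostic_features_shown == NONE`` are the
    two media stop conditions: either makes the observation unscorable.
    """

    clarity: MediaClarity
    diagnostic_features_shown: FeaturesShown


@dataclass(frozen=True)
class SpeciesTraits:
    """Per-species scoring inputs from the curated trait registry."""

    species_name: str
    diagnostic_visibility: DiagnosticVisibility
    similar_species_in_region: bool
    notes: str = ""


@dataclass(frozen=True)
class ObservationRecord:
    record_id: str
    species_name: str
    media: MediaAssessment
    quality_grade: QualityGrade
    observed_on: str | None = None
    latitude: float | None = None
    longitude: float | None = None
    positional_accuracy_m: float | None = None
    accuracy_label: AccuracyLabel | None = None

    def __post_init__(self) -> None:
        if (self.latitude is None) != (self.longitude is None):
            raise DataError(
                f"record {self.record_id!r}: latitude and longitude must be "
                "both present or both absent"
            )
        if self.latitude is not None and not -90.0 <= self.latitude <= 90.0:
            raise DataError(f"record {self.record_id!r}: latitude out of range")
        if self.longitude is not None and not -180.0 <= self.longitude <= 180.0:
            raise DataError(f"record {self.record_id!r}: longitude out of range")
        if self.positional_accuracy_m is not None and self.positional_accuracy_m < 0:
            raise DataError(
                f"record {self.record_id!r}: negative positional accuracy"
            )

    @property
    def has_coordinates(self) -> bool:
        return self.latitude is not None and self.longitude is not None


@dataclass
class ObservationSet:
    """An ordered collection of records with unique ids."""

    records: list[ObservationRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.record_id in seen:
                raise DataError(f"duplicate record_id {rec.record_id!r}")
            seen.add(rec.record_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass(frozen=True)
class RejectedRow:
    """One input row that could not be turned into a record."""

    row_number: int
    record_id: str
    reason: str


# Default observation-CSV column names; a column_map overrides individual
# entries so raw platform exports with different headers can be ingested.
DEFAULT_COLUMNS: dict[str, str] = {
    "record_id": "record_id",
    "species_name": "species_name",
    "observed_on": "observed_on",
    "latitude": "latitude",
    "longitude": "longitude",
    "positional_accuracy_m": "positional_accuracy_m",
    "media_clarity": "media_clarity",
    "media_features": "media_features",
    "quality_grade": "quality_grade",
    "accuracy_label": "accuracy_label",
}

_MANDATORY_FIELDS = ("record_id", "species_name", "quality_grade")


def _blank(cell: str | None) -> bool:
    return cell is None or cell.strip() == ""


def _parse_float(cell: str, what: str) -> float:
    try:
        return float(cell)
    except ValueError:
        raise DataError(f"unparseable {what}: {cell!r}") from None


def _parse_enum(cell: str, enum_cls, what: str):
    try:
        return enum_cls(cell.strip())
    except ValueError:
        valid = ", ".join(e.value for e in enum_cls)
        raise DataError(f"unknown {what} {cell.strip()!r} (expected one of: {valid})") from None


def read_observations(
    path,
    column_map: Mapping[str, str] | None = None,
) -> tuple[ObservationSet, list[RejectedRow]]:
    """Read an observation CSV.

    Returns the parsed set plus a rejection report: rows violating a
    record-level invariant (bad coordinate, negative accuracy, unknown
    enum token) are excluded and reported rather than aborting the read.
    Missing mandatory *columns* are a hard error naming the column.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)

    records: list[ObservationRecord] = []
    rejected: list[RejectedRow] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for fld in _MANDATORY_FIELDS + ("media_clarity", "media_features"):
            if cols[fld] not in header:
                raise DataError(f"missing mandatory column {cols[fld]!r}")
        for i, row in enumerate(reader, start=2):  # row 1 is the header
            rid = (row.get(cols["record_id"]) or "").strip()
            try:
                records.append(_row_to_record(row, cols, rid))
            except DataError as exc:
                rejected.append(RejectedRow(i, rid, str(exc)))
    return ObservationSet(records, provenance=str(path)), rejected


def _row_to_record(row: Mapping[str, str], cols: Mapping[str, str], rid: str) -> ObservationRecord:
    if not rid:
        raise DataError("blank record_id")
    species = (row.get(cols["species_name"]) or "").strip()
    if not species:
        raise DataError("blank species_name")

    lat_cell = row.get(cols["latitude"])
    lon_cell = row.get(cols["longitude"])
    lat = None if _blank(lat_cell) else _parse_float(lat_cell, "latitude")
    lon = None if _blank(lon_cell) else _parse_float(lon_cell, "longitude")

    acc_cell = row.get(cols["positional_accuracy_m"])
    acc = None if _blank(acc_cell) else _parse_float(acc_cell, "positional accuracy")

    media = MediaAssessment(
        clarity=_parse_enum(row[cols["media_clarity"]], MediaClarity, "media clarity"),
        diagnostic_features_shown=_parse_enum(
            row[cols["media_features"]], FeaturesShown, "diagnostic features level"
        ),
    )
    grade = _parse_enum(row[cols["quality_grade"]], QualityGrade, "quality grade")

    label_cell = row.get(cols["accuracy_label"])
    label = None if _blank(label_cell) else _parse_enum(label_cell, AccuracyLabel, "accuracy label")

    date_cell = row.get(cols["observed_on"])
    date = None if _blank(date_cell) else date_cell.strip()

    return ObservationRecord(
        record_id=rid,
        species_name=species,
        observed_on=date,
        latitude=lat,
        longitude=lon,
        positional_accuracy_m=acc,
        media=media,
        quality_grade=grade,
        accuracy_label=label,
    )


REGISTRY_COLUMNS = ("species_name", "diagnostic_visibility", "similar_species_in_region", "notes")

_TRUE_TOKENS = {"true", "yes", "1"}
_FALSE_TOKENS = {"false", "no", "0"}


def read_species_registry(path) -> dict[str, SpeciesTraits]:
    """Read the curated species-trait registry into a unique-key map.

    Duplicate species rows and unknown enum tokens are hard errors (the
    registry is researcher-authored reference data, not bulk export).
    """
    registry: dict[str, SpeciesTraits] = {}
    duplicates: list[str] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in REGISTRY_COLUMNS[:3]:
            if col not in header:
                raise DataError(f"missing mandatory column {col!r}")
        for i, row in enumerate(reader, start=2):
            name = (row.get("species_name") or "").strip()
            if not name:
                raise DataError(f"registry row {i}: blank species_name")
            token = (row.get("similar_species_in_region") or "").strip().lower()
            if token in _TRUE_TOKENS:
                similar = True
            elif token in _FALSE_TOKENS:
                similar = False
            else:
                raise DataError(f"registry row {i}: unknown boolean token {token!r}")
            try:
                visibility = DiagnosticVisibility((row.get("diagnostic_visibility") or "").strip())
            except ValueError:
                raise DataError(
                    f"registry row {i}: unknown diagnostic_visibility token "
                    f"{(row.get('diagnostic_visibility') or '').strip()!r}"
                ) from None
            if name in registry:
                duplicates.append(name)
                continue
            registry[name] = SpeciesTraits(
                species_name=name,
                diagnostic_visibility=visibility,
                similar_species_in_region=similar,
                notes=(row.get("notes") or "").strip(),
            )
    if duplicates:
        raise DataError("duplicate registry species: " + ", ".join(sorted(set(duplicates))))
    return registry


def write_species_registry(registry: Mapping[str, SpeciesTraits], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(REGISTRY_COLUMNS)
        for name in registry:
            t = registry[name]
            writer.writerow(
                [t.species_name, t.diagnostic_visibility.value,
                 str(t.similar_species_in_region).lower(), t.notes]
            )


@dataclass(frozen=True)
class FilterOutcome:
    kept: ObservationSet
    excluded: ObservationSet
    reasons: Mapping[str, str] = field(default_factory=dict)  # record_id -> reason


def apply_habitat_plausibility_filter(
    obs: ObservationSet,
    is_plausible: Callable[[float, float], bool],
) -> FilterOutcome:
    """Partition a set by georeference plausibility.

    For marine taxa the typical predicate is "the point is at sea": records
    placed on land are implausible and are excluded as incorrect before
    scoring. Records *without* coordinates pass through untouched — they hit
    the georeference stop point during scoring instead. A predicate that
    raises on some record routes that record to ``excluded`` with reason
    ``predicate_error`` rather than aborting the run.
    """
    kept: list[ObservationRecord] = []
    excluded: list[ObservationRecord] = []
    reasons: dict[str, str] = {}
    for rec in obs:
        if not rec.has_coordinates:
            kept.append(rec)
            continue
        try:
            ok = bool(is_plausible(rec.latitude, rec.longitude))
        except Exception:
            excluded.append(rec)
            reasons[rec.record_id] = "predicate_error"
            continue
        if ok:
            kept.append(rec)
        else:
            excluded.append(rec)
            reasons[rec.record_id] = "implausible_georeference"
    return FilterOutcome(
        kept=ObservationSet(kept, provenance=obs.provenance),
        excluded=ObservationSet(excluded, provenance=obs.provenance),
        reasons=reasons,
    )


def rectangle_mask(lat_min: float, lat_max: float, lon_min: float, lon_max: float):
    """Toy plausibility predicate: accepts points inside a lat/lon rectangle.

    Real deployments supply a coastline polygon or land-mask raster adapter
    with the same ``(lat, lon) -> bool`` signature.
    """

    def predicate(lat: float, lon: float) -> bool:
        return lat_min <= lat <= lat_max and lon_min <= lon <= lon_max

    return predicate


def write_rejection_report(rejected: Sequence[RejectedRow], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["row_number", "record_id", "reason"])
        for r in rejected:
            writer.writerow([r.row_number, r.record_id, r.reason])
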