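"""The confidence-scoring rubric: three steps, stop points, summation, bands.

An observation is scored in three steps — the species being verified, the
attached media, and the georeference — and the step points are summed to a
total in [4, 18] that falls into one of three bands: low (4–8), medium
(9–13) or high (14–18). Species and media carry wider point ranges than the
georeference step because more factors bear on them. Four conditions stop
scoring outright and make the observation *unscorable*:

* the species needs dissection or molecular work for a species-level ID,
* the media are not clear enough to identify anything,
* the media do not show the required diagnostic features,
* no geographic coordinates were provided.

Point tables, accuracy-bin edges and band edges all live in
:class:`RubricConfig` and can be replaced wholesale from a YAML file; the
defaults below satisfy every structural constraint of the protocol
(attainable totals exactly [4, 18]; species/media ranges wider than geo;
bands disjoint, contiguous and covering [4, 18]) and are validated on load.
"""

from __future__ import annotations

import csv
import enum
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

from .observations import (
    AccuracyLabel,
    ConfigError,
    DataError,
    DiagnosticVisibility,
    FeaturesShown,
    MediaAssessment,
    MediaClarity,
    ObservationRecord,
    ObservationSet,
    QualityGrade,
    SpeciesTraits,
)


class Step(str, enum.Enum):
    SPECIES = "species"
    MEDIA = "media"
    GEOREFERENCE = "georeference"


class StopReason(str, enum.Enum):
    MOLECULAR_REQUIRED = "molecular_required"
    MEDIA_UNUSABLE = "media_unusable"
    FEATURES_NOT_SHOWN = "features_not_shown"
    NO_COORDINATES = "no_coordinates"


class Band(str, enum.Enum):
    UNSCORABLE = "unscorable"
    LOW = "low"
    MEDIUM = "medium"
    HIGH = "high"


@dataclass(frozen=True)
class StepScore:
    step: Step
    points: int | None  # None iff stopped
    stop_reason: StopReason | None = None

    def __post_init__(self) -> None:
        if (self.points is None) == (self.stop_reason is None):
            raise ConfigError("a step score carries either points or a stop reason")

    @property
    def stopped(self) -> bool:
        return self.stop_reason is not None


@dataclass(frozen=True)
class ConfidenceResult:
    species: StepScore
    media: StepScore
    georeference: StepScore
    total: int | None
    band: Band

    @property
    def stop_reason(self) -> StopReason | None:
        for step in (self.species, self.media, self.georeference):
            if step.stopped:
                return step.stop_reason
        return None


class UnregisteredSpeciesError(DataError):
    def __init__(self, species_name: str):
        self.species_name = species_name
        super().__init__(f"unregistered_species: {species_name!r} not in trait registry")


_SPECIES_DEFAULT = {
    (DiagnosticVisibility.EASY_TO_SEE, False): 7,
    (DiagnosticVisibility.EASY_TO_SEE, True): 5,
    (DiagnosticVisibility.VISIBLE_WITH_DIFFICULTY, False): 3,
    (DiagnosticVisibility.VISIBLE_WITH_DIFFICULTY, True): 1,
}

# Full clarity x features table for the non-stop levels; monotone along both
# axes (clearer media or more features shown never scores lower).
_MEDIA_DEFAULT = {
    (MediaClarity.CLEAR, FeaturesShown.ALL): 7,
    (MediaClarity.CLEAR, FeaturesShown.MOST): 5,
    (MediaClarity.CLEAR, FeaturesShown.SOME): 3,
    (MediaClarity.MODERATE, FeaturesShown.ALL): 5,
    (MediaClarity.MODERATE, FeaturesShown.MOST): 3,
    (MediaClarity.MODERATE, FeaturesShown.SOME): 3,
    (MediaClarity.POOR, FeaturesShown.ALL): 3,
    (MediaClarity.POOR, FeaturesShown.MOST): 1,
    (MediaClarity.POOR, FeaturesShown.SOME): 1,
}


@dataclass(frozen=True)
class RubricConfig:
    """Point tables, bin edges and band edges for the scoring rubric.

    ``geo_bin_edges_m`` are half-open, lower-inclusive cut points in metres:
    the default ``[1000, 10000]`` yields bins [0, 1000), [1000, 10000),
    [10000, inf) scored by ``geo_points`` best-to-worst. "Less than 1 km" is
    the strict reading of the top bin.

    ``strict_missing_accuracy`` governs records that have coordinates but no
    positional-accuracy radius: by default they take the *lowest* geo points
    with a warning (a missing radius degrades confidence, it does not void
    the georeference); in strict mode they stop as if uncoordinated.
    """

    species_points: Mapping[tuple[DiagnosticVisibility, bool], int] = field(
        default_factory=lambda: dict(_SPECIES_DEFAULT)
    )
    media_points: Mapping[tuple[MediaClarity, FeaturesShown], int] = field(
        default_factory=lambda: dict(_MEDIA_DEFAULT)
    )
    geo_bin_edges_m: tuple[float, ...] = (1000.0, 10000.0)
    geo_points: tuple[int, ...] = (4, 3, 2)  # best bin first
    band_edges: tuple[tuple[str, int, int], ...] = (
        ("low", 4, 8),
        ("medium", 9, 13),
        ("high", 14, 18),
    )
    strict_missing_accuracy: bool = False

    def __post_init__(self) -> None:
        validate_config(self)


def validate_config(cfg: RubricConfig) -> None:
    """Reject configurations that break the protocol's structural constraints."""
    for vis in (DiagnosticVisibility.EASY_TO_SEE, DiagnosticVisibility.VISIBLE_WITH_DIFFICULTY):
        for similar in (False, True):
            if (vis, similar) not in cfg.species_points:
                raise ConfigError(f"species_points missing level ({vis.value}, similar={similar})")
    for clarity in (MediaClarity.CLEAR, MediaClarity.MODERATE, MediaClarity.POOR):
        for shown in (FeaturesShown.ALL, FeaturesShown.MOST, FeaturesShown.SOME):
            if (clarity, shown) not in cfg.media_points:
                raise ConfigError(f"media_points missing level ({clarity.value}, {shown.value})")
    if len(cfg.geo_points) != len(cfg.geo_bin_edges_m) + 1:
        raise ConfigError("geo_points must have one entry per accuracy bin")
    if list(cfg.geo_bin_edges_m) != sorted(cfg.geo_bin_edges_m) or any(
        e <= 0 for e in cfg.geo_bin_edges_m
    ):
        raise ConfigError("geo_bin_edges_m must be positive and increasing")

    s_vals, m_vals, g_vals = (
        list(cfg.species_points.values()),
        list(cfg.media_points.values()),
        list(cfg.geo_points),
    )
    lo = min(s_vals) + min(m_vals) + min(g_vals)
    hi = max(s_vals) + max(m_vals) + max(g_vals)
    band_lo = min(b[1] for b in cfg.band_edges)
    band_hi = max(b[2] for b in cfg.band_edges)
    if (lo, hi) != (band_lo, band_hi):
        raise ConfigError(
            f"attainable totals [{lo}, {hi}] must coincide with the band range "
            f"[{band_lo}, {band_hi}]"
        )
    # Species and media must carry wider point ranges than georeferencing.
    g_span = max(g_vals) - min(g_vals)
    if max(s_vals) - min(s_vals) <= g_span or max(m_vals) - min(m_vals) <= g_span:
        raise ConfigError("species and media point ranges must be wider than the geo range")
    # Bands must be disjoint, contiguous, and cover the attainable range.
    spans = sorted((b[1], b[2], b[0]) for b in cfg.band_edges)
    if spans[0][0] != lo or spans[-1][1] != hi:
        raise ConfigError("bands must cover the attainable total range")
    for (a_lo, a_hi, _), (b_lo2, _, _) in zip(spans, spans[1:]):
        if a_hi + 1 != b_lo2:
            raise ConfigError("bands must be disjoint and contiguous")


DEFAULT_CONFIG = RubricConfig()


def score_species_step(traits: SpeciesTraits, config: RubricConfig = DEFAULT_CONFIG) -> StepScore:
    """Step 1: how identifiable is this species from ordinary media?"""
    if traits.diagnostic_visibility is DiagnosticVisibility.REQUIRES_DISSECTION_OR_MOLECULAR:
        return StepScore(Step.SPECIES, None, StopReason.MOLECULAR_REQUIRED)
    key = (traits.diagnostic_visibility, traits.similar_species_in_region)
    try:
        return StepScore(Step.SPECIES, config.species_points[key])
    except KeyError:
        raise ConfigError(f"species_points has no entry for {key}") from None


def score_media_step(media: MediaAssessment, config: RubricConfig = DEFAULT_CONFIG) -> StepScore:
    """Step 2: do the uploaded media support an identification?"""
    if media.clarity is MediaClarity.UNUSABLE:
        return StepScore(Step.MEDIA, None, StopReason.MEDIA_UNUSABLE)
    if media.diagnostic_features_shown is FeaturesShown.NONE:
        return StepScore(Step.MEDIA, None, StopReason.FEATURES_NOT_SHOWN)
    key = (media.clarity, media.diagnostic_features_shown)
    try:
        return StepScore(Step.MEDIA, config.media_points[key])
    except KeyError:
        raise ConfigError(f"media_points has no entry for {key}") from None


def score_georeference_step(
    record: ObservationRecord, config: RubricConfig = DEFAULT_CONFIG
) -> StepScore:
    """Step 3: how trustworthy is the georeference?"""
    if not record.has_coordinates:
        return StepScore(Step.GEOREFERENCE, None, StopReason.NO_COORDINATES)
    acc = record.positional_accuracy_m
    if acc is None:
        if config.strict_missing_accuracy:
            return StepScore(Step.GEOREFERENCE, None, StopReason.NO_COORDINATES)
        warnings.warn(
            f"record {record.record_id!r}: coordinates present but positional "
            "accuracy absent; assigning lowest georeference points",
            stacklevel=2,
        )
        return StepScore(Step.GEOREFERENCE, config.geo_points[-1])
    for i, edge in enumerate(config.geo_bin_edges_m):
        if acc < edge:
            return StepScore(Step.GEOREFERENCE, config.geo_points[i])
    return StepScore(Step.GEOREFERENCE, config.geo_points[-1])


def categorize_total(total: int, config: RubricConfig = DEFAULT_CONFIG) -> Band:
    for name, lo, hi in config.band_edges:
        if lo <= total <= hi:
            return Band(name)
    raise ConfigError(f"total {total} outside the attainable range of the configured bands")


def combine_steps(
    species: StepScore,
    media: StepScore,
    geo: StepScore,
    config: RubricConfig = DEFAULT_CONFIG,
) -> ConfidenceResult:
    """Sum the three step scores, or mark unscorable if any step stopped.

    When several steps stop, the reported reason follows step order
    (species, then media, then georeference).
    """
    steps = {species.step, media.step, geo.step}
    if steps != {Step.SPECIES, Step.MEDIA, Step.GEOREFERENCE}:
        raise ConfigError("combine_steps needs one score from each of the three steps")
    if species.stopped or media.stopped or geo.stopped:
        return ConfidenceResult(species, media, geo, total=None, band=Band.UNSCORABLE)
    total = species.points + media.points + geo.points
    return ConfidenceResult(species, media, geo, total=total, band=categorize_total(total, config))


def score_observation(
    record: ObservationRecord,
    registry: Mapping[str, SpeciesTraits],
    config: RubricConfig = DEFAULT_CONFIG,
) -> ConfidenceResult:
    """Run the full rubric on one record."""
    traits = registry.get(record.species_name)
    if traits is None:
        raise UnregisteredSpeciesError(record.species_name)
    return combine_steps(
        score_species_step(traits, config),
        score_media_step(record.media, config),
        score_georeference_step(record, config),
        config,
    )


def score_set(
    obs: ObservationSet,
    registry: Mapping[str, SpeciesTraits],
    config: RubricConfig = DEFAULT_CONFIG,
) -> "ScoredSet":
    return ScoredSet(obs, [score_observation(rec, registry, config) for rec in obs])


@dataclass
class ScoredSet:
    """An observation set zipped with its per-record confidence results."""

    observations: ObservationSet
    results: list[ConfidenceResult]

    def __post_init__(self) -> None:
        if len(self.observations) != len(self.results):
            raise DataError(
                f"{len(self.observations)} records but {len(self.results)} results"
            )

    def __len__(self) -> int:
        return len(self.results)

    def __iter__(self):
        return iter(zip(self.observations, self.results))


SCORED_EXTRA_COLUMNS = (
    "species_step_points",
    "media_step_points",
    "geo_step_points",
    "total",
    "band",
    "stop_reason",
)


def write_scored(scored: ScoredSet, path) -> None:
    """Write the scored set as CSV: all input columns plus scoring columns.

    Shared columns round-trip losslessly through ``read_observations``;
    unscorable records carry an empty total and a populated stop_reason.
    """
    from .observations import DEFAULT_COLUMNS

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(DEFAULT_COLUMNS) + list(SCORED_EXTRA_COLUMNS))
        for rec, res in scored:
            writer.writerow(
                [
                    rec.record_id,
                    rec.species_name,
                    rec.observed_on or "",
                    _fmt(rec.latitude),
                    _fmt(rec.longitude),
                    _fmt(rec.positional_accuracy_m),
                    rec.media.clarity.value,
                    rec.media.diagnostic_features_shown.value,
                    rec.quality_grade.value,
                    rec.accuracy_label.value if rec.accuracy_label else "",
                    "" if res.species.points is None else res.species.points,
                    "" if res.media.points is None else res.media.points,
                    "" if res.georeference.points is None else res.georeference.points,
                    "" if res.total is None else res.total,
                    res.band.value,
                    res.stop_reason.value if res.stop_reason else "",
                ]
            )


def read_scored(path) -> ScoredSet:
    """Read back a CSV produced by :func:`write_scored`."""
    from .observations import read_observations

    obs, rejected = read_observations(path)
    if rejected:
        raise DataError(
            "scored file contains invalid rows: "
            + "; ".join(f"row {r.row_number}: {r.reason}" for r in rejected)
        )
    results: list[ConfidenceResult] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            band = Band(row["band"])
            stop = StopReason(row["stop_reason"]) if row.get("stop_reason") else None
            def step(col: str, kind: Step, reason: StopReason | None) -> StepScore:
                cell = row.get(col, "")
                if cell == "":
                    return StepScore(kind, None, reason)
                return StepScore(kind, int(cell))
            if band is Band.UNSCORABLE:
                species = step(
                    "species_step_points", Step.SPECIES,
                    stop if stop is StopReason.MOLECULAR_REQUIRED else None,
                )
                media = step(
                    "media_step_points", Step.MEDIA,
                    stop if stop in (StopReason.MEDIA_UNUSABLE, StopReason.FEATURES_NOT_SHOWN) else None,
                )
                geo = step(
                    "geo_step_points", Step.GEOREFERENCE,
                    stop if stop is StopReason.NO_COORDINATES else None,
                )
                results.append(ConfidenceResult(species, media, geo, None, band))
            else:
                results.append(
                    ConfidenceResult(
                        StepScore(Step.SPECIES, int(row["species_step_points"])),
                        StepScore(Step.MEDIA, int(row["media_step_points"])),
                        StepScore(Step.GEOREFERENCE, int(row["geo_step_points"])),
                        int(row["total"]),
                        band,
                    )
                )
    return ScoredSet(obs, results)


def config_to_yaml(cfg: RubricConfig, path) -> None:
    doc = {
        "species_points": {
            f"{vis.value},{'similar' if sim else 'no_similar'}": pts
            for (vis, sim), pts in cfg.species_points.items()
        },
        "media_points": {
            f"{clar.value},{shown.value}": pts for (clar, shown), pts in cfg.media_points.items()
        },
        "geo_bin_edges_m": list(cfg.geo_bin_edges_m),
        "geo_points": list(cfg.geo_points),
        "band_edges": [[name, lo, hi] for name, lo, hi in cfg.band_edges],
        "strict_missing_accuracy": cfg.strict_missing_accuracy,
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def config_from_yaml(path) -> RubricConfig:
    """Load and schema-validate a rubric configuration from YAML."""
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError("rubric config must be a YAML mapping")
    try:
        species = {}
        for key, pts in doc["species_points"].items():
            vis_tok, sim_tok = (t.strip() for t in key.split(","))
            species[(DiagnosticVisibility(vis_tok), sim_tok == "similar")] = int(pts)
        media = {}
        for key, pts in doc["media_points"].items():
            clar_tok, shown_tok = (t.strip() for t in key.split(","))
            media[(MediaClarity(clar_tok), FeaturesShown(shown_tok))] = int(pts)
        return RubricConfig(
            species_points=species,
            media_points=media,
            geo_bin_edges_m=tuple(float(e) for e in doc["geo_bin_edges_m"]),
            geo_points=tuple(int(p) for p in doc["geo_points"]),
            band_edges=tuple((str(n), int(lo), int(hi)) for n, lo, hi in doc["band_edges"]),
            strict_missing_accuracy=bool(doc.get("strict_missing_accuracy", False)),
        )
    except ConfigError:
        raise
    except (KeyError, ValueError, TypeError, AttributeError) as exc:
        raise ConfigError(f"malformed rubric config: {exc}") from exc


def _fmt(value: float | None) -> str:
    # repr is the shortest round-tripping decimal form of a float
    return "" if value is None else repr(value)
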