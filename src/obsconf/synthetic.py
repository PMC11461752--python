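"""Synthetic observation sets with known ground truth.

Two sources of test data, neither requiring any download:

* :func:`generate_dataset` draws observation sets from a latent-quality
  model. A single uniform latent u per record drives every rubric input
  monotonically (better latent quality -> more identifiable species,
  clearer media, tighter accuracy radius), and the expert accuracy label
  follows the confidence band with a tunable mixing weight (``association``)
  against uniform noise. The platform quality grade tracks accuracy only
  weakly (``grade_noise``), emulating the empirical pattern that the
  built-in grade is a poor proxy for accuracy. Stops are injected at a
  tunable rate. Everything is deterministic given the seed.

* :func:`case_study_fixture` rebuilds, record by record, a 957-observation
  set whose confidence-band, accuracy and quality-grade *marginal* counts
  equal the South African marine alien/cryptogenic case study's published
  marginals. The joint cells are a documented deterministic fill (the three
  marginals zipped in ascending rank order, i.e. the comonotonic coupling);
  only the marginals are claimed to match anything real.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .observations import (
    AccuracyLabel,
    DiagnosticVisibility,
    FeaturesShown,
    MediaAssessment,
    MediaClarity,
    ObservationRecord,
    ObservationSet,
    QualityGrade,
    SpeciesTraits,
)
from .rubric import DEFAULT_CONFIG, Band, RubricConfig, ScoredSet, score_observation, score_set


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the latent-quality generator.

    association
        Mixing weight in [-1, 1] between the band-aligned accuracy label and
        uniform noise; 1 is deterministic agreement, 0 independence, negative
        values anti-align.
    stop_rate
        Fraction of records forced into a stop condition (molecular-required
        species, unusable media, features not shown, or missing coordinates,
        in roughly the case study's mix).
    grade_noise
        Probability that a record's quality grade is drawn from a fixed
        marginal instead of following its accuracy label; high values make
        the grade a weak proxy for accuracy.
    """

    n: int = 957
    association: float = 0.85
    stop_rate: float = 0.374
    grade_noise: float = 0.85
    seed: int = 0

    def __post_init__(self) -> None:
        if not (isinstance(self.n, (int, np.integer)) and self.n > 0):
            raise ValueError(f"n must be a positive integer, got {self.n!r}")
        if not -1.0 <= self.association <= 1.0:
            raise ValueError("association must be in [-1, 1]")
        for name in ("stop_rate", "grade_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


# One synthetic species per species-step level, plus the molecular-only one.
_SYNTHETIC_SPECIES = {
    (DiagnosticVisibility.VISIBLE_WITH_DIFFICULTY, True): "Simulatus dubius",
    (DiagnosticVisibility.VISIBLE_WITH_DIFFICULTY, False): "Simulatus obscurus",
    (DiagnosticVisibility.EASY_TO_SEE, True): "Simulatus geminus",
    (DiagnosticVisibility.EASY_TO_SEE, False): "Simulatus facilis",
}
_MOLECULAR_SPECIES = "Simulatus crypticus"


def synthetic_registry() -> dict[str, SpeciesTraits]:
    registry = {
        name: SpeciesTraits(name, vis, similar)
        for (vis, similar), name in _SYNTHETIC_SPECIES.items()
    }
    registry[_MOLECULAR_SPECIES] = SpeciesTraits(
        _MOLECULAR_SPECIES,
        DiagnosticVisibility.REQUIRES_DISSECTION_OR_MOLECULAR,
        True,
        notes="species-level identification requires molecular evidence",
    )
    return registry


# Latent-quality cut points: each input improves monotonically with u.
_SPECIES_CUTS = (0.25, 0.5, 0.75)  # quartiles over the 4 species levels
_MEDIA_LEVELS = (
    (MediaClarity.POOR, FeaturesShown.SOME),
    (MediaClarity.MODERATE, FeaturesShown.MOST),
    (MediaClarity.CLEAR, FeaturesShown.MOST),
    (MediaClarity.CLEAR, FeaturesShown.ALL),
)
_GEO_RADII = (25000.0, 5000.0, 250.0)  # thirds over u, worst to best

_ALIGNED_LABEL = {
    Band.LOW: AccuracyLabel.INCORRECT,
    Band.MEDIUM: AccuracyLabel.UNCERTAIN,
    Band.HIGH: AccuracyLabel.CORRECT,
}
_ANTI_LABEL = {
    Band.LOW: AccuracyLabel.CORRECT,
    Band.MEDIUM: AccuracyLabel.UNCERTAIN,
    Band.HIGH: AccuracyLabel.INCORRECT,
}
_GRADE_FOR_LABEL = {
    AccuracyLabel.CORRECT: QualityGrade.RESEARCH_GRADE,
    AccuracyLabel.UNCERTAIN: QualityGrade.NEEDS_ID,
    AccuracyLabel.INCORRECT: QualityGrade.CASUAL,
}
# Marginal grade mix used for the noise component of grade assignment.
_GRADE_MARGINAL = (
    (QualityGrade.RESEARCH_GRADE, 0.57),
    (QualityGrade.NEEDS_ID, 0.42),
    (QualityGrade.CASUAL, 0.01),
)
# Stop-kind mix: molecular-required taxa dominate, per the case study.
_STOP_KINDS = ("molecular", "media_unusable", "features_not_shown", "no_coordinates")
_STOP_PROBS = (0.55, 0.20, 0.20, 0.05)


@dataclass
class SyntheticDataset:
    observations: ObservationSet  # accuracy_label populated on each record
    registry: dict[str, SpeciesTraits]
    params: GeneratorParams


def _level_index(u: float, cuts: tuple[float, ...]) -> int:
    for i, c in enumerate(cuts):
        if u < c:
            return i
    return len(cuts)


def generate_dataset(
    params: GeneratorParams, config: RubricConfig = DEFAULT_CONFIG
) -> SyntheticDataset:
    """Draw a synthetic observation set from the latent-quality model."""
    rng = np.random.default_rng(params.seed)
    n = params.n
    u = rng.random(n)
    stop_draw = rng.random(n)
    stop_kind = rng.choice(len(_STOP_KINDS), size=n, p=_STOP_PROBS)
    label_mix = rng.random(n)
    label_noise = rng.integers(0, 3, size=n)
    grade_mix = rng.random(n)
    grade_probs = np.array([p for _, p in _GRADE_MARGINAL])
    grade_noise_draw = rng.choice(len(_GRADE_MARGINAL), size=n, p=grade_probs)
    lat = -36.0 + 4.0 * rng.random(n)   # offshore box south of Africa
    lon = 15.0 + 10.0 * rng.random(n)

    registry = synthetic_registry()
    species_levels = list(_SYNTHETIC_SPECIES)  # worst to best

    records: list[ObservationRecord] = []
    labels = list(AccuracyLabel)
    for i in range(n):
        sp_key = species_levels[_level_index(u[i], _SPECIES_CUTS)]
        species = _SYNTHETIC_SPECIES[sp_key]
        clarity, shown = _MEDIA_LEVELS[_level_index(u[i], _SPECIES_CUTS)]
        radius = _GEO_RADII[_level_index(u[i], (1 / 3, 2 / 3))]
        latitude, longitude = float(lat[i]), float(lon[i])

        if stop_draw[i] < params.stop_rate:
            kind = _STOP_KINDS[stop_kind[i]]
            if kind == "molecular":
                species = _MOLECULAR_SPECIES
            elif kind == "media_unusable":
                clarity, shown = MediaClarity.UNUSABLE, FeaturesShown.SOME
            elif kind == "features_not_shown":
                clarity, shown = MediaClarity.MODERATE, FeaturesShown.NONE
            else:
                latitude = longitude = None

        record = ObservationRecord(
            record_id=f"syn-{i:05d}",
            species_name=species,
            observed_on=f"2022-{1 + i % 12:02d}-{1 + i % 28:02d}",
            latitude=latitude,
            longitude=longitude,
            positional_accuracy_m=radius,
            media=MediaAssessment(clarity, shown),
            quality_grade=QualityGrade.NEEDS_ID,  # placeholder, set below
        )
        band = score_observation(record, registry, config).band

        a = params.association
        aligned = _ALIGNED_LABEL if a >= 0 else _ANTI_LABEL
        if label_mix[i] < abs(a):
            if band is Band.UNSCORABLE:
                # An unscorable observation cannot be verified correct
                # either: the expert reads it as uncertain, or incorrect
                # when the underlying latent quality is genuinely poor.
                low_label = aligned[Band.LOW]
                mid_label = aligned[Band.MEDIUM]
                label = low_label if u[i] < 1 / 3 else mid_label
            else:
                label = aligned[band]
        else:
            label = labels[label_noise[i]]

        if grade_mix[i] < params.grade_noise:
            grade = _GRADE_MARGINAL[grade_noise_draw[i]][0]
        else:
            grade = _GRADE_FOR_LABEL[label]

        records.append(
            ObservationRecord(
                record_id=record.record_id,
                species_name=record.species_name,
                observed_on=record.observed_on,
                latitude=record.latitude,
                longitude=record.longitude,
                positional_accuracy_m=record.positional_accuracy_m,
                media=record.media,
                quality_grade=grade,
                accuracy_label=label,
            )
        )

    return SyntheticDataset(
        observations=ObservationSet(records, provenance=f"synthetic(seed={params.seed})"),
        registry=registry,
        params=params,
    )


def write_dataset(dataset: SyntheticDataset, out_dir) -> dict[str, str]:
    """Write observations / registry / truth CSVs in the reader's dialect.

    The observations file omits the accuracy label (it is what an expert
    would add later); the truth file carries it separately.
    """
    import os

    from .observations import DEFAULT_COLUMNS, write_species_registry

    paths = {
        "observations": os.path.join(out_dir, "observations.csv"),
        "registry": os.path.join(out_dir, "registry.csv"),
        "truth": os.path.join(out_dir, "truth.csv"),
    }
    with open(paths["observations"], "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        cols = [c for c in DEFAULT_COLUMNS if c != "accuracy_label"]
        writer.writerow(cols)
        for rec in dataset.observations:
            writer.writerow(
                [
                    rec.record_id,
                    rec.species_name,
                    rec.observed_on or "",
                    "" if rec.latitude is None else repr(rec.latitude),
                    "" if rec.longitude is None else repr(rec.longitude),
                    "" if rec.positional_accuracy_m is None else repr(rec.positional_accuracy_m),
                    rec.media.clarity.value,
                    rec.media.diagnostic_features_shown.value,
                    rec.quality_grade.value,
                ]
            )
    write_species_registry(dataset.registry, paths["registry"])
    with open(paths["truth"], "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["record_id", "accuracy_label"])
        for rec in dataset.observations:
            writer.writerow([rec.record_id, rec.accuracy_label.value])
    return paths


@dataclass(frozen=True)
class CaseStudyMarginals:
    """Published marginal counts of the 957-observation case study."""

    band_counts: Mapping[str, int] = field(
        default_factory=lambda: {"unscorable": 358, "low": 32, "medium": 341, "high": 226}
    )
    accuracy_counts: Mapping[str, int] = field(
        default_factory=lambda: {"incorrect": 126, "uncertain": 333, "correct": 498}
    )
    grade_counts: Mapping[str, int] = field(
        default_factory=lambda: {"casual": 7, "needs_id": 407, "research_grade": 543}
    )
    total: int = 957
    # of the 358 unscorable records, those due to molecular-only taxa
    # (20.6% of all 957 observations, rounded to a whole count)
    molecular_unscorable: int = 197

    def __post_init__(self) -> None:
        for counts in (self.band_counts, self.accuracy_counts, self.grade_counts):
            assert sum(counts.values()) == self.total


CASE_STUDY_MARGINALS = CaseStudyMarginals()


def case_study_registry() -> dict[str, SpeciesTraits]:
    """Example registry rows: real marine alien/cryptogenic species names.

    Trait assignments here serve the fixture's deterministic construction;
    they are illustrative, not a curated trait claim for these taxa beyond
    the molecular-evidence flag.
    """
    entries = [
        SpeciesTraits("Carcinus maenas", DiagnosticVisibility.EASY_TO_SEE, False),
        SpeciesTraits("Watersipora subtorquata", DiagnosticVisibility.VISIBLE_WITH_DIFFICULTY, False),
        SpeciesTraits("Bugulina flabellata", DiagnosticVisibility.VISIBLE_WITH_DIFFICULTY, True),
        SpeciesTraits("Mytilus galloprovincialis", DiagnosticVisibility.EASY_TO_SEE, True),
        SpeciesTraits(
            "Ulva lactuca",
            DiagnosticVisibility.REQUIRES_DISSECTION_OR_MOLECULAR,
            True,
            notes="genetic confirmation required for species-level identification",
        ),
    ]
    return {t.species_name: t for t in entries}


# Per-band record templates: (species, media, accuracy radius) chosen so the
# default rubric reproduces the intended band when scored.
_BAND_TEMPLATES = {
    "high": ("Carcinus maenas", MediaClarity.CLEAR, FeaturesShown.ALL, 250.0),
    "medium": ("Watersipora subtorquata", MediaClarity.CLEAR, FeaturesShown.MOST, 5000.0),
    "low": ("Bugulina flabellata", MediaClarity.POOR, FeaturesShown.SOME, 25000.0),
    "unscorable_molecular": ("Ulva lactuca", MediaClarity.CLEAR, FeaturesShown.ALL, 250.0),
    "unscorable_media": ("Mytilus galloprovincialis", MediaClarity.UNUSABLE, FeaturesShown.SOME, 250.0),
}


def case_study_fixture(
    marginals: CaseStudyMarginals = CASE_STUDY_MARGINALS,
    config: RubricConfig = DEFAULT_CONFIG,
) -> ScoredSet:
    """Deterministically rebuild a scored set with the case study's marginals.

    Construction: expand each of the three marginals into a sequence sorted
    in ascending rank order (unscorable < low < medium < high; incorrect <
    uncertain < correct; casual < needs ID < research grade) and zip the
    three sequences positionally — the comonotonic coupling. Unscorable
    records split into molecular-required and unusable-media stops per the
    published molecular fraction. Rubric inputs per band come from fixed
    templates; the returned results are produced by actually scoring those
    inputs, so the fixture doubles as an end-to-end consistency check.
    """
    bands: list[str] = []
    m = marginals
    bands += ["unscorable_molecular"] * m.molecular_unscorable
    bands += ["unscorable_media"] * (m.band_counts["unscorable"] - m.molecular_unscorable)
    bands += ["low"] * m.band_counts["low"]
    bands += ["medium"] * m.band_counts["medium"]
    bands += ["high"] * m.band_counts["high"]

    labels: list[AccuracyLabel] = (
        [AccuracyLabel.INCORRECT] * m.accuracy_counts["incorrect"]
        + [AccuracyLabel.UNCERTAIN] * m.accuracy_counts["uncertain"]
        + [AccuracyLabel.CORRECT] * m.accuracy_counts["correct"]
    )
    grades: list[QualityGrade] = (
        [QualityGrade.CASUAL] * m.grade_counts["casual"]
        + [QualityGrade.NEEDS_ID] * m.grade_counts["needs_id"]
        + [QualityGrade.RESEARCH_GRADE] * m.grade_counts["research_grade"]
    )

    registry = case_study_registry()
    records: list[ObservationRecord] = []
    for i, (band_key, label, grade) in enumerate(zip(bands, labels, grades)):
        species, clarity, shown, radius = _BAND_TEMPLATES[band_key]
        records.append(
            ObservationRecord(
                record_id=f"cs-{i:04d}",
                species_name=species,
                observed_on="2019-06-15",
                latitude=-34.1,
                longitude=18.45,
                positional_accuracy_m=radius,
                media=MediaAssessment(clarity, shown),
                quality_grade=grade,
                accuracy_label=label,
            )
        )
    obs = ObservationSet(records, provenance="case-study marginal fixture (synthetic joint fill)")
    return score_set(obs, registry, config)
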