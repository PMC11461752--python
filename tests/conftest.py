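import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True)
settings.load_profile("ci")

from obsconf import (
    DiagnosticVisibility,
    FeaturesShown,
    MediaAssessment,
    MediaClarity,
    ObservationRecord,
    ObservationSet,
    QualityGrade,
    SpeciesTraits,
)


@pytest.fixture
def registry():
    traits = [
        SpeciesTraits("Carcinus maenas", DiagnosticVisibility.EASY_TO_SEE, False),
        SpeciesTraits("Mytilus galloprovincialis", DiagnosticVisibility.EASY_TO_SEE, True),
        SpeciesTraits("Watersipora subtorquata", DiagnosticVisibility.VISIBLE_WITH_DIFFICULTY, False),
        SpeciesTraits("Bugulina flabellata", DiagnosticVisibility.VISIBLE_WITH_DIFFICULTY, True),
        SpeciesTraits("Ulva lactuca", DiagnosticVisibility.REQUIRES_DISSECTION_OR_MOLECULAR, True),
    ]
    return {t.species_name: t for t in traits}


def make_record(
    record_id="r1",
    species="Carcinus maenas",
    clarity=MediaClarity.CLEAR,
    shown=FeaturesShown.ALL,
    lat=-34.1,
    lon=18.45,
    accuracy=500.0,
    grade=QualityGrade.RESEARCH_GRADE,
    label=None,
):
    return ObservationRecord(
        record_id=record_id,
        species_name=species,
        observed_on="2022-03-01",
        latitude=lat,
        longitude=lon,
        positional_accuracy_m=accuracy,
        media=MediaAssessment(clarity, shown),
        quality_grade=grade,
        accuracy_label=label,
    )


@pytest.fixture
def small_set():
    return ObservationSet(
        [
            make_record("a", accuracy=500.0),
            make_record("b", species="Watersipora subtorquata", clarity=MediaClarity.MODERATE,
                        shown=FeaturesShown.MOST, accuracy=5000.0),
            make_record("c", species="Ulva lactuca"),
            make_record("d", lat=None, lon=None),
        ],
        provenance="unit test",
    )
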