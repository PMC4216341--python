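import pytest

from ethnokit.reports import AilmentCategoryMap, SpeciesRecord, UseReport
from ethnokit.simulate import CategorySpec, SurveyConfig, generate_survey


def make_report(informant, species, ailment, parts=("root",),
                preparations=("infusion",), routes=("oral",), category=None):
    return UseReport(
        informant_id=informant, species_id=species, ailment=ailment,
        plant_parts=frozenset(parts), preparations=frozenset(preparations),
        routes=frozenset(routes), category=category,
    )


def small_config(seed, concentration=1.0, n_categories=4, pool_size=15,
                 intensity=1.5, n_informants=25, **kwargs):
    categories = tuple(
        CategorySpec(name=f"Category {k + 1}", pool_size=pool_size,
                     intensity=intensity, n_ailments=5)
        for k in range(n_categories)
    )
    defaults = dict(n_species=40, n_families=8)
    defaults.update(kwargs)
    return SurveyConfig(seed=seed, categories=categories,
                        n_informants=n_informants,
                        concentration=concentration, **defaults)


@pytest.fixture
def tiny_reports():
    """Three citations in one category: two informants agree on species A."""
    return [
        make_report("i1", "sA", "cough", category="Respiratory system disorders"),
        make_report("i2", "sA", "cough", category="Respiratory system disorders"),
        make_report("i3", "sB", "asthma", category="Respiratory system disorders"),
    ]


@pytest.fixture
def species_table():
    return {
        "sA": SpeciesRecord("sA", "Alpha officinalis", "Rosaceae", "alpha", "V1"),
        "sB": SpeciesRecord("sB", "Beta vulgaris", "Asteraceae", "beta", "V2"),
    }


@pytest.fixture
def respiratory_map():
    return AilmentCategoryMap(
        mapping={"cough": "Respiratory system disorders",
                 "asthma": "Respiratory system disorders"})


@pytest.fixture(scope="session")
def small_survey():
    return generate_survey(small_config(seed=1234))
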