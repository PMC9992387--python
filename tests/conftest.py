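import pytest

from osteokit.records import Mark, SkeletonTemplate, SpecimenRecord, TemplateElement


def make_record(record_id="r1", unit="U1", taxon="Capra ibex",
                element="femur", codes=(), side="indeterminate",
                age="indeterminate", **kw):
    return SpecimenRecord(
        record_id=record_id, unit=unit, taxon=taxon, element=element,
        portion_codes=frozenset(codes), side=side, age_class=age, **kw)


@pytest.fixture
def simple_template():
    """Two-element caprine-like template: paired femur + lumbar pool."""
    return SkeletonTemplate(
        taxon="Capra ibex",
        elements=(
            TemplateElement("femur", 2, "appendicular", 0.6,
                            utility={"Marrow": 70.0}),
            TemplateElement("lumbar", 6, "axial", 0.3),
        ),
        habitat="mountain", rank="high",
        meat_weight_kg={"J": 10.0, "Ad": 25.0, "S": 22.0, "SAd": 18.0,
                        "F": 2.0},
    )


@pytest.fixture
def mark():
    return Mark
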