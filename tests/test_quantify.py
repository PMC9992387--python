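"""NISP/MNE/MNI/MAU: worked examples, oracle equivalence, monotonicity."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from osteokit.quantify import (
    QuantificationError,
    compute_mau,
    compute_mne,
    compute_mni,
    compute_nisp,
    mne_bruteforce,
    mne_by_element,
    mne_decomposition,
    mni_bruteforce,
)
from osteokit.synth import (
    AssemblageScenario,
    TaxonScenario,
    caprine_template,
    generate_assemblage,
)

from conftest import make_record


# ---------------------------------------------------------------------------
# NISP

def test_nisp_counts_only_identified_records():
    records = (
        [make_record(f"i{k}", taxon="Capra ibex", element="") for k in range(3)]
        + [make_record(f"d{k}", taxon="Cervus elaphus", element="")
           for k in range(2)]
        + [make_record(f"s{k}", taxon="", element="", size_class=3)
           for k in range(2)]
    )
    out = compute_nisp(records, "U1")
    assert {t: v["NISP"] for t, v in out.items()} == {
        "Capra ibex": 3, "Cervus elaphus": 2}


def test_nisp_percentage_uses_identified_subtotal():
    records = [make_record(f"i{k}", taxon="Capra ibex", element="")
               for k in range(136)]
    records += [make_record(f"o{k}", taxon="other", element="")
                for k in range(450 - 136)]
    out = compute_nisp(records, "U1")
    assert out["Capra ibex"]["NISP"] == 136
    assert out["Capra ibex"]["%NISP"] == pytest.approx(30.2, abs=0.05)


def test_nisp_unknown_unit_lists_available():
    records = [make_record("r", unit="A2-A1")]
    with pytest.raises(QuantificationError, match="A2-A1"):
        compute_nisp(records, "D3")


def test_nisp_empty_unit():
    records = [make_record("r", unit="U1", taxon="", element="",
                           size_class=2)]
    assert compute_nisp(records, "U1") == {}


# ---------------------------------------------------------------------------
# MNE worked examples

def test_mne_two_sides_force_two_elements():
    recs = [make_record("L", codes=range(1, 6), side="left"),
            make_record("R", codes=range(1, 6), side="right")]
    assert compute_mne(recs, "Capra ibex", "femur") == 2


def test_mne_disjoint_portions_one_element():
    recs = [make_record("a", codes=(1, 2), side="left"),
            make_record("b", codes=(3, 4), side="left"),
            make_record("c", codes=(5,), side="left")]
    assert compute_mne(recs, "Capra ibex", "femur") == 1


def test_mne_pairwise_overlap_beats_code_repetition():
    # no single code repeats more than twice, yet three elements are needed
    recs = [make_record("a", codes=(1, 2)),
            make_record("b", codes=(2, 3)),
            make_record("c", codes=(1, 3))]
    assert compute_mne(recs, "Capra ibex", "femur") == 3


def test_mne_incompatible_ages_split_elements():
    recs = [make_record("a", codes=(1,), age="Ad"),
            make_record("b", codes=(2,), age="J")]
    assert compute_mne(recs, "Capra ibex", "femur") == 2


def test_mne_indeterminate_side_minimises_total():
    recs = [make_record("L", codes=(1, 2), side="left"),
            make_record("i", codes=(3, 4), side="indeterminate")]
    assert compute_mne(recs, "Capra ibex", "femur") == 1


# ---------------------------------------------------------------------------
# MNE oracle equivalence (exhaustive random fixtures, <= 8 specimens)

def _random_fragment(rng, i):
    n = rng.randint(1, 6)
    return make_record(
        f"f{i}",
        codes=tuple(rng.sample(range(1, 21), n)),
        side=rng.choice(["left", "right", "indeterminate"]),
        age=rng.choice(["Ad", "J", "indeterminate"]),
    )


@pytest.mark.parametrize("seed", range(30))
def test_mne_matches_bruteforce_oracle(seed):
    import random
    rng = random.Random(seed)
    frags = [_random_fragment(rng, i) for i in range(rng.randint(1, 8))]
    assert compute_mne(frags, "Capra ibex", "femur") == mne_bruteforce(frags)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.data())
def test_mne_matches_bruteforce_oracle_hypothesis(data):
    frags = []
    n = data.draw(st.integers(1, 7))
    for i in range(n):
        codes = data.draw(st.sets(st.integers(1, 8), min_size=1, max_size=4))
        side = data.draw(st.sampled_from(["left", "right", "indeterminate"]))
        age = data.draw(st.sampled_from(["Ad", "J", "S", "indeterminate"]))
        frags.append(make_record(f"f{i}", codes=tuple(codes), side=side,
                                 age=age))
    assert compute_mne(frags, "Capra ibex", "femur") == mne_bruteforce(frags)


# ---------------------------------------------------------------------------
# MNI

def test_mni_unbalanced_sides(simple_template):
    recs = [make_record(f"L{i}", codes=(1,), side="left", age="Ad")
            for i in range(3)]
    recs.append(make_record("R", codes=(1,), side="right", age="Ad"))
    mni, breakdown = compute_mni(recs, "Capra ibex", simple_template)
    assert mni == 3
    assert breakdown["Ad"] == 3


def test_mni_incompatible_ages_cannot_pair(simple_template):
    recs = [make_record("L", codes=(1,), side="left", age="Ad"),
            make_record("R", codes=(1,), side="right", age="J")]
    mni, breakdown = compute_mni(recs, "Capra ibex", simple_template)
    assert mni == 2
    assert breakdown["Ad"] == 1 and breakdown["J"] == 1


def test_mni_pooled_axial_element(simple_template):
    # 8 lumbar vertebrae (same repeated portion code, so 8 distinct bones)
    # of one age, 6 per skeleton -> 2 individuals
    recs = [make_record(f"v{i}", element="lumbar", codes=(1,), age="Ad")
            for i in range(8)]
    mni, breakdown = compute_mni(recs, "Capra ibex", simple_template)
    assert mni == 2 and breakdown["Ad"] == 2


@pytest.mark.parametrize("seed", range(20))
def test_mni_matches_bruteforce_oracle(seed, simple_template):
    import random
    rng = random.Random(seed)
    recs = []
    for i in range(rng.randint(1, 6)):
        recs.append(make_record(
            f"e{i}", codes=(1,),
            side=rng.choice(["left", "right", "indeterminate"]),
            age=rng.choice(["Ad", "J", "indeterminate"])))
    instances = mne_decomposition(recs, "Capra ibex", "femur")
    mni, _ = compute_mni(recs, "Capra ibex", simple_template)
    assert mni == mni_bruteforce(instances, 2)


# ---------------------------------------------------------------------------
# MAU

def test_mau_hand_arithmetic(simple_template):
    mau, pct = compute_mau({"femur": 4, "lumbar": 6}, simple_template)
    assert mau == {"femur": 2.0, "lumbar": 1.0}
    assert pct == {"femur": 100.0, "lumbar": 50.0}


def test_mau_single_nonzero_element_is_100(simple_template):
    _, pct = compute_mau({"lumbar": 3}, simple_template)
    assert pct == {"lumbar": 100.0}


def test_mau_missing_element_named(simple_template):
    with pytest.raises(QuantificationError, match="tibia"):
        compute_mau({"tibia": 1}, simple_template)


# ---------------------------------------------------------------------------
# Properties

def test_merging_record_sets_never_decreases_indices(simple_template):
    a = [make_record("a1", codes=(1, 2), side="left", age="Ad"),
         make_record("a2", codes=(1, 2), side="right", age="Ad")]
    b = [make_record("b1", codes=(1, 2), side="left", age="J"),
         make_record("b2", codes=(3,), side="left", age="Ad")]
    for sub in (a, b):
        assert (compute_mne(a + b, "Capra ibex", "femur")
                >= compute_mne(sub, "Capra ibex", "femur"))
        assert (compute_mni(a + b, "Capra ibex", simple_template)[0]
                >= compute_mni(sub, "Capra ibex", simple_template)[0])


def test_lossless_generation_recovers_truth_exactly():
    tpl = caprine_template(8)
    n = 4
    scenario = AssemblageScenario(
        unit="SYN", taxa={tpl.taxon: TaxonScenario(n)}, alpha=0.0, beta=0.0,
        fragmentation=1.0, seed=17)
    records, truth = generate_assemblage(scenario, {tpl.taxon: tpl})
    mne = mne_by_element(records, tpl.taxon)
    assert mne == {e.element: n * e.skeleton_count for e in tpl.elements}
    mni, _ = compute_mni(records, tpl.taxon, tpl)
    assert mni == n == truth["n_individuals"][tpl.taxon]
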