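"""Complex building, specificity classification and breakpoint reuse."""

import pytest

from karyofish.core import CREvent, EventMatrix
from karyofish.comparative import (
    breakpoint_reuse,
    build_complexes,
    classify_specificity,
    count_by_sharing,
    count_polymorphic_types,
    count_species_specific,
    raw_event_types,
    split_label,
)


def matrix(events, materials, grid):
    return EventMatrix(events=events, materials=materials,
                       presence=[[c == "+" for c in row] for row in grid])


TWO_SPECIES = [("S1", "E_sibiricus"), ("S2", "E_sibiricus"),
               ("N1", "E_nutans"), ("N2", "E_nutans")]


@pytest.mark.parametrize("label, expected", [
    ("PeI I", ["PeI I"]),
    ("PeI VI, PeI VII, RT (4Y/5Y)", ["PeI VI", "PeI VII", "RT (4Y/5Y)"]),
    ("PaI I, II", ["PaI I", "PaI II"]),
    ("PaI, RT (4H/3Y)", ["PaI", "RT (4H/3Y)"]),
])
def test_combined_labels_split_into_member_events(label, expected):
    assert split_label(label) == expected


def test_inversion_series_collapses_to_one_complex():
    m = matrix([("1H", "PeI I"), ("1H", "PeI II")], TWO_SPECIES,
               ["++++", "++++"])
    per_material = build_complexes(m)
    for mat in ("S1", "N2"):
        (cx,) = per_material[mat].values()
        assert cx.kind == "inversion_series"
        assert cx.member_events == ("PeI I", "PeI II")


def test_reciprocal_partner_rows_merge():
    m = matrix([("4H", "RT (4H/6H)"), ("6H", "RT (4H/6H)")], TWO_SPECIES,
               ["++--", "++--"])
    (cx,) = build_complexes(m)["S1"].values()
    assert cx.kind == "translocation"
    assert cx.chroms == ("4H", "6H")
    assert build_complexes(m)["N1"] == {}


def test_material_without_events_has_empty_set():
    m = matrix([("1H", "PeI I")], TWO_SPECIES, ["++-+"])
    assert build_complexes(m)["N1"] == {}


def test_uniform_one_species_complexes_are_specific():
    m = matrix([("1H", "PeI I"), ("2St", "De (1H514)")], TWO_SPECIES,
               ["++--", "++--"])
    calls = classify_specificity(m)
    assert count_species_specific(calls, "E_sibiricus") == 2
    assert count_species_specific(calls, "E_nutans") == 0
    assert count_polymorphic_types(m, "E_sibiricus") == 0


def test_shared_uniform_complex_not_specific():
    m = matrix([("1H", "PeI I")], TWO_SPECIES, ["++++"])
    calls = classify_specificity(m)
    assert {c.call for c in calls} == {"uniform_shared"}


def test_same_chromosome_different_series_are_distinct_signatures():
    # series {PeI I} in one species vs {PeI I, PeI II} in the other: both
    # uniform, different identity, hence both species-specific
    m = matrix([("1H", "PeI I"), ("1H", "PeI II")], TWO_SPECIES,
               ["++++", "--++"])
    calls = classify_specificity(m)
    assert count_species_specific(calls, "E_sibiricus") == 1
    assert count_species_specific(calls, "E_nutans") == 1


def test_calls_invariant_to_material_and_row_order(event_matrix):
    base = classify_specificity(event_matrix)
    shuffled = EventMatrix(
        events=list(reversed(event_matrix.events)),
        materials=list(reversed(event_matrix.materials)),
        presence=[list(reversed(r)) for r in reversed(event_matrix.presence)])
    other = classify_specificity(shuffled)
    as_set = lambda calls: {(c.species, c.call, c.complex.signature)
                            for c in calls}
    assert as_set(base) == as_set(other)
    for sp in ("E_sibiricus", "E_nutans"):
        assert (count_polymorphic_types(event_matrix, sp)
                == count_polymorphic_types(shuffled, sp))


def test_outgroup_excluded_from_specificity(event_matrix):
    calls = classify_specificity(event_matrix)
    assert all(c.species != "H_bogdanii" for c in calls)
    # the 1H inversion counts for E. sibiricus although the outgroup shares it
    assert any(c.complex.chroms == ("1H",) and c.species == "E_sibiricus"
               and c.call == "species_specific" for c in calls)


def test_rt_tag_on_single_row_still_one_complex():
    m = matrix([("3H", "RT (3H/6H)")], TWO_SPECIES, ["+---"])
    (cx,) = build_complexes(m)["S1"].values()
    assert cx.kind == "translocation"


def test_sharing_counts_partition_polymorphic_types(event_matrix):
    total = count_polymorphic_types(event_matrix, "E_nutans")
    by_k = [count_by_sharing(event_matrix, "E_nutans", k)
            for k in range(1, 4)]
    assert sum(by_k) == total
    assert by_k == [9, 4, 2]


class TestBreakpointReuse:
    def test_shared_endpoint_counted_per_complex(self):
        inv = lambda c, lo, hi: CREvent("PaI", (c,), ((lo, hi),))
        loci = breakpoint_reuse({"A": [inv("1H", 2, 5)],
                                 "B": [inv("1H", 2, 7)]})
        assert loci[("1", 2)]["count"] == 2
        assert loci[("1", 2)]["reused"]
        assert loci[("1", 5)]["count"] == loci[("1", 7)]["count"] == 1

    def test_distinct_endpoints_all_single(self):
        loci = breakpoint_reuse({
            "A": [CREvent("PaI", ("1H",), ((0, 3),))],
            "B": [CREvent("PaI", ("2H",), ((1, 4),))]})
        assert all(v["count"] == 1 for v in loci.values())

    def test_identical_shared_complexes_deduplicated(self):
        ev = [CREvent("PeI", ("4H",), ((1, 4),), label="PeI I")]
        loci = breakpoint_reuse({"A": ev, "B": ev})
        assert all(v["count"] == 1 for v in loci.values())

    def test_endpoint_conservation(self):
        events = {
            "A": [CREvent("PeI", ("4H",), ((1, 4),), label="PeI I"),
                  CREvent("PaI", ("4H",), ((5, 7),), label="PaI I")],
            "B": [CREvent("PaI", ("2St",), ((0, 2),))],
            "C": [CREvent("RT", ("4H", "6H"), ((6, 9), (0, 2)))],
        }
        loci = breakpoint_reuse(events)
        # complexes: A's 4H series (4 endpoints), B's inversion (2),
        # C's translocation (4) -> 10 endpoint incidences in total
        assert sum(v["count"] for v in loci.values()) == 10
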