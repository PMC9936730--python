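"""Minimal inversion scenarios, event classification and detection."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from oracles import iddfs_min_scenarios
from karyofish.collinearity import CENTROMERE, Permutation, count_breakpoints
from karyofish.inference import (
    apply_scenario,
    classify_inversion,
    detect_copy_number,
    detect_translocations,
    infer_events,
    min_inversion_scenarios,
    reference_sequence,
)
from karyofish.simulate import SimEvent, SimSpec, simulate_karyotype


def make_perm(markers, token_at, ref_slot):
    seq = list(markers)
    seq.insert(token_at, CENTROMERE)
    n = len(markers)
    return Permutation(
        chrom_id="test", group=1, sequence=tuple(seq), ref_slot=ref_slot,
        dense_to_probe=tuple(f"p{i}" for i in range(n)),
        boundary_to_ref=tuple(range(n + 1)))


class TestScenarioSearch:
    def test_identity_needs_no_steps(self):
        perm = make_perm(range(6), 3, 3)
        d, scens = min_inversion_scenarios(perm)
        assert d == 0
        assert scens[0].steps == ()

    def test_single_paracentric_block_swap(self):
        # (0,2,1,3) with the centromere after the last marker
        perm = make_perm((0, 2, 1, 3), 4, 4)
        d, scens = min_inversion_scenarios(perm)
        assert d == 1
        assert len(scens) == 1
        assert scens[0].steps == (((1, 3), "PaI"),)

    def test_single_pericentric_mirrors_markers_across_centromere(self):
        # reference 0 1 2 | 3; markers (1,2) flipped across the token
        perm = make_perm((0, 2, 1, 3), 1, 3)
        d, scens = min_inversion_scenarios(perm)
        assert d == 1
        assert all(len(s) == 1 and s.steps[0][1] == "PeI" for s in scens)

    def test_two_disjoint_reversals_need_two_steps(self):
        # b = 4 forces d >= 2; construction gives d <= 2
        markers = (1, 0, 2, 3, 6, 5, 4, 7)
        perm = make_perm(markers, 8, 8)
        assert count_breakpoints(markers) == 4
        d, scens = min_inversion_scenarios(perm)
        assert d == 2
        assert {tuple(sorted(s.intervals)) for s in scens} == {
            ((0, 2), (4, 7))}

    def test_depth_cap_returns_infinity(self):
        perm = make_perm((3, 6, 0, 5, 2, 7, 1, 4), 0, 0)
        d, scens = min_inversion_scenarios(perm, max_depth=2)
        assert d == math.inf and scens == []

    def test_scenarios_reproduce_observed_order(self):
        perm = make_perm((2, 0, 3, 1), 2, 1)
        d, scens = min_inversion_scenarios(perm)
        start = reference_sequence(perm)
        for s in scens:
            assert apply_scenario(start, s) == perm.sequence

    def test_scenarios_sorted_canonically(self):
        perm = make_perm((1, 0, 3, 2), 4, 4)
        _, scens = min_inversion_scenarios(perm)
        ivs = [s.intervals for s in scens]
        assert ivs == sorted(ivs)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_agrees_with_iterative_deepening_oracle(self, seed):
        import numpy as np
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 8))
        markers = tuple(int(x) for x in rng.permutation(n))
        perm = make_perm(markers, int(rng.integers(0, n + 1)),
                         int(rng.integers(0, n + 1)))
        d, scens = min_inversion_scenarios(perm, max_depth=3)
        d2, ivset = iddfs_min_scenarios(
            reference_sequence(perm), perm.sequence, 3)
        assert d == d2
        assert {s.intervals for s in scens} == ivset

    def test_dmin_bounded_below_by_half_breakpoints(self):
        for markers in [(1, 0, 2), (2, 1, 0, 3), (1, 3, 0, 2), (0, 1, 2)]:
            perm = make_perm(markers, 0, 0)
            d, _ = min_inversion_scenarios(perm, max_depth=4)
            if d != math.inf:
                assert d >= math.ceil(count_breakpoints(markers) / 2)

    def test_reversal_involution(self):
        from karyofish.inference import _reverse
        seq = (0, 1, CENTROMERE, 2, 3)
        assert _reverse(_reverse(seq, 1, 4), 1, 4) == seq


@pytest.mark.parametrize("interval, token_rank, expected", [
    ((1, 4), 2, "PeI"),   # spans the token
    ((3, 6), 2, "PaI"),   # wholly long-arm side
    ((0, 2), 2, "PaI"),   # wholly short-arm side
    ((2, 3), 2, "PeI"),   # token alone inside counts as spanning
])
def test_classify_inversion(interval, token_rank, expected):
    assert classify_inversion(interval, token_rank) == expected


class TestTranslocations:
    def test_reciprocal_exchange_called_once(self, reference, manifest):
        events = {"4H": [SimEvent("rt", partner="6H", k=2, k_partner=1,
                                  end="S")]}
        ky, _ = simulate_karyotype(SimSpec(subgenomes=("St", "H"),
                                           events=events),
                                   reference=reference, manifest=manifest)
        calls = detect_translocations(ky, reference, manifest)
        assert [(c.event_type, c.chroms) for c in calls] == [
            ("RT", ("4H", "6H"))]

    def test_one_way_transfer_called_as_t(self, reference, manifest):
        events = {"4H": [SimEvent("t", partner="3H", k=2, end="L",
                                  partner_end="S")]}
        ky, _ = simulate_karyotype(SimSpec(subgenomes=("H",), events=events),
                                   reference=reference, manifest=manifest)
        calls = detect_translocations(ky, reference, manifest)
        assert [(c.event_type, c.chroms) for c in calls] == [
            ("T", ("4H", "3H"))]

    def test_no_foreign_runs_no_calls(self, reference, manifest):
        ky, _ = simulate_karyotype(SimSpec(subgenomes=("St", "H")),
                                   reference=reference, manifest=manifest)
        assert detect_translocations(ky, reference, manifest) == []

    def test_single_marker_swap_still_reciprocal(self, reference, manifest):
        events = {"4H": [SimEvent("rt", partner="6H", k=1, k_partner=1,
                                  end="S")]}
        ky, _ = simulate_karyotype(SimSpec(subgenomes=("St", "H"),
                                           events=events),
                                   reference=reference, manifest=manifest)
        calls = detect_translocations(ky, reference, manifest)
        assert [c.event_type for c in calls] == ["RT"]


class TestCopyNumber:
    def test_interstitial_foreign_site_is_duplication(self, reference,
                                                      manifest):
        # extra interstitial 2H558 site on 1Y, group-2 homes intact
        events = {"1Y": [SimEvent("du", probe="2H558", at=5, partner="1Y")]}
        ky, _ = simulate_karyotype(
            SimSpec(subgenomes=("St", "H", "Y"), events=events),
            reference=reference, manifest=manifest)
        calls = detect_copy_number(ky, reference, manifest)
        assert [(c.event_type, c.chroms, c.probes) for c in calls] == [
            ("Du", ("1Y",), ("2H558",))]

    def test_distal_missing_probe_with_neighbours_is_deletion(
            self, reference, manifest):
        events = {"1St": [SimEvent("de", probe="1H514")]}
        ky, _ = simulate_karyotype(
            SimSpec(subgenomes=("St", "H", "Y"), events=events),
            reference=reference, manifest=manifest)
        calls = detect_copy_number(ky, reference, manifest)
        assert [(c.event_type, c.chroms, c.probes) for c in calls] == [
            ("De", ("1St",), ("1H514",))]

    def test_complete_karyotype_yields_nothing(self, reference, manifest):
        ky, _ = simulate_karyotype(SimSpec(subgenomes=("St", "H", "Y")),
                                   reference=reference, manifest=manifest)
        assert detect_copy_number(ky, reference, manifest) == []

    def test_translocated_run_not_called_deleted(self, reference, manifest):
        events = {"4H": [SimEvent("t", partner="3H", k=2, end="L",
                                  partner_end="S")]}
        ky, _ = simulate_karyotype(SimSpec(subgenomes=("H",), events=events),
                                   reference=reference, manifest=manifest)
        assert detect_copy_number(ky, reference, manifest) == []


class TestInferEvents:
    def test_collinear_karyotype_yields_no_events(self, reference, manifest):
        ky, _ = simulate_karyotype(SimSpec(subgenomes=("St", "H")),
                                   reference=reference, manifest=manifest)
        events, scenarios = infer_events(ky, reference, manifest)
        assert events == []
        assert all(d == 0 for d, _ in scenarios.values())

    def test_recovers_inversion_and_translocation_jointly(self, reference,
                                                          manifest):
        events = {
            "2H": [SimEvent("inversion", interval=(2, 5))],  # PeI over token
            "4H": [SimEvent("rt", partner="6H", k=2, k_partner=1, end="S")],
        }
        ky, truth = simulate_karyotype(SimSpec(subgenomes=("St", "H"),
                                               events=events),
                                       reference=reference, manifest=manifest)
        inferred, scenarios = infer_events(ky, reference, manifest)
        kinds = sorted((e.event_type, e.chroms) for e in inferred)
        assert kinds == [("PeI", ("2H",)), ("RT", ("4H", "6H"))]
        d, scens = scenarios["2H"]
        assert d == 1
        pei = next(e for e in inferred if e.event_type == "PeI")
        # the inverted block covers reference indices 2..3 (marker 2H170
        # and the adjacent long-arm marker 2H288)
        assert pei.ref_interval == ((2, 4),)
        assert pei.probes == ("2H170", "2H288")
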