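"""Permutation construction and breakpoint counting."""

import pytest
from hypothesis import given, settings, strategies as st

from oracles import enumerate_breakpoints
from karyofish.collinearity import (
    CENTROMERE,
    build_permutation,
    count_breakpoints,
)
from karyofish.core import KaryoValidationError
from karyofish.simulate import SimEvent, SimSpec, simulate_karyotype


def _perms(karyotype, reference, manifest):
    from karyofish.inference import build_permutations
    return build_permutations(karyotype, reference, manifest)


def test_collinear_chromosome_gives_identity(reference, manifest):
    ky, _ = simulate_karyotype(SimSpec(subgenomes=("St", "H")),
                               reference=reference, manifest=manifest)
    perms = _perms(ky, reference, manifest)
    for cid, perm in perms.items():
        assert perm.is_identity(), cid
        assert not perm.foreign_runs and not perm.missing and not perm.extras
        assert count_breakpoints(perm) == 0


def test_terminal_foreign_run_isolated(reference, manifest):
    # distal 4H long-arm segment transferred onto the 3H short arm
    events = {"4H": [SimEvent("t", partner="3H", k=2, end="L",
                              partner_end="S")]}
    ky, _ = simulate_karyotype(
        SimSpec(subgenomes=("H",), events=events, material_id="HB"),
        reference=reference, manifest=manifest)
    perm = _perms(ky, reference, manifest)["3H"]
    assert len(perm.foreign_runs) == 1
    run = perm.foreign_runs[0]
    assert run.terminal
    assert run.source_group == 4
    assert run.source_arm == "L"
    assert run.probe_ids == ("4H530", "4H604")
    # remaining backbone is the full group-3 identity
    assert perm.is_identity()
    assert perm.dense_to_probe == reference[3].ordered_probe_ids


def test_missing_probe_shrinks_and_reranks(reference, manifest):
    events = {"2H": [SimEvent("de", probe="2H288")]}
    ky, _ = simulate_karyotype(SimSpec(subgenomes=("H",), events=events),
                               reference=reference, manifest=manifest)
    perm = _perms(ky, reference, manifest)["2H"]
    assert perm.missing == ("2H288",)
    assert perm.size == len(reference[2]) - 1
    assert perm.markers == tuple(range(perm.size))
    # dense boundaries still address the full reference order
    assert perm.boundary_to_ref[-1] == len(reference[2])


def test_extra_copy_routed_to_extras(reference, manifest):
    events = {"3H": [SimEvent("du", probe="3H448", at=2)]}
    ky, _ = simulate_karyotype(SimSpec(subgenomes=("H",), events=events),
                               reference=reference, manifest=manifest)
    perm = _perms(ky, reference, manifest)["3H"]
    assert [s.probe_id for s in perm.extras] == ["3H448"]
    assert perm.markers == tuple(range(perm.size))


def test_unknown_probe_rejected(reference, manifest):
    ky, _ = simulate_karyotype(SimSpec(subgenomes=("H",)),
                               reference=reference, manifest=manifest)
    chrom = ky.chromosomes["1H"]
    from karyofish.core import ChromosomeMap, MarkerSite
    sites = (MarkerSite("NOPE", 0.01, "S"),) + chrom.sites
    mutated = ChromosomeMap(chrom.chrom_id, chrom.centromere, sites)
    with pytest.raises(KaryoValidationError, match="NOPE"):
        build_permutation(mutated, reference[1], manifest)


def test_build_permutation_idempotent(reference, manifest):
    ky, _ = simulate_karyotype(SimSpec(seed=9, n_inversions=2),
                               reference=reference, manifest=manifest)
    for cid, chrom in ky.chromosomes.items():
        p1 = build_permutation(chrom, reference[chrom.group], manifest)
        p2 = build_permutation(chrom, reference[chrom.group], manifest)
        assert p1 == p2


@pytest.mark.parametrize("sequence, expected", [
    (tuple(range(7)), 0),            # identity
    ((0, 2, 1, 3), 2),               # enumerated: (0,2) and (1,3) break
    ((3, 2, 1, 0), 2),               # full reversal: only sentinels break
    ((1, 0), 2),
])
def test_breakpoint_counts_match_enumeration(sequence, expected):
    assert count_breakpoints(sequence) == expected
    assert enumerate_breakpoints(sequence) == expected


def test_centromere_token_ignored_in_breakpoints():
    assert count_breakpoints((0, CENTROMERE, 1, 2)) == 0
    assert count_breakpoints((0, 2, CENTROMERE, 1, 3)) == 2


@settings(derandomize=True, max_examples=200)
@given(st.permutations(list(range(8))))
def test_breakpoints_invariant_under_reversal_complementation(markers):
    """Reversing the whole sequence and complementing indices preserves
    the framed adjacency structure."""
    n = len(markers)
    mirrored = [n - 1 - x for x in reversed(markers)]
    assert count_breakpoints(tuple(markers)) == count_breakpoints(
        tuple(mirrored)) == enumerate_breakpoints(markers)


@settings(derandomize=True, max_examples=100)
@given(st.integers(0, 2**31 - 1))
def test_single_disjoint_reversal_creates_two_breakpoints(reference,
                                                          manifest, seed):
    ky, truth = simulate_karyotype(
        SimSpec(seed=seed, n_inversions=1, subgenomes=("H",)),
        reference=reference, manifest=manifest)
    (ev,) = truth
    perm = _perms(ky, reference, manifest)[ev.chroms[0]]
    assert count_breakpoints(perm) == 2
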