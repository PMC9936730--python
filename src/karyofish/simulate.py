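"""Synthetic karyotypes and pattern matrices with known ground truth.

The karyotype simulator starts every chromosome as the identity map over
its group's reference order and applies a known event list — inversions
(reversing a marker sub-sequence, carrying the centromere token along for
pericentric ones), reciprocal or one-way terminal translocations,
duplications and deletions — then re-spaces marker positions uniformly on
[0, 1] preserving order.  Because the applied events are returned as
ground truth, every inference stage has a recovery test.

When inversions are *sampled* rather than given explicitly, the default
constraints make their reference intervals pairwise separated by at least
one untouched marker and at least two markers long.  Each such reversal
then creates exactly two fresh breakpoints, so k sampled inversions leave
2k breakpoints and the minimal scenario length is provably exactly k —
the property the recovery tests assert.  With the constraint relaxed,
overlapping reversals may compose into fewer steps, and only d_min <= k
holds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .collinearity import CENTROMERE, Element
from .core import (
    ChromosomeMap,
    CREvent,
    Karyotype,
    KaryoValidationError,
    MarkerSite,
    PatternMatrix,
    ProbeManifest,
    ProbeRecord,
    ReferenceOrder,
    SPECIES_BY_SUBGENOMES,
)


@dataclass
class SimSpec:
    """Recipe for one simulated karyotype.

    ``events`` maps chromosome id -> explicit event list (see
    ``simulate_karyotype``); alternatively ``n_inversions`` samples that
    many inversions on randomly chosen chromosomes.  Defaults emulate the
    observed marker density: 7-10 single-gene markers per chromosome, here
    8 by default with the centromere near the middle.
    """

    seed: int = 0
    subgenomes: tuple[str, ...] = ("St", "H")
    markers_per_group: int = 8
    events: Optional[Mapping[str, Sequence["SimEvent"]]] = None
    n_inversions: int = 0
    breakpoint_disjoint: bool = True
    min_interval: int = 2
    material_id: str = "SIM"

    def __post_init__(self) -> None:
        if frozenset(self.subgenomes) not in SPECIES_BY_SUBGENOMES:
            raise KaryoValidationError(
                f"subgenome set {self.subgenomes} matches no species")
        if self.markers_per_group < 4 or self.markers_per_group > 12:
            raise KaryoValidationError("markers_per_group outside 4..12")


@dataclass(frozen=True)
class SimEvent:
    """One explicit event to apply.

    kind "inversion": ``interval`` is a half-open positional interval over
    the chromosome's current marker+token sequence.  kind "rt": swap
    terminal runs of ``k`` and ``k_partner`` markers with ``partner`` at
    the ``end`` ("S" or "L") of both.  kind "t": move a terminal run of
    ``k`` markers from this chromosome's ``end`` onto ``partner`` (at its
    short-arm end for end "S", long-arm end otherwise).  kind "du": insert
    an extra copy of ``probe`` at marker slot ``at`` (may target another
    chromosome via ``partner``).  kind "de": remove ``probe``.
    """

    kind: str
    interval: Optional[tuple[int, int]] = None
    partner: Optional[str] = None
    k: int = 1
    k_partner: int = 1
    end: str = "S"
    partner_end: Optional[str] = None  # defaults to ``end``
    probe: Optional[str] = None
    at: Optional[int] = None


def default_reference(markers_per_group: int = 8,
                      ) -> tuple[dict[int, ReferenceOrder], ProbeManifest]:
    """Synthetic collinearity standard: ``markers_per_group`` markers per
    group named G<group>M<index>, centromere just left of the middle."""
    reference: dict[int, ReferenceOrder] = {}
    records: list[ProbeRecord] = []
    slot = markers_per_group // 2
    for group in range(1, 8):
        probes = tuple(f"G{group}M{i}" for i in range(markers_per_group))
        reference[group] = ReferenceOrder(group, probes, slot)
        for i, p in enumerate(probes):
            records.append(ProbeRecord(
                probe_id=p, home_group=group,
                home_arm="S" if i < slot else "L",
                reference_index=i))
    return reference, ProbeManifest(records)


class _SimChromosome:
    """Mutable marker+token sequence while events are applied."""

    def __init__(self, chrom_id: str, ref: ReferenceOrder):
        self.chrom_id = chrom_id
        self.seq: list[tuple[str, int]] = [
            (p, 1) for p in ref.ordered_probe_ids]
        self.seq.insert(ref.centromere_slot, (CENTROMERE, 0))

    def token_index(self) -> int:
        return next(i for i, (p, _) in enumerate(self.seq)
                    if p == CENTROMERE)

    def reverse(self, lo: int, hi: int) -> None:
        if not (0 <= lo < hi <= len(self.seq)) or hi - lo < 2:
            raise KaryoValidationError(
                f"{self.chrom_id}: inapplicable inversion interval "
                f"({lo}, {hi})")
        self.seq[lo:hi] = self.seq[lo:hi][::-1]

    def terminal_slice(self, end: str, k: int) -> list[tuple[str, int]]:
        if k >= len(self.seq) - 1:
            raise KaryoValidationError(
                f"{self.chrom_id}: terminal run of {k} markers too long")
        return self.seq[:k] if end == "S" else self.seq[-k:]

    def replace_terminal(self, end: str, k: int,
                         new: list[tuple[str, int]]) -> None:
        if end == "S":
            self.seq[:k] = new
        else:
            self.seq[len(self.seq) - k:] = new


def simulate_karyotype(spec: SimSpec,
                       reference: Optional[Mapping[int, ReferenceOrder]] = None,
                       manifest: Optional[ProbeManifest] = None,
                       ) -> tuple[Karyotype, list[CREvent]]:
    """Build a karyotype from a spec; returns it with the ground truth.

    Fully reproducible: identical specs (including seed) give identical
    karyotypes.  Explicit events are applied in order; an interval out of
    range raises.  Sampled inversions honour the spec constraints.
    """
    if reference is None or manifest is None:
        reference, manifest = default_reference(spec.markers_per_group)
    rng = np.random.default_rng(spec.seed)

    chroms: dict[str, _SimChromosome] = {}
    for group in range(1, 8):
        for sub in spec.subgenomes:
            cid = f"{group}{sub}"
            chroms[cid] = _SimChromosome(cid, reference[group])

    truth: list[CREvent] = []
    if spec.events:
        for cid, evs in spec.events.items():
            for ev in evs:
                truth.extend(_apply_event(chroms, cid, ev, reference))
    if spec.n_inversions:
        truth.extend(_sample_inversions(chroms, spec, rng))

    karyotype = Karyotype(
        material_id=spec.material_id,
        chromosomes={cid: _materialise(sc) for cid, sc in chroms.items()})
    return karyotype, truth


def _apply_event(chroms: Mapping[str, _SimChromosome], cid: str,
                 ev: SimEvent,
                 reference: Mapping[int, ReferenceOrder]) -> list[CREvent]:
    sc = chroms[cid]
    if ev.kind == "inversion":
        if ev.interval is None:
            raise KaryoValidationError("inversion event needs an interval")
        lo, hi = ev.interval
        token = sc.token_index()
        kind = "PeI" if lo <= token < hi else "PaI"
        probes = tuple(p for p, _ in sc.seq[lo:hi] if p != CENTROMERE)
        sc.reverse(lo, hi)
        return [CREvent(event_type=kind, chroms=(cid,),
                        ref_interval=((lo, hi),), probes=probes)]
    if ev.kind == "rt":
        if ev.partner is None:
            raise KaryoValidationError("rt event needs a partner")
        other = chroms[ev.partner]
        a = sc.terminal_slice(ev.end, ev.k)
        b = other.terminal_slice(ev.end, ev.k_partner)
        sc.replace_terminal(ev.end, ev.k, b)
        other.replace_terminal(ev.end, ev.k_partner, a)
        pair = tuple(sorted((cid, ev.partner)))
        return [CREvent(event_type="RT", chroms=pair,
                        probes=tuple(p for p, _ in a + b),
                        label=f"RT ({pair[0]}/{pair[1]})")]
    if ev.kind == "t":
        if ev.partner is None:
            raise KaryoValidationError("t event needs a partner")
        other = chroms[ev.partner]
        run = sc.terminal_slice(ev.end, ev.k)
        sc.replace_terminal(ev.end, ev.k, [])
        if (ev.partner_end or ev.end) == "S":
            other.seq[:0] = run
        else:
            other.seq.extend(run)
        return [CREvent(event_type="T", chroms=(cid, ev.partner),
                        probes=tuple(p for p, _ in run),
                        label=f"T ({cid})")]
    if ev.kind == "du":
        if ev.probe is None or ev.at is None:
            raise KaryoValidationError("du event needs probe and at")
        target = chroms[ev.partner] if ev.partner else sc
        copies = sum(1 for p, _ in target.seq if p == ev.probe)
        if not 0 <= ev.at <= len(target.seq):
            raise KaryoValidationError(
                f"du insertion slot {ev.at} out of range")
        target.seq.insert(ev.at, (ev.probe, copies + 1))
        tcid = ev.partner or cid
        return [CREvent(event_type="Du", chroms=(tcid,),
                        probes=(ev.probe,), label=f"Du ({ev.probe})")]
    if ev.kind == "de":
        if ev.probe is None:
            raise KaryoValidationError("de event needs a probe")
        idx = [i for i, (p, _) in enumerate(sc.seq) if p == ev.probe]
        if not idx:
            raise KaryoValidationError(
                f"{cid}: cannot delete absent probe {ev.probe}")
        del sc.seq[idx[-1]]
        return [CREvent(event_type="De", chroms=(cid,),
                        probes=(ev.probe,), label=f"De ({ev.probe})")]
    raise KaryoValidationError(f"unknown simulated event kind {ev.kind!r}")


def _sample_inversions(chroms: Mapping[str, _SimChromosome], spec: SimSpec,
                       rng: np.random.Generator) -> list[CREvent]:
    """Sample ``n_inversions`` inversions on one random chromosome.

    Under the breakpoint-disjoint constraint, intervals are drawn over the
    marker sequence so that they are pairwise separated by at least one
    marker and never touch the token-only case; each covers
    >= min_interval markers.
    """
    cid = str(rng.choice(sorted(chroms)))
    sc = chroms[cid]
    m = len(sc.seq)
    events: list[CREvent] = []
    if spec.breakpoint_disjoint:
        # choose disjoint, separated marker intervals on the reference
        n = m - 1  # marker count
        placed: list[tuple[int, int]] = []
        for _restart in range(200):
            placed = []
            for _try in range(100):
                if len(placed) == spec.n_inversions:
                    break
                length = int(rng.integers(spec.min_interval,
                                          max(spec.min_interval, n // 2) + 1))
                lo = int(rng.integers(0, n - length + 1))
                hi = lo + length
                # at least one untouched marker between intervals
                if all(hi <= plo - 1 or lo >= phi + 1
                       for plo, phi in placed):
                    placed.append((lo, hi))
            if len(placed) == spec.n_inversions:
                break
        else:
            raise KaryoValidationError(
                "cannot place breakpoint-disjoint inversions; "
                "reduce n_inversions or enlarge markers_per_group")
        # apply in random order, translating marker intervals to current
        # positional intervals (disjoint => marker order outside intact)
        for lo, hi in placed:
            probes_in = {p for p, _ in _marker_slice(sc, lo, hi)}
            pos = [i for i, (p, _) in enumerate(sc.seq) if p in probes_in]
            plo, phi = min(pos), max(pos) + 1
            token = sc.token_index()
            kind = "PeI" if plo <= token < phi else "PaI"
            sc.reverse(plo, phi)
            events.append(CREvent(
                event_type=kind, chroms=(cid,), ref_interval=((lo, hi),),
                probes=tuple(sorted(probes_in))))
    else:
        for _ in range(spec.n_inversions):
            hi = 0
            lo = 0
            while hi - lo < 2:
                lo = int(rng.integers(0, m - 1))
                hi = int(rng.integers(lo + 2, m + 1))
            token = sc.token_index()
            kind = "PeI" if lo <= token < hi else "PaI"
            probes = tuple(p for p, _ in sc.seq[lo:hi] if p != CENTROMERE)
            sc.reverse(lo, hi)
            events.append(CREvent(
                event_type=kind, chroms=(cid,), ref_interval=((lo, hi),),
                probes=probes))
    return events


def _marker_slice(sc: _SimChromosome, lo: int, hi: int
                  ) -> list[tuple[str, int]]:
    markers = [(p, c) for p, c in sc.seq if p != CENTROMERE]
    return markers[lo:hi]


def _materialise(sc: _SimChromosome) -> ChromosomeMap:
    """Re-space markers uniformly in [0, 1] preserving order; the
    centromere lands midway between its flanking markers."""
    markers = [(p, c) for p, c in sc.seq if p != CENTROMERE]
    m = len(markers)
    token = sc.token_index()
    centromere = (token + 0.5) / (m + 1)
    sites = []
    for i, (p, c) in enumerate(markers):
        pos = (i + 1) / (m + 1)
        sites.append(MarkerSite(
            probe_id=p, position=pos,
            arm="S" if pos < centromere else "L", copy_index=c))
    return ChromosomeMap(chrom_id=sc.chrom_id, centromere=centromere,
                         sites=tuple(sites))


# ---------------------------------------------------------------------------
# pattern matrices
# ---------------------------------------------------------------------------

def simulate_pattern_matrix(seed: int, materials: Sequence[str],
                            chromosomes: Sequence[str],
                            n_variant_cells: int,
                            n_primed: int = 0,
                            species: str = "E_sibiricus",
                            ) -> tuple[PatternMatrix, dict]:
    """Letter grid with known distinct-pattern counts per column.

    Every cell starts as the base pattern 'a'; ``n_variant_cells`` cells
    (at most one fewer than the material count per column, so the base
    letter always survives) receive a fresh letter, ``n_primed`` of those
    additionally a prime.  The expected per-column summary is built from
    the construction plan, independent of the finished grid, and returned
    as the oracle: ``{"variants": {chrom: n}, "primed": {chrom: n},
    "total": n, "primed_total": n}``.
    """
    n_rows, n_cols = len(materials), len(chromosomes)
    per_col_cap = n_rows - 1
    if n_variant_cells > per_col_cap * n_cols:
        raise KaryoValidationError(
            f"cannot place {n_variant_cells} variant cells in a "
            f"{n_rows}x{n_cols} grid keeping the base pattern")
    if not 0 <= n_primed <= n_variant_cells:
        raise KaryoValidationError("n_primed must not exceed n_variant_cells")
    rng = np.random.default_rng(seed)

    cells: list[list[tuple[str, bool]]] = [
        [("a", False)] * n_cols for _ in range(n_rows)]
    free = [(i, j) for j in range(n_cols) for i in range(1, n_rows)]
    order = rng.permutation(len(free))
    chosen: list[tuple[int, int]] = []
    used_per_col: dict[int, int] = {}
    for idx in order:
        if len(chosen) == n_variant_cells:
            break
        i, j = free[idx]
        if used_per_col.get(j, 0) >= per_col_cap or used_per_col.get(j, 0) >= 25:
            continue
        used_per_col[j] = used_per_col.get(j, 0) + 1
        chosen.append((i, j))
    if len(chosen) < n_variant_cells:
        raise KaryoValidationError("could not place all variant cells")

    letters_used: dict[int, int] = {}
    primed_cells = set(map(tuple, rng.permutation(chosen)[:n_primed].tolist())) \
        if n_primed else set()
    expected_var = {c: 1 for c in chromosomes}
    expected_primed = {c: 0 for c in chromosomes}
    for i, j in chosen:
        nxt = letters_used.get(j, 0) + 1
        letters_used[j] = nxt
        letter = chr(ord("a") + nxt)  # fresh letter per column
        primed = (i, j) in primed_cells
        cells[i][j] = (letter, primed)
        expected_var[chromosomes[j]] += 1
        if primed:
            expected_primed[chromosomes[j]] += 1

    matrix = PatternMatrix(
        materials=[(m, species) for m in materials],
        chromosomes=list(chromosomes),
        cells=cells)
    expected = {
        "variants": expected_var,
        "primed": expected_primed,
        "total": sum(expected_var.values()),
        "primed_total": sum(expected_primed.values()),
    }
    return matrix, expected
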