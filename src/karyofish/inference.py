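"""Rearrangement inference: minimal inversion scenarios, pericentric vs.
paracentric classification, translocation and copy-number calls.

The inversion model is unsigned sorting-by-reversals with a centromere
constraint: single-gene FISH reports marker position but not orientation,
so a chromosome's backbone is an unsigned permutation carrying a centromere
token.  A reversal acts on any contiguous interval of the token-bearing
sequence; a step whose interval spans the token is pericentric (PeI, the
centromere changes flank and arm ratios shift), otherwise paracentric
(PaI).  The search is exact: a breadth-first expansion over reversals from
the reference order to the observed order, returning the minimal depth and
*all* minimal scenarios.  A scenario of length d exists only if
d >= ceil(b/2) where b is the unsigned breakpoint count, since one reversal
can repair at most two breakpoints; this admissible bound is used to prune
states that cannot reach the target within the remaining depth, which
leaves the result set unchanged.
"""

from __future__ import annotations

import math
from typing import Mapping, Optional, Sequence, Union

from .collinearity import (
    CENTROMERE,
    Element,
    ForeignRun,
    Permutation,
    build_permutation,
    count_breakpoints,
)
from .core import (
    CREvent,
    ChromosomeMap,
    Karyotype,
    KaryoValidationError,
    ProbeManifest,
    ReferenceOrder,
    Scenario,
)

INFINITE = math.inf

_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]


def classify_inversion(interval: tuple[int, int], token_rank: int) -> str:
    """``"PeI"`` iff the half-open interval contains the centromere token."""
    lo, hi = interval
    return "PeI" if lo <= token_rank < hi else "PaI"


def _reverse(seq: tuple[Element, ...], lo: int, hi: int) -> tuple[Element, ...]:
    return seq[:lo] + seq[lo:hi][::-1] + seq[hi:]


def apply_scenario(reference: Sequence[Element],
                   scenario: Scenario) -> tuple[Element, ...]:
    """Apply a scenario's reversals in order to a reference sequence."""
    seq = tuple(reference)
    for (lo, hi), _ in scenario.steps:
        seq = _reverse(seq, lo, hi)
    return seq


def reference_sequence(perm: Permutation) -> tuple[Element, ...]:
    """The reference-order sequence the observed one is compared against:
    dense identity with the centromere token at the reference slot."""
    seq: list[Element] = list(range(perm.size))
    seq.insert(perm.ref_slot, CENTROMERE)
    return tuple(seq)


def _breakpoints_vs(seq: tuple[Element, ...],
                    target_pos: dict[int, int], k: int) -> int:
    """Breakpoints of ``seq`` relative to the target's marker order."""
    markers = [target_pos[x] for x in seq if x != CENTROMERE]
    framed = [-1] + markers + [k]
    return sum(1 for a, b in zip(framed, framed[1:]) if abs(a - b) != 1)


def min_inversion_scenarios(perm: Permutation, max_depth: int = 4
                            ) -> tuple[float, list[Scenario]]:
    """Search for all minimal reversal scenarios reference -> observed.

    Returns ``(d_min, scenarios)`` with scenarios sorted lexicographically
    by interval list; ``(inf, [])`` when no scenario of length <= max_depth
    exists.  Valid reversal intervals cover >= 2 sequence elements, i.e.
    two markers or one marker plus the centromere token.
    """
    markers = perm.markers
    if sorted(markers) != list(range(perm.size)):
        raise KaryoValidationError(
            f"{perm.chrom_id}: backbone is not a permutation of "
            f"0..{perm.size - 1}")

    start = reference_sequence(perm)
    target = perm.sequence
    if start == target:
        return 0, [Scenario()]

    k = perm.size
    target_pos = {x: i for i, x in enumerate(markers)}
    m = len(start)
    intervals = [(lo, hi) for lo in range(m) for hi in range(lo + 2, m + 1)]

    lb0 = math.ceil(_breakpoints_vs(start, target_pos, k) / 2)
    if lb0 > max_depth:
        return INFINITE, []

    # level-synchronised BFS; parents[state] -> [(previous state, interval)]
    frontier: dict[tuple[Element, ...], None] = {start: None}
    parents: dict[tuple[Element, ...], list] = {start: []}
    depth_of = {start: 0}
    found_at: Optional[int] = None
    for depth in range(1, max_depth + 1):
        if found_at is not None:
            break
        nxt: dict[tuple[Element, ...], None] = {}
        budget = max_depth - depth
        for state in frontier:
            for lo, hi in intervals:
                child = _reverse(state, lo, hi)
                d_child = depth_of.get(child)
                if d_child is not None and d_child < depth:
                    continue  # reached earlier: not on a shortest path here
                if d_child is None:
                    if child != target and (
                            math.ceil(_breakpoints_vs(child, target_pos, k) / 2)
                            > budget):
                        continue  # cannot reach the target in time
                    depth_of[child] = depth
                    parents[child] = []
                    nxt[child] = None
                parents[child].append((state, (lo, hi)))
        if target in nxt:
            found_at = depth
        frontier = nxt
        if not frontier:
            break
    if found_at is None:
        return INFINITE, []

    # enumerate all shortest paths through the parent DAG
    paths: list[tuple[tuple[int, int], ...]] = []

    def walk(state: tuple[Element, ...], acc: list) -> None:
        if state == start:
            paths.append(tuple(reversed(acc)))
            return
        for prev, interval in parents[state]:
            acc.append(interval)
            walk(prev, acc)
            acc.pop()

    walk(target, [])
    scenarios = []
    for ivs in sorted(set(paths)):
        seq = start
        steps = []
        for lo, hi in ivs:
            token_rank = seq.index(CENTROMERE)
            steps.append(((lo, hi), classify_inversion((lo, hi), token_rank)))
            seq = _reverse(seq, lo, hi)
        assert seq == target
        scenarios.append(Scenario(steps=tuple(steps)))
    return float(found_at), scenarios


# ---------------------------------------------------------------------------
# translocations
# ---------------------------------------------------------------------------

def _home_vacant(karyotype: Karyotype, manifest: ProbeManifest,
                 probe_id: str) -> bool:
    """True when some home chromosome of the probe lacks its copy (each
    chromosome of a home group is expected to carry one site)."""
    for rec in manifest.records(probe_id):
        for chrom in karyotype.chromosomes_of_group(rec.home_group):
            if all(s.probe_id != probe_id for s in chrom.sites):
                return True
    return False


def _translocation_runs(perm: Permutation, karyotype: Karyotype,
                        manifest: ProbeManifest) -> list[ForeignRun]:
    """Terminal foreign runs that qualify as translocation signal: any run
    of >= 2 probes, or a single-probe run whose home site is vacant."""
    out = []
    for run in perm.foreign_runs:
        if not run.terminal:
            continue
        if len(run.probe_ids) >= 2 or any(
                _home_vacant(karyotype, manifest, p) for p in run.probe_ids):
            out.append(run)
    return out


def detect_translocations(karyotype: Karyotype,
                          reference: Mapping[int, ReferenceOrder],
                          manifest: ProbeManifest,
                          perms: Optional[Mapping[str, Permutation]] = None,
                          ) -> list[CREvent]:
    """Call reciprocal (RT) and simple (T) translocations from terminal
    foreign runs.

    For a terminal run on chromosome A sourced from group g: if some
    chromosome B of group g carries a terminal run sourced from A's group,
    the two runs are a reciprocal exchange, emitted once as RT with the
    pair sorted lexicographically; otherwise the run is a one-way transfer
    T(source -> A).  Interstitial runs are left to the copy-number caller.
    """
    if perms is None:
        perms = build_permutations(karyotype, reference, manifest)
    trans: dict[str, list[ForeignRun]] = {
        cid: _translocation_runs(perms[cid], karyotype, manifest)
        for cid in perms}

    events: list[CREvent] = []
    used: set[tuple[str, int]] = set()  # (chrom, start_rank) consumed runs
    for a in sorted(trans):
        for run in trans[a]:
            if (a, run.start_rank) in used:
                continue
            partner: Optional[tuple[str, ForeignRun]] = None
            for b in sorted(trans):
                if b == a:
                    continue
                if perms[b].group != run.source_group:
                    continue
                for brun in trans[b]:
                    if (b, brun.start_rank) in used:
                        continue
                    if brun.source_group == perms[a].group:
                        partner = (b, brun)
                        break
                if partner:
                    break
            if partner is not None:
                b, brun = partner
                used.add((a, run.start_rank))
                used.add((b, brun.start_rank))
                pair = tuple(sorted((a, b)))
                probes = (run.probe_ids + brun.probe_ids
                          if pair[0] == a else brun.probe_ids + run.probe_ids)
                events.append(CREvent(
                    event_type="RT", chroms=pair, probes=probes,
                    label=f"RT ({pair[0]}/{pair[1]})"))
            else:
                used.add((a, run.start_rank))
                donor = _find_donor(karyotype, run)
                events.append(CREvent(
                    event_type="T", chroms=(donor, a), probes=run.probe_ids,
                    label=f"T ({donor})"))
    return events


def _find_donor(karyotype: Karyotype, run: ForeignRun) -> str:
    """The source-group chromosome most depleted of the run's probes; ties
    break lexicographically."""
    candidates = sorted(
        c.chrom_id for c in karyotype.chromosomes_of_group(run.source_group))
    if not candidates:
        return f"{run.source_group}?"

    def n_absent(cid: str) -> int:
        held = set(karyotype.chromosomes[cid].probe_ids)
        return sum(1 for p in run.probe_ids if p not in held)

    # max() keeps the first of equally depleted candidates: lexicographic tie-break
    return max(candidates, key=n_absent)


# ---------------------------------------------------------------------------
# duplications / deletions
# ---------------------------------------------------------------------------

def detect_copy_number(karyotype: Karyotype,
                       reference: Mapping[int, ReferenceOrder],
                       manifest: ProbeManifest,
                       perms: Optional[Mapping[str, Permutation]] = None,
                       ) -> list[CREvent]:
    """Call duplication-and-insertion (Du) and deletion (De) events.

    Du: a probe observed beyond its expected per-subgenome complement — an
    extra own-group copy, an interstitial foreign site, or a single-probe
    terminal foreign site whose home complement is intact.  De: an expected
    own-group probe absent while its two nearest reference neighbours are
    present on the chromosome (guarding against truncated maps), and the
    probe's copy has not merely moved elsewhere in the karyotype.
    """
    if perms is None:
        perms = build_permutations(karyotype, reference, manifest)
    events: list[CREvent] = []
    for cid in sorted(perms):
        perm = perms[cid]
        ref = reference[perm.group]
        # extra own-group copies
        for site in perm.extras:
            events.append(CREvent(
                event_type="Du", chroms=(cid,), probes=(site.probe_id,),
                ref_interval=((ref.index_of(site.probe_id),
                               ref.index_of(site.probe_id) + 1),),
                label=f"Du ({site.probe_id})"))
        # foreign sites that are not translocation signal
        for run in perm.foreign_runs:
            is_trans = run.terminal and (
                len(run.probe_ids) >= 2 or any(
                    _home_vacant(karyotype, manifest, p)
                    for p in run.probe_ids))
            if is_trans:
                continue
            for p in run.probe_ids:
                events.append(CREvent(
                    event_type="Du", chroms=(cid,), probes=(p,),
                    label=f"Du ({p})"))
        # deletions
        chrom = karyotype.chromosomes[cid]
        held = {s.probe_id for s in chrom.sites}
        for probe in perm.missing:
            if _moved_not_lost(karyotype, manifest, probe, perm.group):
                continue
            idx = ref.index_of(probe)
            neighbours = sorted(
                (p for p in ref.ordered_probe_ids if p != probe),
                key=lambda p: abs(ref.index_of(p) - idx))[:2]
            if len(neighbours) >= 2 and all(p in held for p in neighbours):
                events.append(CREvent(
                    event_type="De", chroms=(cid,), probes=(probe,),
                    ref_interval=((idx, idx + 1),),
                    label=f"De ({probe})"))
    return events


def _moved_not_lost(karyotype: Karyotype, manifest: ProbeManifest,
                    probe_id: str, group: int) -> bool:
    """True when the karyotype still holds the full complement of the probe
    (its copy sits elsewhere, e.g. in a translocated run), so absence from
    one chromosome is not a deletion."""
    n_sub = len({c.subgenome for c in karyotype.chromosomes.values()})
    expected = manifest.complement(probe_id) * n_sub
    return karyotype.site_count(probe_id) >= expected


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def build_permutations(karyotype: Karyotype,
                       reference: Mapping[int, ReferenceOrder],
                       manifest: ProbeManifest) -> dict[str, Permutation]:
    return {
        cid: build_permutation(chrom, reference[chrom.group], manifest)
        for cid, chrom in karyotype.chromosomes.items()}


def infer_events(karyotype: Karyotype,
                 reference: Mapping[int, ReferenceOrder],
                 manifest: ProbeManifest,
                 max_depth: int = 4,
                 ) -> tuple[list[CREvent], dict[str, tuple[float, list[Scenario]]]]:
    """Full per-karyotype inference.

    Foreign runs are excised first (translocation calls), copy-number
    events are called next, and the residual own-group permutation of each
    chromosome is searched for minimal inversion scenarios.  The canonical
    (lexicographically first) scenario names the inversion events — one
    CREvent per step, labelled "PeI I", "PaI I", ... per chromosome — while
    the full minimal scenario set is returned alongside.
    """
    perms = build_permutations(karyotype, reference, manifest)
    events = detect_translocations(karyotype, reference, manifest, perms)
    events += detect_copy_number(karyotype, reference, manifest, perms)

    scenarios: dict[str, tuple[float, list[Scenario]]] = {}
    for cid in sorted(perms):
        d_min, found = min_inversion_scenarios(perms[cid], max_depth=max_depth)
        scenarios[cid] = (d_min, found)
        if not found or d_min == 0:
            continue
        canonical = found[0]
        counters = {"PeI": 0, "PaI": 0}
        seq = reference_sequence(perms[cid])
        for (lo, hi), kind in canonical.steps:
            counters[kind] += 1
            # reference span of the inverted segment: dense marker values
            # inside the interval, mapped back to full-reference boundaries
            inner = [x for x in seq[lo:hi] if x != CENTROMERE]
            probes = tuple(perms[cid].dense_to_probe[x] for x in sorted(inner))
            ref_lo = perms[cid].boundary_to_ref[min(inner)] if inner else lo
            ref_hi = (perms[cid].boundary_to_ref[max(inner) + 1]
                      if inner else hi)
            events.append(CREvent(
                event_type=kind, chroms=(cid,),
                ref_interval=((ref_lo, ref_hi),),
                probes=probes,
                label=f"{kind} {_ROMAN[counters[kind] - 1]}"))
            seq = _reverse(seq, lo, hi)
    return events, scenarios
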