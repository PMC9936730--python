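"""Observed chromosome -> permutation over the reference collinearity order.

A chromosome map is reduced to an unsigned permutation of its group's
reference indices with a distinguished centromere token ``CENTROMERE``
inserted at the observed centromere's rank.  Foreign-group runs (the raw
signal of translocations), missing probes and extra copies are separated
out first, so inversion inference downstream sees only the own-group
single-copy backbone — mirroring how the source maps are read: inversions
from own-group probe order, translocations from cross-group signals.

Missing probes shrink the reference index set, which is re-ranked densely
so the backbone is always a permutation of ``0..k-1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from .core import (
    ChromosomeMap,
    KaryoValidationError,
    MarkerSite,
    ProbeManifest,
    ReferenceOrder,
)

#: centromere token used inside permutation sequences
CENTROMERE = "C"

Element = Union[int, str]


@dataclass(frozen=True)
class ForeignRun:
    """A maximal run of sites whose home group differs from the chromosome's.

    ``terminal`` is true when the run touches either end of the map —
    terminal runs are translocation candidates, interstitial ones are
    duplication candidates.
    """

    probe_ids: tuple[str, ...]
    source_group: int
    source_arm: str
    terminal: bool
    start_rank: int  # rank of the run's first site among all sites


@dataclass
class Permutation:
    """Own-group backbone of a chromosome relative to its reference order.

    ``sequence`` holds dense reference indices (0..k-1) in observed order
    with the centromere token at the observed centromere's rank;
    ``ref_slot`` is the token's slot in the reference (dense coordinates).
    ``dense_to_probe`` maps dense index -> probe id; ``boundary_to_ref``
    maps a dense boundary (0..k) back to the boundary in the full
    reference order, so breakpoint loci stay comparable across materials
    with different missing sets.
    """

    chrom_id: str
    group: int
    sequence: tuple[Element, ...]
    ref_slot: int
    dense_to_probe: tuple[str, ...]
    boundary_to_ref: tuple[int, ...]
    foreign_runs: tuple[ForeignRun, ...] = ()
    missing: tuple[str, ...] = ()
    extras: tuple[MarkerSite, ...] = ()

    @property
    def markers(self) -> tuple[int, ...]:
        """The sequence without the centromere token."""
        return tuple(x for x in self.sequence if x != CENTROMERE)

    @property
    def size(self) -> int:
        return len(self.dense_to_probe)

    def is_identity(self) -> bool:
        return self.markers == tuple(range(self.size)) and (
            self.sequence.index(CENTROMERE) == self.ref_slot)


def build_permutation(chrom: ChromosomeMap, ref: ReferenceOrder,
                      manifest: ProbeManifest) -> Permutation:
    """Reduce one observed chromosome to a Permutation.

    Deterministic: sites are processed in (strictly increasing) position
    order.  Raises on probes absent from the manifest or a group mismatch.
    """
    if chrom.group != ref.group:
        raise KaryoValidationError(
            f"{chrom.chrom_id}: chromosome group {chrom.group} does not "
            f"match reference group {ref.group}")

    own_sites: list[tuple[int, MarkerSite]] = []   # (rank, site)
    foreign: list[tuple[int, MarkerSite, int, str]] = []  # rank, site, group, arm
    for rank, site in enumerate(chrom.sites):
        if site.probe_id not in manifest:
            raise KaryoValidationError(
                f"{chrom.chrom_id}: probe {site.probe_id!r} not in manifest")
        rec = manifest.record_in_group(site.probe_id, chrom.group)
        if rec is not None:
            own_sites.append((rank, site))
        else:
            # a probe may have several homes; attribute the run to its
            # first booked home
            home = manifest.records(site.probe_id)[0]
            foreign.append((rank, site, home.home_group, home.home_arm))

    # maximal runs of rank-consecutive foreign sites from one source group
    runs: list[ForeignRun] = []
    i = 0
    n_sites = len(chrom.sites)
    while i < len(foreign):
        j = i
        while (j + 1 < len(foreign)
               and foreign[j + 1][0] == foreign[j][0] + 1
               and foreign[j + 1][2] == foreign[i][2]):
            j += 1
        ranks = [foreign[k][0] for k in range(i, j + 1)]
        terminal = ranks[0] == 0 or ranks[-1] == n_sites - 1
        runs.append(ForeignRun(
            probe_ids=tuple(foreign[k][1].probe_id for k in range(i, j + 1)),
            source_group=foreign[i][2],
            source_arm=foreign[i][3],
            terminal=terminal,
            start_rank=ranks[0],
        ))
        i = j + 1

    # extra copies: for each own-group probe keep the lowest copy index in
    # the backbone, route the rest to extras
    placed: dict[str, MarkerSite] = {}
    extras: list[MarkerSite] = []
    for _, site in own_sites:
        prev = placed.get(site.probe_id)
        if prev is None:
            placed[site.probe_id] = site
        elif site.copy_index < prev.copy_index:
            extras.append(prev)
            placed[site.probe_id] = site
        else:
            extras.append(site)

    present = [p for p in ref.ordered_probe_ids if p in placed]
    missing = tuple(p for p in ref.ordered_probe_ids if p not in placed)
    dense_index = {p: i for i, p in enumerate(present)}
    orig_index = {p: ref.index_of(p) for p in present}

    # dense boundary b lies before the b-th present probe; express it as a
    # boundary of the full reference order
    boundary_to_ref = tuple(
        [orig_index[p] for p in present] + [len(ref)]) if present else (0,)

    ordered = sorted(placed.values(), key=lambda s: s.position)
    seq: list[Element] = [dense_index[s.probe_id] for s in ordered]
    cent_rank = sum(1 for s in ordered if s.position < chrom.centromere)
    seq.insert(cent_rank, CENTROMERE)

    ref_slot = sum(1 for p in present
                   if ref.index_of(p) < ref.centromere_slot)

    return Permutation(
        chrom_id=chrom.chrom_id,
        group=chrom.group,
        sequence=tuple(seq),
        ref_slot=ref_slot,
        dense_to_probe=tuple(present),
        boundary_to_ref=boundary_to_ref,
        foreign_runs=tuple(runs),
        missing=missing,
        extras=tuple(extras),
    )


def count_breakpoints(perm: Union[Permutation, Sequence[Element]]) -> int:
    """Number of reference adjacencies disrupted in the observed order.

    The centromere token is ignored; sentinel values frame the ends, so a
    sequence of k markers yields k+1 framed pairs and the count lies in
    [0, k+1].  A pair (i, j) is an intact adjacency iff |i - j| == 1.
    """
    seq = perm.sequence if isinstance(perm, Permutation) else perm
    markers = [x for x in seq if x != CENTROMERE]
    if not markers:
        raise KaryoValidationError("empty marker sequence")
    framed = [-1] + markers + [len(markers)]
    return sum(1 for a, b in zip(framed, framed[1:]) if abs(a - b) != 1)


def breakpoint_pairs(perm: Union[Permutation, Sequence[Element]]
                     ) -> set[frozenset[int]]:
    """The disrupted reference-adjacent pairs themselves (with -1 and k as
    telomere sentinels), for reuse analysis and tests."""
    seq = perm.sequence if isinstance(perm, Permutation) else perm
    markers = [x for x in seq if x != CENTROMERE]
    framed = [-1] + markers + [len(markers)]
    return {frozenset((a, b)) for a, b in zip(framed, framed[1:])
            if abs(a - b) != 1}
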