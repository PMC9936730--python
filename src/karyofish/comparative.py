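"""Cross-material and cross-species accounting of rearrangements.

Two counting granularities coexist, deliberately:

* **Complexes** drive species-specificity.  All inversion events on one
  chromosome in one material collapse into a single inversion series
  (a chromosome rearranged by several successive inversions is one
  rearrangement), reciprocal-translocation partner rows merge into one
  complex, and each Du/De stands alone.  A complex signature is
  species-specific for species X iff it is identical across all materials
  of X and is not identical-and-uniform across the other species'
  materials.  The diploid H-genome outgroup (H. bogdanii) is excluded
  from the comparison.
* **Raw event types** (chromosome + event label, with reciprocal partner
  rows deduplicated by their "(A/B)" tag) drive polymorphic-type
  accounting, because co-located polymorphic events on one chromosome
  count separately there.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .core import CREvent, EventMatrix, KaryoValidationError, ReferenceOrder

OUTGROUP = "H_bogdanii"

_INVERSION = ("PeI", "PaI")
_TRANS = ("RT", "T")


@dataclass(frozen=True)
class CRComplex:
    """A counting unit of rearrangement: an inversion series on one
    chromosome, a (reciprocal) translocation, or one copy-number event."""

    kind: str  # "inversion_series" | "translocation" | "copy_number"
    chroms: tuple[str, ...]
    member_events: tuple[str, ...]

    @property
    def signature(self) -> tuple:
        return (self.kind, self.chroms, self.member_events)


@dataclass(frozen=True)
class SpecificityCall:
    complex: CRComplex
    species: str
    call: str  # "species_specific" | "polymorphic" | "uniform_shared"


def _event_type(label: str) -> str:
    return label.split()[0] if label.split() else label


def split_label(label: str) -> list[str]:
    """Split a combined row label into member event labels.

    ``"PeI VI, PeI VII, RT (4Y/5Y)"`` -> three events; a bare series token
    (``"PaI I, II"``) inherits the preceding event type.
    """
    out: list[str] = []
    prev_type: Optional[str] = None
    for part in (p.strip() for p in label.split(",")):
        if not part:
            continue
        head = part.split()[0]
        if head in ("PeI", "PaI", "RT", "T", "Du", "De"):
            prev_type = head
            out.append(part)
        else:
            if prev_type is None:
                raise KaryoValidationError(
                    f"cannot parse event label {label!r}")
            out.append(f"{prev_type} {part}")
    return out


def _raw_type_key(chrom: str, member_label: str) -> tuple:
    """Identity of a raw event type; RT/T rows are keyed by their partner
    tag so the two sides of a reciprocal exchange merge."""
    etype = _event_type(member_label)
    if etype in _TRANS and "(" in member_label:
        return (etype, member_label[member_label.find("("):])
    return (chrom, member_label)


def raw_event_types(matrix: EventMatrix) -> dict[tuple, set[str]]:
    """Map raw event type -> set of materials carrying it."""
    out: dict[tuple, set[str]] = {}
    for (chrom, label), row in zip(matrix.events, matrix.presence):
        for member in split_label(label):
            key = _raw_type_key(chrom, member)
            mats = out.setdefault(key, set())
            mats.update(m for (m, _), p in zip(matrix.materials, row) if p)
    return out


def build_complexes(matrix: EventMatrix) -> dict[str, dict[tuple, CRComplex]]:
    """Per-material complex sets keyed by signature.

    An RT tag appearing on a single chromosome row still forms one
    translocation complex (treated as a simple translocation).
    """
    per_material: dict[str, dict[tuple, CRComplex]] = {
        m: {} for m, _ in matrix.materials}
    inv: dict[str, dict[str, list[str]]] = {m: {} for m, _ in matrix.materials}
    for (chrom, label), row in zip(matrix.events, matrix.presence):
        for member in split_label(label):
            etype = _event_type(member)
            for (mat, _), present in zip(matrix.materials, row):
                if not present:
                    continue
                if etype in _INVERSION:
                    inv[mat].setdefault(chrom, []).append(member)
                elif etype in _TRANS:
                    tag = (member[member.find("("):]
                           if "(" in member else member)
                    # merge partner rows: key ignores the row chromosome
                    key = ("translocation", etype, tag)
                    prev = per_material[mat].get(key)
                    chroms = tuple(sorted(set(
                        (prev.chroms if prev else ()) + (chrom,))))
                    per_material[mat][key] = CRComplex(
                        "translocation", chroms, (f"{etype} {tag}",))
                else:
                    cx = CRComplex("copy_number", (chrom,), (member,))
                    per_material[mat][cx.signature] = cx
    for mat, by_chrom in inv.items():
        for chrom, members in by_chrom.items():
            cx = CRComplex("inversion_series", (chrom,),
                           tuple(sorted(members)))
            per_material[mat][cx.signature] = cx
    return per_material


def _comparison_signature(key: tuple, cx: CRComplex) -> tuple:
    """Signature used for cross-material identity.  Translocations compare
    by their tag only (partner-row bookkeeping may differ), everything
    else by full signature."""
    if cx.kind == "translocation":
        return ("translocation",) + tuple(cx.member_events)
    return cx.signature


def classify_specificity(matrix: EventMatrix) -> list[SpecificityCall]:
    """Classify every complex signature per Elymus species.

    Requires at least two non-outgroup species in the matrix; the diploid
    outgroup is excluded from the comparison.
    """
    species = [sp for sp in matrix.species() if sp != OUTGROUP]
    if len(species) < 2:
        raise KaryoValidationError(
            "specificity comparison needs at least two Elymus species")
    per_material = build_complexes(matrix)
    mats_of = {sp: matrix.materials_of_species(sp) for sp in species}
    sig_sets = {
        m: {_comparison_signature(k, cx): cx
            for k, cx in per_material[m].items()}
        for m in per_material}

    calls: list[SpecificityCall] = []
    for sp in species:
        mats = mats_of[sp]
        others = [o for o in species if o != sp]
        seen: dict[tuple, CRComplex] = {}
        for m in mats:
            seen.update(sig_sets[m])
        for sig in sorted(seen, key=repr):
            n = sum(1 for m in mats if sig in sig_sets[m])
            if n == len(mats):
                uniform_elsewhere = any(
                    all(sig in sig_sets[m] for m in mats_of[o])
                    for o in others)
                call = "uniform_shared" if uniform_elsewhere else "species_specific"
            else:
                call = "polymorphic"
            calls.append(SpecificityCall(seen[sig], sp, call))
    return calls


def count_species_specific(calls: Sequence[SpecificityCall],
                           species: str) -> int:
    return sum(1 for c in calls
               if c.species == species and c.call == "species_specific")


def count_polymorphic_types(matrix: EventMatrix, species: str) -> int:
    """Number of distinct raw event types present in some but not all
    materials of the species."""
    return len(_polymorphic_types(matrix, species))


def count_by_sharing(matrix: EventMatrix, species: str, k: int) -> int:
    """Number of polymorphic raw event types present in exactly k of the
    species' materials."""
    return sum(1 for mats in _polymorphic_types(matrix, species).values()
               if len(mats) == k)


def _polymorphic_types(matrix: EventMatrix,
                       species: str) -> dict[tuple, set[str]]:
    mats = set(matrix.materials_of_species(species))
    if not mats:
        raise KaryoValidationError(f"no materials of species {species!r}")
    out = {}
    for key, carriers in raw_event_types(matrix).items():
        mine = carriers & mats
        if 0 < len(mine) < len(mats):
            out[key] = mine
    return out


# ---------------------------------------------------------------------------
# breakpoint reuse
# ---------------------------------------------------------------------------

def _event_endpoints(ev: CREvent) -> list[tuple[str, int]]:
    """Breakpoint loci touched by one event, as (chrom_or_group, boundary)
    pairs; an interval [lo, hi) breaks the boundaries lo and hi."""
    out = []
    for chrom, (lo, hi) in zip(ev.chroms, ev.ref_interval):
        group = chrom[0] if chrom else chrom
        out.append((group, lo))
        out.append((group, hi))
    return out


def breakpoint_reuse(events_by_material: Mapping[str, Sequence[CREvent]],
                     reference: Optional[Mapping[int, ReferenceOrder]] = None,
                     ) -> dict[tuple[str, int], dict]:
    """Tally how many distinct rearrangement complexes break each locus.

    A locus is the open interval between two reference-adjacent probes
    (boundary b of group g lies before the b-th reference probe; b = 0 and
    b = n are the telomere gaps).  Events are grouped into complexes first
    (inversion series per material and chromosome; other events stand
    alone) and identical complexes shared across materials are counted
    once — reuse means *independent* origins hitting one interval, not one
    inherited event observed repeatedly.  Loci with count >= 2 are flagged
    reused.
    """
    complexes: dict[tuple, set[tuple[str, int]]] = {}
    for material, events in events_by_material.items():
        series: dict[tuple, list[CREvent]] = {}
        for ev in events:
            if not ev.ref_interval:
                continue
            if ev.event_type in _INVERSION:
                series.setdefault(("inv", ev.chroms), []).append(ev)
            else:
                sig = (ev.event_type, ev.chroms, ev.ref_interval)
                complexes.setdefault(sig, set()).update(_event_endpoints(ev))
        for (_, chroms), members in series.items():
            sig = ("inv", chroms, tuple(sorted(
                (m.label, m.ref_interval) for m in members)))
            pts = complexes.setdefault(sig, set())
            for m in members:
                pts.update(_event_endpoints(m))

    loci: dict[tuple[str, int], dict] = {}
    for sig, endpoints in complexes.items():
        for locus in endpoints:
            entry = loci.setdefault(
                locus, {"count": 0, "complexes": [], "reused": False})
            entry["count"] += 1
            entry["complexes"].append(sig)
    for locus, entry in loci.items():
        entry["complexes"].sort(key=repr)
        entry["reused"] = entry["count"] >= 2
        if reference is not None:
            group = int(locus[0])
            ref = reference.get(group)
            if ref is not None:
                b = locus[1]
                left = ref.ordered_probe_ids[b - 1] if b > 0 else "telomere"
                right = (ref.ordered_probe_ids[b]
                         if b < len(ref) else "telomere")
                entry["between"] = (left, right)
    return loci
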