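"""Domain types, coordinate conventions and TSV readers/writers.

Coordinate conventions used throughout the package:

* Marker positions are fractions of the chromosome length in ``[0, 1]``
  measured from the short-arm telomere.  Only the *order* of markers (and
  their side of the centromere) carries information — FISH gives relative
  placement, not base pairs — so positions are used for sorting and arm
  assignment only.
* Reference indices are 0-based; intervals are half-open ``[lo, hi)``.
* A chromosome id is the homoeologous group digit followed by the
  subgenome symbol, e.g. ``"4H"``, ``"2St"``, ``"5Y"``.

All files are UTF-8, tab-separated; lines starting with ``#`` are comments.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Union

SUBGENOMES = ("St", "H", "Y")
EVENT_TYPES = ("PeI", "PaI", "RT", "T", "Du", "De")

#: species are identified by the subgenome complement of their karyotype
SPECIES_BY_SUBGENOMES = {
    frozenset({"H"}): "H_bogdanii",
    frozenset({"St", "H"}): "E_sibiricus",
    frozenset({"St", "H", "Y"}): "E_nutans",
}
SUBGENOMES_BY_SPECIES = {v: set(k) for k, v in SPECIES_BY_SUBGENOMES.items()}

_CHROM_RE = re.compile(r"^([1-7])(St|H|Y)$")


class KaryoFormatError(ValueError):
    """A file does not follow the expected TSV dialect."""


class KaryoValidationError(ValueError):
    """A file parses but violates a domain invariant."""


def parse_chrom_id(chrom_id: str) -> tuple[int, str]:
    """Split a chromosome id like ``"2St"`` into ``(group, subgenome)``."""
    m = _CHROM_RE.match(chrom_id)
    if not m:
        raise KaryoValidationError(f"malformed chromosome id {chrom_id!r}")
    return int(m.group(1)), m.group(2)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbeRecord:
    """One legitimate hybridisation site of a single-gene probe.

    Probes with two legitimate sites (``multi_site``, e.g. 7H244 which maps
    to both group 7 short arm and group 5 long arm) appear as one record per
    site; all other probe ids are unique in a manifest.
    """

    probe_id: str
    home_group: int
    home_arm: str  # "S" | "L"
    reference_index: int
    multi_site: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.home_group <= 7:
            raise KaryoValidationError(
                f"probe {self.probe_id}: group {self.home_group} outside 1-7")
        if self.home_arm not in ("S", "L"):
            raise KaryoValidationError(
                f"probe {self.probe_id}: arm must be S or L")
        if self.reference_index < 0:
            raise KaryoValidationError(
                f"probe {self.probe_id}: negative reference index")


class ProbeManifest:
    """Lookup table of probe records, keyed by (probe_id, home_group)."""

    def __init__(self, records: Iterable[ProbeRecord]):
        self._by_probe: dict[str, list[ProbeRecord]] = {}
        self._by_key: dict[tuple[str, int], ProbeRecord] = {}
        for rec in records:
            key = (rec.probe_id, rec.home_group)
            if key in self._by_key:
                raise KaryoValidationError(
                    f"duplicate manifest record for {rec.probe_id} in group "
                    f"{rec.home_group}")
            sibs = self._by_probe.setdefault(rec.probe_id, [])
            if sibs and not (rec.multi_site and all(s.multi_site for s in sibs)):
                raise KaryoValidationError(
                    f"probe {rec.probe_id} has several records but is not "
                    "flagged multi_site")
            sibs.append(rec)
            self._by_key[key] = rec

    def __contains__(self, probe_id: str) -> bool:
        return probe_id in self._by_probe

    def __len__(self) -> int:
        return len(self._by_key)

    def __iter__(self) -> Iterator[ProbeRecord]:
        return iter(self._by_key.values())

    @property
    def probe_ids(self) -> list[str]:
        return list(self._by_probe)

    def records(self, probe_id: str) -> tuple[ProbeRecord, ...]:
        try:
            return tuple(self._by_probe[probe_id])
        except KeyError:
            raise KaryoValidationError(f"unknown probe {probe_id!r}") from None

    def record_in_group(self, probe_id: str, group: int) -> Optional[ProbeRecord]:
        return self._by_key.get((probe_id, group))

    def home_groups(self, probe_id: str) -> tuple[int, ...]:
        return tuple(r.home_group for r in self.records(probe_id))

    def complement(self, probe_id: str) -> int:
        """Expected number of sites per subgenome (1, or 2 for true
        multi-site probes with two booked homes)."""
        return len(self.records(probe_id))


@dataclass
class ReferenceOrder:
    """Collinearity standard for one homoeologous group: ordered probe ids
    with the centromere at a slot between (or flanking) probes."""

    group: int
    ordered_probe_ids: tuple[str, ...]
    centromere_slot: int

    def __post_init__(self) -> None:
        self.ordered_probe_ids = tuple(self.ordered_probe_ids)
        if len(set(self.ordered_probe_ids)) != len(self.ordered_probe_ids):
            raise KaryoValidationError(
                f"group {self.group}: duplicate probe in reference order")
        if not 0 <= self.centromere_slot <= len(self.ordered_probe_ids):
            raise KaryoValidationError(
                f"group {self.group}: centromere slot outside [0, n]")

    def index_of(self, probe_id: str) -> int:
        return self.ordered_probe_ids.index(probe_id)

    def __len__(self) -> int:
        return len(self.ordered_probe_ids)


@dataclass(frozen=True)
class MarkerSite:
    """An observed probe site on one chromosome."""

    probe_id: str
    position: float  # fraction of chromosome length from short-arm telomere
    arm: str  # "S" | "L", derived from position vs. centromere
    copy_index: int = 1


@dataclass
class ChromosomeMap:
    """One observed chromosome: ordered marker sites plus centromere."""

    chrom_id: str
    centromere: float
    sites: tuple[MarkerSite, ...]

    def __post_init__(self) -> None:
        self.sites = tuple(self.sites)
        group, sub = parse_chrom_id(self.chrom_id)
        self.group = group
        self.subgenome = sub
        if not 0.0 < self.centromere < 1.0:
            raise KaryoValidationError(
                f"{self.chrom_id}: centromere {self.centromere} outside (0,1)")
        pos = [s.position for s in self.sites]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise KaryoValidationError(
                f"{self.chrom_id}: site positions not strictly increasing")
        for s in self.sites:
            expected = "S" if s.position < self.centromere else "L"
            if s.arm != expected:
                raise KaryoValidationError(
                    f"{self.chrom_id}: site {s.probe_id} arm {s.arm} "
                    f"inconsistent with position {s.position}")

    @property
    def probe_ids(self) -> tuple[str, ...]:
        return tuple(s.probe_id for s in self.sites)


@dataclass
class Karyotype:
    """All chromosomes observed in one plant material."""

    material_id: str
    chromosomes: dict[str, ChromosomeMap]
    species: str = ""

    def __post_init__(self) -> None:
        subs = frozenset(c.subgenome for c in self.chromosomes.values())
        derived = SPECIES_BY_SUBGENOMES.get(subs)
        if not self.species:
            if derived is None:
                raise KaryoValidationError(
                    f"{self.material_id}: subgenome set {set(subs)} matches "
                    "no known species")
            self.species = derived
        else:
            expect = SUBGENOMES_BY_SPECIES.get(self.species)
            if expect is None:
                raise KaryoValidationError(
                    f"unknown species tag {self.species!r}")
            if subs and set(subs) != expect:
                raise KaryoValidationError(
                    f"{self.material_id}: {self.species} karyotype must hold "
                    f"subgenomes {expect}, found {set(subs)}")

    def chromosomes_of_group(self, group: int) -> list[ChromosomeMap]:
        return [c for c in self.chromosomes.values() if c.group == group]

    def site_count(self, probe_id: str) -> int:
        return sum(
            1 for c in self.chromosomes.values()
            for s in c.sites if s.probe_id == probe_id)


@dataclass(frozen=True)
class CREvent:
    """A typed chromosomal rearrangement.

    ``chroms`` holds one chromosome id for inversions/Du/De and an ordered
    pair for translocations (RT pairs sorted lexicographically; simple
    translocations as (source, target)).  ``ref_interval`` gives one
    half-open index interval per involved chromosome, in the coordinates of
    the marker sequence the event acted on.
    """

    event_type: str
    chroms: tuple[str, ...]
    ref_interval: tuple[tuple[int, int], ...] = ()
    probes: tuple[str, ...] = ()
    label: str = ""

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise KaryoValidationError(
                f"unknown event type {self.event_type!r}")
        if self.event_type == "RT" and len(self.chroms) != 2:
            raise KaryoValidationError("RT must involve exactly two chromosomes")
        if self.event_type in ("PeI", "PaI", "Du", "De") and len(self.chroms) != 1:
            raise KaryoValidationError(
                f"{self.event_type} must involve exactly one chromosome")


@dataclass
class EventMatrix:
    """Presence/absence of rearrangement events across materials.

    ``annotations`` keeps the superscript marks of the source table (``'``
    species-specific claim, ``''`` possibly ancestral) for cross-checking
    only; they play no role in any computation.
    """

    events: list[tuple[str, str]]          # (chrom, label) per row
    materials: list[tuple[str, str]]       # (material_id, species) per column
    presence: list[list[bool]]
    annotations: list[list[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.presence) != len(self.events) or any(
                len(r) != len(self.materials) for r in self.presence):
            raise KaryoValidationError("event grid dimensions do not match")

    def materials_of_species(self, species: str) -> list[str]:
        return [m for m, sp in self.materials if sp == species]

    def species(self) -> list[str]:
        seen: list[str] = []
        for _, sp in self.materials:
            if sp not in seen:
                seen.append(sp)
        return seen

    def materials_with(self, chrom: str, label: str) -> set[str]:
        i = self.events.index((chrom, label))
        return {m for (m, _), p in zip(self.materials, self.presence[i]) if p}


@dataclass
class PatternMatrix:
    """Repeat-FISH pattern codes per material x chromosome.

    A cell is ``(letter, primed)`` — the same letter marks the same repeat
    pattern within a column; the prime flags a co-occurring polymorphic
    rearrangement — or ``None`` where the species lacks that subgenome.
    """

    materials: list[tuple[str, str]]
    chromosomes: list[str]
    cells: list[list[Optional[tuple[str, bool]]]]

    def __post_init__(self) -> None:
        if len(self.cells) != len(self.materials) or any(
                len(r) != len(self.chromosomes) for r in self.cells):
            raise KaryoValidationError("pattern grid dimensions do not match")
        for row in self.cells:
            for cell in row:
                if cell is not None and not (
                        len(cell[0]) == 1 and cell[0].islower()):
                    raise KaryoValidationError(
                        f"pattern letter {cell!r} not a single a-z letter")

    def restrict(self, species: str) -> "PatternMatrix":
        """Sub-matrix of one species' materials, dropping chromosomes the
        species does not carry."""
        rows = [i for i, (_, sp) in enumerate(self.materials) if sp == species]
        if not rows:
            raise KaryoValidationError(f"no materials of species {species!r}")
        keep = [j for j in range(len(self.chromosomes))
                if any(self.cells[i][j] is not None for i in rows)]
        return PatternMatrix(
            materials=[self.materials[i] for i in rows],
            chromosomes=[self.chromosomes[j] for j in keep],
            cells=[[self.cells[i][j] for j in keep] for i in rows],
        )


@dataclass(frozen=True)
class Scenario:
    """An ordered list of reversals transforming the reference marker
    sequence (with its centromere token) into the observed one.

    Each step is ``((lo, hi), kind)`` with a half-open positional interval
    over the sequence *at the time the step is applied* and kind ``"PeI"``
    (interval spans the centromere token) or ``"PaI"``.
    """

    steps: tuple[tuple[tuple[int, int], str], ...] = ()

    @property
    def intervals(self) -> tuple[tuple[int, int], ...]:
        return tuple(iv for iv, _ in self.steps)

    def __len__(self) -> int:
        return len(self.steps)


# ---------------------------------------------------------------------------
# TSV plumbing
# ---------------------------------------------------------------------------

def _data_lines(path: Union[str, Path]) -> Iterator[tuple[int, list[str]]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


def _header(path: Union[str, Path], expected: Sequence[str]) -> Iterator[tuple[int, list[str]]]:
    rows = _data_lines(path)
    try:
        lineno, cols = next(rows)
    except StopIteration:
        raise KaryoFormatError(f"{path}: no records") from None
    if [c.strip() for c in cols[:len(expected)]] != list(expected):
        raise KaryoFormatError(
            f"{path}:{lineno}: expected header starting with "
            f"{list(expected)}, found {cols}")
    return rows


def read_karyotype(path: Union[str, Path]) -> Karyotype:
    """Read one material's marker map.

    Columns: material, chrom, centromere, probe, position, copy.  Sites are
    sorted by position and arms derived from position vs. centromere.
    """
    rows = _header(path, ["material", "chrom", "centromere", "probe",
                          "position", "copy"])
    material: Optional[str] = None
    centromeres: dict[str, float] = {}
    sites: dict[str, list[tuple[float, str, int]]] = {}
    seen: set[tuple[str, str, int]] = set()
    count = 0
    for lineno, cols in rows:
        if len(cols) < 6:
            raise KaryoFormatError(f"{path}:{lineno}: expected 6 columns")
        mat, chrom, cent_s, probe, pos_s, copy_s = (c.strip() for c in cols[:6])
        if material is None:
            material = mat
        elif mat != material:
            raise KaryoFormatError(
                f"{path}:{lineno}: several materials in one map file "
                f"({material!r} and {mat!r})")
        try:
            cent = float(cent_s)
            pos = float(pos_s)
            copy = int(copy_s)
        except ValueError as exc:
            raise KaryoFormatError(f"{path}:{lineno}: {exc}") from None
        if not 0.0 <= pos <= 1.0:
            raise KaryoValidationError(
                f"{path}:{lineno}: position {pos} outside [0,1]")
        key = (chrom, probe, copy)
        if key in seen:
            raise KaryoFormatError(
                f"{path}:{lineno}: duplicate (chrom, probe, copy) {key}")
        seen.add(key)
        prev = centromeres.setdefault(chrom, cent)
        if prev != cent:
            raise KaryoFormatError(
                f"{path}:{lineno}: conflicting centromere for {chrom}")
        sites.setdefault(chrom, []).append((pos, probe, copy))
        count += 1
    if count == 0 or material is None:
        raise KaryoFormatError(f"{path}: no records")
    chromosomes = {}
    for chrom, entries in sites.items():
        cent = centromeres[chrom]
        entries.sort()
        chromosomes[chrom] = ChromosomeMap(
            chrom_id=chrom,
            centromere=cent,
            sites=tuple(
                MarkerSite(probe_id=p, position=pos,
                           arm="S" if pos < cent else "L", copy_index=c)
                for pos, p, c in entries),
        )
    return Karyotype(material_id=material, chromosomes=chromosomes)


def write_karyotype(karyotype: Karyotype, path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("material\tchrom\tcentromere\tprobe\tposition\tcopy\n")
        for chrom_id in sorted(karyotype.chromosomes):
            cm = karyotype.chromosomes[chrom_id]
            for s in cm.sites:
                fh.write(f"{karyotype.material_id}\t{chrom_id}\t"
                         f"{cm.centromere!r}\t{s.probe_id}\t"
                         f"{s.position!r}\t{s.copy_index}\n")


def read_reference(path: Union[str, Path]) -> dict[int, ReferenceOrder]:
    """Read the collinearity standard: one row per homoeologous group with
    columns group, centromere_slot, probes (comma-separated, in order)."""
    rows = _header(path, ["group", "centromere_slot", "probes"])
    out: dict[int, ReferenceOrder] = {}
    for lineno, cols in rows:
        if len(cols) < 3:
            raise KaryoFormatError(f"{path}:{lineno}: expected 3 columns")
        try:
            group = int(cols[0])
            slot = int(cols[1])
        except ValueError as exc:
            raise KaryoFormatError(f"{path}:{lineno}: {exc}") from None
        probes = tuple(p.strip() for p in cols[2].split(",") if p.strip())
        if group in out:
            raise KaryoFormatError(f"{path}:{lineno}: duplicate group {group}")
        out[group] = ReferenceOrder(group, probes, slot)
    if not out:
        raise KaryoFormatError(f"{path}: no records")
    return out


def write_reference(reference: Mapping[int, ReferenceOrder],
                    path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("group\tcentromere_slot\tprobes\n")
        for group in sorted(reference):
            ref = reference[group]
            fh.write(f"{group}\t{ref.centromere_slot}\t"
                     f"{','.join(ref.ordered_probe_ids)}\n")


def read_manifest(path: Union[str, Path]) -> ProbeManifest:
    """Read a probe manifest; rows with status other than ``active`` (the
    discarded candidates) are skipped."""
    rows = _header(path, ["probe_id", "group", "arm", "reference_index",
                          "multi_site", "origin", "status"])
    records = []
    for lineno, cols in rows:
        if len(cols) < 7:
            raise KaryoFormatError(f"{path}:{lineno}: expected 7 columns")
        if cols[6].strip() != "active":
            continue
        try:
            records.append(ProbeRecord(
                probe_id=cols[0].strip(),
                home_group=int(cols[1]),
                home_arm=cols[2].strip(),
                reference_index=int(cols[3]),
                multi_site=cols[4].strip().lower() == "true",
            ))
        except ValueError as exc:
            raise KaryoFormatError(f"{path}:{lineno}: {exc}") from None
    if not records:
        raise KaryoFormatError(f"{path}: no records")
    return ProbeManifest(records)


def _format_intervals(event: CREvent) -> str:
    return ";".join(f"{lo}:{hi}" for lo, hi in event.ref_interval)


def _parse_intervals(text: str) -> tuple[tuple[int, int], ...]:
    if not text or text == "-":
        return ()
    out = []
    for part in text.split(";"):
        lo, hi = part.split(":")
        out.append((int(lo), int(hi)))
    return tuple(out)


def write_events(events: Union[Iterable[CREvent], Mapping[str, Sequence[CREvent]]],
                 path: Union[str, Path]) -> None:
    """Write events to TSV.  Accepts a flat event list (written under the
    empty material id) or a mapping material -> events."""
    if not isinstance(events, Mapping):
        events = {"": list(events)}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("material\tevent_type\tchroms\tlabel\tprobes\tref_interval\n")
        for material in events:
            for ev in events[material]:
                fh.write("\t".join([
                    material,
                    ev.event_type,
                    ",".join(ev.chroms),
                    ev.label or "-",
                    ",".join(ev.probes) or "-",
                    _format_intervals(ev) or "-",
                ]) + "\n")


def read_events(path: Union[str, Path]) -> dict[str, list[CREvent]]:
    rows = _header(path, ["material", "event_type", "chroms", "label",
                          "probes", "ref_interval"])
    out: dict[str, list[CREvent]] = {}
    for lineno, cols in rows:
        if len(cols) < 6:
            raise KaryoFormatError(f"{path}:{lineno}: expected 6 columns")
        mat = cols[0].strip()
        try:
            ev = CREvent(
                event_type=cols[1].strip(),
                chroms=tuple(c for c in cols[2].split(",") if c),
                label="" if cols[3].strip() == "-" else cols[3].strip(),
                probes=tuple(p for p in cols[4].split(",") if p and p != "-"),
                ref_interval=_parse_intervals(cols[5].strip()),
            )
        except (ValueError, KaryoValidationError) as exc:
            raise KaryoFormatError(f"{path}:{lineno}: {exc}") from None
        out.setdefault(mat, []).append(ev)
    return out


_CELL_RE = re.compile(r"^([a-z])('*)$")


def read_pattern_matrix(path: Union[str, Path]) -> PatternMatrix:
    """Read a repeat-FISH pattern grid.

    Columns: material, species, then one column per chromosome id.  Cells
    are a single letter with an optional trailing apostrophe (prime flag);
    ``-`` marks chromosomes the material's species does not carry.
    """
    rows = _data_lines(path)
    try:
        lineno, header = next(rows)
    except StopIteration:
        raise KaryoFormatError(f"{path}: no records") from None
    if header[:2] != ["material", "species"]:
        raise KaryoFormatError(
            f"{path}:{lineno}: header must start with material, species")
    chromosomes = [c.strip() for c in header[2:]]
    for c in chromosomes:
        parse_chrom_id(c)
    materials: list[tuple[str, str]] = []
    cells: list[list[Optional[tuple[str, bool]]]] = []
    for lineno, cols in rows:
        if len(cols) != 2 + len(chromosomes):
            raise KaryoFormatError(
                f"{path}:{lineno}: row length {len(cols) - 2} does not match "
                f"{len(chromosomes)} chromosomes")
        mat, species = cols[0].strip(), cols[1].strip()
        if not species:
            raise KaryoFormatError(f"{path}:{lineno}: species tag missing")
        if species not in SUBGENOMES_BY_SPECIES:
            raise KaryoFormatError(
                f"{path}:{lineno}: unknown species tag {species!r}")
        row: list[Optional[tuple[str, bool]]] = []
        for c, chrom in zip(cols[2:], chromosomes):
            c = c.strip()
            if c in ("-", "0", ""):
                row.append(None)
                continue
            m = _CELL_RE.match(c)
            if not m or len(m.group(2)) > 1:
                raise KaryoFormatError(
                    f"{path}:{lineno}: malformed pattern cell {c!r} ({chrom})")
            row.append((m.group(1), bool(m.group(2))))
        materials.append((mat, species))
        cells.append(row)
    if not materials:
        raise KaryoFormatError(f"{path}: no records")
    return PatternMatrix(materials=materials, chromosomes=chromosomes,
                         cells=cells)


def write_pattern_matrix(matrix: PatternMatrix, path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("material\tspecies\t" + "\t".join(matrix.chromosomes) + "\n")
        for (mat, sp), row in zip(matrix.materials, matrix.cells):
            rendered = ["-" if c is None else c[0] + ("'" if c[1] else "")
                        for c in row]
            fh.write(f"{mat}\t{sp}\t" + "\t".join(rendered) + "\n")


_PRESENCE_RE = re.compile(r"^([+\-0])('{0,2})$")


def read_event_matrix(path: Union[str, Path]) -> EventMatrix:
    """Read an event presence matrix.

    Columns: chrom, label, then one ``material:species`` column per
    material.  Cells are ``+`` (present), ``-`` (absent) or ``0`` (the
    species lacks that subgenome), optionally annotated with trailing
    quote marks which are stripped into the annotation grid.
    """
    rows = _data_lines(path)
    try:
        lineno, header = next(rows)
    except StopIteration:
        raise KaryoFormatError(f"{path}: no records") from None
    if header[:2] != ["chrom", "label"]:
        raise KaryoFormatError(
            f"{path}:{lineno}: header must start with chrom, label")
    materials: list[tuple[str, str]] = []
    for col in header[2:]:
        if ":" not in col:
            raise KaryoFormatError(
                f"{path}:{lineno}: species tag missing in column {col!r}")
        mat, species = col.split(":", 1)
        if species not in SUBGENOMES_BY_SPECIES:
            raise KaryoFormatError(
                f"{path}:{lineno}: unknown species tag {species!r}")
        materials.append((mat.strip(), species.strip()))
    events: list[tuple[str, str]] = []
    presence: list[list[bool]] = []
    annotations: list[list[str]] = []
    for lineno, cols in rows:
        if len(cols) != 2 + len(materials):
            raise KaryoFormatError(
                f"{path}:{lineno}: row length does not match material list")
        chrom = cols[0].strip()
        parse_chrom_id(chrom)
        label = cols[1].strip()
        if (chrom, label) in events:
            raise KaryoFormatError(
                f"{path}:{lineno}: duplicate event row ({chrom}, {label})")
        prow, arow = [], []
        for c in cols[2:]:
            m = _PRESENCE_RE.match(c.strip())
            if not m:
                raise KaryoFormatError(
                    f"{path}:{lineno}: malformed presence cell {c!r}")
            prow.append(m.group(1) == "+")
            arow.append(m.group(2))
        events.append((chrom, label))
        presence.append(prow)
        annotations.append(arow)
    if not events:
        raise KaryoFormatError(f"{path}: no records")
    return EventMatrix(events=events, materials=materials,
                       presence=presence, annotations=annotations)


def write_event_matrix(matrix: EventMatrix, path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("chrom\tlabel\t" +
                 "\t".join(f"{m}:{sp}" for m, sp in matrix.materials) + "\n")
        ann = matrix.annotations or [[""] * len(matrix.materials)
                                     for _ in matrix.events]
        for (chrom, label), prow, arow in zip(matrix.events, matrix.presence,
                                              ann):
            cells = [("+" if p else "-") + a for p, a in zip(prow, arow)]
            fh.write(f"{chrom}\t{label}\t" + "\t".join(cells) + "\n")
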