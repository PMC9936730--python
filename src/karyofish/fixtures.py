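"""Packaged fixtures and prose-derived demonstration karyotypes.

The TSVs under ``karyofish/data`` hold the transcribed comparative tables
(event presence grid, repeat-FISH pattern grid) plus a prose-derived
reconstruction of the probe manifest and the D-genome-standard reference
orders.  The demonstration karyotypes built here apply the narrated
rearrangements of two materials to that reference via the simulator; they
illustrate the pipeline end to end but, being reconstructions, support
demonstrations and smoke tests rather than quantitative claims.
"""

from __future__ import annotations

from importlib import resources

from .core import (
    CREvent,
    EventMatrix,
    Karyotype,
    PatternMatrix,
    ProbeManifest,
    ReferenceOrder,
    read_event_matrix,
    read_manifest,
    read_pattern_matrix,
    read_reference,
)
from .simulate import SimEvent, SimSpec, simulate_karyotype


def _data(name: str) -> str:
    return str(resources.files("karyofish") / "data" / name)


def load_manifest() -> ProbeManifest:
    """The 59-probe manifest (active records; discarded candidates are
    kept in the file but skipped by the reader)."""
    return read_manifest(_data("probes_manifest.tsv"))


def load_reference() -> dict[int, ReferenceOrder]:
    """Reference collinearity order per homoeologous group."""
    return read_reference(_data("reference_orders.tsv"))


def load_event_matrix() -> EventMatrix:
    """Transcribed structure-variation presence grid (43 event rows x 11
    materials across the three species)."""
    return read_event_matrix(_data("table1_events.tsv"))


def load_pattern_matrix() -> PatternMatrix:
    """Transcribed repeat-FISH pattern grid (material rows only)."""
    return read_pattern_matrix(_data("table2_patterns.tsv"))


def fixture_path(name: str) -> str:
    """Filesystem path of a packaged data file (for CLI examples)."""
    return _data(name)


# ---------------------------------------------------------------------------
# prose-derived demonstration karyotypes
# ---------------------------------------------------------------------------

#: narrated species-specific rearrangements of the E. sibiricus reference
#: material: pericentric inversions on 1H, 2H, 3H, 6H, 2St and 5St, a
#: paracentric inversion on the 4St long arm, a doubly inverted 4H, and the
#: reciprocal exchange of the 4H/6H distal short arms.
_DY_EVENTS = {
    "1H": [SimEvent("inversion", interval=(3, 6))],
    "2H": [SimEvent("inversion", interval=(2, 5))],
    "3H": [SimEvent("inversion", interval=(2, 5))],
    "6H": [SimEvent("inversion", interval=(3, 6))],
    "2St": [SimEvent("inversion", interval=(2, 5))],
    "5St": [SimEvent("inversion", interval=(2, 5))],
    "4St": [SimEvent("inversion", interval=(5, 8))],
    "4H": [SimEvent("inversion", interval=(3, 6)),
           SimEvent("inversion", interval=(2, 6)),
           SimEvent("rt", partner="6H", k=1, k_partner=1, end="S")],
}

#: narrated H. bogdanii rearrangements: the ancestral 1H pericentric
#: inversion, the one-way transfer of the distal 4H long arm onto the 3H
#: short arm, and the extra interstitial 1H514 site on the 5H long arm.
_HBW_EVENTS = {
    "1H": [SimEvent("inversion", interval=(3, 6))],
    "4H": [SimEvent("t", partner="3H", k=2, end="L", partner_end="S")],
    "5H": [SimEvent("du", probe="1H514", at=6)],
}


def demo_karyotype(material: str) -> tuple[Karyotype, list[CREvent]]:
    """Build a prose-derived demonstration karyotype.

    ``material`` is ``"DY"`` (E. sibiricus reference material) or
    ``"Hbw"`` (the diploid H-genome outgroup).  Returns the karyotype and
    the applied ground-truth events.
    """
    reference, manifest = load_reference(), load_manifest()
    if material == "DY":
        spec = SimSpec(subgenomes=("St", "H"), events=_DY_EVENTS,
                       material_id="DY")
    elif material == "Hbw":
        spec = SimSpec(subgenomes=("H",), events=_HBW_EVENTS,
                       material_id="Hbw")
    else:
        raise ValueError(f"no demonstration karyotype for {material!r}")
    return simulate_karyotype(spec, reference=reference, manifest=manifest)


def group4_breakpoint_events() -> dict[str, list[CREvent]]:
    """Figure-derived group-4 scenario set for the breakpoint-reuse
    demonstration (synthetic reconstruction).

    Four independent inversion complexes — in the outgroup, in the shared
    E. sibiricus series (identical in two materials, deduplicated by the
    reuse tally), in the divergent XN material and in E. nutans — all
    break the reference interval between probes 4H138 (reference index 1)
    and 4H289 (index 2), i.e. boundary 2 of group 4, while their other
    endpoints scatter.
    """
    pei = lambda lo, hi: CREvent(event_type="PeI", chroms=("4H",),
                                 ref_interval=((lo, hi),), label="PeI")
    pai = lambda lo, hi: CREvent(event_type="PaI", chroms=("4H",),
                                 ref_interval=((lo, hi),), label="PaI")
    return {
        "Hbw": [pei(2, 6)],
        "DY": [pei(2, 5)],
        "GEM": [pei(2, 5)],   # same shared complex as DY: counted once
        "XN": [pei(2, 7)],
        "PJC": [pai(2, 4)],
    }
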