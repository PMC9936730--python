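"""Single-copy collinear gene selection for probe design.

Candidate genes are screened per homoeologous group: keep genes that are
single-copy in every subgenome, collinear across the reference genomes and
longer than a minimum (FISH needs enough target for a detectable signal),
then thin them to an even physical spacing by a greedy left-to-right pick:
take the first eligible gene, then repeatedly the eligible gene nearest to
(last pick + target spacing), until the chromosome runs out.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

from .core import KaryoFormatError, KaryoValidationError, _header


@dataclass(frozen=True)
class GeneRecord:
    """A candidate gene on a reference pseudomolecule."""

    gene_id: str
    group: int
    position_mb: float
    length_bp: int
    copies_per_subgenome: Mapping[str, int] = field(default_factory=dict)
    collinear: bool = True

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise KaryoValidationError(
                f"gene {self.gene_id}: non-positive length")
        if any(v < 0 for v in self.copies_per_subgenome.values()):
            raise KaryoValidationError(
                f"gene {self.gene_id}: negative copy number")


def is_eligible(gene: GeneRecord, min_length_bp: float) -> bool:
    return (gene.collinear
            and gene.length_bp > min_length_bp
            and all(v == 1 for v in gene.copies_per_subgenome.values())
            and len(gene.copies_per_subgenome) > 0)


def select_probes(genes: Iterable[GeneRecord],
                  min_length_bp: float = 2000.0,
                  target_spacing_mb: float = 100.0) -> list[str]:
    """Deterministic greedy selection of evenly spaced single-copy genes.

    Selection runs independently per homoeologous group; within a group,
    ties in distance to the spacing target break toward the smaller
    position.  Returns the selected gene ids in (group, position) order.
    """
    by_group: dict[int, list[GeneRecord]] = {}
    for g in genes:
        by_group.setdefault(g.group, []).append(g)
    selected: list[str] = []
    for group in sorted(by_group):
        eligible = sorted(
            (g for g in by_group[group] if is_eligible(g, min_length_bp)),
            key=lambda g: (g.position_mb, g.gene_id))
        if not eligible:
            warnings.warn(f"group {group}: no eligible probe candidates",
                          stacklevel=2)
            continue
        picks = [eligible[0]]
        while True:
            target = picks[-1].position_mb + target_spacing_mb
            ahead = [g for g in eligible if g.position_mb > picks[-1].position_mb]
            if not ahead:
                break
            picks.append(min(ahead, key=lambda g: (abs(g.position_mb - target),
                                                   g.position_mb)))
        selected.extend(g.gene_id for g in picks)
    return selected


def read_genes(path: Union[str, Path]) -> list[GeneRecord]:
    """Read a gene-candidate table.

    Columns: gene_id, group, position_mb, length_bp, collinear, then one
    ``copies_<subgenome>`` column per reference subgenome.
    """
    rows = _header(path, ["gene_id", "group", "position_mb", "length_bp",
                          "collinear"])
    # re-read header to capture copy columns
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip() and not line.lstrip().startswith("#"):
                header = line.rstrip("\n").split("\t")
                break
    copy_cols = [(i, c.split("_", 1)[1]) for i, c in enumerate(header)
                 if c.startswith("copies_")]
    if not copy_cols:
        raise KaryoFormatError(f"{path}: no copies_<subgenome> columns")
    genes = []
    for lineno, cols in rows:
        try:
            genes.append(GeneRecord(
                gene_id=cols[0].strip(),
                group=int(cols[1]),
                position_mb=float(cols[2]),
                length_bp=int(cols[3]),
                collinear=cols[4].strip().lower() == "true",
                copies_per_subgenome={
                    sub: int(cols[i]) for i, sub in copy_cols},
            ))
        except (ValueError, IndexError) as exc:
            raise KaryoFormatError(f"{path}:{lineno}: {exc}") from None
    return genes


def write_selection(gene_ids: Sequence[str], path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\n")
        for gid in gene_ids:
            fh.write(gid + "\n")
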