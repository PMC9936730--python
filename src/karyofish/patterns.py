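"""Chromosome-variant accounting from repeat-FISH pattern matrices.

Homologous chromosomes that show the same repeat-FISH banding pattern in
different materials carry the same letter code; a prime flags a variant
that additionally carries a polymorphic rearrangement.  A primed letter is
a distinct variant from its unprimed base (a and a' are two variants) —
a chromosome that looks alike in repeats but differs structurally is a
different variant.
"""

from __future__ import annotations

import pandas as pd

from .core import KaryoValidationError, PatternMatrix, parse_chrom_id


def _column_sets(matrix: PatternMatrix) -> list[set[tuple[str, bool]]]:
    return [
        {matrix.cells[i][j] for i in range(len(matrix.materials))
         if matrix.cells[i][j] is not None}
        for j in range(len(matrix.chromosomes))
    ]


def _summarise(matrix: PatternMatrix, counts: list[int]) -> pd.Series:
    index = list(matrix.chromosomes)
    s = pd.Series(counts, index=index, dtype=int)
    genomes = {}
    for chrom in index:
        _, sub = parse_chrom_id(chrom)
        genomes.setdefault(sub, []).append(chrom)
    for sub, chroms in genomes.items():
        s[f"{sub}_total"] = int(s[chroms].sum())
    s["total"] = sum(counts)
    return s


def count_variants(matrix: PatternMatrix, species: str) -> pd.Series:
    """Distinct (letter, primed) patterns per chromosome column for one
    species, with per-subgenome totals and a grand total.

    Returns a Series indexed by chromosome id plus ``<sub>_total`` and
    ``total`` entries.
    """
    sub = matrix.restrict(species)
    return _summarise(sub, [len(c) for c in _column_sets(sub)])


def count_primed_variants(matrix: PatternMatrix, species: str) -> pd.Series:
    """Distinct *primed* patterns per chromosome column (variants carrying
    a polymorphic rearrangement), with the same totals layout."""
    sub = matrix.restrict(species)
    counts = [sum(1 for cell in col if cell[1]) for col in _column_sets(sub)]
    return _summarise(sub, counts)


def variants_table(matrix: PatternMatrix, species: str) -> pd.DataFrame:
    """Both summary rows side by side, mirroring a printed summary block."""
    return pd.DataFrame({
        "variants": count_variants(matrix, species),
        "variants_with_polymorphic_CRs": count_primed_variants(matrix, species),
    })
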