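"""Independent oracles used to cross-check the library implementations.

These deliberately share no code with the package: the scenario oracle is
a recursive iterative-deepening depth-first search with its own inline
breakpoint counter, and the counting oracles are direct enumerations.
"""

from __future__ import annotations

from typing import Sequence

TOKEN = "C"


def iddfs_min_scenarios(start: Sequence, target: Sequence, max_depth: int
                        ) -> tuple[float, set[tuple[tuple[int, int], ...]]]:
    """All minimal reversal scenarios start -> target, by iterative
    deepening.  Returns (d_min, set of interval tuples); (inf, empty) when
    nothing is found within max_depth."""
    start = tuple(start)
    target = tuple(target)
    tpos = {v: i for i, v in enumerate(x for x in target if x != TOKEN)}
    k = len(tpos)

    def breaks(seq) -> int:
        ms = [tpos[x] for x in seq if x != TOKEN]
        framed = [-1] + ms + [k]
        return sum(1 for a, b in zip(framed, framed[1:]) if abs(a - b) != 1)

    m = len(start)
    intervals = [(i, j) for i in range(m) for j in range(i + 2, m + 1)]
    found: list[tuple[tuple[int, int], ...]] = []

    def dfs(seq, depth, limit, acc) -> None:
        if seq == target:
            if depth == limit:
                found.append(tuple(acc))
            return
        if depth == limit or (breaks(seq) + 1) // 2 > limit - depth:
            return
        for lo, hi in intervals:
            acc.append((lo, hi))
            dfs(seq[:lo] + seq[lo:hi][::-1] + seq[hi:], depth + 1, limit, acc)
            acc.pop()

    for limit in range(max_depth + 1):
        found.clear()
        dfs(start, 0, limit, [])
        if found:
            return float(limit), set(found)
    return float("inf"), set()


def enumerate_breakpoints(markers: Sequence[int]) -> int:
    """Direct enumeration of disrupted framed adjacencies."""
    framed = [-1, *markers, len(markers)]
    return sum(1 for a, b in zip(framed, framed[1:]) if abs(a - b) != 1)


def distinct_column_patterns(columns: Sequence[Sequence]) -> list[int]:
    """Brute-force distinct-cell count per column (None cells ignored)."""
    return [len({c for c in col if c is not None}) for col in columns]
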