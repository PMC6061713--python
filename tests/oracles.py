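"""Independent brute-force oracles, kept deliberately naive.

Each function re-derives a pipeline quantity from first principles (explicit
loops, textbook formulas) without touching the package's implementation
paths, so tests can compare the two routes.
"""

from __future__ import annotations

import math
from typing import Sequence

GAP = "-"


def brute_force_differential_columns(
    sequences: dict[str, str], sensitive_ids: Sequence[str], insensitive_ids: Sequence[str]
) -> list[int]:
    """0-based columns satisfying the group-specific identity rule, by explicit scan."""
    length = len(next(iter(sequences.values())))
    hits = []
    for col in range(length):
        sens = [sequences[i][col].upper() for i in sensitive_ids]
        insens = [sequences[i][col].upper() for i in insensitive_ids]
        if any(c == GAP for c in sens):
            continue
        if len(set(sens)) != 1:
            continue
        residue = sens[0]
        if all(c != residue for c in insens):
            hits.append(col)
    return hits


def brute_force_reference_positions(reference: str) -> dict[int, int]:
    """Column -> 1-based position map via a cumulative non-gap counter."""
    mapping = {}
    count = 0
    for col, char in enumerate(reference):
        if char != GAP:
            count += 1
            mapping[col] = count
    return mapping


def brute_force_sem(values: Sequence[float]) -> float:
    n = len(values)
    mean = sum(values) / n
    if n < 2:
        return 0.0
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return math.sqrt(var) / math.sqrt(n)


def brute_force_pooled_t(a: Sequence[float], b: Sequence[float]) -> float:
    """Classic pooled-variance two-sample t statistic from the textbook formula."""
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    sa2 = sum((v - ma) ** 2 for v in a) / (na - 1)
    sb2 = sum((v - mb) ** 2 for v in b) / (nb - 1)
    sp2 = ((na - 1) * sa2 + (nb - 1) * sb2) / (na + nb - 2)
    return (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))


def brute_force_region_lookup(
    position: int, regions: Sequence[tuple[str, int, int]]
) -> str:
    for label, start, end in regions:
        if start <= position <= end:
            return label
    raise ValueError(f"position {position} not covered")


def brute_force_group_conservation(
    letters: Sequence[str],
) -> tuple[str | None, float]:
    """Consensus residue (ties alphabetical) and its fraction of the group."""
    non_gap = [c for c in letters if c != GAP]
    if not non_gap:
        return None, 0.0
    best, best_count = None, -1
    for residue in sorted(set(non_gap)):
        count = sum(1 for c in non_gap if c == residue)
        if count > best_count:
            best, best_count = residue, count
    return best, best_count / len(letters)
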