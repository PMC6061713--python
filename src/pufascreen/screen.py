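"""Differential paralog-conservation screen.

Candidate PUFA-sensitivity positions are alignment columns where every
sequence of the sensitive paralog group (TRPL, TRPgamma) carries one
identical non-gap residue while every sequence of the insensitive paralog
(TRP) carries something else.  Comparison is case-insensitive exact identity;
a gap in the insensitive group counts as "different" (the residue is
physically absent) whereas a gap within the sensitive group disqualifies the
column.  Candidates are then labelled against the channel topology: outside
the analysis window, within the pore-proximal exclusion interval, in the
distal C-terminus (excluded because of its role in multimerization), or
retained.  A cross-species profiler quantifies how conserved each candidate
is within each paralog group across an ortholog panel.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .alignment import GAP, ParalogAlignment, map_to_reference
from .topology import TopologyAnnotation, assign_region

STATUS_CANDIDATE = "candidate"
STATUS_EXCLUDED_PORE = "excluded_pore"
STATUS_EXCLUDED_DISTAL = "excluded_distal"
STATUS_OUTSIDE_WINDOW = "outside_window"

CLASS_FULL = "fully_conserved_both_groups"
CLASS_PARTIAL = "partially_conserved"
CLASS_NOT = "not_conserved"


@dataclass
class CandidatePosition:
    """One differential column, numbered in reference coordinates."""

    reference_position: int
    column_index: int
    residues: dict[str, str]  # paralog -> distinct residue letters seen
    status: str = STATUS_CANDIDATE
    region: str | None = None


def find_differential_positions(
    alignment: ParalogAlignment,
    sensitive_paralogs: Sequence[str],
    insensitive_paralog: str | Sequence[str],
) -> list[CandidatePosition]:
    """Scan every reference-mapped column for the group-specific identity rule.

    A column is returned iff (i) all sensitive-group sequences share one
    identical non-gap residue and (ii) every insensitive-group sequence
    differs from it (gaps in the insensitive group count as different).
    Output is sorted by reference position.
    """
    if not sensitive_paralogs:
        raise ValueError("sensitive paralog group is empty")
    sens_records = alignment.group(sensitive_paralogs)
    insens_records = alignment.group(insensitive_paralog)
    if alignment.reference.paralog not in set(sensitive_paralogs):
        raise ValueError(
            f"reference record {alignment.reference_id!r} must belong to the "
            f"sensitive paralog group {list(sensitive_paralogs)}"
        )
    refmap = map_to_reference(alignment)

    sens = alignment.to_matrix(sens_records)
    insens = alignment.to_matrix(insens_records)

    # Rule (i): one identical non-gap residue across the sensitive group.
    sens_identical = (sens == sens[0]).all(axis=0) & (sens[0] != GAP)
    # Rule (ii): every insensitive sequence differs from that residue.
    insens_all_differ = (insens != sens[0]).all(axis=0)
    hits = np.flatnonzero(sens_identical & insens_all_differ)

    out: list[CandidatePosition] = []
    for col in hits:
        pos = refmap.position(int(col))
        if pos is None:  # reference gap column: no residue number
            continue
        by_paralog: dict[str, set[str]] = {}
        for rec in sens_records + insens_records:
            by_paralog.setdefault(rec.paralog, set()).add(rec.sequence[col].upper())
        out.append(
            CandidatePosition(
                reference_position=pos,
                column_index=int(col),
                residues={p: "".join(sorted(r)) for p, r in by_paralog.items()},
            )
        )
    out.sort(key=lambda c: c.reference_position)
    return out


def apply_region_filter(
    candidates: Iterable[CandidatePosition],
    topology: TopologyAnnotation,
    window: tuple[int, int] | None = None,
) -> list[CandidatePosition]:
    """Label candidates by topology; nothing is dropped, only labelled.

    Precedence: pore-proximal exclusion interval -> distal C-terminus ->
    outside the analysis window -> retained candidate.  The default window
    runs from just before S1 to the end of the proximal C-terminus.
    """
    lo_span, hi_span = topology.span
    if window is None:
        window = topology.default_window()
    w_lo, w_hi = window
    if w_lo < lo_span or w_hi > hi_span or w_lo > w_hi:
        raise ValueError(
            f"analysis window [{w_lo}, {w_hi}] outside topology span "
            f"[{lo_span}, {hi_span}]"
        )
    pore = topology.pore_exclusion
    out = []
    for cand in candidates:
        pos = cand.reference_position
        assignment = assign_region(pos, topology)
        if pore is not None and pore[0] <= pos <= pore[1]:
            status = STATUS_EXCLUDED_PORE
        elif assignment.region == "distal C-term":
            status = STATUS_EXCLUDED_DISTAL
        elif not (w_lo <= pos <= w_hi):
            status = STATUS_OUTSIDE_WINDOW
        else:
            status = STATUS_CANDIDATE
        out.append(
            CandidatePosition(
                reference_position=pos,
                column_index=cand.column_index,
                residues=dict(cand.residues),
                status=status,
                region=assignment.region,
            )
        )
    return out


@dataclass
class ConservationThresholds:
    """Cut-offs turning per-group conservation fractions into classes.

    ``fully_conserved_both_groups`` requires both fractions to equal 1.0 with
    distinct group consensus residues; ``partially_conserved`` requires both
    fractions to reach ``partial``; everything else is ``not_conserved``.
    """

    partial: float = 0.7


@dataclass
class ConservationProfile:
    """Cross-species conservation of one position, per paralog group."""

    reference_position: int
    sensitive_consensus: str | None
    insensitive_consensus: str | None
    sensitive_fraction: float | None
    insensitive_fraction: float | None
    conservation_class: str | None
    error: str | None = None


def _consensus(letters: Sequence[str]) -> tuple[str | None, float]:
    """Most common non-gap residue and its fraction of the whole group."""
    non_gap = [c for c in letters if c != GAP]
    if not non_gap:
        return None, 0.0
    counts = Counter(non_gap)
    top = max(sorted(counts), key=counts.get)  # ties break alphabetically
    return top, counts[top] / len(letters)


def cross_species_conservation(
    alignment: ParalogAlignment,
    positions: Iterable[int],
    sensitive_paralogs: Sequence[str],
    insensitive_paralog: str | Sequence[str],
    thresholds: ConservationThresholds | None = None,
) -> list[ConservationProfile]:
    """Profile each position's conservation within both paralog groups.

    For each position the group consensus residue and the fraction of group
    sequences carrying it are computed; positions that do not map to a column
    of the ortholog alignment are reported with an ``error`` rather than
    raising.
    """
    thresholds = thresholds or ConservationThresholds()
    refmap = map_to_reference(alignment)
    sens = alignment.to_matrix(alignment.group(sensitive_paralogs))
    insens = alignment.to_matrix(alignment.group(insensitive_paralog))

    profiles = []
    for pos in positions:
        try:
            col = refmap.column(pos)
        except KeyError as exc:
            profiles.append(
                ConservationProfile(
                    reference_position=pos,
                    sensitive_consensus=None,
                    insensitive_consensus=None,
                    sensitive_fraction=None,
                    insensitive_fraction=None,
                    conservation_class=None,
                    error=str(exc),
                )
            )
            continue
        s_cons, s_frac = _consensus(list(sens[:, col]))
        i_cons, i_frac = _consensus(list(insens[:, col]))
        if (
            s_frac == 1.0
            and i_frac == 1.0
            and s_cons is not None
            and i_cons is not None
            and s_cons != i_cons
        ):
            cls = CLASS_FULL
        elif min(s_frac, i_frac) >= thresholds.partial:
            cls = CLASS_PARTIAL
        else:
            cls = CLASS_NOT
        profiles.append(
            ConservationProfile(
                reference_position=pos,
                sensitive_consensus=s_cons,
                insensitive_consensus=i_cons,
                sensitive_fraction=s_frac,
                insensitive_fraction=i_frac,
                conservation_class=cls,
            )
        )
    return profiles


def write_screen_report(
    path: str | Path,
    candidates: Sequence[CandidatePosition],
    profiles: Sequence[ConservationProfile] | None = None,
) -> None:
    """TSV report: one row per candidate, joined with conservation profiles."""
    by_pos = {p.reference_position: p for p in profiles or []}
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            [
                "reference_position",
                "residues_by_paralog",
                "status",
                "region",
                "sensitive_conservation",
                "insensitive_conservation",
                "class",
            ]
        )
        for cand in candidates:
            prof = by_pos.get(cand.reference_position)
            writer.writerow(
                [
                    cand.reference_position,
                    ";".join(f"{p}={r}" for p, r in sorted(cand.residues.items())),
                    cand.status,
                    cand.region or "",
                    "" if prof is None or prof.sensitive_fraction is None
                    else f"{prof.sensitive_fraction:.3f}",
                    "" if prof is None or prof.insensitive_fraction is None
                    else f"{prof.insensitive_fraction:.3f}",
                    "" if prof is None else (prof.conservation_class or prof.error or ""),
                ]
            )
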