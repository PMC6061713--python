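"""Membrane topology of a TRP-channel subunit in reference residue coordinates.

A topology annotation is an ordered, gap-free, non-overlapping list of closed
1-based intervals covering the subunit from the cytosolic N-terminus through
the six transmembrane helices (S1-S6), the pore loop between S5 and S6, and
the proximal/distal cytosolic C-terminus.  Positions are mapped to regions by
interval containment; the S2-S4 span and the proximal C-terminus get explicit
flags because they are the two hotspots of the PUFA-sensitivity screen.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

REGION_LABELS: tuple[str, ...] = (
    "N-term",
    "S1",
    "S1-S2 linker",
    "S2",
    "S2-S3 linker",
    "S3",
    "S3-S4 linker",
    "S4",
    "S4-S5 linker",
    "S5",
    "pore",
    "S6",
    "proximal C-term",
    "distal C-term",
)

#: Region labels comprising the transmembrane S2-S4 stretch (helices plus
#: their intervening linkers).
S2_S4_LABELS: frozenset[str] = frozenset(
    {"S2", "S2-S3 linker", "S3", "S3-S4 linker", "S4"}
)


@dataclass(frozen=True)
class Region:
    """A named closed interval ``[start, end]`` in 1-based reference coordinates."""

    label: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"invalid interval for region {self.label!r}: [{self.start}, {self.end}]"
            )

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class RegionAssignment:
    """Placement of a single residue position within the topology."""

    position: int
    region: str
    in_s2_s4_span: bool
    in_proximal_cterm: bool


@dataclass
class TopologyAnnotation:
    """Ordered, contiguous partition of the reference span into regions.

    Parameters
    ----------
    regions
        Region intervals; sorted on construction.  Overlaps or gaps raise
        ``ValueError`` naming the offending pair.
    pore_exclusion
        Closed interval of pore-proximal positions excluded from the
        mutagenesis screen (wider than the pore region itself).
    window_margin
        Residues prepended before S1 when deriving the default analysis
        window.
    """

    regions: list[Region]
    pore_exclusion: tuple[int, int] | None = None
    window_margin: int = 10
    name: str = ""

    def __post_init__(self) -> None:
        self.regions = sorted(
            (r if isinstance(r, Region) else Region(*r) for r in self.regions),
            key=lambda r: r.start,
        )
        if not self.regions:
            raise ValueError("topology must contain at least one region")
        for prev, cur in zip(self.regions, self.regions[1:]):
            if cur.start <= prev.end:
                raise ValueError(
                    f"overlapping regions: {prev.label!r} [{prev.start},{prev.end}] "
                    f"and {cur.label!r} [{cur.start},{cur.end}]"
                )
            if cur.start != prev.end + 1:
                raise ValueError(
                    f"gap between regions {prev.label!r} (ends {prev.end}) "
                    f"and {cur.label!r} (starts {cur.start})"
                )

    @property
    def span(self) -> tuple[int, int]:
        return self.regions[0].start, self.regions[-1].end

    def region_of(self, position: int) -> Region:
        for region in self.regions:
            if position in region:
                return region
        lo, hi = self.span
        raise ValueError(f"position {position} outside annotated span [{lo}, {hi}]")

    def start_of(self, label: str) -> int:
        for region in self.regions:
            if region.label == label:
                return region.start
        raise KeyError(f"no region labelled {label!r}")

    def end_of(self, label: str) -> int:
        for region in self.regions:
            if region.label == label:
                return region.end
        raise KeyError(f"no region labelled {label!r}")

    def default_window(self) -> tuple[int, int]:
        """Analysis window: just before S1 up to the end of the proximal C-terminus."""
        lo, _ = self.span
        return max(lo, self.start_of("S1") - self.window_margin), self.end_of(
            "proximal C-term"
        )

    def save(self, path: str | Path) -> None:
        payload = {
            "name": self.name,
            "pore_exclusion": list(self.pore_exclusion) if self.pore_exclusion else None,
            "window_margin": self.window_margin,
            "regions": [
                {"region": r.label, "start": r.start, "end": r.end}
                for r in self.regions
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_topology(path: str | Path) -> TopologyAnnotation:
    """Read a topology annotation from JSON or TSV.

    JSON carries ``regions`` (list of ``{region, start, end}``) plus optional
    ``pore_exclusion`` and ``window_margin``; TSV has columns
    ``region<TAB>start<TAB>end``.  Regions are sorted on load and validated
    for overlaps and gaps.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".tsv", ".txt"}:
        regions = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                regions.append(Region(row["region"], int(row["start"]), int(row["end"])))
        return TopologyAnnotation(regions=regions, name=path.stem)
    payload = json.loads(path.read_text())
    regions = [
        Region(r["region"], int(r["start"]), int(r["end"])) for r in payload["regions"]
    ]
    pore = payload.get("pore_exclusion")
    return TopologyAnnotation(
        regions=regions,
        pore_exclusion=tuple(pore) if pore else None,
        window_margin=int(payload.get("window_margin", 10)),
        name=payload.get("name", path.stem),
    )


def default_topology() -> TopologyAnnotation:
    """The packaged TRPL topology (a calibrated, fully overridable fixture)."""
    with resources.as_file(
        resources.files("pufascreen.data") / "trpl_topology.json"
    ) as p:
        return load_topology(p)


def assign_region(position: int, topology: TopologyAnnotation) -> RegionAssignment:
    """Assign a residue position to its unique topology region."""
    region = topology.region_of(position)
    return RegionAssignment(
        position=position,
        region=region.label,
        in_s2_s4_span=region.label in S2_S4_LABELS,
        in_proximal_cterm=region.label == "proximal C-term",
    )


@dataclass
class RegionCounts:
    """Per-region tallies of a residue-position set, with span aggregates."""

    by_region: dict[str, int]
    s2_s4_span: int
    proximal_cterm: int
    total: int


def count_by_region(
    positions: Iterable[int], topology: TopologyAnnotation
) -> RegionCounts:
    """Count positions per region; counts always sum to ``len(positions)``."""
    counts = {r.label: 0 for r in topology.regions}
    span = 0
    proximal = 0
    total = 0
    for pos in positions:
        a = assign_region(pos, topology)
        counts[a.region] += 1
        span += a.in_s2_s4_span
        proximal += a.in_proximal_cterm
        total += 1
    return RegionCounts(
        by_region=counts, s2_s4_span=span, proximal_cterm=proximal, total=total
    )
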