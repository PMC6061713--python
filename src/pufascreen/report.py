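"""End-to-end screen report: pipeline -> classification -> topology join.

Drives the full trace pipeline over one or more trace tables, classifies
every construct against the wild type, joins single-mutant positions onto
the channel topology, tallies required positions per region, and lists the
ligand-discriminating constructs when both agonists are present.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .model import (
    DiscriminationResult,
    DiscriminationRule,
    MutantCall,
    PufaResponseModel,
    PufaScreenResults,
    mutated_position,
)
from .topology import RegionCounts, TopologyAnnotation, count_by_region
from .traces import AmplitudeConfig, GatingConfig, TraceSet, load_traces


@dataclass
class ScreenReport:
    """Aggregated outcome of the functional screen."""

    results: PufaScreenResults
    calls: list[MutantCall]
    required_positions: list[int]
    region_counts: RegionCounts | None
    discrimination: list[DiscriminationResult]

    @property
    def required_constructs(self) -> list[str]:
        return [c.construct for c in self.calls if c.required_for_pufa_activation]

    @property
    def discriminating_constructs(self) -> list[str]:
        return [d.construct for d in self.discrimination if d.discriminating]

    def construct_table(self) -> pd.DataFrame:
        df = self.results.summary_frame
        calls = {
            (c.construct, c.ligand): c.required_for_pufa_activation for c in self.calls
        }
        df["required_for_pufa_activation"] = [
            calls.get((c, l)) for c, l in zip(df["construct"], df["ligand"])
        ]
        df["position"] = [mutated_position(c) for c in df["construct"]]
        return df

    def to_json(self, path: str | Path) -> None:
        payload = {
            "required_positions": self.required_positions,
            "required_constructs": self.required_constructs,
            "discriminating_constructs": self.discriminating_constructs,
            "region_counts": None
            if self.region_counts is None
            else {
                "by_region": self.region_counts.by_region,
                "s2_s4_span": self.region_counts.s2_s4_span,
                "proximal_cterm": self.region_counts.proximal_cterm,
                "total": self.region_counts.total,
            },
            "constructs": json.loads(
                self.construct_table().to_json(orient="records")
            ),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    def to_tsv(self, path: str | Path) -> None:
        self.construct_table().to_csv(path, sep="\t", index=False)


def run_screen_report(
    trace_files: Sequence[str | Path] | TraceSet,
    topology: TopologyAnnotation | None,
    stimulus_time: float | None = None,
    wt_construct: str = "TRPL-WT",
    ligand: str = "ETYA",
    threshold: float = 50.0,
    rule: DiscriminationRule | None = None,
    gating: GatingConfig | None = None,
    amplitude: AmplitudeConfig | None = None,
) -> ScreenReport:
    """Run the full pipeline over trace tables and aggregate the screen calls.

    ``trace_files`` may be CSV paths (concatenated into one experiment) or an
    already-loaded :class:`TraceSet`.  The wild-type construct must be present
    for every ligand or the run aborts.
    """
    if isinstance(trace_files, TraceSet):
        trace_set = trace_files
    else:
        if stimulus_time is None:
            raise ValueError("stimulus_time is required when loading trace files")
        frames = [load_traces(p, stimulus_time=stimulus_time).data for p in trace_files]
        data = pd.concat(frames, ignore_index=True).drop_duplicates(
            subset=["construct", "ligand", "cell_id", "time_s"]
        )
        trace_set = TraceSet(data=data, stimulus_time=stimulus_time)

    model = PufaResponseModel(
        trace_set,
        wt_construct=wt_construct,
        gating=gating or GatingConfig(),
        amplitude=amplitude or AmplitudeConfig(),
    )
    results = model.fit()

    calls = results.classify(ligand=ligand, threshold=threshold)
    required_positions = results.required_positions(ligand=ligand, threshold=threshold)
    region_counts = (
        count_by_region(required_positions, topology) if topology is not None else None
    )
    discrimination = results.discriminate(rule=rule)
    return ScreenReport(
        results=results,
        calls=calls,
        required_positions=required_positions,
        region_counts=region_counts,
        discrimination=discrimination,
    )
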