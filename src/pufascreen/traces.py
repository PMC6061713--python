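"""Ratiometric Fura-2 trace handling.

Single-cell recordings arrive as a tidy table with one row per cell and
timepoint carrying the two excitation channels (F340, F380), an expression
marker intensity (YFP) and, per construct/ligand recording, a no-cell
background ROI series under the sentinel cell id ``BACKGROUND``.  The
quantification chain is:

1. background correction and ratio:
   ``R(t) = (F340(t) - bg340(t)) / (F380(t) - bg380(t))``;
2. expression gating on the YFP marker (percentile window per construct);
3. per-cell signal amplitude: post-stimulus maximum of the median-smoothed
   ratio minus the pre-stimulus baseline mean.

The ratio is invariant to any common scaling of both channels and both
backgrounds (illumination intensity), which is the point of ratiometric
dyes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BACKGROUND_ID = "BACKGROUND"
TRACE_COLUMNS = ("construct", "ligand", "cell_id", "time_s", "f340", "f380", "yfp")


class TraceSchemaError(ValueError):
    """Trace table violates the fixture schema."""


@dataclass
class TraceSet:
    """All recordings of an experiment, grouped by (construct, ligand).

    Parameters
    ----------
    data
        Tidy frame with columns ``construct, ligand, cell_id, time_s, f340,
        f380, yfp``.  Each (construct, ligand) group must contain a
        ``BACKGROUND`` series per channel (same rows, both channels).
    stimulus_time
        Ligand application time in seconds; must fall inside the recorded
        span.
    ligand_concentration_um
        Annotation only; ligands are applied at a supramaximal 40 uM in the
        emulated protocol.
    """

    data: pd.DataFrame
    stimulus_time: float
    ligand_concentration_um: float = 40.0

    def __post_init__(self) -> None:
        missing = [c for c in TRACE_COLUMNS if c not in self.data.columns]
        if missing:
            raise TraceSchemaError(f"trace table missing columns: {missing}")
        if self.stimulus_time is None:
            raise TraceSchemaError("stimulus_time metadata is required")
        neg = self.data.index[(self.data["f340"] < 0) | (self.data["f380"] < 0)]
        if len(neg):
            raise TraceSchemaError(
                f"negative fluorescence at row {int(neg[0])} "
                f"(columns f340/f380 must be >= 0)"
            )
        for (construct, ligand), group in self.data.groupby(
            ["construct", "ligand"], sort=False
        ):
            cells = group["cell_id"].unique()
            if BACKGROUND_ID not in cells:
                raise TraceSchemaError(
                    f"missing {BACKGROUND_ID} series for construct "
                    f"{construct!r}, ligand {ligand!r}"
                )
            for cell, trace in group.groupby("cell_id", sort=False):
                t = trace["time_s"].to_numpy(float)
                if len(t) > 1 and not np.all(np.diff(t) > 0):
                    bad = int(trace.index[np.argmin(np.diff(t) > 0) + 1])
                    raise TraceSchemaError(
                        f"time_s not strictly increasing for cell {cell!r} of "
                        f"{construct!r}/{ligand!r} (row {bad})"
                    )
            tmin, tmax = group["time_s"].min(), group["time_s"].max()
            if not (tmin <= self.stimulus_time <= tmax):
                raise TraceSchemaError(
                    f"stimulus_time {self.stimulus_time} outside the recorded "
                    f"span [{tmin}, {tmax}] of {construct!r}/{ligand!r}"
                )

    def groups(self) -> Iterator[tuple[tuple[str, str], pd.DataFrame]]:
        yield from self.data.groupby(["construct", "ligand"], sort=False)

    @property
    def constructs(self) -> list[tuple[str, str]]:
        return list(
            self.data[["construct", "ligand"]].drop_duplicates().itertuples(index=False)
        )

    def n_cells(self, construct: str, ligand: str) -> int:
        group = self.data[
            (self.data["construct"] == construct) & (self.data["ligand"] == ligand)
        ]
        return group.loc[group["cell_id"] != BACKGROUND_ID, "cell_id"].nunique()


def load_traces(
    path: str | Path,
    stimulus_time: float | None = None,
    ligand_concentration_um: float = 40.0,
) -> TraceSet:
    """Load and validate a tidy trace CSV into a :class:`TraceSet`.

    ``stimulus_time`` is experiment metadata not carried by the CSV and must
    be supplied; missing background series, non-monotone time or schema
    violations raise :class:`TraceSchemaError` naming the offending column,
    row or cell.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = pd.read_csv(path)
    if stimulus_time is None:
        raise TraceSchemaError("stimulus_time metadata is required to load traces")
    return TraceSet(
        data=data,
        stimulus_time=float(stimulus_time),
        ligand_concentration_um=ligand_concentration_um,
    )


@dataclass
class RatioTraces:
    """Background-corrected ratio traces for one (construct, ligand) group.

    ``ratios`` is a cells x timepoints matrix with NaN at flagged-invalid
    timepoints (corrected F380 <= eps).
    """

    construct: str
    ligand: str
    times: np.ndarray
    cell_ids: list[str]
    ratios: np.ndarray
    yfp: np.ndarray  # per-cell scalar marker intensity

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


def _pivot(group: pd.DataFrame, column: str) -> pd.DataFrame:
    return group.pivot(index="cell_id", columns="time_s", values=column)


def background_correct_and_ratio(
    trace_set: TraceSet, eps: float = 1e-6
) -> list[RatioTraces]:
    """Compute per-cell background-corrected 340/380 ratio traces.

    Timepoints with corrected F380 <= ``eps`` are flagged invalid (NaN);
    cells whose every timepoint is invalid are dropped with a log entry.
    """
    out = []
    for (construct, ligand), group in trace_set.groups():
        f340 = _pivot(group, "f340")
        f380 = _pivot(group, "f380")
        bg340 = f340.loc[BACKGROUND_ID].to_numpy(float)
        bg380 = f380.loc[BACKGROUND_ID].to_numpy(float)
        cells = [c for c in f340.index if c != BACKGROUND_ID]
        num = f340.loc[cells].to_numpy(float) - bg340[None, :]
        den = f380.loc[cells].to_numpy(float) - bg380[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = np.where(den > eps, num / den, np.nan)
        valid_cells = ~np.all(np.isnan(ratios), axis=1)
        for cell, ok in zip(cells, valid_cells):
            if not ok:
                logger.warning(
                    "dropping cell %r of %r/%r: no valid timepoint after "
                    "background correction",
                    cell,
                    construct,
                    ligand,
                )
        yfp = (
            group[group["cell_id"] != BACKGROUND_ID]
            .groupby("cell_id", sort=False)["yfp"]
            .first()
            .reindex(cells)
            .to_numpy(float)
        )
        out.append(
            RatioTraces(
                construct=construct,
                ligand=ligand,
                times=f340.columns.to_numpy(float),
                cell_ids=[c for c, ok in zip(cells, valid_cells) if ok],
                ratios=ratios[valid_cells],
                yfp=yfp[valid_cells],
            )
        )
    return out


@dataclass
class GatingConfig:
    """Expression gating on the YFP marker.

    A per-construct percentile window emulates selecting a defined range of
    relative marker intensities; ``absolute_window`` (intensity units)
    overrides the percentile window when set.  ``min_cells`` is the QC floor
    below which a warning (not an error) is emitted.
    """

    lower_percentile: float = 20.0
    upper_percentile: float = 80.0
    absolute_window: tuple[float, float] | None = None
    min_cells: int = 60
    enabled: bool = True


def select_cells(ratio_traces: RatioTraces, gating: GatingConfig) -> RatioTraces:
    """Retain cells whose YFP lies within the construct's gating window."""
    if not gating.enabled:
        keep = np.ones(ratio_traces.n_cells, bool)
    elif gating.absolute_window is not None:
        lo, hi = gating.absolute_window
        keep = (ratio_traces.yfp >= lo) & (ratio_traces.yfp <= hi)
    else:
        lo = np.nanpercentile(ratio_traces.yfp, gating.lower_percentile)
        hi = np.nanpercentile(ratio_traces.yfp, gating.upper_percentile)
        keep = (ratio_traces.yfp >= lo) & (ratio_traces.yfp <= hi)
    n_keep = int(keep.sum())
    if n_keep == 0:
        raise ValueError(
            f"expression gating retained zero cells for "
            f"{ratio_traces.construct!r}/{ratio_traces.ligand!r}"
        )
    if n_keep < gating.min_cells:
        warnings.warn(
            f"only {n_keep} cells of {ratio_traces.construct!r}/"
            f"{ratio_traces.ligand!r} survive expression gating "
            f"(QC floor is {gating.min_cells})",
            stacklevel=2,
        )
    return RatioTraces(
        construct=ratio_traces.construct,
        ligand=ratio_traces.ligand,
        times=ratio_traces.times,
        cell_ids=[c for c, k in zip(ratio_traces.cell_ids, keep) if k],
        ratios=ratio_traces.ratios[keep],
        yfp=ratio_traces.yfp[keep],
    )


@dataclass
class AmplitudeConfig:
    """Windows and smoothing for the per-cell signal-amplitude operator.

    baseline_s
        Length of the pre-stimulus baseline window ``[t_stim - baseline_s,
        t_stim)``.
    smooth_points
        Width of the moving-median filter applied before taking the
        post-stimulus extremum (robust to single-frame spikes).
    mode
        ``"peak"``: maximum of the smoothed post-stimulus ratio;
        ``"plateau_mean"``: mean of the smoothed post-stimulus ratio.
    min_points
        Minimum valid timepoints required in each window.
    """

    baseline_s: float = 60.0
    smooth_points: int = 5
    mode: str = "peak"
    min_points: int = 3


def _moving_median(matrix: np.ndarray, window: int) -> np.ndarray:
    """Centered moving median along the time axis, NaN-tolerant at the edges."""
    if window <= 1:
        return matrix
    df = pd.DataFrame(matrix.T)
    smoothed = df.rolling(window, center=True, min_periods=1).median()
    return smoothed.to_numpy().T


def compute_amplitudes(
    ratio_traces: RatioTraces,
    stimulus_time: float,
    config: AmplitudeConfig | None = None,
) -> pd.DataFrame:
    """Per-cell signal amplitude: post-stimulus extremum minus baseline mean.

    Returns a frame with columns ``cell_id, amplitude, baseline, valid,
    reason``; cells with fewer than ``min_points`` valid timepoints in either
    window are excluded with a reason.  Amplitudes may be negative.
    """
    config = config or AmplitudeConfig()
    t = ratio_traces.times
    base_mask = (t >= stimulus_time - config.baseline_s) & (t < stimulus_time)
    resp_mask = t > stimulus_time
    ratios = ratio_traces.ratios
    smoothed = _moving_median(ratios, config.smooth_points)

    baseline_counts = np.sum(~np.isnan(ratios[:, base_mask]), axis=1)
    response_counts = np.sum(~np.isnan(ratios[:, resp_mask]), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        baseline = np.nanmean(ratios[:, base_mask], axis=1)
        if config.mode == "peak":
            response = np.nanmax(smoothed[:, resp_mask], axis=1)
        elif config.mode == "plateau_mean":
            response = np.nanmean(smoothed[:, resp_mask], axis=1)
        else:
            raise ValueError(f"unknown amplitude mode {config.mode!r}")

    valid = (baseline_counts >= config.min_points) & (
        response_counts >= config.min_points
    )
    amplitude = np.where(valid, response - baseline, np.nan)
    reasons = np.where(
        valid,
        "",
        np.where(
            baseline_counts < config.min_points,
            "insufficient baseline points",
            "insufficient response points",
        ),
    )
    return pd.DataFrame(
        {
            "cell_id": ratio_traces.cell_ids,
            "amplitude": amplitude,
            "baseline": baseline,
            "valid": valid,
            "reason": reasons,
        }
    )
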