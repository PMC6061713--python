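"""Synthetic study data with known ground truth.

Two generators mirror the two experimental arms:

* :func:`generate_paralog_families` builds an ungapped paralog/ortholog
  alignment (three paralogs across a species panel) with *planted*
  group-specific positions — columns where the sensitive paralogs all carry
  one residue and the insensitive paralog a different one — and returns the
  planted truth alongside, so the differential screen can be validated
  exactly.
* :func:`generate_trace_set` emits per-cell two-channel Fura-2 recordings
  with a known response amplitude relative to wild type: the true ratio sits
  at a baseline before ligand application and, for responder cells, rises
  linearly over a configurable rise time to a sustained plateau whose height
  is ``wt_delta_ratio x amplitude_scale``.  Channels carry additive constant
  background and Gaussian noise; a no-cell background ROI is emitted per
  recording; YFP expression intensities are log-normal so gating has
  something to gate on.

All randomness flows from the explicit ``seed`` of each config; identical
configs produce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment import AMINO_ACIDS, AlignedRecord, ParalogAlignment
from .traces import BACKGROUND_ID, TraceSet

DEFAULT_SPECIES = (
    "Dmel",
    "Dsim",
    "Dyak",
    "Agam",
    "Aaeg",
    "Cqui",
    "Bmor",
    "Tcas",
    "Amel",
    "Nvit",
)


@dataclass
class SequenceGenConfig:
    """Parameters of the planted-truth alignment generator.

    per_site_substitution_rate is the probability, per unplanted site and per
    terminal lineage, of drawing a residue different from the ancestor.
    """

    n_species: int = 10
    paralogs: tuple[str, ...] = ("TRPL", "TRPgamma", "TRP")
    sensitive_paralogs: tuple[str, ...] = ("TRPL", "TRPgamma")
    insensitive_paralog: str = "TRP"
    seq_length: int = 200
    n_planted_differential: int = 10
    n_planted_background_conserved: int = 0
    per_site_substitution_rate: float = 0.0
    planted_positions: tuple[int, ...] | None = None  # 1-based; overrides random draw
    seed: int = 0

    def validate(self) -> None:
        if self.n_species < 1 or self.seq_length < 1:
            raise ValueError("n_species and seq_length must be positive")
        if not 0.0 <= self.per_site_substitution_rate <= 1.0:
            raise ValueError("per_site_substitution_rate must lie in [0, 1]")
        n_planted = (
            len(self.planted_positions)
            if self.planted_positions is not None
            else self.n_planted_differential
        )
        if n_planted + self.n_planted_background_conserved > self.seq_length:
            raise ValueError(
                f"infeasible config: {n_planted} differential + "
                f"{self.n_planted_background_conserved} background-conserved "
                f"positions exceed sequence length {self.seq_length}"
            )
        if self.planted_positions is not None:
            bad = [p for p in self.planted_positions if not 1 <= p <= self.seq_length]
            if bad:
                raise ValueError(f"planted positions outside sequence: {bad}")
        if not set(self.sensitive_paralogs) <= set(self.paralogs):
            raise ValueError("sensitive_paralogs must be a subset of paralogs")
        if self.insensitive_paralog not in self.paralogs:
            raise ValueError("insensitive_paralog must be one of paralogs")


@dataclass
class PlantedTruth:
    """Ground truth of an emitted alignment: where and what was planted."""

    differential_positions: frozenset[int]
    sensitive_residue: dict[int, str]
    insensitive_residue: dict[int, str]
    background_conserved_positions: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        for pos in self.differential_positions:
            s, i = self.sensitive_residue[pos], self.insensitive_residue[pos]
            if s == i:
                raise ValueError(
                    f"planted position {pos} has identical sensitive/insensitive "
                    f"residue {s!r}"
                )


def _species_labels(n: int) -> list[str]:
    labels = list(DEFAULT_SPECIES[:n])
    labels += [f"sp{i:02d}" for i in range(len(labels) + 1, n + 1)]
    return labels


def generate_paralog_families(
    config: SequenceGenConfig,
) -> tuple[ParalogAlignment, PlantedTruth]:
    """Generate an ungapped paralog x species alignment with planted truth.

    Planted differential positions are held fixed (one residue across the
    sensitive group, a different one across the insensitive paralog);
    background-conserved positions are held fixed in every sequence;
    remaining sites substitute independently per lineage at the configured
    rate.  Column ``i`` corresponds to reference position ``i + 1``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    aa = np.array(list(AMINO_ACIDS))
    length = config.seq_length

    ancestor = rng.choice(len(aa), size=length)

    all_positions = np.arange(1, length + 1)
    if config.planted_positions is not None:
        diff_pos = np.array(sorted(set(config.planted_positions)), int)
    else:
        diff_pos = np.sort(
            rng.choice(all_positions, size=config.n_planted_differential, replace=False)
        )
    remaining = np.setdiff1d(all_positions, diff_pos)
    bg_pos = np.sort(
        rng.choice(
            remaining, size=config.n_planted_background_conserved, replace=False
        )
    )

    # Planted residues: sensitive group keeps the ancestor residue; the
    # insensitive paralog gets a distinct one.
    sensitive_res = {int(p): str(aa[ancestor[p - 1]]) for p in diff_pos}
    insensitive_res = {}
    for p in diff_pos:
        shift = rng.integers(1, len(aa))
        insensitive_res[int(p)] = str(aa[(ancestor[p - 1] + shift) % len(aa)])

    frozen = np.zeros(length, bool)
    frozen[diff_pos - 1] = True
    frozen[bg_pos - 1] = True

    species = _species_labels(config.n_species)
    records = []
    for paralog in config.paralogs:
        is_insensitive = paralog == config.insensitive_paralog
        for sp in species:
            idx = ancestor.copy()
            mutate = (~frozen) & (
                rng.random(length) < config.per_site_substitution_rate
            )
            # substitute with a residue different from the current one
            shifts = rng.integers(1, len(aa), size=length)
            idx[mutate] = (idx[mutate] + shifts[mutate]) % len(aa)
            seq = aa[idx]
            for p in diff_pos:
                seq[p - 1] = (
                    insensitive_res[int(p)] if is_insensitive else sensitive_res[int(p)]
                )
            records.append(AlignedRecord(sp, paralog, "".join(seq)))

    reference_id = f"{species[0]}|{config.sensitive_paralogs[0]}"
    alignment = ParalogAlignment(records=records, reference_id=reference_id)
    truth = PlantedTruth(
        differential_positions=frozenset(int(p) for p in diff_pos),
        sensitive_residue=sensitive_res,
        insensitive_residue=insensitive_res,
        background_conserved_positions=frozenset(int(p) for p in bg_pos),
    )
    return alignment, truth


@dataclass
class ConstructSpec:
    """One simulated construct: its label, ligand, effect size and cell count."""

    construct: str
    ligand: str
    amplitude_scale: float  # response height relative to wild type (WT = 1.0)
    n_cells: int

    def validate(self) -> None:
        if self.amplitude_scale < 0:
            raise ValueError(f"{self.construct!r}: amplitude_scale must be >= 0")
        if self.n_cells < 1:
            raise ValueError(f"{self.construct!r}: n_cells must be >= 1")


@dataclass
class TraceGenConfig:
    """Parameters of the single-cell Fura-2 trace generator.

    Units: seconds for times, arbitrary fluorescence units for channel
    levels, dimensionless for ratios.  ``wt_delta_ratio`` is the plateau
    height (ratio units) a full wild-type response adds over baseline;
    each construct scales it by its ``amplitude_scale``.
    """

    constructs: list[ConstructSpec] = field(default_factory=list)
    stimulus_time: float = 60.0
    sampling_interval: float = 2.0
    total_duration: float = 360.0
    rise_time: float = 30.0
    baseline_ratio: float = 1.0
    wt_delta_ratio: float = 0.8
    responder_fraction: float = 0.9
    noise_sd: float = 2.0  # per channel, fluorescence units
    background_level: float = 10.0  # additive, per channel
    f380_baseline: float = 200.0  # cellular F380 signal before correction
    yfp_log_mean: float = 5.0
    yfp_log_sd: float = 0.5
    ligand_concentration_um: float = 40.0  # annotation: supramaximal application
    seed: int = 0

    def validate(self) -> None:
        if not self.constructs:
            raise ValueError("at least one construct is required")
        if self.sampling_interval <= 0 or self.total_duration <= 0:
            raise ValueError("durations and intervals must be positive")
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ValueError("responder_fraction must lie in [0, 1]")
        if not 0.0 <= self.stimulus_time < self.total_duration:
            raise ValueError("stimulus_time must fall within the recording")
        if self.rise_time < 0 or self.noise_sd < 0 or self.background_level < 0:
            raise ValueError("rise_time, noise_sd and background_level must be >= 0")
        for spec in self.constructs:
            spec.validate()


def _response_profile(
    times: np.ndarray, config: TraceGenConfig, delta: float
) -> np.ndarray:
    """Baseline, then linear rise over rise_time to a sustained plateau."""
    after = np.clip(times - config.stimulus_time, 0.0, None)
    if config.rise_time > 0:
        ramp = np.clip(after / config.rise_time, 0.0, 1.0)
    else:
        ramp = (after > 0).astype(float)
    return config.baseline_ratio + delta * ramp


def generate_trace_set(config: TraceGenConfig) -> TraceSet:
    """Simulate per-cell F340/F380 series for every configured construct.

    The true per-cell ratio follows the rise-and-plateau profile (flat for
    non-responders drawn per cell from Bernoulli(responder_fraction)); F380
    is a constant cellular signal, F340 = ratio x F380, and both measured
    channels add the constant background plus Gaussian noise.  One no-cell
    BACKGROUND series per recording carries background plus noise only.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    times = np.arange(0.0, config.total_duration + 1e-9, config.sampling_interval)
    frames = []
    for spec in config.constructs:
        responders = rng.random(spec.n_cells) < config.responder_fraction
        yfp = rng.lognormal(config.yfp_log_mean, config.yfp_log_sd, size=spec.n_cells)
        delta = config.wt_delta_ratio * spec.amplitude_scale
        profile = _response_profile(times, config, delta)
        flat = np.full_like(times, config.baseline_ratio)
        for i in range(spec.n_cells):
            ratio_true = profile if responders[i] else flat
            f380_true = np.full_like(times, config.f380_baseline)
            f340_true = ratio_true * f380_true
            f340 = (
                f340_true
                + config.background_level
                + rng.normal(0.0, config.noise_sd, size=times.size)
            )
            f380 = (
                f380_true
                + config.background_level
                + rng.normal(0.0, config.noise_sd, size=times.size)
            )
            frames.append(
                pd.DataFrame(
                    {
                        "construct": spec.construct,
                        "ligand": spec.ligand,
                        "cell_id": f"cell{i + 1:04d}",
                        "time_s": times,
                        "f340": np.clip(f340, 0.0, None),
                        "f380": np.clip(f380, 0.0, None),
                        "yfp": yfp[i],
                    }
                )
            )
        bg340 = config.background_level + rng.normal(0.0, config.noise_sd, times.size)
        bg380 = config.background_level + rng.normal(0.0, config.noise_sd, times.size)
        frames.append(
            pd.DataFrame(
                {
                    "construct": spec.construct,
                    "ligand": spec.ligand,
                    "cell_id": BACKGROUND_ID,
                    "time_s": times,
                    "f340": np.clip(bg340, 0.0, None),
                    "f380": np.clip(bg380, 0.0, None),
                    "yfp": np.nan,
                }
            )
        )
    data = pd.concat(frames, ignore_index=True)
    return TraceSet(
        data=data,
        stimulus_time=config.stimulus_time,
        ligand_concentration_um=config.ligand_concentration_um,
    )
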