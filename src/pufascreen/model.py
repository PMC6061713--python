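"""Construct-level modelling of PUFA-evoked calcium responses.

:class:`PufaResponseModel` is built from a :class:`~pufascreen.traces.TraceSet`
and, on :meth:`~PufaResponseModel.fit`, runs the full quantification chain
(background correction and ratio, expression gating, per-cell amplitude) and
estimates per-construct statistics: mean amplitude +/- SEM, the WT-normalized
percentage (WT = 100 by definition), and an unpaired two-sample t test
against the wild type.  The returned :class:`PufaScreenResults` carries the
estimates and exposes the two downstream decision rules:

* the functional classification — a construct is called *required for PUFA
  activation* when its WT-normalized amplitude is reduced by strictly more
  than 50% (configurable threshold);
* the ligand-discrimination call — a construct discriminates between the two
  agonists when its ETI-minus-ETYA normalized difference is large while the
  ETYA response is lost (>50% reduction) and the ETI response retained.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .traces import (
    AmplitudeConfig,
    GatingConfig,
    RatioTraces,
    TraceSet,
    background_correct_and_ratio,
    compute_amplitudes,
    load_traces,
    select_cells,
)

SIGNIFICANCE_ALPHA = 0.05


@dataclass
class ConstructSummary:
    """Amplitude statistics of one construct under one ligand."""

    construct: str
    ligand: str
    n_cells: int
    mean_amplitude: float
    sem: float
    normalized_percent: float | None
    t_statistic: float | None = None
    p_value: float | None = None

    @property
    def significant(self) -> bool | None:
        if self.p_value is None:
            return None
        return self.p_value <= SIGNIFICANCE_ALPHA


@dataclass
class MutantCall:
    """Outcome of the strict >50%-reduction functional classification."""

    construct: str
    ligand: str
    normalized_percent: float
    reduction_percent: float
    required_for_pufa_activation: bool
    threshold_used: float = 50.0


@dataclass
class DiscriminationRule:
    """Thresholds of the ETI-versus-ETYA discrimination call.

    A construct discriminates when the ETI-minus-ETYA normalized difference
    reaches ``min_difference`` percentage points, the ETYA response is
    reduced by strictly more than ``reduction_threshold`` percent, and the
    ETI response is not.
    """

    min_difference: float = 30.0
    reduction_threshold: float = 50.0


@dataclass
class DiscriminationResult:
    """Ligand-discrimination outcome for one construct."""

    construct: str
    normalized_percent_etya: float
    normalized_percent_eti: float
    difference: float  # ETI - ETYA, percentage points
    discriminating: bool
    rule: DiscriminationRule


def summarize_construct(
    amplitudes: Sequence[float] | np.ndarray,
    construct: str,
    ligand: str,
    wt_summary: ConstructSummary | None = None,
) -> ConstructSummary:
    """Mean, SEM (sd/sqrt(n)) and WT-normalized percentage of one construct.

    With ``wt_summary=None`` the construct *is* the wild type and its
    normalized percentage is exactly 100.  Normalization against a
    non-positive WT mean is refused.
    """
    amps = np.asarray(amplitudes, float)
    amps = amps[~np.isnan(amps)]
    if amps.size == 0:
        raise ValueError(f"no valid amplitudes for construct {construct!r}")
    mean = float(np.mean(amps))
    sem = float(np.std(amps, ddof=1) / np.sqrt(amps.size)) if amps.size > 1 else 0.0
    if wt_summary is None:
        normalized = 100.0
    else:
        if wt_summary.mean_amplitude <= 0:
            raise ValueError(
                f"cannot normalize {construct!r}: WT mean amplitude "
                f"{wt_summary.mean_amplitude} is not positive"
            )
        normalized = 100.0 * mean / wt_summary.mean_amplitude
    return ConstructSummary(
        construct=construct,
        ligand=ligand,
        n_cells=int(amps.size),
        mean_amplitude=mean,
        sem=sem,
        normalized_percent=normalized,
    )


def compare_to_wt(
    mutant_amplitudes: Sequence[float] | np.ndarray,
    wt_amplitudes: Sequence[float] | np.ndarray,
    equal_var: bool = True,
) -> tuple[float, float]:
    """Two-sided unpaired two-sample t test (pooled variance by default).

    Degenerate zero-variance samples follow the convention p = 1 when the
    means are equal and p = 0 otherwise.
    """
    a = np.asarray(mutant_amplitudes, float)
    b = np.asarray(wt_amplitudes, float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least two observations")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        return (np.inf if np.mean(a) > np.mean(b) else -np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def classify_mutant(summary: ConstructSummary, threshold: float = 50.0) -> MutantCall:
    """Strict >threshold%-reduction rule; a reduction of exactly 50% is *not* called."""
    if summary.normalized_percent is None:
        raise ValueError(f"construct {summary.construct!r} has no normalized percent")
    reduction = 100.0 - summary.normalized_percent
    return MutantCall(
        construct=summary.construct,
        ligand=summary.ligand,
        normalized_percent=summary.normalized_percent,
        reduction_percent=reduction,
        required_for_pufa_activation=reduction > threshold,
        threshold_used=threshold,
    )


def discrimination_score(
    summary_etya: ConstructSummary,
    summary_eti: ConstructSummary,
    rule: DiscriminationRule | None = None,
    etya_label: str = "ETYA",
    eti_label: str = "ETI",
) -> DiscriminationResult:
    """ETI-minus-ETYA difference of normalized amplitudes and the discrimination call."""
    rule = rule or DiscriminationRule()
    if summary_etya.construct != summary_eti.construct:
        raise ValueError(
            f"construct mismatch: {summary_etya.construct!r} vs {summary_eti.construct!r}"
        )
    if summary_etya.ligand != etya_label or summary_eti.ligand != eti_label:
        raise ValueError(
            f"ligand labels mismatched: got ({summary_etya.ligand!r}, "
            f"{summary_eti.ligand!r}), expected ({etya_label!r}, {eti_label!r})"
        )
    etya = summary_etya.normalized_percent
    eti = summary_eti.normalized_percent
    if etya is None or eti is None:
        raise ValueError("both summaries must carry a normalized percentage")
    difference = eti - etya
    discriminating = (
        difference >= rule.min_difference
        and (100.0 - etya) > rule.reduction_threshold
        and (100.0 - eti) <= rule.reduction_threshold
    )
    return DiscriminationResult(
        construct=summary_etya.construct,
        normalized_percent_etya=etya,
        normalized_percent_eti=eti,
        difference=difference,
        discriminating=discriminating,
        rule=rule,
    )


_MUTANT_RE = re.compile(r"^(?:TRPL-)?([A-Z])(\d+)([A-Z])$")


def mutated_position(construct: str) -> int | None:
    """Reference position encoded in a single-mutant label like ``F467Y``; else None."""
    m = _MUTANT_RE.match(construct)
    return int(m.group(2)) if m else None


class PufaResponseModel:
    """Per-construct response model over a single-cell Fura-2 trace set.

    Parameters
    ----------
    trace_set
        Validated single-cell trace table (see :class:`~pufascreen.traces.TraceSet`).
    wt_construct
        Label of the wild-type construct every other construct is normalized
        against (per ligand); it must be present for every ligand at fit time.
    gating, amplitude
        Expression-gating and amplitude-operator configuration.
    equal_var
        Pooled-variance (classic unpaired) t test when True; Welch otherwise.

    Examples
    --------
    >>> model = PufaResponseModel.from_csv("traces.csv", stimulus_time=60.0)
    >>> results = model.fit()
    >>> print(results.summary())
    """

    def __init__(
        self,
        trace_set: TraceSet,
        wt_construct: str = "TRPL-WT",
        gating: GatingConfig | None = None,
        amplitude: AmplitudeConfig | None = None,
        equal_var: bool = True,
        eps: float = 1e-6,
    ) -> None:
        self.trace_set = trace_set
        self.wt_construct = wt_construct
        self.gating = gating or GatingConfig()
        self.amplitude = amplitude or AmplitudeConfig()
        self.equal_var = equal_var
        self.eps = eps

    @classmethod
    def from_csv(
        cls, path: str | Path, stimulus_time: float, **kwargs
    ) -> "PufaResponseModel":
        return cls(load_traces(path, stimulus_time=stimulus_time), **kwargs)

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, stimulus_time: float, **kwargs
    ) -> "PufaResponseModel":
        return cls(TraceSet(data=data, stimulus_time=stimulus_time), **kwargs)

    def fit(self) -> "PufaScreenResults":
        """Run the quantification chain and estimate per-construct statistics."""
        ratio_groups = background_correct_and_ratio(self.trace_set, eps=self.eps)
        gated = [select_cells(g, self.gating) for g in ratio_groups]
        amp_frames = []
        amp_by_group: dict[tuple[str, str], np.ndarray] = {}
        for g in gated:
            amps = compute_amplitudes(g, self.trace_set.stimulus_time, self.amplitude)
            amps.insert(0, "construct", g.construct)
            amps.insert(1, "ligand", g.ligand)
            amp_frames.append(amps)
            values = amps.loc[amps["valid"], "amplitude"].to_numpy(float)
            amp_by_group[(g.construct, g.ligand)] = values

        ligands = {lig for _, lig in amp_by_group}
        for lig in ligands:
            if (self.wt_construct, lig) not in amp_by_group:
                raise ValueError(
                    f"wild-type construct {self.wt_construct!r} missing for "
                    f"ligand {lig!r}; normalization impossible"
                )

        summaries: list[ConstructSummary] = []
        for (construct, ligand), values in amp_by_group.items():
            wt_values = amp_by_group[(self.wt_construct, ligand)]
            if construct == self.wt_construct:
                summary = summarize_construct(values, construct, ligand, None)
                summary.t_statistic, summary.p_value = 0.0, 1.0
            else:
                wt_summary = summarize_construct(
                    wt_values, self.wt_construct, ligand, None
                )
                summary = summarize_construct(values, construct, ligand, wt_summary)
                summary.t_statistic, summary.p_value = compare_to_wt(
                    values, wt_values, equal_var=self.equal_var
                )
            summaries.append(summary)

        return PufaScreenResults(
            model=self,
            summaries=summaries,
            amplitudes=pd.concat(amp_frames, ignore_index=True),
            ratio_traces=gated,
        )


class PufaScreenResults:
    """Fitted per-construct estimates with classification and discrimination.

    Attributes
    ----------
    summaries
        :class:`ConstructSummary` per (construct, ligand).
    amplitudes
        Tidy per-cell amplitude table (construct, ligand, cell_id, amplitude,
        baseline, valid, reason).
    ratio_traces
        Gated per-group ratio traces, kept for plotting/diagnostics.
    """

    def __init__(
        self,
        model: PufaResponseModel,
        summaries: list[ConstructSummary],
        amplitudes: pd.DataFrame,
        ratio_traces: list[RatioTraces],
    ) -> None:
        self.model = model
        self.summaries = summaries
        self.amplitudes = amplitudes
        self.ratio_traces = ratio_traces

    # -- tabular views ---------------------------------------------------

    @property
    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "construct": [s.construct for s in self.summaries],
                "ligand": [s.ligand for s in self.summaries],
                "n_cells": [s.n_cells for s in self.summaries],
                "mean_amplitude": [s.mean_amplitude for s in self.summaries],
                "sem": [s.sem for s in self.summaries],
                "normalized_percent": [s.normalized_percent for s in self.summaries],
                "t_statistic": [s.t_statistic for s in self.summaries],
                "p_value": [s.p_value for s in self.summaries],
                "significant": [s.significant for s in self.summaries],
            }
        )

    def summary(self) -> str:
        """Human-readable estimates table, one row per construct and ligand."""
        df = self.summary_frame.copy()
        df["mean±SEM"] = [
            f"{m:.3f}±{s:.3f}" for m, s in zip(df["mean_amplitude"], df["sem"])
        ]
        df["% of WT"] = [f"{v:.1f}" for v in df["normalized_percent"]]
        df["p"] = [f"{p:.3g}{'*' if p <= SIGNIFICANCE_ALPHA else ''}" for p in df["p_value"]]
        cols = ["construct", "ligand", "n_cells", "mean±SEM", "% of WT", "p"]
        title = "PUFA-evoked calcium response summary (WT = 100%)"
        body = df[cols].to_string(index=False)
        rule = "=" * max(len(title), body.index("\n") if "\n" in body else len(body))
        return f"{title}\n{rule}\n{body}\n{rule}"

    def get_summary(self, construct: str, ligand: str) -> ConstructSummary:
        for s in self.summaries:
            if s.construct == construct and s.ligand == ligand:
                return s
        raise KeyError(f"no summary for {construct!r}/{ligand!r}")

    # -- decision rules --------------------------------------------------

    def classify(
        self, ligand: str = "ETYA", threshold: float = 50.0, include_wt: bool = False
    ) -> list[MutantCall]:
        """Apply the strict >threshold%-reduction rule to every construct."""
        calls = []
        for s in self.summaries:
            if s.ligand != ligand:
                continue
            if s.construct == self.model.wt_construct and not include_wt:
                continue
            calls.append(classify_mutant(s, threshold=threshold))
        return calls

    def required_positions(
        self, ligand: str = "ETYA", threshold: float = 50.0
    ) -> list[int]:
        """Sorted reference positions of single mutants called required."""
        positions = {
            p
            for call in self.classify(ligand=ligand, threshold=threshold)
            if call.required_for_pufa_activation
            and (p := mutated_position(call.construct)) is not None
        }
        return sorted(positions)

    def discriminate(
        self,
        rule: DiscriminationRule | None = None,
        etya_label: str = "ETYA",
        eti_label: str = "ETI",
    ) -> list[DiscriminationResult]:
        """Pair each construct's ETYA and ETI summaries and score discrimination."""
        rule = rule or DiscriminationRule()
        by_key = {(s.construct, s.ligand): s for s in self.summaries}
        results = []
        for s in self.summaries:
            if s.ligand != etya_label or s.construct == self.model.wt_construct:
                continue
            eti = by_key.get((s.construct, eti_label))
            if eti is None:
                continue
            results.append(
                discrimination_score(
                    s, eti, rule=rule, etya_label=etya_label, eti_label=eti_label
                )
            )
        return results

    # -- diagnostics -----------------------------------------------------

    def mean_trace(self, construct: str, ligand: str) -> pd.DataFrame:
        """Across-cell mean ratio trace +/- SEM (for plotting)."""
        for g in self.ratio_traces:
            if g.construct == construct and g.ligand == ligand:
                mean = np.nanmean(g.ratios, axis=0)
                sem = np.nanstd(g.ratios, axis=0, ddof=1) / np.sqrt(g.n_cells)
                return pd.DataFrame(
                    {"time_s": g.times, "mean_ratio": mean, "sem": sem}
                )
        raise KeyError(f"no ratio traces for {construct!r}/{ligand!r}")

    def plot_mean_traces(self, constructs=None, ligand: str = "ETYA", ax=None):
        """Plot mean ratio traces for the given constructs (matplotlib axes)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        wanted = constructs or sorted(
            {g.construct for g in self.ratio_traces if g.ligand == ligand}
        )
        for construct in wanted:
            tr = self.mean_trace(construct, ligand)
            ax.plot(tr["time_s"], tr["mean_ratio"], label=construct)
            ax.fill_between(
                tr["time_s"],
                tr["mean_ratio"] - tr["sem"],
                tr["mean_ratio"] + tr["sem"],
                alpha=0.2,
            )
        ax.axvline(self.model.trace_set.stimulus_time, ls="--", c="grey", lw=0.8)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("F340/F380 ratio")
        ax.legend(fontsize="small")
        return ax
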