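"""Amplitude operator, construct statistics, classification and discrimination."""

import numpy as np
import pytest

from pufascreen.model import (
    ConstructSummary,
    DiscriminationRule,
    classify_mutant,
    compare_to_wt,
    discrimination_score,
    mutated_position,
    summarize_construct,
)
from pufascreen.traces import AmplitudeConfig, RatioTraces, compute_amplitudes

from oracles import brute_force_pooled_t, brute_force_sem


def _ratio_group(ratios, times=None):
    ratios = np.atleast_2d(np.asarray(ratios, float))
    times = (
        np.arange(ratios.shape[1], dtype=float) if times is None else np.asarray(times)
    )
    return RatioTraces(
        construct="C",
        ligand="ETYA",
        times=times,
        cell_ids=[f"c{i}" for i in range(ratios.shape[0])],
        ratios=ratios,
        yfp=np.full(ratios.shape[0], 100.0),
    )


class TestAmplitudeOperator:
    def test_noiseless_step_to_plateau(self):
        trace = [1.0] * 10 + [1.8] * 10
        group = _ratio_group(trace)
        amps = compute_amplitudes(group, stimulus_time=9.5)
        assert amps["amplitude"].iloc[0] == pytest.approx(0.8)

    def test_flat_trace_zero_amplitude(self):
        group = _ratio_group([1.0] * 20)
        amps = compute_amplitudes(group, stimulus_time=9.5)
        assert amps["amplitude"].iloc[0] == pytest.approx(0.0)

    def test_negative_deflection_kept_negative(self):
        trace = [1.0] * 10 + [0.6] * 10
        amps = compute_amplitudes(_ratio_group(trace), stimulus_time=9.5)
        assert amps["amplitude"].iloc[0] == pytest.approx(-0.4)

    def test_median_smoothing_suppresses_single_frame_spike(self):
        trace = [1.0] * 10 + [1.2] * 10
        trace[15] = 9.0  # one-frame artefact
        amps = compute_amplitudes(_ratio_group(trace), stimulus_time=9.5)
        assert amps["amplitude"].iloc[0] == pytest.approx(0.2)

    def test_insufficient_baseline_points_excluded_with_reason(self):
        group = _ratio_group([1.0] * 20)
        amps = compute_amplitudes(
            group, stimulus_time=1.5, config=AmplitudeConfig(baseline_s=60.0)
        )
        assert not amps["valid"].iloc[0]
        assert "baseline" in amps["reason"].iloc[0]

    def test_noisy_plateau_within_tolerance_across_100_seeds(self):
        """Ratio noise sd 0.01, true step +0.5: amplitude in [0.47, 0.53]."""
        times = np.arange(0.0, 360.0, 2.0)
        step = np.where(times > 60.0, 1.5, 1.0)
        for seed in range(100):
            rng = np.random.default_rng(seed)
            trace = step + rng.normal(0.0, 0.01, size=times.size)
            amps = compute_amplitudes(_ratio_group(trace, times), stimulus_time=60.0)
            assert 0.47 <= amps["amplitude"].iloc[0] <= 0.53

    def test_plateau_mean_mode(self):
        trace = [1.0] * 10 + [1.8] * 10
        amps = compute_amplitudes(
            _ratio_group(trace),
            stimulus_time=9.5,
            config=AmplitudeConfig(mode="plateau_mean"),
        )
        assert amps["amplitude"].iloc[0] == pytest.approx(0.8, abs=0.05)


class TestSummaries:
    def test_equal_amplitudes_sem_zero_normalized_100(self):
        wt = summarize_construct([0.8, 0.8, 0.8], "TRPL-WT", "ETYA", None)
        s = summarize_construct([0.8, 0.8, 0.8], "M", "ETYA", wt)
        assert s.mean_amplitude == pytest.approx(0.8)
        assert s.sem == pytest.approx(0.0)
        assert s.normalized_percent == pytest.approx(100.0)

    def test_normalized_percent_arithmetic(self):
        wt = summarize_construct([0.8] * 3, "TRPL-WT", "ETYA", None)
        s = summarize_construct([0.24] * 3, "M", "ETYA", wt)
        assert s.normalized_percent == pytest.approx(30.0)

    def test_sem_hand_computed(self):
        s = summarize_construct([1.0, 2.0, 3.0], "M", "ETYA", None)
        assert s.sem == pytest.approx(0.5774, abs=1e-4)

    def test_wt_normalized_exactly_100(self):
        wt = summarize_construct([0.3, 0.9, 0.75], "TRPL-WT", "ETYA", None)
        assert wt.normalized_percent == 100.0

    def test_nonpositive_wt_mean_refused(self):
        wt = summarize_construct([-0.1, 0.1], "TRPL-WT", "ETYA", None)
        with pytest.raises(ValueError, match="not positive"):
            summarize_construct([0.5], "M", "ETYA", wt)

    @pytest.mark.parametrize("seed", range(10))
    def test_sem_matches_brute_force_on_random_samples(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(1.0, 0.4, size=int(rng.integers(2, 11)))
        s = summarize_construct(values, "M", "ETYA", None)
        assert s.sem == pytest.approx(brute_force_sem(list(values)))


class TestCompareToWT:
    def test_identical_samples(self):
        t, p = compare_to_wt([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_textbook_example(self):
        t, p = compare_to_wt([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert p == pytest.approx(0.0214, abs=1e-3)

    def test_zero_variance_equal_means_p_one(self):
        t, p = compare_to_wt([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)

    def test_zero_variance_different_means_p_zero(self):
        t, p = compare_to_wt([3.0, 3.0], [2.0, 2.0])
        assert p == 0.0

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError, match="two observations"):
            compare_to_wt([1.0], [1.0, 2.0])

    def test_significance_boundary_inclusive(self):
        s = ConstructSummary("M", "ETYA", 3, 0.5, 0.1, 60.0, p_value=0.05)
        assert s.significant is True
        s2 = ConstructSummary("M", "ETYA", 3, 0.5, 0.1, 60.0, p_value=0.051)
        assert s2.significant is False

    @pytest.mark.parametrize("seed", range(10))
    def test_t_statistic_matches_brute_force(self, seed):
        rng = np.random.default_rng(100 + seed)
        a = rng.normal(0.5, 0.2, size=int(rng.integers(2, 11)))
        b = rng.normal(0.7, 0.3, size=int(rng.integers(2, 11)))
        t, _ = compare_to_wt(a, b)
        assert t == pytest.approx(brute_force_pooled_t(list(a), list(b)))


def _summary(construct, ligand, normalized):
    return ConstructSummary(construct, ligand, 50, 0.5, 0.05, normalized)


class TestClassification:
    @pytest.mark.parametrize(
        "normalized, required",
        [(45.0, True), (100.0, False), (50.0, False), (49.999, True), (120.0, False)],
    )
    def test_strict_reduction_rule(self, normalized, required):
        call = classify_mutant(_summary("M", "ETYA", normalized))
        assert call.required_for_pufa_activation is required
        assert call.reduction_percent == pytest.approx(100.0 - normalized)

    def test_lowering_amplitude_never_unflags(self):
        # classification is monotone in the normalized amplitude
        flags = [
            classify_mutant(_summary("M", "ETYA", v)).required_for_pufa_activation
            for v in np.linspace(120.0, 0.0, 61)
        ]
        assert flags == sorted(flags)  # False ... False True ... True


class TestDiscrimination:
    def test_etya_lost_eti_retained_discriminates(self):
        r = discrimination_score(
            _summary("I465V", "ETYA", 30.0), _summary("I465V", "ETI", 100.0)
        )
        assert r.difference == pytest.approx(70.0)
        assert r.discriminating

    def test_both_reduced_does_not_discriminate(self):
        r = discrimination_score(
            _summary("F467Y", "ETYA", 30.0), _summary("F467Y", "ETI", 30.0)
        )
        assert r.difference == pytest.approx(0.0)
        assert not r.discriminating

    def test_equal_full_responses_not_discriminating(self):
        r = discrimination_score(
            _summary("M", "ETYA", 100.0), _summary("M", "ETI", 100.0)
        )
        assert r.difference == 0.0
        assert not r.discriminating

    def test_large_difference_without_etya_loss_not_discriminating(self):
        r = discrimination_score(
            _summary("M", "ETYA", 60.0), _summary("M", "ETI", 100.0)
        )
        assert not r.discriminating

    def test_construct_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            discrimination_score(
                _summary("A", "ETYA", 30.0), _summary("B", "ETI", 100.0)
            )

    def test_ligand_label_mismatch_rejected(self):
        with pytest.raises(ValueError, match="ligand"):
            discrimination_score(
                _summary("A", "ETI", 30.0), _summary("A", "ETYA", 100.0)
            )


@pytest.mark.parametrize(
    "label, position",
    [("F467Y", 467), ("TRPL-V438I", 438), ("TRPL-WT", None), ("TRP-complete", None),
     ("WEEV443FEEL", None)],
)
def test_mutated_position_parsing(label, position):
    assert mutated_position(label) == position
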