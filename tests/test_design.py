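"""Trial-schedule generator: cell counts, displacement laws, responders, filters."""

import numpy as np
import pandas as pd
import pytest

from ssdmodels.design import (
    INFINITE_NOISE,
    BlockSpec,
    DisplacementDistributions,
    ExperimentDesign,
    build_schedule,
    continuous_design,
    filter_by_timing,
    get_design,
    human_categorical_design,
    monkey_control_design,
    motor_noise_design,
    read_design,
    read_trial_table,
    respond_categorical,
    respond_continuous,
    write_design,
    write_trial_table,
)
from ssdmodels.continuous import ContinuousObserverParams


class TestDisplacementDistributions:
    def test_invariant_enforced(self):
        with pytest.raises(ValueError):
            DisplacementDistributions(sigma_jump=0.01, sigma_nojump=0.5)
        with pytest.raises(ValueError):
            DisplacementDistributions(sigma_jump=1.5, sigma_nojump=0.0)

    def test_infinite_noise_rejected_in_categorical_design(self):
        block = BlockSpec(prior_label=0.5, cells=(((INFINITE_NOISE, "testing"), (10, 0.5)),))
        with pytest.raises(ValueError, match="continuous"):
            ExperimentDesign(
                design_id="bad",
                displacement=DisplacementDistributions(),
                blocks=(block,),
                timing_mean_ms=-17.25,
                timing_sd_ms=1.8,
            )


class TestBuildSchedule:
    def test_human_session_fractions(self):
        """Per prior: training trials are 32.3% and each testing cell 6.9% of 1300."""
        table = build_schedule(human_categorical_design(), seed=0)
        assert len(table) == 1300
        for prior in (0.9, 0.1):
            train = table[(table.prior_label == prior) & (table.phase == "training")]
            assert len(train) == 420
            assert round(100 * len(train) / len(table), 1) == 32.3
            for noise in (0.25, 0.5):
                test = table[
                    (table.prior_label == prior)
                    & (table.phase == "testing")
                    & (table.noise_sigma_deg == noise)
                ]
                assert len(test) == 90
                assert round(100 * len(test) / len(table), 1) == 6.9

    @pytest.mark.parametrize(
        "design_id", ["human_categorical", "monkey_categorical", "monkey_control",
                      "continuous", "motor_noise"]
    )
    def test_cell_counts_exact_and_seed_reproducible(self, design_id):
        design = get_design(design_id)
        t1 = build_schedule(design, seed=7)
        t2 = build_schedule(design, seed=7)
        pd.testing.assert_frame_equal(t1, t2)
        # exact counts per (prior, noise, phase) cell
        expected = {}
        for block in design.blocks:
            for (noise, phase), (count, _) in block.cells:
                key = (block.prior_label, noise, phase, block.saccade)
                expected[key] = expected.get(key, 0) + count
        observed = (
            t1.groupby(["prior_label", "noise_sigma_deg", "phase", "saccade_made"])
            .size()
            .to_dict()
        )
        assert observed == expected
        # a different seed shuffles order but preserves counts
        t3 = build_schedule(design, seed=8)
        assert not t3["displacement_deg"].equals(t1["displacement_deg"])
        observed3 = (
            t3.groupby(["prior_label", "noise_sigma_deg", "phase", "saccade_made"])
            .size()
            .to_dict()
        )
        assert observed3 == expected

    def test_displacement_law(self):
        """Sample SD of displacements matches the generating widths within 5%."""
        design = motor_noise_design(n_per_cell=4000)
        table = build_schedule(design, seed=3)
        jump_sd = table.loc[table.jumped, "displacement_deg"].std()
        nojump_sd = table.loc[~table.jumped, "displacement_deg"].std()
        assert len(table[table.jumped]) >= 10_000
        assert abs(jump_sd - 2.5) / 2.5 < 0.05
        assert abs(nojump_sd - 0.2) / 0.2 < 0.05

    def test_veridical_jump_probability(self):
        """Empirical jump fraction tracks the cue in training, 0.5 in testing."""
        design = human_categorical_design()
        table = pd.concat(
            [build_schedule(design, seed=s) for s in range(5)], ignore_index=True
        )
        for prior in (0.9, 0.1):
            train = table[(table.prior_label == prior) & (table.phase == "training")]
            se = np.sqrt(prior * (1 - prior) / len(train))
            assert abs(train.jumped.mean() - prior) < 3 * se
            test = table[(table.prior_label == prior) & (table.phase == "testing")]
            se = np.sqrt(0.25 / len(test))
            assert abs(test.jumped.mean() - 0.5) < 3 * se

    def test_direction_field_follows_sign(self):
        table = build_schedule(human_categorical_design(), seed=1)
        with_mask = table.direction_vs_saccade == "with"
        assert (table.loc[with_mask, "displacement_deg"] >= 0).all()
        assert (table.loc[~with_mask, "displacement_deg"] < 0).all()


class TestRespondCategorical:
    def test_constant_one_reports_all_jumped(self):
        table = build_schedule(human_categorical_design(), seed=0)
        out = respond_categorical(table, lambda x, p, n: 1.0, seed=0)
        assert (out.response == 1.0).all()

    def test_half_probability_rate(self):
        table = build_schedule(motor_noise_design(n_per_cell=2000), seed=0)
        out = respond_categorical(table, lambda x, p, n: 0.5, seed=1)
        n = len(out)
        se = np.sqrt(0.25 / n)
        assert abs(out.response.mean() - 0.5) < 3 * se

    def test_invalid_probability_rejected(self):
        table = build_schedule(human_categorical_design(), seed=0)
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            respond_categorical(table, lambda x, p, n: 1.5, seed=0)


class TestRespondContinuous:
    def _params(self, sigma_l):
        return ContinuousObserverParams(
            mu_prior=0.0, sigma_prior=1.0,
            sigma_likelihood_by_noise={0.1: sigma_l, 0.5: sigma_l, 1.0: sigma_l},
        )

    def test_equal_reliability_halves_displacement(self):
        table = build_schedule(continuous_design(), seed=0)
        out = respond_continuous(table, self._params(1.0), report_noise_sd=0.0, seed=0)
        finite = out[out.noise_sigma_deg != INFINITE_NOISE]
        np.testing.assert_allclose(
            finite.response, finite.displacement_deg / 2, atol=1e-12
        )

    def test_infinite_noise_reports_presaccadic_location(self):
        table = build_schedule(continuous_design(), seed=0)
        out = respond_continuous(table, self._params(1.0), report_noise_sd=0.0, seed=0)
        inf = out[out.noise_sigma_deg == INFINITE_NOISE]
        assert len(inf) == 200
        assert (inf.response == 0.0).all()

    def test_vanishing_likelihood_noise_reports_displacement(self):
        table = build_schedule(continuous_design(), seed=0)
        out = respond_continuous(table, self._params(1e-9), report_noise_sd=0.0, seed=0)
        finite = out[out.noise_sigma_deg != INFINITE_NOISE]
        np.testing.assert_allclose(
            finite.response, finite.displacement_deg, atol=1e-6
        )


class TestFilterByTiming:
    @pytest.mark.parametrize(
        "frame_ms,expected_kept", [(8.33, 1), (16.7, 2)]
    )
    def test_threshold_enumeration(self, frame_ms, expected_kept):
        table = build_schedule(human_categorical_design(), seed=0).head(3).copy()
        table["jump_cmd_to_saccade_end_ms"] = [-20.0, -10.0, -5.0]
        out = filter_by_timing(table, frame_ms=frame_ms)
        assert len(out) == expected_kept
        assert out.attrs["n_excluded_by_timing"] == 3 - expected_kept

    def test_nothing_removed_when_all_late(self):
        table = build_schedule(human_categorical_design(), seed=0).copy()
        table["jump_cmd_to_saccade_end_ms"] = -5.0
        out = filter_by_timing(table, frame_ms=8.33)
        assert len(out) == len(table)

    def test_missing_timing_rejected(self):
        table = build_schedule(human_categorical_design(), seed=0).copy()
        table.loc[0, "jump_cmd_to_saccade_end_ms"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            filter_by_timing(table, frame_ms=8.33)


class TestSerialization:
    def test_trial_table_roundtrip(self, tmp_path):
        table = build_schedule(continuous_design(), seed=2)
        path = tmp_path / "trials.csv"
        write_trial_table(table, path)
        back = read_trial_table(path)
        assert list(back.columns) == list(table.columns)
        assert (back.noise_sigma_deg == table.noise_sigma_deg).all()
        np.testing.assert_allclose(back.displacement_deg, table.displacement_deg)

    def test_design_roundtrip(self, tmp_path):
        design = monkey_control_design()
        path = tmp_path / "design.yaml"
        write_design(design, path)
        back = read_design(path)
        assert back == design
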