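import numpy as np
import pandas as pd
import pytest

from priorityfx.core_model import aggregate_performance, validate_design
from priorityfx.errors import InvalidInputError
from priorityfx.priority_indices import compute_all_indices, relative_index
from priorityfx.synthetic_data import (
    EffectSpec,
    expected_indices,
    generate_experiment,
    paper_like_spec,
    recovery_study,
)


class TestEffectSpecValidation:
    def test_preset_is_valid(self, default_spec):
        default_spec.validate()

    def test_invalid_fields_are_named(self, default_spec):
        spec = EffectSpec(
            baseline_mean={**default_spec.baseline_mean, ("grass", "G"): -1.0},
            arrival_multipliers=default_spec.arrival_multipliers,
            p_fix=1.5,
        )
        with pytest.raises(InvalidInputError) as err:
            spec.validate()
        assert "baseline_mean" in str(err.value)
        assert "p_fix" in str(err.value)

    def test_missing_baseline_is_reported(self, default_spec):
        incomplete = dict(default_spec.baseline_mean)
        del incomplete[("legume", "GL")]
        spec = EffectSpec(
            baseline_mean=incomplete,
            arrival_multipliers=default_spec.arrival_multipliers,
        )
        with pytest.raises(InvalidInputError, match="legume"):
            spec.validate()


class TestGenerateExperiment:
    def test_default_design_is_complete(self, default_spec):
        frame = generate_experiment(default_spec, seed=0)
        report = validate_design(frame)
        assert report.ok and report.n_pots == 40

    def test_byte_identical_reproducibility(self, default_spec, tmp_path):
        a = generate_experiment(default_spec, seed=123)
        b = generate_experiment(default_spec, seed=123)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        a.to_csv(pa, index=False)
        b.to_csv(pb, index=False)
        assert pa.read_bytes() == pb.read_bytes()

    def test_different_seeds_differ(self, default_spec):
        a = generate_experiment(default_spec, seed=1)
        b = generate_experiment(default_spec, seed=2)
        assert not np.allclose(
            a["shoot_dry_weight"].to_numpy(), b["shoot_dry_weight"].to_numpy()
        )

    def test_noise_free_mode_is_deterministic_at_the_means(self, default_spec):
        spec = default_spec.without_noise()
        frame = generate_experiment(spec, seed=0)
        for _, row in frame.iterrows():
            assert row["shoot_dry_weight"] == pytest.approx(
                spec.mean_biomass(row["group"], row["arrival"], row["composition"])
            )

    def test_percent_n_stays_inside_bounds(self, default_spec):
        frame = generate_experiment(
            paper_like_spec(npercent_sd=3.0), seed=11
        )
        assert (frame["n_percent"] > 0).all()
        assert (frame["n_percent"] < 100).all()


class TestExpectedIndices:
    def test_simple_multiplier_arithmetic(self, default_spec):
        truth = expected_indices(default_spec).set_index(
            ["kind", "origin", "composition"]
        )["value"]
        # B_E in G: exotic Early multiplier 2.4 vs Sync1 baseline
        assert truth[("B", "E", "G")] == pytest.approx(relative_index(2.4, 1.0))
        # P_E in G: 0.04 ratio against the Sync2 control
        assert truth[("P", "E", "G")] == pytest.approx(
            relative_index(0.04, 1.0)
        )
        assert truth[("P", "E", "G")] == pytest.approx(-0.9231, abs=5e-4)

    def test_symmetric_multipliers_give_antisymmetric_indices(self, default_spec):
        k = 3.0
        up = paper_like_spec()
        spec_up = EffectSpec(
            baseline_mean=up.baseline_mean,
            arrival_multipliers={("exotic", "Early", "G"): k},
        )
        spec_down = EffectSpec(
            baseline_mean=up.baseline_mean,
            arrival_multipliers={("exotic", "Early", "G"): 1.0 / k},
        )
        t_up = expected_indices(spec_up).set_index(
            ["kind", "origin", "composition"]
        )["value"][("B", "E", "G")]
        t_down = expected_indices(spec_down).set_index(
            ["kind", "origin", "composition"]
        )["value"][("B", "E", "G")]
        assert t_up == pytest.approx(-t_down)

    def test_all_multipliers_one_gives_all_zero(self, default_spec):
        spec = EffectSpec(
            baseline_mean=default_spec.baseline_mean, arrival_multipliers={}
        )
        truth = expected_indices(spec)
        assert np.allclose(truth["value"].to_numpy(), 0.0)


class TestPipelineRecovery:
    def test_noise_free_pipeline_equals_truth_exactly(self, default_spec):
        spec = default_spec.without_noise()
        matrix = aggregate_performance(generate_experiment(spec, seed=0))
        tidy = compute_all_indices(matrix)
        got = tidy.groupby(["kind", "origin", "composition"])["value"].mean()
        truth = expected_indices(spec).set_index(
            ["kind", "origin", "composition"]
        )["value"]
        for key in truth.index:
            assert got[key] == pytest.approx(truth[key], abs=1e-12)

    def test_noise_free_recovery_study_zero_bias(self, default_spec):
        report = recovery_study(
            default_spec.without_noise(), n_simulations=3, seed=0
        )
        assert np.allclose(report.summary["bias"].to_numpy(), 0.0, atol=1e-12)
        assert np.allclose(report.summary["coverage"].to_numpy(), 1.0)

    def test_recovery_study_shapes_and_mc_se(self, default_spec):
        report = recovery_study(default_spec, n_simulations=20, seed=1)
        assert len(report.summary) == 8
        assert (report.summary["bias_mc_se"] > 0).all()
        assert report.summary["coverage"].between(0, 1).all()

    def test_too_few_simulations_rejected(self, default_spec):
        with pytest.raises(InvalidInputError):
            recovery_study(default_spec, n_simulations=1)
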