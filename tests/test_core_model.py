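import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from priorityfx.core_model import (
    PotRecord,
    aggregate_performance,
    percent_change,
    records_to_frame,
    validate_design,
)
from priorityfx.errors import (
    InvalidInputError,
    ParseError,
    UndefinedReferenceError,
)


def make_record(**kwargs):
    defaults = dict(
        pot_id="GL-Sync1-1",
        composition="GL",
        arrival="Sync1",
        replicate=1,
        group="grass",
        shoot_dry_weight=1.0,
    )
    defaults.update(kwargs)
    return PotRecord(**defaults)


class TestPotRecord:
    def test_rejects_illegal_levels(self):
        with pytest.raises(ParseError, match="composition"):
            make_record(composition="XL")
        with pytest.raises(ParseError, match="arrival"):
            make_record(arrival="Sync3")
        with pytest.raises(ParseError, match="group"):
            make_record(group="forb")

    def test_rejects_out_of_range_measurements(self):
        with pytest.raises(InvalidInputError):
            make_record(shoot_dry_weight=-0.1)
        with pytest.raises(InvalidInputError):
            make_record(n_percent=120.0)
        with pytest.raises(InvalidInputError):
            make_record(n_percent=60.0, c_percent=50.0)


class TestValidateDesign:
    def test_full_design_has_no_flags(self, noise_free_frame):
        report = validate_design(noise_free_frame)
        assert report.ok
        assert report.n_pots == 40
        assert set(report.cell_counts.values()) == {5}
        assert len(report.cell_counts) == 8

    def test_missing_pot_flags_exactly_one_cell(self, noise_free_frame):
        frame = noise_free_frame.loc[
            noise_free_frame["pot_id"] != "G-Late-3"
        ].reset_index(drop=True)
        report = validate_design(frame)
        assert len(report.flags) == 1
        assert "(G, Late)" in report.flags[0]
        assert "4 replicates" in report.flags[0]
        assert report.cell_counts[("G", "Late")] == 4

    def test_legume_in_grasses_only_composition_is_flagged(self, noise_free_frame):
        bad = records_to_frame(
            [make_record(pot_id="G-Sync1-1", composition="G", group="legume")]
        )
        frame = pd.concat([noise_free_frame, bad], ignore_index=True)
        report = validate_design(frame)
        assert any("legume record inside" in f for f in report.flags)

    def test_duplicate_pot_group_is_flagged(self, noise_free_frame):
        frame = pd.concat(
            [noise_free_frame, noise_free_frame.iloc[[0]]], ignore_index=True
        )
        report = validate_design(frame)
        assert any("duplicate" in f for f in report.flags)

    def test_empty_input_raises(self):
        with pytest.raises(InvalidInputError):
            validate_design([])

    def test_input_not_mutated(self, noise_free_frame):
        before = noise_free_frame.copy()
        validate_design(noise_free_frame)
        pd.testing.assert_frame_equal(before, noise_free_frame)


class TestAggregatePerformance:
    def test_native_total_is_grass_plus_legume(self):
        records = [
            make_record(group="grass", shoot_dry_weight=2.0),
            make_record(group="legume", shoot_dry_weight=3.0),
            make_record(group="exotic", shoot_dry_weight=1.0),
        ]
        matrix = aggregate_performance(records)
        assert matrix.get("GL", "Sync1", "N").iloc[0] == pytest.approx(5.0)
        assert matrix.get("GL", "Sync1", "E").iloc[0] == pytest.approx(1.0)

    def test_native_total_additivity_on_full_design(self, noisy_frame):
        matrix = aggregate_performance(noisy_frame)
        data = matrix.data
        for comp in ("G", "GL"):
            for arr in ("Early", "Late", "Sync1", "Sync2"):
                n = matrix.get(comp, arr, "N")
                grass = matrix.get(comp, arr, "grass")
                expected = grass.copy()
                if comp == "GL":
                    expected = grass + matrix.get(comp, arr, "legume")
                assert np.allclose(n.to_numpy(), expected.to_numpy())

    def test_grasses_only_native_equals_grass(self):
        records = [
            make_record(pot_id="G-Sync1-1", composition="G", group="grass",
                        shoot_dry_weight=4.5),
            make_record(pot_id="G-Sync1-1", composition="G", group="exotic",
                        shoot_dry_weight=2.0),
        ]
        matrix = aggregate_performance(records)
        assert matrix.get("G", "Sync1", "N").iloc[0] == pytest.approx(4.5)

    def test_shoot_n_content_definition(self):
        records = [make_record(shoot_dry_weight=10.0, n_percent=2.0)]
        matrix = aggregate_performance(records, "shoot_n_content")
        assert matrix.get("GL", "Sync1", "grass").iloc[0] == pytest.approx(0.2)

    def test_missing_n_percent_propagates(self):
        records = [make_record(shoot_dry_weight=10.0)]
        matrix = aggregate_performance(records, "shoot_n_content")
        assert np.isnan(matrix.get("GL", "Sync1", "grass").iloc[0])

    def test_unknown_response_raises(self):
        with pytest.raises(InvalidInputError):
            aggregate_performance([make_record()], "root_dry_weight")


class TestPercentChange:
    @pytest.mark.parametrize(
        "treatment,reference,expected",
        [(4.0, 2.0, 100.0), (2.0, 4.0, -50.0), (3.3, 3.3, 0.0)],
    )
    def test_definition(self, treatment, reference, expected):
        assert percent_change(treatment, reference) == pytest.approx(expected)

    def test_nonpositive_reference_raises(self):
        with pytest.raises(UndefinedReferenceError):
            percent_change(1.0, 0.0)

    @settings(max_examples=100, deadline=None)
    @given(
        a=st.floats(0.01, 1e6, allow_nan=False),
        b=st.floats(0.01, 1e6, allow_nan=False),
    )
    def test_reciprocity_identity(self, a, b):
        # (a - b)*100 = pc(a,b)*b = -pc(b,a)*a, so pc(a,b) == -pc(b,a)*a/b
        lhs = percent_change(a, b)
        rhs = -percent_change(b, a) * a / b
        assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-9)
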