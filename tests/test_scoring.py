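"""Normalization scoring: targets, efficacy ratios, composite values."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from degradesign._util import round_half_up
from degradesign.errors import DomainError, ShapeError
from degradesign.scoring import (
    DEFAULT_WEIGHTS,
    Orientation,
    TargetMode,
    TargetPolicy,
    WeightVector,
    comprehensive_score,
    efficacy_coefficient,
    score_table,
    select_target,
)
from degradesign.tables_io import CompoundRecord

positive = st.floats(min_value=1e-6, max_value=1e6, allow_nan=False)


class TestSelectTarget:
    def test_reference_compound_magnitude(self, effects_records):
        values = [r.binding_free_energy for r in effects_records]
        ids = [r.compound_id for r in effects_records]
        policy = TargetPolicy(
            mode=TargetMode.REFERENCE_COMPOUND, reference_id="TCIPP"
        )
        assert select_target(
            values, policy, ids=ids, use_magnitude=True
        ) == pytest.approx(144.537)

    def test_lower_median_order_statistic_equals_reference(self, effects_records):
        """The 11th of 22 ascending |dG| magnitudes is the reference value."""
        values = [r.binding_free_energy for r in effects_records]
        policy = TargetPolicy(mode=TargetMode.ORDER_STATISTIC, order_index=11)
        assert select_target(values, policy, use_magnitude=True) == pytest.approx(
            144.537
        )

    def test_upper_median_transition_energy(self, effects_records):
        """The 12th of 22 ascending transition energies is the reference value."""
        values = [r.transition_energy for r in effects_records]
        policy = TargetPolicy(mode=TargetMode.ORDER_STATISTIC, order_index=12)
        assert select_target(values, policy) == pytest.approx(7.2211)

    @pytest.mark.parametrize(
        "policy",
        [
            TargetPolicy(mode=TargetMode.REFERENCE_COMPOUND, reference_id="ONLY"),
            TargetPolicy(mode=TargetMode.ORDER_STATISTIC, order_index=1),
        ],
    )
    def test_singleton(self, policy):
        assert select_target([3.5], policy, ids=["ONLY"]) == 3.5

    def test_errors(self):
        policy = TargetPolicy(mode=TargetMode.REFERENCE_COMPOUND, reference_id="X")
        with pytest.raises(DomainError):
            select_target([], policy, ids=[])
        with pytest.raises(DomainError, match="not found"):
            select_target([1.0], policy, ids=["Y"])


class TestEfficacyCoefficient:
    @pytest.mark.parametrize(
        "x, target, orientation, expected",
        [
            (123.731, 144.537, Orientation.RATIO_GE1, 1.168),
            (41.842, 144.537, Orientation.RATIO_GE1, 3.454),
            (4.3292, 7.2211, Orientation.RATIO_LE1, 0.600),
        ],
    )
    def test_published_spot_values(self, x, target, orientation, expected):
        assert round_half_up(efficacy_coefficient(x, target, orientation), 3) == (
            expected
        )

    @pytest.mark.parametrize("orientation", list(Orientation))
    def test_identity_at_target(self, orientation):
        assert efficacy_coefficient(5.0, 5.0, orientation) == 1.0

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(DomainError):
            efficacy_coefficient(-1.0, 2.0, Orientation.RATIO_LE1)
        with pytest.raises(DomainError):
            efficacy_coefficient(1.0, 0.0, Orientation.RATIO_GE1)

    @settings(derandomize=True, max_examples=200)
    @given(x=positive, target=positive)
    def test_reciprocity(self, x, target):
        """le1 and ge1 orientations are exact reciprocals."""
        lo = efficacy_coefficient(x, target, Orientation.RATIO_LE1)
        hi = efficacy_coefficient(x, target, Orientation.RATIO_GE1)
        assert lo * hi == pytest.approx(1.0, rel=1e-12)
        assert lo <= 1.0 <= hi

    @settings(derandomize=True, max_examples=200)
    @given(x=positive, target=positive, scale=st.floats(1e-3, 1e3))
    def test_scale_invariance(self, x, target, scale):
        for orientation in Orientation:
            assert efficacy_coefficient(
                x * scale, target * scale, orientation
            ) == pytest.approx(efficacy_coefficient(x, target, orientation))


class TestComprehensiveScore:
    @pytest.mark.parametrize(
        "x_bio, x_photo, expected",
        [
            (41.842, 7.2874, 2.22),  # TCPP
            (9.191, 8.1795, 8.30),  # TnPP
        ],
    )
    def test_published_composites_from_unrounded_coefficients(
        self, x_bio, x_photo, expected
    ):
        r1 = efficacy_coefficient(x_bio, 144.537, Orientation.RATIO_GE1)
        r2 = efficacy_coefficient(x_photo, 7.2211, Orientation.RATIO_LE1)
        assert round_half_up(comprehensive_score((r1, r2), DEFAULT_WEIGHTS), 2) == (
            expected
        )

    def test_unit_coefficients_give_unit_score(self):
        assert comprehensive_score((1.0, 1.0), WeightVector((0.3, 0.7))) == 1.0

    def test_shape_mismatch(self):
        with pytest.raises(ShapeError):
            comprehensive_score((1.0,), DEFAULT_WEIGHTS)

    @settings(derandomize=True, max_examples=100)
    @given(
        r1=positive, r2=positive, delta=st.floats(0.0, 10.0), w=st.floats(0.0, 1.0)
    )
    def test_monotone_in_each_coefficient(self, r1, r2, delta, w):
        weights = WeightVector((w, 1.0 - w))
        base = comprehensive_score((r1, r2), weights)
        assert comprehensive_score((r1 + delta, r2), weights) >= base
        assert comprehensive_score((r1, r2 + delta), weights) >= base


class TestScoreTable:
    def test_full_reference_table_reproduced(self, effects_records, effects_frame):
        """All 22 rows x 3 computed columns match at printed precision."""
        rounded = score_table(effects_records).rounded()
        for cid in effects_frame.index:
            assert rounded.loc[cid, "R_biodegradation"] == pytest.approx(
                effects_frame.loc[cid, "efficacy_biodegradation"]
            ), cid
            assert rounded.loc[cid, "R_photodegradation"] == pytest.approx(
                effects_frame.loc[cid, "efficacy_photodegradation"]
            ), cid
            assert rounded.loc[cid, "comprehensive"] == pytest.approx(
                effects_frame.loc[cid, "comprehensive_value"]
            ), cid

    def test_targets_recorded(self, effects_records):
        result = score_table(effects_records)
        assert result.targets["biodegradation"] == pytest.approx(144.537)
        assert result.targets["photodegradation"] == pytest.approx(7.2211)

    def test_constant_table_scores_all_ones(self):
        records = [
            CompoundRecord(f"C{i}", binding_free_energy=-100.0, transition_energy=6.0)
            for i in range(5)
        ]
        policy = TargetPolicy(mode=TargetMode.ORDER_STATISTIC, order_index=3)
        frame = score_table(records, policies=(policy, policy)).frame
        assert (frame == 1.0).all().all()
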