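"""Improvement intensities and the environment-friendly practicality screen."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from degradesign import data, reference
from degradesign._util import round_half_up
from degradesign.derivatives import (
    DerivativeComparison,
    change_rate,
    effect_ratio,
    enhanced_rate,
    increase_intensity,
    reduction_intensity,
    screen_environment_friendly,
)
from degradesign.errors import DomainError, ValidationError
from degradesign.verify import _property_comparisons

nonzero = st.floats(min_value=0.1, max_value=1e4, allow_nan=False)


class TestRates:
    @pytest.mark.parametrize(
        "old, new, fn, expected",
        [
            (225.72, 209.57, enhanced_rate, 7.15),  # flame retardancy enhanced
            (5.38, 5.15, change_rate, -4.28),  # gap change
            (-1023.57, -1536.08, change_rate, -50.07),  # energy change (negative old)
            (1.0, 2.0, increase_intensity, 100.0),
            (3.0, 3.0, reduction_intensity, 0.0),
        ],
    )
    def test_spot_values(self, old, new, fn, expected):
        assert round_half_up(fn(old, new), 2) == expected

    def test_prediction_intensity_within_input_rounding(self):
        """(2.09 -> 3.11) recomputes to 48.80 vs the published 48.68."""
        assert round_half_up(increase_intensity(2.09, 3.11), 2) == 48.80

    def test_zero_old_rejected(self):
        for fn in (reduction_intensity, increase_intensity):
            with pytest.raises(DomainError):
                fn(0.0, 1.0)

    @settings(derandomize=True, max_examples=100)
    @given(old=nonzero, new=nonzero)
    def test_reduction_increase_sign_identity(self, old, new):
        """reduction + (new/old)x100 = 100 and reduction = -increase."""
        red = reduction_intensity(old, new)
        assert red + new / old * 100.0 == pytest.approx(100.0)
        assert red == pytest.approx(-increase_intensity(old, new))


class TestEffectRatio:
    @pytest.mark.parametrize(
        "bio, photo, expected",
        [(55.48, 46.37, 1.20), (42.43, 52.98, 0.80), (7.0, 7.0, 1.00)],
    )
    def test_published_ratios(self, bio, photo, expected):
        assert round_half_up(effect_ratio(bio, photo), 2) == expected

    def test_zero_denominator(self):
        with pytest.raises(DomainError):
            effect_ratio(10.0, 0.0)


class TestReferenceTables:
    def test_property_change_rates_recompute(self):
        """Gap/energy rates exact; flame rates to one unit in the last digit
        (the published flame rates derive from unrounded enthalpies)."""
        props = data.load_derivative_properties()
        parents = props[props["role"] == "parent"].set_index("compound_id")
        for _, row in props[props["role"] == "derivative"].iterrows():
            parent = row["parent_id"]
            flame = round_half_up(
                enhanced_rate(
                    parents.loc[parent, "flame_retardancy_kcal_mol"],
                    row["flame_retardancy_kcal_mol"],
                ),
                2,
            )
            assert abs(flame - row["flame_enhanced_rate_pct"]) <= 0.01 + 1e-12, (
                row["compound_id"]
            )
            gap = round_half_up(
                change_rate(parents.loc[parent, "energy_gap_ev"], row["energy_gap_ev"]),
                2,
            )
            assert gap == row["gap_change_rate_pct"], row["compound_id"]
            energy = round_half_up(
                change_rate(parents.loc[parent, "energy_au"], row["energy_au"]), 2
            )
            assert energy == row["energy_change_rate_pct"], row["compound_id"]

    def test_screen_passes_exactly_the_seven_named_derivatives(self):
        verdicts = {
            c.derivative_id: screen_environment_friendly(c)
            for c in _property_comparisons(None)
        }
        assert len(verdicts) == 14
        passed = {d for d, v in verdicts.items() if v.passed}
        assert passed == set(reference.ENVIRONMENT_FRIENDLY)
        for d, v in verdicts.items():
            if d not in passed:
                assert not v.criteria["flame_retardancy_enhanced"], d

    def test_prediction_intensities_within_propagation_bound(self):
        """Published intensities recompute from printed C/B/P inputs to
        within the half-ulp rounding propagation bound; the two cells the
        source prints inconsistently are excluded."""
        preds = data.load_derivative_predictions()
        parents = preds[preds["role"] == "parent"].set_index("compound_id")
        specs = [
            ("c_pred", "c_reduction_pct", -1),
            ("b_pred", "b_increase_pct", 1),
            ("p_pred_ev", "p_reduction_pct", -1),
        ]
        for _, row in preds[preds["role"] == "derivative"].iterrows():
            for value_col, pct_col, sign in specs:
                if (row["compound_id"], pct_col) in (
                    reference.KNOWN_INCONSISTENT_INTENSITIES
                ):
                    continue
                old, new = parents.loc[row["parent_id"], value_col], row[value_col]
                got = sign * change_rate(old, new)
                tol = 100.0 * 0.005 * (abs(old) + abs(new)) / old**2 + 0.005
                assert abs(got - row[pct_col]) <= tol, (row["compound_id"], pct_col)


def _passing_comparison() -> DerivativeComparison:
    return DerivativeComparison(
        parent_id="P",
        derivative_id="D",
        c_pred_parent=2.0,
        c_pred_derivative=1.5,
        b_pred_parent=1.6,
        b_pred_derivative=2.5,
        p_pred_parent=7.3,
        p_pred_derivative=4.0,
        flame_retardancy_parent=225.0,
        flame_retardancy_derivative=210.0,
        gap_parent=5.4,
        gap_derivative=5.2,
        energy_parent=-1000.0,
        energy_derivative=-1500.0,
        min_frequency_derivative=2.0,
    )


class TestScreen:
    def test_all_criteria_true_passes(self):
        verdict = screen_environment_friendly(_passing_comparison())
        assert verdict.passed and all(verdict.criteria.values())

    def test_identical_values_fail_on_no_reduction(self):
        cmp = _passing_comparison()
        cmp.c_pred_derivative = cmp.c_pred_parent
        cmp.b_pred_derivative = cmp.b_pred_parent
        cmp.p_pred_derivative = cmp.p_pred_parent
        verdict = screen_environment_friendly(cmp)
        assert not verdict.passed
        assert not verdict.criteria["comprehensive_reduced"]

    def test_missing_field_names_the_criterion_inputs(self):
        cmp = _passing_comparison()
        cmp.gap_parent = None
        with pytest.raises(ValidationError, match="gap_parent"):
            screen_environment_friendly(cmp)

    def test_gap_tolerance_is_configurable(self):
        cmp = _passing_comparison()
        cmp.gap_derivative = cmp.gap_parent * 0.90  # 10% insulation loss
        assert not screen_environment_friendly(cmp, gap_tolerance=5.0).passed
        assert screen_environment_friendly(cmp, gap_tolerance=15.0).passed

    @pytest.mark.parametrize(
        "field, worse",
        [
            ("c_pred_derivative", 10.0),
            ("b_pred_derivative", -10.0),
            ("p_pred_derivative", 100.0),
            ("flame_retardancy_derivative", 500.0),
            ("gap_derivative", -100.0),
            ("min_frequency_derivative", -1.0),
        ],
    )
    def test_screen_monotone_worsening_never_flips_fail_to_pass(self, field, worse):
        base = _passing_comparison()
        base.p_pred_derivative = base.p_pred_parent + 1  # already failing
        assert not screen_environment_friendly(base).passed
        worse_cmp = dataclasses.replace(base, **{field: worse})
        assert not screen_environment_friendly(worse_cmp).passed
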