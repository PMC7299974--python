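"""Behavioral and biochemical indices: conversions, ratios, CPP, qPCR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circafeed import (
    DEFAULT_DENSITIES,
    DialysateSeries,
    cpp_prebias_filter,
    cumulative_24h,
    ddct,
    kd_inclusion,
    overconsumption,
    percent_change,
    pool_dialysate,
    preference_fraction,
    preference_index,
    to_kcal,
)
from circafeed.behavior import intake_to_common_unit
from circafeed.exceptions import (
    GridError,
    InsufficientFractionsError,
    MissingBinError,
    UndefinedPreferenceError,
    UnknownItemError,
)


def intake_table(rows):
    return pd.DataFrame(
        rows,
        columns=["animal_id", "group", "item", "bin_start", "bin_width", "amount", "unit"],
    )


class TestCaloricConversion:
    @pytest.mark.parametrize(
        "grams,item,kcal",
        [(1.0, "chow", 2.988), (0.0, "chocolate", 0.0), (0.46, "chocolate", 2.438),
         (1.0, "cookie", 4.95)],
    )
    def test_energy_densities(self, grams, item, kcal):
        assert to_kcal(grams, item) == pytest.approx(kcal)

    def test_unknown_item_named_in_error(self):
        with pytest.raises(UnknownItemError, match="pellet"):
            to_kcal(1.0, "pellet")

    def test_negative_amount_rejected(self):
        with pytest.raises(ValueError):
            to_kcal(-0.1, "chow")

    def test_licks_pass_through_unconverted(self):
        df = intake_table([("a", "g1", "water", 0, 6, 120, "licks")])
        out = intake_to_common_unit(df)
        assert out["amount"].iloc[0] == 120 and out["unit"].iloc[0] == "licks"

    def test_mixed_units_after_conversion_rejected(self):
        df = intake_table(
            [("a", "g1", "chow", 0, 6, 1.0, "g"), ("a", "g1", "water", 0, 6, 10, "licks")]
        )
        with pytest.raises(ValueError, match="mixed units"):
            intake_to_common_unit(df)


class TestPreferenceIndex:
    @pytest.mark.parametrize(
        "cond,opp,pi", [(300, 300, 0.5), (450, 150, 0.75), (100, 0, 1.0)]
    )
    def test_two_chamber_convention(self, cond, opp, pi):
        assert preference_index(t_conditioned=cond, t_opposite=opp) == pytest.approx(pi)

    def test_neutral_corridor_optional(self):
        pi = preference_index(
            t_conditioned=150, t_opposite=150, t_neutral=100, include_neutral=True
        )
        assert pi == pytest.approx(150 / 400)

    def test_all_zero_dwell_times_undefined(self):
        with pytest.raises(UndefinedPreferenceError):
            preference_index(t_conditioned=0, t_opposite=0)

    @pytest.mark.parametrize(
        "pi,included", [(0.5, True), (0.35, True), (0.65, True), (0.9, False), (0.1, False)]
    )
    def test_prebias_filter_inclusive_bounds(self, pi, included):
        assert cpp_prebias_filter(pi) is included

    def test_prebias_filter_validates_bounds(self):
        with pytest.raises(ValueError):
            cpp_prebias_filter(0.5, lo=0.7, hi=0.3)


class TestOverconsumption:
    def test_self_ratio_is_one_in_every_bin(self):
        rows = [
            ("a1", "g", "chow", s, 6, v, "g")
            for s, v in zip([0, 6, 12, 18], [0.5, 0.8, 1.2, 0.9])
        ]
        prof = overconsumption(intake_table(rows), intake_table(rows))
        assert np.allclose(prof.ratios.to_numpy(), 1.0)
        assert not prof.table["undefined"].any()

    def test_hand_computed_caloric_ratio(self):
        base = intake_table([("b1", "g", "chow", 0, 6, 2 / 2.988, "g")])
        choice = intake_table(
            [
                ("c1", "g", "chow", 0, 6, 1 / 2.988, "g"),
                ("c1", "g", "chocolate", 0, 6, 5 / 5.3, "g"),
            ]
        )
        prof = overconsumption(choice, base)
        assert prof.ratios.loc[0] == pytest.approx(3.0)

    def test_density_cancels_for_single_item(self):
        """Grams vs kcal give identical ratios when one item is involved."""
        rows_g = [("a", "g", "chow", s, 6, v, "g") for s, v in zip([0, 6], [1.0, 2.0])]
        rows_b = [("b", "g", "chow", s, 6, v, "g") for s, v in zip([0, 6], [0.5, 0.8])]
        kcal = lambda rows: [
            (a, g, i, s, w, v * 2.988, "kcal") for a, g, i, s, w, v, _ in rows
        ]
        p_g = overconsumption(intake_table(rows_g), intake_table(rows_b))
        p_k = overconsumption(intake_table(kcal(rows_g)), intake_table(kcal(rows_b)))
        assert np.allclose(p_g.ratios.to_numpy(), p_k.ratios.to_numpy())

    def test_missing_bin_rejected(self):
        base = intake_table([("b", "g", "chow", 0, 6, 1.0, "g")])
        choice = intake_table(
            [("c", "g", "chow", 0, 6, 1.0, "g"), ("c", "g", "chow", 6, 6, 1.0, "g")]
        )
        with pytest.raises(MissingBinError):
            overconsumption(choice, base)

    def test_zero_baseline_flagged_not_infinite(self):
        base = intake_table(
            [("b", "g", "chow", 0, 6, 0.0, "g"), ("b", "g", "chow", 6, 6, 1.0, "g")]
        )
        choice = intake_table(
            [("c", "g", "chow", 0, 6, 1.0, "g"), ("c", "g", "chow", 6, 6, 1.0, "g")]
        )
        prof = overconsumption(choice, base)
        row0 = prof.table[prof.table["bin_start"] == 0].iloc[0]
        assert np.isnan(row0["ratio"]) and bool(row0["undefined"])

    def test_animal_matched_mode_uses_own_baseline(self):
        base = intake_table(
            [("a1", "g", "chow", 0, 6, 1.0, "kcal"), ("a2", "g", "chow", 0, 6, 4.0, "kcal")]
        )
        choice = intake_table(
            [("a1", "g", "chow", 0, 6, 2.0, "kcal"), ("a2", "g", "chow", 0, 6, 2.0, "kcal")]
        )
        prof = overconsumption(choice, base, baseline_source="animal-matched")
        t = prof.table.set_index("animal_id")["ratio"]
        assert t["a1"] == pytest.approx(2.0) and t["a2"] == pytest.approx(0.5)

    def test_animal_matched_requires_matching_ids(self):
        base = intake_table([("a1", "g", "chow", 0, 6, 1.0, "kcal")])
        choice = intake_table([("zz", "g", "chow", 0, 6, 2.0, "kcal")])
        with pytest.raises(MissingBinError):
            overconsumption(choice, base, baseline_source="animal-matched")


class TestPreferenceFraction:
    @pytest.mark.parametrize("h,b,f", [(5, 5, 0.5), (5, 0, 1.0), (3, 1, 0.75)])
    def test_examples(self, h, b, f):
        assert preference_fraction(h, b) == pytest.approx(f)

    def test_zero_total_undefined(self):
        with pytest.raises(UndefinedPreferenceError):
            preference_fraction(0, 0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        a=st.floats(0, 1e6, allow_nan=False),
        b=st.floats(0, 1e6, allow_nan=False),
    )
    def test_complement_sums_to_one(self, a, b):
        if a + b > 0:
            assert preference_fraction(a, b) + preference_fraction(b, a) == pytest.approx(1.0)


class TestCumulativeIntake:
    def test_four_unit_bins(self):
        rows = [("a", "g", "chow", s, 6, 1.0, "kcal") for s in [0, 6, 12, 18]]
        assert cumulative_24h(intake_table(rows)) == pytest.approx(4.0)

    def test_empty_day_is_zero(self):
        rows = [("a", "g", "chow", s, 6, 0.0, "kcal") for s in [0, 6, 12, 18]]
        assert cumulative_24h(intake_table(rows)) == 0.0

    def test_gap_in_grid_rejected(self):
        rows = [("a", "g", "chow", s, 6, 1.0, "kcal") for s in [0, 6, 18]]
        with pytest.raises(GridError):
            cumulative_24h(intake_table(rows))

    def test_overlap_rejected(self):
        rows = [("a", "g", "chow", s, 8, 1.0, "kcal") for s in [0, 6, 12, 18]]
        with pytest.raises(GridError):
            cumulative_24h(intake_table(rows))

    def test_matches_naive_row_loop_on_generated_day(self, config):
        from circafeed import gen_intake

        df = gen_intake(config)
        one = df[df["animal_id"] == df["animal_id"].iloc[0]]
        # independent oracle: convert and sum row by row in plain Python
        expected = 0.0
        for r in one.itertuples():
            expected += r.amount * DEFAULT_DENSITIES[r.item]
        assert cumulative_24h(one) == pytest.approx(expected, rel=1e-12)


class TestDialysate:
    def _series(self, pre, post, snack=100.0):
        times = list(range(10, 10 * (len(pre) + 1), 10)) + list(
            range(110, 110 + 10 * len(post), 10)
        )
        return DialysateSeries("m1", tuple(times), tuple(pre + post), snack)

    def test_constant_series(self):
        s = self._series([3.0] * 5, [3.0] * 5)
        assert pool_dialysate(s) == (3.0, 3.0)

    def test_arithmetic_means(self):
        s = self._series([1, 2, 3, 4, 5], [2, 3, 4, 5, 6])
        assert pool_dialysate(s) == (3.0, 4.0)

    def test_uses_k_fractions_nearest_snack(self):
        s = self._series([99, 1, 2, 3, 4, 5], [2, 3, 4, 5, 6, 99])
        assert pool_dialysate(s, k=5) == (3.0, 4.0)

    def test_insufficient_fractions(self):
        s = self._series([1, 2, 3], [4, 5, 6])
        with pytest.raises(InsufficientFractionsError):
            pool_dialysate(s, k=5)

    def test_strictly_increasing_times_enforced(self):
        with pytest.raises(ValueError):
            DialysateSeries("m", (10.0, 10.0, 30.0), (1.0, 2.0, 3.0), 20.0)


class TestPercentChange:
    @pytest.mark.parametrize(
        "base,post,pct", [(100, 135, 35.0), (100, 100, 0.0), (100, 80, -20.0)]
    )
    def test_sign_convention(self, base, post, pct):
        assert percent_change(base, post) == pytest.approx(pct)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            percent_change(0.0, 50.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        b=st.floats(1e-3, 1e6, allow_nan=False),
        x=st.floats(-99.0, 500.0, allow_nan=False),
    )
    def test_round_trip(self, b, x):
        assert percent_change(b, b * (1 + x / 100.0)) == pytest.approx(x, abs=1e-6)


class TestDDCt:
    def test_identity(self):
        assert ddct(20, 20, 20, 20).fold_change == pytest.approx(1.0)

    def test_one_cycle_doubling(self):
        # sample delta-Ct one cycle below calibrator delta-Ct
        assert ddct(19, 18, 20, 18).fold_change == pytest.approx(2.0)

    def test_worked_example(self):
        assert ddct(20, 18, 22, 18).fold_change == pytest.approx(4.0)

    @pytest.mark.parametrize("k", [1, 2, 3.5])
    def test_shift_multiplies_fold_by_power_of_two(self, k):
        base = ddct(20, 18, 22, 18).fold_change
        shifted = ddct(20 - k, 18, 22, 18).fold_change
        assert shifted == pytest.approx(base * 2**k)

    def test_nonfinite_ct_rejected(self):
        with pytest.raises(ValueError):
            ddct(np.nan, 18, 22, 18)


class TestKnockdownInclusion:
    @pytest.mark.parametrize(
        "rel,included", [(0.3, True), (0.499, True), (0.5, False), (1.0, False)]
    )
    def test_strictly_more_than_half_reduction(self, rel, included):
        assert kd_inclusion(rel) is included

    def test_custom_threshold(self):
        assert kd_inclusion(0.25, threshold=0.7) is True
        assert kd_inclusion(0.35, threshold=0.7) is False
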