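"""Direction calls: CIs, the equivalence-containment rule, FDR flags."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from transreg import (
    EquivalenceParams,
    bh_flags,
    call_feature,
    call_from_summary,
    call_layer,
    equivalence_contained,
    mean_ci,
)
from transreg.errors import (
    InsufficientReplicatesError,
    UndefinedRatioError,
    ValidationError,
)
from transreg.io import AbundanceTable


class TestMeanCI:
    def test_zero_variance_collapses_to_point(self):
        assert mean_ci([10, 10, 10, 10]) == (10, 10)

    def test_hand_computed_t_interval(self):
        # mean 2.5, sd 1.29099, t_{0.975,3} = 3.18245
        lo, hi = mean_ci([1, 2, 3, 4], 0.95)
        assert lo == pytest.approx(0.4457, abs=1e-4)
        assert hi == pytest.approx(4.5543, abs=1e-4)

    def test_single_value_rejected(self):
        with pytest.raises(InsufficientReplicatesError):
            mean_ci([1.0])


class TestEquivalence:
    @pytest.mark.parametrize(
        "control, treated, expected",
        [((10, 20), (8, 25), True),   # band is [7, 26]
         ((10, 20), (6, 25), False),  # 6 < 7
         ((5, 5), (5, 5), True)],
    )
    def test_band_arithmetic(self, control, treated, expected):
        assert equivalence_contained(control, treated) is expected

    def test_identical_intervals_always_contained(self):
        params = EquivalenceParams(upper_factor=1.0, lower_factor=1.0)
        assert equivalence_contained((3, 9), (3, 9), params)

    @settings(max_examples=300, derandomize=True)
    @given(st.lists(st.floats(0, 100), min_size=4, max_size=4),
           st.floats(0.1, 1.0), st.floats(1.0, 2.0))
    def test_matches_brute_force_oracle(self, bounds, lo_f, hi_f):
        c = (min(bounds[0], bounds[1]), max(bounds[0], bounds[1]))
        t = (min(bounds[2], bounds[3]), max(bounds[2], bounds[3]))
        params = EquivalenceParams(lower_factor=lo_f, upper_factor=hi_f)
        band = (lo_f * max(c[0], 0.0), hi_f * c[1])
        oracle = band[0] <= t[0] and t[1] <= band[1]
        assert equivalence_contained(c, t, params) == oracle

    def test_negative_control_low_is_clamped(self):
        # without clamping the 70% factor would invert the band's low end
        assert equivalence_contained((-4, 10), (0, 12))

    def test_monotone_in_treated_width(self):
        # widening the treated CI can only break containment, never create it
        rng = np.random.default_rng(0)
        for _ in range(200):
            c = np.sort(rng.uniform(0, 10, 2))
            center, half = rng.uniform(0, 12), rng.uniform(0, 5)
            narrow = (center - half, center + half)
            wide = (center - 2 * half, center + 2 * half)
            if equivalence_contained(tuple(c), wide):
                assert equivalence_contained(tuple(c), narrow)


class TestBHFlags:
    def test_all_rejected_when_uniformly_small(self):
        assert bh_flags([0.01, 0.02, 0.03, 0.04], 0.05).all()

    def test_none_rejected(self):
        assert not bh_flags([0.04, 0.5, 0.9], 0.05).any()

    def test_empty(self):
        assert bh_flags([]).size == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_flags([0.5, 1.5])


class TestCallFeature:
    def test_clear_doubling_is_up(self):
        call = call_feature([10, 11, 9, 10], [20, 21, 19, 20])
        assert call.call == "up" and call.ratio == pytest.approx(2.0)
        assert call.p_value < 1e-4

    def test_identical_samples_stable(self):
        call = call_feature([10, 11, 9, 10], [10, 11, 9, 10])
        assert call.call == "stable"

    def test_zero_variance_equal_means_stable_with_p_one(self):
        call = call_feature([5, 5, 5], [5, 5, 5])
        assert call.call == "stable" and call.p_value == 1.0

    def test_zero_control_mean_raises(self):
        with pytest.raises(UndefinedRatioError):
            call_feature([0, 0, 0], [1, 2, 3])

    def test_insufficient_replicates(self):
        with pytest.raises(InsufficientReplicatesError):
            call_feature([1.0], [2.0, 3.0])

    @pytest.mark.parametrize("reading", ["sd", "sem"])
    def test_published_total_rna_example_is_stable(self, reading):
        # 26.7 +/- 4.5 vs 24.9 +/- 3.6 at n = 4: statistically equivalent
        # under either reading of the spread
        call = call_from_summary(26.7, 4.5, 4, 24.9, 3.6, 4, spread_is=reading)
        assert call.call == "stable"

    def test_scale_equivariance(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            c = rng.uniform(1, 20, 4)
            t = rng.uniform(1, 20, 4)
            k = rng.uniform(0.01, 100)
            assert call_feature(c, t).call == call_feature(k * c, k * t).call

    def test_verdicts_partition_the_outcome_space(self):
        rng = np.random.default_rng(4)
        seen = set()
        for _ in range(300):
            c = rng.lognormal(1, 1, 4)
            t = rng.lognormal(1 + rng.normal(0, 1), rng.uniform(0.05, 1), 4)
            seen.add(call_feature(c, t).call)
        assert seen <= {"up", "down", "stable", "other"}
        assert {"up", "down"} <= seen


def _table(values_by_layer, n_units=4):
    cols, meta = {}, []
    for layer, (ctrl, trt) in values_by_layer.items():
        for cond, mat in (("control", ctrl), ("treated", trt)):
            for u in range(n_units):
                sid = f"{layer}_{cond}_u{u + 1}"
                cols[sid] = mat[:, u]
                meta.append(dict(sample_id=sid, layer=layer, condition=cond,
                                 unit=f"u{u + 1}"))
    n = len(next(iter(values_by_layer.values()))[0])
    data = pd.DataFrame(cols, index=[f"f{i}" for i in range(n)])
    return AbundanceTable(data, pd.DataFrame(meta).set_index("sample_id"))


class TestCallLayer:
    def test_null_features_called_mostly_stable(self, small_dataset):
        truth = small_dataset.truth.table
        calls = call_layer(small_dataset.abundance, "total")
        stable_groups = truth.index[truth["group_id"].isin([1, 4, 13, 14])]
        null = truth.index[truth["group_id"].isin([4, 13, 14])]
        frac = (calls.loc[null, "call"] == "stable").mean()
        assert frac >= 0.90

    def test_protein_up_features_called_up(self, small_dataset):
        truth = small_dataset.truth.table
        calls = call_layer(small_dataset.abundance, "protein")
        up = truth.index[truth["group_id"].isin([1, 4])]
        assert (calls.loc[up, "call"] == "up").mean() >= 0.90

    def test_bh_gate_never_more_permissive_than_raw(self, small_dataset):
        raw = call_layer(small_dataset.abundance, "protein", gate="raw")
        bh = call_layer(small_dataset.abundance, "protein", gate="bh")
        raw_sig = raw["call"].isin(["up", "down"])
        bh_sig = bh["call"].isin(["up", "down"])
        assert not (bh_sig & ~raw_sig).any()

    def test_missing_values_yield_other_with_reason(self):
        rng = np.random.default_rng(0)
        ctrl = rng.uniform(5, 10, (3, 4))
        trt = rng.uniform(5, 10, (3, 4))
        ctrl[1, :3] = np.nan
        tbl = _table({"protein": (ctrl, trt)})
        calls = call_layer(tbl, "protein")
        assert calls.at["f1", "call"] == "other"
        assert calls.at["f1", "reason"] == "insufficient replicates"

    def test_zero_control_mean_yields_other(self):
        ctrl = np.ones((2, 4))
        ctrl[0] = 0.0
        tbl = _table({"protein": (ctrl, np.ones((2, 4)) * 2)})
        calls = call_layer(tbl, "protein")
        assert calls.at["f0", "call"] == "other"
        assert calls.at["f0", "reason"] == "zero control mean"
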