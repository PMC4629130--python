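"""Response-matrix assembly, band statistics, class biases, tuning-curve
arrangement and the K value."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import cimexolf as co
from cimexolf.errors import (
    InsufficientDataError,
    SchemaError,
    UndefinedKurtosisError,
)
from conftest import toy_matrix


def _records(cells: dict) -> pd.DataFrame:
    rows = []
    for (od, cls, sens), reps in cells.items():
        for i, r in enumerate(reps):
            rows.append(
                dict(
                    odorant=od,
                    odorant_class=cls,
                    sensillum=sens,
                    replicate=i,
                    spikes_per_s=r,
                )
            )
    return pd.DataFrame(rows)


class TestBuildMatrix:
    def test_mean_and_sem_aggregation(self):
        m = co.build_response_matrix(
            _records({("x", "aldehyde", "Da"): [40.0] * 6})
        )
        assert m.mean.loc["x", "Da"] == 40.0
        assert m.sem.loc["x", "Da"] == 0.0
        assert m.n.loc["x", "Da"] == 6

    def test_sub_15_mean_flagged_non_responder(self):
        m = co.build_response_matrix(
            _records(
                {
                    ("x", "aldehyde", "Da"): [14.9, 14.9],
                    ("y", "aldehyde", "Da"): [15.0, 15.0],
                }
            )
        )
        assert bool(m.non_responder.loc["x", "Da"])
        assert not bool(m.non_responder.loc["y", "Da"])

    def test_conflicting_class_labels_rejected(self):
        records = _records(
            {("x", "aldehyde", "Da"): [1.0], ("x", "amine", "Db"): [1.0]}
        )
        with pytest.raises(SchemaError):
            co.build_response_matrix(records)

    def test_missing_combination_rejected(self):
        records = _records(
            {("x", "aldehyde", "Da"): [1.0], ("y", "aldehyde", "Db"): [1.0]}
        )
        with pytest.raises(SchemaError):
            co.build_response_matrix(records)


class TestBandDistribution:
    def test_all_zero_matrix_in_weak_band(self):
        m = toy_matrix({s: [0.0, 0.0] for s in co.panel.SENSILLA})
        bands = co.band_distribution(m)
        assert bands.loc["<50", "count"] == m.n_cells
        assert bands["count"].sum() == m.n_cells

    def test_shared_endpoints_go_to_lower_band(self):
        m = toy_matrix({"Da": [100.0, 50.0, 150.0, 200.0, 200.5]})
        bands = co.band_distribution(m)
        assert bands.loc["[50,100]", "count"] == 2  # 50 and 100
        assert bands.loc["(100,150]", "count"] == 1
        assert bands.loc["(150,200]", "count"] == 1
        assert bands.loc["(200,inf)", "count"] == 1

    @given(st.integers(0, 10_000))
    def test_partition_is_exact_for_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        m = toy_matrix(
            {s: rng.uniform(-20, 260, 9) for s in co.panel.SENSILLA}
        )
        bands = co.band_distribution(m)
        assert bands["count"].sum() == m.n_cells
        assert abs(bands["percent"].sum() - 100.0) < 0.3


class TestClassBias:
    def _matrix(self):
        # 11 aldehydes, 9 of them at or above the 50 spikes/s criterion
        rates = [60, 70, 80, 90, 100, 110, 120, 130, 140, 10, 5]
        odorants = [f"ald{i:02d}" for i in range(11)] + ["acid0", "acid1"]
        values = {
            s: rates + [0, 0] if s == "Da" else [0.0] * 13
            for s in co.panel.SENSILLA
        }
        classes = dict.fromkeys(odorants[:11], "aldehyde")
        classes.update(dict.fromkeys(odorants[11:], "carboxylic_acid"))
        return toy_matrix(values, classes, index=odorants)

    def test_nine_of_eleven_rounds_to_82_percent(self):
        bias = co.class_bias(self._matrix(), mode="max")
        assert round(bias["aldehyde"]) == 82

    def test_class_without_responders_scores_zero(self):
        bias = co.class_bias(self._matrix(), mode="max")
        assert bias["carboxylic_acid"] == 0.0

    def test_saturated_class_scores_100(self):
        m = toy_matrix(
            {s: [55.0, 60.0] for s in co.panel.SENSILLA},
            {0: "amine", 1: "amine"},
        )
        assert co.class_bias(m, mode="max")["amine"] == 100.0

    def test_per_sensillum_variant_shape(self, ref_matrix):
        bias = co.class_bias(ref_matrix)
        assert bias.shape == (11, 6)
        # no acid reaches the criterion on any sensillum
        assert (bias.loc["carboxylic_acid"] == 0).all()


class TestTuningCurve:
    def test_forced_three_point_arrangement(self):
        m = toy_matrix({s: [10.0, 30.0, 20.0] for s in co.panel.SENSILLA})
        curve = co.tuning_curve(m, "Da")
        np.testing.assert_array_equal(curve.ordered_rates, [20.0, 30.0, 10.0])

    def test_output_is_permutation_of_column(self, sim_matrix):
        curve = co.tuning_curve(sim_matrix, "Dg")
        col = np.sort(sim_matrix.mean["Dg"].values)
        np.testing.assert_allclose(np.sort(curve.ordered_rates), col)
        assert sorted(curve.odorant_order) == sorted(sim_matrix.odorants)

    def test_strongest_odorant_sits_at_center(self, ref_matrix):
        curve = co.tuning_curve(ref_matrix, "Da")
        center = len(curve.odorant_order) // 2
        assert curve.odorant_order[center] == "nonanal"

    def test_ties_resolved_by_odorant_id(self):
        values = {s: [7.0, 7.0, 7.0, 1.0] for s in co.panel.SENSILLA}
        ids = ["b", "a", "c", "d"]
        classes = dict.fromkeys(ids, "aldehyde")
        m = toy_matrix(values, classes, index=ids)
        curve = co.tuning_curve(m, "Da")
        # rates tie at 7 for a, b, c: lexicographic order decides the ranks
        assert curve.odorant_order == ["d", "b", "a", "c"]

    def test_constant_column_flagged_degenerate(self):
        m = toy_matrix({s: [5.0] * 6 for s in co.panel.SENSILLA})
        curve = co.tuning_curve(m, "Da")
        assert curve.degenerate and curve.k is None


def _kurtosis_oracle(x):
    """Corrected sample excess kurtosis, written out in full."""
    x = np.asarray(x, dtype=float)
    n = x.size
    s = x.std(ddof=1)
    term = np.sum(((x - x.mean()) / s) ** 4)
    return (
        n * (n + 1) / ((n - 1) * (n - 2) * (n - 3)) * term
        - 3 * (n - 1) ** 2 / ((n - 2) * (n - 3))
    )


class TestKurtosisK:
    @given(st.integers(0, 10_000))
    def test_matches_corrected_formula(self, seed):
        x = np.random.default_rng(seed).normal(10.0, 4.0, 25)
        assert np.isclose(co.kurtosis_k(x), _kurtosis_oracle(x), rtol=1e-12)

    def test_gaussian_sample_scores_near_zero(self):
        x = np.random.default_rng(0).normal(size=10_000)
        assert abs(co.kurtosis_k(x)) < 0.2

    @given(
        st.integers(0, 10_000),
        st.floats(-50.0, 50.0),
        st.sampled_from([-3.0, -0.5, 0.25, 2.0, 10.0]),
    )
    def test_location_scale_invariance(self, seed, b, a):
        x = np.random.default_rng(seed).normal(5.0, 2.0, 30)
        assert np.isclose(co.kurtosis_k(a * x + b), co.kurtosis_k(x), atol=1e-8)

    def test_raw_convention_is_excess_plus_three(self):
        x = np.random.default_rng(3).normal(size=50)
        assert np.isclose(
            co.kurtosis_k(x, excess=False), co.kurtosis_k(x) + 3.0
        )

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(InsufficientDataError):
            co.kurtosis_k([1.0, 2.0, 3.0])
        with pytest.raises(UndefinedKurtosisError):
            co.kurtosis_k([5.0] * 10)

    def test_sharper_tuning_raises_k(self):
        """Growing a single dominant response sharpens the K value."""
        base = np.full(50, 5.0) + np.random.default_rng(1).uniform(0, 1, 50)
        ks = []
        for peak in (50.0, 100.0, 200.0, 400.0):
            col = base.copy()
            col[0] = peak
            ks.append(co.kurtosis_k(col))
        assert np.all(np.diff(ks) > 0)

    def test_narrow_c_sensillum_exceeds_broad_db(self, sim_matrix):
        """The amine-specialist C column is more sharply tuned than Dβ."""
        k_c = co.kurtosis_k(sim_matrix.mean["C"].values)
        k_db = co.kurtosis_k(sim_matrix.mean["Db"].values)
        assert k_c > k_db
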