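"""Empirical direct-EF estimation: filtering, per-plot EFs, aggregation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fertghg.efdirect import (
    DirectEFEstimate,
    PairedPlotRecord,
    estimate_all,
    estimate_country_efs,
    estimate_global_ef,
    estimate_regional_efs,
    filter_synthetic_only,
    plot_level_ef,
    store_from_frame,
    estimates_to_frame,
)


def _rec(record_id="r1", country="X1", region="Europe", n_applied=100.0,
         treated=1.0, control=0.5):
    return PairedPlotRecord(record_id, country, region, "wheat",
                            n_applied, treated, control)


def _raw_frame(rows):
    cols = ["record_id", "country", "region", "crop", "n_applied_kg_ha",
            "n2o_treated_kg_ha", "n2o_control_kg_ha", "climate", "fertiliser_type"]
    return pd.DataFrame(rows, columns=cols)


class TestPlotLevelEF:
    @pytest.mark.parametrize(
        "treated, control, n_applied, expected",
        [
            (0.7, 0.7, 120.0, 0.0),  # treated == control -> no fertiliser effect
            (1.5, 0.5, 100.0, 0.01),
            (0.3, 0.5, 100.0, -0.002),  # control can out-emit: negative EF kept
        ],
    )
    def test_flux_difference_over_n_applied(self, treated, control, n_applied, expected):
        rec = _rec(treated=treated, control=control, n_applied=n_applied)
        assert plot_level_ef(rec) == pytest.approx(expected)

    def test_nonpositive_n_applied_rejected(self):
        with pytest.raises(ValueError, match="n_applied"):
            _rec(n_applied=0.0)

    def test_nonfinite_flux_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            _rec(treated=float("nan"))


class TestFilter:
    def test_synthetic_only_with_duplicates_removed(self):
        rows = [
            ["a", "X1", "Europe", "wheat", 100, 1.0, 0.5, "wet", "synthetic"],
            ["b", "X1", "Europe", "maize", 150, 1.2, 0.4, "wet", "synthetic"],
            ["c", "X1", "Europe", "wheat", 100, 1.0, 0.5, "wet", "organic"],
            ["d", "X1", "Europe", "wheat", 100, 1.0, 0.5, "wet", "mixed"],
            ["e", "X1", "Europe", "wheat", 100, 1.0, 0.5, "wet", "synthetic"],  # dup of a
        ]
        records, counts = filter_synthetic_only(_raw_frame(rows))
        assert len(records) == 2
        assert counts["non_synthetic"] == 2
        assert counts["duplicate"] == 1

    def test_missing_control_dropped_and_counted(self):
        rows = [
            ["a", "X1", "Europe", "wheat", 100, 1.0, 0.5, "wet", "synthetic"],
            ["b", "X1", "Europe", "rice", 100, 1.0, None, "wet", "synthetic"],
        ]
        records, counts = filter_synthetic_only(_raw_frame(rows))
        assert len(records) == 1
        assert counts["missing_plot_data"] == 1

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            filter_synthetic_only(_raw_frame([]))

    def test_all_filtered_out_is_an_error(self):
        rows = [["a", "X1", "Europe", "wheat", 100, 1.0, 0.5, "wet", "organic"]]
        with pytest.raises(ValueError, match="no usable records"):
            filter_synthetic_only(_raw_frame(rows))

    def test_missing_column_named_in_error(self):
        df = _raw_frame([["a", "X1", "Europe", "w", 100, 1.0, 0.5, "wet", "synthetic"]])
        with pytest.raises(ValueError, match="n2o_control_kg_ha"):
            filter_synthetic_only(df.drop(columns=["n2o_control_kg_ha"]))


class TestCountryEstimates:
    def test_mean_and_sample_sd(self):
        # plot EFs 0.01, 0.02, 0.03 -> mean 0.02, sd (n-1) = 0.01
        recs = [
            _rec("a", treated=0.5 + e * 100, control=0.5)
            for e in (0.01, 0.02, 0.03)
        ]
        est = estimate_country_efs(recs)["X1"]
        assert est.mean == pytest.approx(0.02)
        assert est.sd == pytest.approx(0.01)
        assert est.n_points == 3

    def test_single_plot_gets_zero_sd(self, caplog):
        est = estimate_country_efs([_rec(treated=1.0, control=0.5)])["X1"]
        assert est.mean == pytest.approx(0.005)
        assert est.sd == 0.0
        assert "single paired plot" in caplog.text

    def test_two_countries_two_estimates(self):
        recs = [_rec(country="X1"), _rec(country="X2")]
        assert set(estimate_country_efs(recs)) == {"X1", "X2"}


class TestRegionalAndGlobal:
    def test_points_weighted_regional_mean(self):
        efs = {
            "A": DirectEFEstimate("country", "A", 0.01, 0.0, 3),
            "B": DirectEFEstimate("country", "B", 0.02, 0.0, 1),
        }
        reg = estimate_regional_efs(efs, {"A": "Europe", "B": "Europe"})["Europe"]
        assert reg.mean == pytest.approx(0.0125)
        assert reg.n_points == 4

    def test_single_country_region_equals_country(self):
        efs = {"A": DirectEFEstimate("country", "A", 0.013, 0.002, 5)}
        reg = estimate_regional_efs(efs, {"A": "Africa"})["Africa"]
        assert reg.mean == pytest.approx(0.013)
        assert reg.sd == pytest.approx(0.002)
        assert reg.n_points == 5

    def test_regional_sd_matches_pooled_plot_efs(self):
        # independent oracle: sd of the concatenated plot-level EFs
        rng = np.random.default_rng(42)
        efs_a, efs_b = rng.normal(0.01, 0.004, 7), rng.normal(0.02, 0.006, 4)
        country = {
            "A": DirectEFEstimate("country", "A", efs_a.mean(), efs_a.std(ddof=1), 7),
            "B": DirectEFEstimate("country", "B", efs_b.mean(), efs_b.std(ddof=1), 4),
        }
        reg = estimate_regional_efs(country, {"A": "Oceania", "B": "Oceania"})["Oceania"]
        pooled = np.concatenate([efs_a, efs_b])
        assert reg.mean == pytest.approx(np.average(pooled))
        assert reg.sd == pytest.approx(pooled.std(ddof=1))

    def test_country_weighted_global_mean(self):
        regional = {
            "Europe": DirectEFEstimate("region", "Europe", 0.01, 0.0, 50),
            "Africa": DirectEFEstimate("region", "Africa", 0.03, 0.0, 10),
        }
        glob = estimate_global_ef(regional, {"Europe": 5, "Africa": 5})
        assert glob.mean == pytest.approx(0.02)

    def test_single_region_global_equals_regional(self):
        regional = {"Europe": DirectEFEstimate("region", "Europe", 0.011, 0.003, 9)}
        glob = estimate_global_ef(regional, {"Europe": 4})
        assert glob.mean == pytest.approx(0.011)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            estimate_global_ef({}, {})

    def test_estimates_frame_round_trip(self):
        recs = [_rec("a", country="X1"), _rec("b", country="X2", treated=1.4),
                _rec("c", country="X2", treated=0.9)]
        store = estimate_all(recs)
        frame = estimates_to_frame(store)
        back = store_from_frame(frame, store.country_region)
        assert back.global_.mean == pytest.approx(store.global_.mean)
        assert back.country.keys() == store.country.keys()


@st.composite
def plot_records(draw):
    n = draw(st.integers(2, 12))
    recs = []
    for i in range(n):
        country = draw(st.sampled_from(["A", "B", "C"]))
        recs.append(
            PairedPlotRecord(
                f"r{i}", country, "Europe", "crop",
                draw(st.floats(10, 400)),
                draw(st.floats(-2, 5)),
                draw(st.floats(0, 2)),
            )
        )
    return recs


class TestProperties:
    @given(plot_records())
    @settings(max_examples=50, deadline=None)
    def test_order_invariance(self, recs):
        a = estimate_country_efs(recs)
        b = estimate_country_efs(list(reversed(recs)))
        for c in a:
            assert a[c].mean == pytest.approx(b[c].mean)
            assert a[c].sd == pytest.approx(b[c].sd, abs=1e-12)

    @given(plot_records())
    @settings(max_examples=50, deadline=None)
    def test_doubling_flux_difference_doubles_efs(self, recs):
        doubled = [
            PairedPlotRecord(r.record_id, r.country, r.region, r.crop,
                             r.n_applied, r.n2o_control + 2 * (r.n2o_treated - r.n2o_control),
                             r.n2o_control)
            for r in recs
        ]
        a, b = estimate_country_efs(recs), estimate_country_efs(doubled)
        for c in a:
            assert b[c].mean == pytest.approx(2 * a[c].mean, abs=1e-12)

    @given(plot_records())
    @settings(max_examples=50, deadline=None)
    def test_regional_mean_within_member_country_means(self, recs):
        country = estimate_country_efs(recs)
        regions = estimate_regional_efs(country, {c: "Europe" for c in country})
        means = [e.mean for e in country.values()]
        assert min(means) - 1e-12 <= regions["Europe"].mean <= max(means) + 1e-12


class TestParameterRecovery:
    def test_estimates_converge_to_known_truth(self):
        """At 200 plots/country the country estimate sits within
        2 sd/sqrt(n) of the generating truth in >= 90% of seeds."""
        from fertghg.synthetic import gen_paired_plots

        truth = {"X1": 0.012}
        hits = 0
        n = 200
        for seed in range(20):
            plots = gen_paired_plots(truth, n, {"X1": "Europe"}, seed=seed)
            recs, _ = filter_synthetic_only(plots)
            est = estimate_country_efs(recs)["X1"]
            if abs(est.mean - 0.012) < 2 * est.sd / math.sqrt(n):
                hits += 1
        assert hits >= 18
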