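"""Coverage indices: K-S D oracles, gradient joins, summaries, histograms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import surveygap as sg
from surveygap.coverage import ALL_GRADIENTS, temporal_d_duration_weighted

from .conftest import ks_brute_force, survey_stats_frame


class TestKsD:
    def test_identical_multisets_give_zero(self):
        assert sg.ks_d([1, 2, 2, 3], [1, 2, 2, 3]) == 0.0

    def test_disjoint_supports_give_one(self):
        assert sg.ks_d([1, 2, 3], [10, 11]) == 1.0

    def test_hand_example(self):
        # surveyed {1..4} vs background {1..8}: D = 0.5 at x = 4
        assert sg.ks_d([1, 2, 3, 4], list(range(1, 9))) == pytest.approx(0.5)

    def test_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a = rng.choice(20, size=rng.integers(1, 30)) + rng.random()
            b = rng.choice(20, size=rng.integers(1, 30))
            assert sg.ks_d(a, b) == pytest.approx(ks_brute_force(a, b), abs=1e-12)

    def test_ties_handled_right_continuously(self):
        # heavy ties: the sup must be evaluated after the full step at each value
        a = [1, 1, 1, 2]
        b = [1, 2, 2, 2]
        assert sg.ks_d(a, b) == pytest.approx(ks_brute_force(a, b), abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            sg.ks_d([], [1.0])

    @settings(derandomize=True, max_examples=200)
    @given(
        st.lists(st.integers(0, 10), min_size=1, max_size=30),
        st.lists(st.integers(0, 10), min_size=1, max_size=30),
    )
    def test_bounds_and_zero_iff_identical_ecdf(self, a, b):
        d = sg.ks_d(a, b)
        assert 0.0 <= d <= 1.0
        same = ks_brute_force(a, b) == 0.0
        assert (d == 0.0) == same


class TestTemporalD:
    def test_uniform_counts_give_zero(self):
        assert sg.temporal_d([5] * 11) == 0.0

    def test_all_mass_in_first_interval(self):
        assert sg.temporal_d([9] + [0] * 10) == pytest.approx(10 / 11)

    def test_all_mass_in_last_interval(self):
        assert sg.temporal_d([0] * 10 + [9]) == pytest.approx(10 / 11)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            sg.temporal_d([0] * 11)

    def test_duration_weighted_null_flat_for_proportional_counts(self):
        durations = [20] * 10 + [14]
        counts = [20] * 10 + [14]
        assert temporal_d_duration_weighted(counts, durations) == pytest.approx(0.0)


class TestZonalPercent:
    def grid(self):
        return sg.GridSpec(0, 0, 0.2, 0.1, cell_size=0.1)  # two cells side by side

    def test_pixel_counting(self):
        # left cell pixels {21, 81, 41, 41}: urban 25, agriculture 25
        raster = np.array([[21, 81, 22, 22], [41, 41, 22, 22]])
        out = sg.zonal_percent(raster, self.grid())
        left, right = out.iloc[0], out.iloc[1]
        assert (left["urban"], left["agriculture"], left["disturbed"]) == (25, 25, 50)
        assert (right["urban"], right["agriculture"]) == (100, 0)

    def test_empty_class_set_gives_zero(self):
        raster = np.full((2, 4), 41)
        out = sg.zonal_percent(raster, self.grid(), {"urban": set()})
        assert (out["urban"] == 0).all()

    def test_invalid_pixels_excluded(self):
        # left cell has one valid pixel (class 21); right cell all valid
        raster = np.array([[21, -1, 41, 41], [-1, -1, 41, 41]])
        out = sg.zonal_percent(raster, self.grid())
        assert out.iloc[0]["urban"] == pytest.approx(100.0)
        assert out.iloc[1]["urban"] == pytest.approx(0.0)

    def test_misaligned_grid_rejected(self):
        with pytest.raises(ValueError, match="multiple"):
            sg.zonal_percent(np.zeros((3, 5)), self.grid())


class TestJoinGradients:
    def test_constant_raster_gives_constant_cells(self):
        grid = sg.GridSpec(0, 0, 0.3, 0.2, cell_size=0.1)
        out = sg.join_gradients(grid, {"elevation": np.full((4, 6), 7.5)})
        assert (out["elevation"] == 7.5).all()
        assert len(out) == 6

    def test_fine_linear_trend_recovers_cell_center_value(self):
        grid = sg.GridSpec(0, 0, 0.5, 0.1, cell_size=0.1)
        nx = 50  # 10x finer than cells
        px = (np.arange(nx) + 0.5) / nx * 0.5  # pixel-center longitudes
        raster = np.tile(px * 100.0, (10, 1))
        out = sg.join_gradients(grid, {"mat": raster})
        centers = out["longitude"].to_numpy() * 100.0
        step = 0.5 / nx * 100.0
        assert np.abs(out["mat"].to_numpy() - centers).max() <= step / 2

    def test_landscape_round_trip(self, landscape):
        src = landscape.table.set_index("cell_id")
        out = sg.join_gradients(landscape.grid, {"mat": src["mat"], "map": src["map"]})
        assert np.allclose(out["mat"], landscape.table["mat"])
        assert np.allclose(out["latitude"], landscape.table["latitude"])

    def test_mostly_missing_gradient_is_hard_error(self):
        grid = sg.GridSpec(0, 0, 1.0, 1.0, cell_size=0.1)
        sparse = pd.Series([1.0, 2.0], index=[0, 1])
        with pytest.raises(ValueError, match="missing"):
            sg.join_gradients(grid, {"elevation": sparse})


def make_classified(landscape, pool, seed, dataset="d", **effort_kw):
    effort = sg.EffortModel(seed=seed, **effort_kw)
    records, _ = sg.simulate_records(landscape, pool, effort)
    return survey_stats_frame(
        records, landscape.grid, sg.TimePeriodScheme.standard(), dataset
    )


class TestCoverageMatrix:
    def test_full_survey_gives_zero_d_everywhere(self, landscape, uniform_pool):
        classified = make_classified(
            landscape, uniform_pool, seed=9,
            mean_effort=60, visited_fraction=1.0, dispersion=np.inf,
        )
        cov = sg.coverage_matrix(classified, landscape.gradients())
        assert len(cov) == 22  # 1 dataset x 11 gradients x 2 classes
        spatial = cov[(cov["gradient"] != "temporal")
                      & (cov["cell_class"] == "all_surveyed")]
        assert (spatial["D"] == 0.0).all()

    def test_biased_sampling_raises_d_on_biased_gradient(self, landscape, uniform_pool):
        classified = make_classified(
            landscape, uniform_pool, seed=10,
            mean_effort=20, visited_fraction=0.3, bias_gradient="mat", beta=3.0,
        )
        cov = sg.coverage_matrix(classified, landscape.gradients())
        sub = cov[cov["cell_class"] == "all_surveyed"].set_index("gradient")["D"]
        # dmap is generated independently of MAT; bias on MAT must dominate it
        assert sub["mat"] > sub["dmap"]

    def test_empty_well_surveyed_class_marked_na(self, landscape, logseries_pool):
        classified = make_classified(
            landscape, logseries_pool, seed=11, mean_effort=3, visited_fraction=0.2,
        )
        assert not classified["pass_moderate"].any()  # sparse effort: nothing passes
        cov = sg.coverage_matrix(classified, landscape.gradients())
        ws = cov[cov["cell_class"] == "well_surveyed"]
        assert ws["D"].isna().all()
        assert (ws["n_surveyed"] == 0).all()

    def test_unknown_gradient_rejected(self, landscape, uniform_pool):
        classified = make_classified(landscape, uniform_pool, seed=9,
                                     mean_effort=10, visited_fraction=0.5)
        with pytest.raises(ValueError, match="unknown gradient"):
            sg.coverage_matrix(classified, landscape.gradients(),
                               gradient_names=["mat", "phlogiston"])


class TestSummarizeCoverage:
    def constant_coverage(self, n_datasets, d=0.26):
        rows = []
        for i in range(n_datasets):
            for cls in ("all_surveyed", "well_surveyed"):
                for grad in ALL_GRADIENTS:
                    rows.append({"dataset": f"ds{i:02d}", "gradient": grad,
                                 "cell_class": cls, "D": d,
                                 "n_surveyed": 5, "n_background": 100})
        return pd.DataFrame(rows)

    def test_constant_table_sums_and_means(self):
        cov = self.constant_coverage(1, d=0.1)
        out = sg.summarize_coverage(cov)
        cum = out["cumulative"]
        assert np.allclose(cum["cumulative_D"], 1.1)
        gm = out["gradient_group_means"]
        for col in [c for c in gm.columns if c.startswith("mean_D_")]:
            assert np.allclose(gm[col], 0.1)

    def test_grand_mean_on_264_entry_table(self):
        # 12 dataset x 11 gradient x 2 class entries at a constant index
        cov = self.constant_coverage(12, d=0.26)
        assert len(cov) == 264
        pooled = sg.summarize_coverage(cov)["pooled"]
        row = pooled[pooled["cell_class"] == "pooled"].iloc[0]
        assert row["mean_D"] == pytest.approx(0.26)
        assert row["n_tests"] == 264

    def test_group_means_match_hand_average(self):
        cov = self.constant_coverage(2)
        cov.loc[(cov["dataset"] == "ds00") & (cov["gradient"] == "latitude")
                & (cov["cell_class"] == "all_surveyed"), "D"] = 0.5
        out = sg.summarize_coverage(cov)["gradient_group_means"]
        row = out[(out["dataset"] == "ds00")
                  & (out["cell_class"] == "all_surveyed")].iloc[0]
        assert row["mean_D_spatial"] == pytest.approx((0.5 + 0.26) / 2)

    def test_cumulative_equals_sum_of_gradient_ds(self, landscape, uniform_pool):
        classified = make_classified(landscape, uniform_pool, seed=12,
                                     mean_effort=15, visited_fraction=0.4)
        cov = sg.coverage_matrix(classified, landscape.gradients())
        out = sg.summarize_coverage(cov)["cumulative"]
        for _, row in out.iterrows():
            manual = cov[(cov["dataset"] == row["dataset"])
                         & (cov["cell_class"] == row["cell_class"])]["D"].sum(
                skipna=False)
            assert row["cumulative_D"] == manual or (
                np.isnan(row["cumulative_D"]) and np.isnan(manual))

    def test_na_rows_excluded_from_means_and_counted(self):
        cov = self.constant_coverage(1)
        cov.loc[cov.index[:2], "D"] = np.nan
        out = sg.summarize_coverage(cov)["gradient_group_means"]
        assert out["n_excluded_all"].sum() == 2

    def test_dataset_group_means(self):
        cov = self.constant_coverage(2, d=0.2)
        out = sg.summarize_coverage(
            cov, dataset_groups={"first": ["ds00"], "both": ["ds00", "ds01"]}
        )["dataset_group_means"]
        assert np.allclose(out["mean_D_first"], 0.2)

    def test_empty_gradient_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sg.summarize_coverage(self.constant_coverage(1), gradient_groups={"g": []})


class TestHistograms:
    def test_identical_populations_identical_histograms(self):
        v = np.arange(50.0)
        h = sg.export_histograms(v, v, n_bins=10)
        assert np.allclose(h["freq_surveyed"], h["freq_background"])

    def test_frequencies_normalized(self):
        rng = np.random.default_rng(4)
        h = sg.export_histograms(rng.random(40), rng.random(400), n_bins=7)
        assert h["freq_surveyed"].sum() == pytest.approx(1.0, abs=1e-12)
        assert h["freq_background"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_fine_binned_cumulative_recovers_d(self):
        rng = np.random.default_rng(5)
        s = rng.normal(0.3, 1.0, 150)
        b = rng.normal(0.0, 1.0, 200)
        h = sg.export_histograms(s, b, n_bins=2000)
        d_binned = np.abs(np.cumsum(h["freq_surveyed"]) -
                          np.cumsum(h["freq_background"])).max()
        assert abs(d_binned - sg.ks_d(s, b)) <= 2 / min(len(s), len(b))

    def test_zero_bins_rejected(self):
        with pytest.raises(ValueError):
            sg.export_histograms([1.0], [1.0], n_bins=0)
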