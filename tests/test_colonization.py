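import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mycoroot.colonization import (
    assign_plots_to_units,
    categorical_to_percent,
    filter_records,
    plot_weighted_intensity,
    select_plot_subset,
    species_mean_colonization,
    split_dual_abundance,
    unit_intensity,
)
from mycoroot.errors import DataError, MissingDataError
from mycoroot.raster import RasterGrid
from mycoroot.spatial_units import build_unit_map


def _records(rows):
    return pd.DataFrame(
        rows, columns=["species", "value", "unit_kind", "naturalness", "season"]
    )


class TestFilterRecords:
    @pytest.mark.parametrize(
        "naturalness,season,kept",
        [
            ("natural", "growing", True),
            ("non_natural", "growing", False),  # plantations, pots, nurseries
            ("natural", "non_growing", False),
            ("unknown", "unknown", True),  # maintained when not stated
        ],
    )
    def test_naturalness_and_season_rules(self, naturalness, season, kept):
        recs = _records([("Acer sp1", 40.0, "AM", naturalness, season)])
        assert len(filter_records(recs)) == (1 if kept else 0)


class TestCategoricalToPercent:
    def test_labels_replaced_via_mapping(self):
        recs = _records([("A a", "class2", "AM", "natural", "growing")])
        out = categorical_to_percent(recs, {"class2": 37.5})
        assert out["value"].tolist() == [37.5]

    def test_numeric_values_pass_through(self):
        recs = _records([("A a", 42, "AM", "natural", "growing")])
        out = categorical_to_percent(recs, {})
        assert out["value"].tolist() == [42.0]

    def test_unmapped_label_raises_with_label_name(self):
        recs = _records([("A a", "classX", "AM", "natural", "growing")])
        with pytest.raises(DataError, match="classX"):
            categorical_to_percent(recs, {"class2": 37.5})

    def test_out_of_range_percent_raises(self):
        recs = _records([("A a", 130.0, "AM", "natural", "growing")])
        with pytest.raises(DataError):
            categorical_to_percent(recs, {})


class TestSpeciesMeans:
    def test_mean_and_count_per_kind(self):
        recs = _records(
            [
                ("Acer sp1", 40.0, "AM", "natural", "growing"),
                ("Acer sp1", 60.0, "AM", "natural", "growing"),
                ("Acer sp1", 30.0, "EcM", "natural", "growing"),
            ]
        )
        out = species_mean_colonization(recs).set_index(["species", "unit_kind"])
        assert out.loc[("acer sp1", "AM"), "mean_intensity"] == 50.0
        assert out.loc[("acer sp1", "AM"), "n_obs"] == 2
        assert out.loc[("acer sp1", "EcM"), "mean_intensity"] == 30.0

    def test_names_matched_case_insensitively(self):
        recs = _records(
            [
                ("ACER  sp1", 10.0, "AM", "natural", "growing"),
                ("acer sp1", 30.0, "AM", "natural", "growing"),
            ]
        )
        out = species_mean_colonization(recs)
        assert len(out) == 1 and out.loc[0, "mean_intensity"] == 20.0

    def test_statistical_recovery_of_true_mean(self, rng):
        mu, sd, n = 55.0, 8.0, 400
        recs = _records(
            [("X x", v, "AM", "natural", "growing") for v in rng.normal(mu, sd, n)]
        )
        out = species_mean_colonization(recs)
        assert out.loc[0, "mean_intensity"] == pytest.approx(mu, abs=3 * sd / np.sqrt(n))


class TestSplitDualAbundance:
    traits = pd.DataFrame(
        {
            "genus": ["Amgen", "Ecmgen", "Dualgen", "Facgen", "Othergen"],
            "myc_type": ["AM", "EcM", "dual", "facultative_AM", "other"],
        }
    )

    def _plots(self, rows):
        return pd.DataFrame(rows, columns=["plot_id", "lon", "lat", "species", "rel_abundance"])

    def test_dual_species_split_half_and_half(self):
        plots = self._plots([("p1", 0.0, 0.0, "Dualgen sp1", 0.30)])
        out = split_dual_abundance(plots, self.traits)
        shares = out.set_index("myc_type")["abundance"]
        assert shares.loc["AM"] == pytest.approx(0.15)
        assert shares.loc["EcM"] == pytest.approx(0.15)

    def test_pure_type_keeps_full_abundance(self):
        plots = self._plots([("p1", 0.0, 0.0, "Amgen sp1", 0.2)])
        out = split_dual_abundance(plots, self.traits)
        assert out["myc_type"].tolist() == ["AM"]
        assert out["abundance"].tolist() == [0.2]

    def test_facultative_am_counts_as_am(self):
        plots = self._plots([("p1", 0.0, 0.0, "Facgen sp1", 0.4)])
        out = split_dual_abundance(plots, self.traits)
        assert out["myc_type"].tolist() == ["AM"]

    @pytest.mark.parametrize("species", ["Othergen sp1", "Nowheregen sp1"])
    def test_unassignable_species_excluded(self, species):
        plots = self._plots([("p1", 0.0, 0.0, species, 0.5)])
        assert split_dual_abundance(plots, self.traits).empty

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(abundance=st.floats(0.0, 1.0))
    def test_dual_split_conserves_total_abundance(self, abundance):
        plots = self._plots([("p1", 0.0, 0.0, "Dualgen sp1", abundance)])
        out = split_dual_abundance(plots, self.traits)
        assert out["abundance"].sum() == pytest.approx(abundance, abs=1e-12)


def _unit_map_1d(n):
    shape = (1, n)
    mk = lambda arr: RasterGrid(np.asarray(arr, dtype=np.int32), 0.0, 1.0, 1.0, 1.0)
    return build_unit_map(
        mk(np.arange(1, n + 1).reshape(shape)),
        mk(np.ones(shape)),
        mk(np.ones(shape)),
        excluded_classes=(),
    )


def _plot(plot_id, lon):
    return ("%s" % plot_id, lon, 0.5, "Sp x", 1.0)


class TestSelectPlotSubset:
    cols = ["plot_id", "lon", "lat", "species", "rel_abundance"]

    def test_largest_coverage_wins(self):
        units = _unit_map_1d(3)
        s1 = pd.DataFrame([_plot("a", 0.5), _plot("b", 1.5)], columns=self.cols)
        s2 = pd.DataFrame(
            [_plot("c", 0.5), _plot("d", 1.5), _plot("e", 2.5)], columns=self.cols
        )
        chosen, report = select_plot_subset([s1, s2], units)
        assert report["chosen_subset"] == 1
        assert set(chosen["plot_id"]) == {"c", "d", "e"}

    def test_tie_goes_to_first_subset(self):
        units = _unit_map_1d(2)
        s1 = pd.DataFrame([_plot("a", 0.5), _plot("b", 1.5)], columns=self.cols)
        s2 = pd.DataFrame([_plot("c", 0.5), _plot("d", 1.5)], columns=self.cols)
        _, report = select_plot_subset([s1, s2], units)
        assert report["chosen_subset"] == 0

    def test_empty_units_supplemented_from_other_subsets(self):
        units = _unit_map_1d(3)
        s1 = pd.DataFrame([_plot("a", 0.5), _plot("b", 1.5)], columns=self.cols)
        s2 = pd.DataFrame([_plot("c", 2.5), _plot("d", 0.6)], columns=self.cols)
        chosen, report = select_plot_subset([s1, s2], units)
        assert report["chosen_subset"] == 0
        assert set(chosen["plot_id"]) == {"a", "b", "c"}  # d covers a full unit
        # brute-force recount: coverage after supplementation is all 3 units
        covered = {units.unit_at(lon, lat) for lon, lat in zip(chosen["lon"], chosen["lat"])}
        assert covered == {1, 2, 3}

    def test_all_subsets_empty_raises(self):
        units = _unit_map_1d(1)
        empty = pd.DataFrame(columns=self.cols)
        with pytest.raises(MissingDataError):
            select_plot_subset([empty, empty], units)


class TestPlotWeightedIntensity:
    def test_worked_example_renormalizes_over_covered_species(self):
        # A 0.6 abundance / mean 40%, B 0.2 / 10%, C 0.2 / no data
        plot = pd.DataFrame(
            {
                "species": ["a a", "b b", "c c"],
                "myc_type": ["AM"] * 3,
                "growth_form": ["woody"] * 3,
                "abundance": [0.6, 0.2, 0.2],
            }
        )
        means = pd.DataFrame(
            {
                "species": ["a a", "b b"],
                "unit_kind": ["AM", "AM"],
                "mean_intensity": [40.0, 10.0],
                "n_obs": [2, 4],
            }
        )
        out = plot_weighted_intensity(plot, means)
        row = out.iloc[0]
        assert row["intensity"] == pytest.approx(32.5)
        assert row["coverage"] == pytest.approx(80.0)
        assert row["mean_obs_per_species"] == pytest.approx(3.0)

    def test_single_covered_species_returns_its_mean(self):
        plot = pd.DataFrame(
            {
                "species": ["a a"],
                "myc_type": ["AM"],
                "growth_form": ["herbaceous"],
                "abundance": [0.37],
            }
        )
        means = pd.DataFrame(
            {"species": ["a a"], "unit_kind": ["AM"], "mean_intensity": [63.0], "n_obs": [1]}
        )
        out = plot_weighted_intensity(plot, means)
        assert out.iloc[0]["intensity"] == pytest.approx(63.0)
        assert out.iloc[0]["coverage"] == pytest.approx(100.0)

    def test_pool_without_data_is_empty(self):
        plot = pd.DataFrame(
            {
                "species": ["a a"],
                "myc_type": ["AM"],
                "growth_form": ["woody"],
                "abundance": [0.5],
            }
        )
        means = pd.DataFrame(
            {"species": [], "unit_kind": [], "mean_intensity": [], "n_obs": []}
        )
        assert plot_weighted_intensity(plot, means).empty

    def test_unknown_growth_form_kept_only_in_tundra_pool(self):
        plot = pd.DataFrame(
            {
                "species": ["a a"],
                "myc_type": ["AM"],
                "growth_form": ["unknown"],
                "abundance": [0.5],
            }
        )
        means = pd.DataFrame(
            {"species": ["a a"], "unit_kind": ["AM"], "mean_intensity": [50.0], "n_obs": [1]}
        )
        assert plot_weighted_intensity(plot, means, tundra=False).empty
        tundra = plot_weighted_intensity(plot, means, tundra=True)
        assert tundra.iloc[0]["growth_form"] == "tundra_all"

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_intensity_bounded_by_species_means_and_weights_renormalized(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(2, 8))
        means_vals = r.uniform(0, 100, n)
        plot = pd.DataFrame(
            {
                "species": [f"s{i} x" for i in range(n)],
                "myc_type": ["AM"] * n,
                "growth_form": ["woody"] * n,
                "abundance": r.dirichlet(np.ones(n)),
            }
        )
        means = pd.DataFrame(
            {
                "species": [f"s{i} x" for i in range(n - 1)],  # last species uncovered
                "unit_kind": ["AM"] * (n - 1),
                "mean_intensity": means_vals[: n - 1],
                "n_obs": np.ones(n - 1, dtype=int),
            }
        )
        out = plot_weighted_intensity(plot, means)
        if out.empty:
            return
        row = out.iloc[0]
        lo, hi = means_vals[: n - 1].min(), means_vals[: n - 1].max()
        assert lo - 1e-9 <= row["intensity"] <= hi + 1e-9
        # renormalized weights sum to one within float tolerance
        assert row["covered_abundance"] > 0


class TestUnitIntensity:
    def test_unweighted_mean_over_plots(self):
        pools = pd.DataFrame(
            {
                "unit_id": [1, 1],
                "plot_id": ["p1", "p2"],
                "myc_type": ["AM", "AM"],
                "growth_form": ["woody", "woody"],
                "intensity": [30.0, 50.0],
                "coverage": [100.0, 80.0],
                "mean_obs_per_species": [2.0, 4.0],
                "n_species_covered": [2, 3],
                "total_abundance": [1.0, 1.0],
                "covered_abundance": [1.0, 0.8],
            }
        )
        out = unit_intensity(pools)
        row = out.iloc[0]
        assert row["mean_intensity"] == pytest.approx(40.0)
        assert row["n_plots"] == 2
        assert row["mean_obs_per_species"] == pytest.approx(3.0)
        assert row["mean_coverage"] == pytest.approx(90.0)

    def test_unit_without_plots_absent(self):
        pools = pd.DataFrame(
            columns=[
                "unit_id",
                "plot_id",
                "myc_type",
                "growth_form",
                "intensity",
                "coverage",
                "mean_obs_per_species",
                "n_species_covered",
                "total_abundance",
                "covered_abundance",
            ]
        )
        assert unit_intensity(pools).empty


def test_plots_on_nodata_pixels_are_dropped(exact_world, exact_result):
    plots = exact_world.inputs.plots
    assigned = assign_plots_to_units(plots, exact_result.units)
    n_unique = plots["plot_id"].nunique()
    uid = exact_result.units.unit_raster
    on_valid = sum(
        1
        for p, lon, lat in plots[["plot_id", "lon", "lat"]]
        .drop_duplicates("plot_id")
        .itertuples(index=False)
        if exact_result.units.unit_at(lon, lat) is not None
    )
    assert len(assigned) == on_valid <= n_unique
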