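import numpy as np
import pandas as pd
import pytest

from mycoroot.colonization import TUNDRA_POOL, genus_of
from mycoroot.errors import ConfigurationError
from mycoroot.synthetic_data import (
    WorldConfig,
    generate_categorical_colonization,
    generate_world,
    read_world,
    write_world,
)

from oracles import brute_unit_triples


class TestWorldConfig:
    def test_excluded_classes_covering_everything_rejected(self):
        with pytest.raises(ConfigurationError):
            WorldConfig(
                n_landcover_classes=2, excluded_classes=frozenset({1, 2})
            ).validate()

    def test_proportion_out_of_range_rejected(self):
        with pytest.raises(ConfigurationError):
            WorldConfig(fraction_woody=1.5).validate()

    def test_yaml_round_trip(self, tmp_path):
        cfg = WorldConfig(
            grid_shape=(10, 12),
            plots_per_unit=(3, 7),
            categorical_class_bounds=((0.0, 50.0), (50.0, 100.0)),
            true_intensity_per_unit={(1, 1, 1): {("AM", "woody"): 42.0}},
            seed=99,
        )
        cfg.to_yaml(tmp_path / "cfg.yml")
        assert WorldConfig.from_yaml(tmp_path / "cfg.yml") == cfg


class TestCategoricalColonization:
    bounds = ((0.0, 25.0), (25.0, 50.0), (50.0, 100.0))

    @staticmethod
    def _records(values):
        return pd.DataFrame(
            {
                "species": [f"G sp{i}" for i in range(len(values))],
                "value": values,
                "unit_kind": "AM",
                "naturalness": "natural",
                "season": "growing",
            }
        )

    def test_value_falls_in_stated_class_with_midpoint_mapping(self):
        out, mapping = generate_categorical_colonization(
            self._records([37.0]), self.bounds, fraction=1.0
        )
        assert out.loc[0, "value"] == "class2"
        assert mapping["class2"] == 37.5

    def test_zero_goes_to_lowest_class(self):
        out, _ = generate_categorical_colonization(
            self._records([0.0]), self.bounds, fraction=1.0
        )
        assert out.loc[0, "value"] == "class1"

    def test_hundred_goes_to_highest_class(self):
        out, _ = generate_categorical_colonization(
            self._records([100.0]), self.bounds, fraction=1.0
        )
        assert out.loc[0, "value"] == "class3"

    def test_empty_bounds_convert_nothing(self):
        recs = self._records([10.0, 90.0])
        out, mapping = generate_categorical_colonization(recs, [])
        pd.testing.assert_frame_equal(out, recs)
        assert mapping == {}

    @pytest.mark.parametrize(
        "bounds",
        [
            ((0.0, 30.0), (40.0, 100.0)),  # gap
            ((0.0, 60.0), (50.0, 100.0)),  # overlap
            ((10.0, 50.0), (50.0, 100.0)),  # does not start at 0
        ],
    )
    def test_non_partition_bounds_rejected(self, bounds):
        with pytest.raises(ConfigurationError):
            generate_categorical_colonization(self._records([10.0]), bounds)


class TestGenerateWorld:
    def test_same_seed_gives_byte_identical_files(self, tmp_path):
        cfg = WorldConfig(grid_shape=(12, 12), species_pool_size=60, plots_per_unit=4, seed=21)
        d1, d2 = tmp_path / "w1", tmp_path / "w2"
        write_world(generate_world(cfg), d1)
        write_world(generate_world(cfg), d2)
        files = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
        assert files == sorted(p.relative_to(d2) for p in d2.rglob("*") if p.is_file())
        for f in files:
            assert (d1 / f).read_bytes() == (d2 / f).read_bytes(), f

    def test_rasters_share_grid_and_nodata_convention(self, default_world):
        inp = default_world.inputs
        coarse = [inp.ecoregion, inp.continent, inp.am_tree, inp.ecm_total]
        for g in coarse[1:]:
            assert coarse[0].same_grid(g)
        fine = [inp.landcover_fine, inp.bgb_woody_fine, inp.bgb_tundra_fine]
        for g in fine[1:]:
            assert fine[0].same_grid(g)
        assert fine[0].pixel_width * inp.fine_factor == pytest.approx(
            coarse[0].pixel_width
        )

    def test_am_plus_ecm_fraction_bounded_within_each_growth_form(self, default_world):
        inp = default_world.inputs
        for am, ecm in [
            (inp.am_tree, inp.ecm_tree),
            (inp.am_shrub, inp.ecm_shrub),
            (inp.am_herb, inp.ecm_herb),
            (inp.am_total, inp.ecm_total),
        ]:
            valid = am.valid_mask()
            total = am.values[valid] + ecm.values[valid]
            assert (total <= 1.0 + 1e-9).all()

    def test_no_dual_species_when_fraction_dual_is_zero(self):
        cfg = WorldConfig(
            grid_shape=(12, 12), species_pool_size=120, plots_per_unit=4,
            fraction_dual_type=0.0, seed=3,
        )
        world = generate_world(cfg)
        traits = world.inputs.myc_type_traits
        dual_genera = set(traits.loc[traits["myc_type"] == "dual", "genus"])
        species = world.inputs.plots["species"]
        # brute-force recount of the emitted plot table: no species of a dual
        # genus occurs, so AM+EcM abundance equals the single-type total
        assert not species.map(genus_of).isin(dual_genera).any()

    def test_ground_truth_recomputable_from_emitted_files(self, exact_world):
        """Brute-force recomputation of per-unit truths from emitted rasters."""
        inp = exact_world.inputs
        truth = exact_world.truth
        f = inp.fine_factor
        # units from a scan of the emitted categorical layers
        lc_off = (f - 1) // 2
        lc = inp.landcover_fine.values[lc_off::f, lc_off::f]
        triples = brute_unit_triples(
            inp.ecoregion.values, lc, inp.continent.values, set(inp.excluded_classes)
        )
        assert len(triples) == len(truth.unit_table)

        # per-unit mean AM fraction from the emitted fraction raster
        table = truth.unit_table.set_index("unit_id")
        frac = truth.unit_fractions.set_index("unit_id")
        for uid in list(table.index[:6]):
            row = table.loc[uid]
            mask = (
                (inp.ecoregion.values == row["ecoregion"])
                & (lc == row["landcover"])
                & (inp.continent.values == row["continent"])
            )
            am = inp.am_total.values[mask]
            assert np.allclose(
                am.mean(), frac.loc[uid, "am_fraction"], rtol=1e-12
            )

    def test_species_truth_consistent_with_records_at_zero_noise(self, exact_world):
        recs = exact_world.inputs.colonization_records
        clean = recs[(recs["naturalness"] != "non_natural") & (recs["season"] != "non_growing")]
        means = clean.groupby(["species", "unit_kind"])["value"].mean()
        truth = exact_world.truth.species_means.set_index(["species", "unit_kind"])
        # every species with records: observed mean equals the true trait value
        for (species, kind), mu in means.items():
            assert mu == pytest.approx(truth.loc[(species, kind), "true_mean"], rel=1e-12)

    def test_flagged_records_are_biased_and_marked(self, default_world):
        recs = default_world.inputs.colonization_records
        flagged = recs[(recs["naturalness"] == "non_natural") | (recs["season"] == "non_growing")]
        assert len(flagged) > 0

    def test_world_round_trips_through_disk(self, tmp_path, default_world):
        write_world(default_world, tmp_path / "w")
        back = read_world(tmp_path / "w")
        assert back.config == default_world.config
        pd.testing.assert_frame_equal(
            back.truth.unit_pools, default_world.truth.unit_pools
        )
        assert np.array_equal(
            back.inputs.landcover_fine.values,
            default_world.inputs.landcover_fine.values,
        )
        assert back.categorical_mapping == default_world.categorical_mapping
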