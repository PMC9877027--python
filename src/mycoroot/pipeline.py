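"""End-to-end orchestration of the mycorrhizal root-stock mapping workflow.

``run_pipeline`` takes a complete input world (rasters + tables, see
:class:`PipelineInputs`), and chains the stages:

1. nearest-neighbour coarsening of the fine land-cover layer and overlay
   into the spatial-unit map (with land-cover exclusions);
2. block-mean aggregation of the belowground biomass layers, conversion to
   fine-root stocks in the top of the soil, and multiplication with the
   AM/EcM fractions (tree+shrub summed into woody; the growth-form-free
   tundra path for tundra units); zonal means per unit pool;
3. record filtering, categorical conversion, species trait means, plot
   subset selection, dual-type abundance splitting, community-weighted plot
   intensities and unit-level averaging;
4. colonized stocks per pool, pool-level gap-filling by ecoregion x
   continent mean, per-type totals, rasterization (piecewise constant per
   unit, as in the published product) and quality-index layers.

The result object carries every intermediate table plus the output rasters
(Table-2-style names: ``AM_roots``, ``AM_roots_colonized``,
``AM_roots_colonized_filled``, ``AM_intensity_colonization``, per-form
colonized layers and the three quality layers per type).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import colonization as col
from . import map_assembly as ma
from .quality import quality_rasters, unit_quality
from .raster import RasterGrid, aggregate_mean, resample_categorical_nearest
from .root_stocks import (
    RootFractionParams,
    fine_fraction_from_ratios,
    fine_root_stock,
    myc_root_stock,
    woody_myc_fraction,
    zonal_mean,
)
from .spatial_units import SpatialUnitMap, build_unit_map
from .colonization import TUNDRA_POOL

__all__ = ["PipelineInputs", "PipelineResult", "run_pipeline"]

_FORM_LABEL = {"woody": "woody", "herbaceous": "herbs", TUNDRA_POOL: "tundra"}


@dataclass
class PipelineInputs:
    """The full input world of the mapping workflow.

    Rasters are WGS84 lon/lat. ``landcover_fine`` and the three biomass
    layers are at fine resolution (``fine_factor`` times the coarse pixel);
    everything else is at the coarse (output) resolution. Tables follow the
    documented CSV headers; ``plots`` carries a ``subset`` column with the
    candidate resampled subsets.
    """

    ecoregion: RasterGrid
    landcover_fine: RasterGrid
    continent: RasterGrid
    bgb_woody_fine: RasterGrid
    bgb_herb_fine: RasterGrid
    bgb_tundra_fine: RasterGrid
    am_tree: RasterGrid
    am_shrub: RasterGrid
    am_herb: RasterGrid
    ecm_tree: RasterGrid
    ecm_shrub: RasterGrid
    ecm_herb: RasterGrid
    am_total: RasterGrid
    ecm_total: RasterGrid
    colonization_records: pd.DataFrame
    plots: pd.DataFrame
    growth_form_traits: pd.DataFrame
    myc_type_traits: pd.DataFrame
    ratio_table: pd.DataFrame
    fine_factor: int = 1
    excluded_classes: frozenset[int] = frozenset()
    tundra_ecoregions: frozenset[int] = frozenset()
    categorical_mapping: Mapping[str, float] = field(default_factory=dict)


@dataclass
class PipelineResult:
    units: SpatialUnitMap
    params: RootFractionParams
    stock_pools: pd.DataFrame
    species_means: pd.DataFrame
    plot_pools: pd.DataFrame
    unit_colonization: pd.DataFrame
    unit_summary: pd.DataFrame
    unit_summary_observed: pd.DataFrame
    unit_totals: pd.DataFrame
    unit_totals_observed: pd.DataFrame
    quality: pd.DataFrame
    rasters: dict[str, RasterGrid]
    report: dict


def _pool_stock_rasters(
    inputs: PipelineInputs, params: RootFractionParams
) -> tuple[dict[tuple[str, str], RasterGrid], dict[str, RasterGrid]]:
    """Per-pool mycorrhizal fine-root stock rasters at coarse resolution."""
    f = inputs.fine_factor
    bgb = {
        "woody": aggregate_mean(inputs.bgb_woody_fine, f),
        "herbaceous": aggregate_mean(inputs.bgb_herb_fine, f),
        TUNDRA_POOL: aggregate_mean(inputs.bgb_tundra_fine, f),
    }
    fine_roots = {
        form: fine_root_stock(
            grid, params.fine_fraction_for(form), params.depth_fraction_for(form)
        )
        for form, grid in bgb.items()
    }
    fractions = {
        ("AM", "woody"): woody_myc_fraction(inputs.am_tree, inputs.am_shrub),
        ("EcM", "woody"): woody_myc_fraction(inputs.ecm_tree, inputs.ecm_shrub),
        ("AM", "herbaceous"): inputs.am_herb,
        ("EcM", "herbaceous"): inputs.ecm_herb,
        ("AM", TUNDRA_POOL): inputs.am_total,
        ("EcM", TUNDRA_POOL): inputs.ecm_total,
    }
    pools = {
        (myc, form): myc_root_stock(fine_roots[form], frac)
        for (myc, form), frac in fractions.items()
    }
    return pools, fine_roots


def run_pipeline(
    inputs: PipelineInputs,
    params: RootFractionParams | None = None,
    recompute_fine_fractions: bool = False,
) -> PipelineResult:
    """Run the whole workflow on an input world; see the module docstring.

    With ``recompute_fine_fractions`` the fine-root fractions are rederived
    from the coarse/fine ratio table (back-transformed log means) instead of
    using the shipped constants.
    """
    params = params or RootFractionParams()
    if recompute_fine_fractions:
        ffw = fine_fraction_from_ratios(inputs.ratio_table, "woody")
        ffh = fine_fraction_from_ratios(inputs.ratio_table, "herbaceous")
        params = RootFractionParams(
            fine_fraction_woody=ffw,
            fine_fraction_herb=ffh,
            fine_fraction_tundra=ffh,
            beta_tree=params.beta_tree,
            beta_shrub=params.beta_shrub,
            beta_herb=params.beta_herb,
            beta_tundra=params.beta_tundra,
            depth_cm=params.depth_cm,
        )
    report: dict = {}

    # 1. spatial units -----------------------------------------------------
    landcover = resample_categorical_nearest(inputs.landcover_fine, inputs.fine_factor)
    units = build_unit_map(
        inputs.ecoregion,
        landcover,
        inputs.continent,
        inputs.excluded_classes,
        inputs.tundra_ecoregions,
    )
    report["n_units"] = units.n_units

    # 2. stocks ------------------------------------------------------------
    pool_rasters, fine_roots = _pool_stock_rasters(inputs, params)
    tundra_ids = units.tundra_unit_ids()
    stock_rows = []
    for (myc, form), grid in pool_rasters.items():
        zm = zonal_mean(grid, units)
        for unit_id, value in zm.items():
            is_tundra = unit_id in tundra_ids
            if is_tundra != (form == TUNDRA_POOL):
                continue
            stock_rows.append((unit_id, myc, form, value))
    stock_pools = pd.DataFrame(
        stock_rows, columns=["unit_id", "myc_type", "growth_form", "fine_root_stock"]
    ).sort_values(["unit_id", "myc_type", "growth_form"], ignore_index=True)

    # 3. colonization intensity --------------------------------------------
    records = col.filter_records(inputs.colonization_records)
    records = col.categorical_to_percent(records, inputs.categorical_mapping)
    species_means = col.species_mean_colonization(records)

    subset_ids = sorted(inputs.plots["subset"].unique()) if "subset" in inputs.plots else [0]
    if "subset" in inputs.plots:
        subsets = [inputs.plots[inputs.plots["subset"] == s] for s in subset_ids]
    else:
        subsets = [inputs.plots]
    chosen_plots, subset_report = col.select_plot_subset(subsets, units)
    report["plot_subsets"] = subset_report

    resolved = col.split_dual_abundance(
        chosen_plots, inputs.myc_type_traits, inputs.growth_form_traits
    )
    plot_units = col.assign_plots_to_units(chosen_plots, units)
    report["n_plots_assigned"] = len(plot_units)
    plot_pools = col.plots_weighted_intensity(resolved, species_means, plot_units, units)
    unit_colonization = col.unit_intensity(plot_pools)

    # 4. assembly ----------------------------------------------------------
    summary = ma.build_unit_summary(
        stock_pools, unit_colonization, units.unit_table, apply_gap_fill=True
    )
    summary_observed = ma.build_unit_summary(
        stock_pools, unit_colonization, units.unit_table, apply_gap_fill=False
    )
    totals = ma.combine_pools(summary, units.unit_table)
    totals_observed = ma.combine_pools(summary_observed, units.unit_table)
    report["n_pools_gap_filled"] = int(
        (summary["fill_status"] == ma.FILL_GROUP_MEAN).sum()
    )
    report["n_pools_unfilled"] = int(
        (summary["fill_status"] == ma.FILL_UNFILLED).sum()
    )

    quality = unit_quality(plot_pools)

    # 5. rasters -----------------------------------------------------------
    rasters: dict[str, RasterGrid] = {}
    all_ids = units.unit_table["unit_id"].to_numpy()

    def _series(frame: pd.DataFrame, column: str) -> pd.Series:
        s = frame.set_index("unit_id")[column].astype(float).reindex(all_ids)
        s.index = all_ids
        return s

    for myc in ("AM", "EcM"):
        tot = totals[totals["myc_type"] == myc]
        tot_obs = totals_observed[totals_observed["myc_type"] == myc]
        rasters[f"{myc}_roots"] = ma.rasterize_units(
            _series(tot, "fine_root_stock"), units
        )
        rasters[f"{myc}_roots_colonized"] = ma.rasterize_units(
            _series(tot_obs, "colonized_stock"), units
        )
        rasters[f"{myc}_roots_colonized_filled"] = ma.rasterize_units(
            _series(tot, "colonized_stock"), units
        )
        stock = _series(tot_obs, "fine_root_stock")
        colzd = _series(tot_obs, "colonized_stock")
        with np.errstate(invalid="ignore", divide="ignore"):
            intensity = pd.Series(
                np.where(stock > 0, colzd / stock * 100.0, np.nan), index=stock.index
            )
        rasters[f"{myc}_intensity_colonization"] = ma.rasterize_units(intensity, units)
        for form in ("woody", "herbaceous", TUNDRA_POOL):
            sub = summary_observed[
                (summary_observed["myc_type"] == myc)
                & (summary_observed["growth_form"] == form)
            ]
            rasters[f"{myc}_{_FORM_LABEL[form]}_roots_colonized"] = ma.rasterize_units(
                _series(sub, "colonized_stock"), units
            )
    rasters.update(quality_rasters(quality, units))

    return PipelineResult(
        units=units,
        params=params,
        stock_pools=stock_pools,
        species_means=species_means,
        plot_pools=plot_pools,
        unit_colonization=unit_colonization,
        unit_summary=summary,
        unit_summary_observed=summary_observed,
        unit_totals=totals,
        unit_totals_observed=totals_observed,
        quality=quality,
        rasters=rasters,
        report=report,
    )
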