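"""Quality-index maps and SE-filtered raster comparison.

Three per-type quality indices accompany the intensity estimates, each a
per-spatial-unit average computed *before* gap-filling (borrowed values
carry no observed quality):

1. mean number of colonization observations per covered species (plot mean,
   then unit mean over plots) — captures how well intraspecific variation
   is sampled;
2. mean relative abundance of species with colonization data (%) — captures
   how much of the community the weighted mean actually covers;
3. number of vegetation plots in the unit — captures how well the unit's
   vegetation variability is represented.

``compare_rasters`` is the generic validation operation: difference map and
histogram against a reference layer, masking reference pixels whose
standard error exceeds a threshold (default 20 percentage points).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .map_assembly import rasterize_units
from .raster import RasterGrid, require_same_grid
from .spatial_units import SpatialUnitMap

__all__ = ["unit_quality", "quality_rasters", "compare_rasters"]

#: raster layer name patterns, one triple per mycorrhizal type
QUALITY_LAYERS = ("{t}_occurrences_colonization", "{t}_rel.abundance_colonization", "{t}_plots")


def unit_quality(plot_pools: pd.DataFrame) -> pd.DataFrame:
    """Per-unit, per-type quality indices from the per-plot pool table.

    Growth-form pools are merged at the plot level first (coverage as the
    covered share of the plot's pooled abundance; observation counts
    weighted by the number of covered species), then averaged over plots.
    """
    df = plot_pools.copy()
    df["_obs_sum"] = df["mean_obs_per_species"] * df["n_species_covered"]
    plot_level = df.groupby(["unit_id", "plot_id", "myc_type"], sort=True).agg(
        total_abundance=("total_abundance", "sum"),
        covered_abundance=("covered_abundance", "sum"),
        _obs_sum=("_obs_sum", "sum"),
        _ncov=("n_species_covered", "sum"),
    )
    plot_level["coverage"] = (
        plot_level["covered_abundance"] / plot_level["total_abundance"] * 100.0
    )
    plot_level["mean_obs"] = plot_level["_obs_sum"] / plot_level["_ncov"]
    out = (
        plot_level.reset_index()
        .groupby(["unit_id", "myc_type"], sort=True)
        .agg(
            mean_obs_per_species=("mean_obs", "mean"),
            mean_coverage=("coverage", "mean"),
            n_plots=("plot_id", "size"),
        )
        .reset_index()
    )
    return out


def quality_rasters(
    quality: pd.DataFrame, units: SpatialUnitMap
) -> dict[str, RasterGrid]:
    """Rasterize the three quality indices per mycorrhizal type.

    Units without observed intensity stay nodata. Layer names follow the
    published product: ``{type}_occurrences_colonization``,
    ``{type}_rel.abundance_colonization`` and ``{type}_plots``.
    """
    out: dict[str, RasterGrid] = {}
    all_units = units.unit_table["unit_id"]
    for myc in ("AM", "EcM"):
        sub = quality[quality["myc_type"] == myc].set_index("unit_id")
        for pattern, column in zip(
            QUALITY_LAYERS, ("mean_obs_per_species", "mean_coverage", "n_plots")
        ):
            values = sub[column].astype(float).reindex(all_units)
            values.index = all_units.to_numpy()
            out[pattern.format(t=myc)] = rasterize_units(values, units)
    return out


def compare_rasters(
    ours: RasterGrid,
    reference: RasterGrid,
    reference_se: RasterGrid | None = None,
    se_threshold: float = 20.0,
    bin_edges: np.ndarray | None = None,
) -> tuple[RasterGrid, pd.DataFrame]:
    """Difference map (ours - reference) with an SE filter, plus histogram.

    Reference pixels with standard error above ``se_threshold`` (percentage
    points) are masked out, as are pixels invalid in either input. The
    histogram uses 10-percentage-point bins over [-100, 100] by default.
    Swapping the inputs negates the unmasked differences.
    """
    require_same_grid(ours, reference)
    mask = ours.valid_mask() & reference.valid_mask()
    if reference_se is not None:
        require_same_grid(ours, reference_se)
        mask &= reference_se.valid_mask() & (
            reference_se.masked() <= se_threshold
        )
    diff = np.full(ours.shape, np.nan)
    diff[mask] = ours.masked()[mask] - reference.masked()[mask]
    diff_grid = ours.with_values(diff, nodata=None)

    if bin_edges is None:
        bin_edges = np.arange(-100.0, 101.0, 10.0)
    counts, edges = np.histogram(diff[mask], bins=bin_edges)
    hist = pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
    return diff_grid, hist
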