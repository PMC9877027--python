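"""Final map assembly: colonized stocks, gap-filling, rasterization.

The colonized fine-root C stock of a pool is simply
``stock x intensity / 100``. Per-unit pool values are gap-filled before the
growth forms are combined: a unit whose pool has no plot/colonization data
receives the arithmetic mean of the observed values of that pool among units
sharing its ecoregion and continent; groups with no observed member remain
unfilled (nodata). Observed units are never altered and filling never
crosses ecoregion x continent boundaries.

Per-type totals sum woody + herbaceous pools for ordinary units and use the
tundra pool alone for tundra units; a pool missing everywhere for a type
(the real-data situation for EcM herbaceous vegetation) contributes zero,
not missing. Rasterization assigns each pixel its unit's value, leaving
excluded/nodata pixels and unfilled units as nodata.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ContractError, DomainError
from .raster import RasterGrid
from .spatial_units import UNIT_NODATA, SpatialUnitMap
from .colonization import TUNDRA_POOL

__all__ = [
    "FILL_OBSERVED",
    "FILL_GROUP_MEAN",
    "FILL_UNFILLED",
    "colonized_stock",
    "gap_fill",
    "build_unit_summary",
    "combine_pools",
    "rasterize_units",
]

logger = logging.getLogger(__name__)

FILL_OBSERVED = "observed"
FILL_GROUP_MEAN = "ecoregion_continent_mean"
FILL_UNFILLED = "unfilled"


def colonized_stock(stock, intensity):
    """Colonized fine-root C stock: ``stock x intensity / 100`` (MgC ha-1).

    Accepts scalars or arrays; NaNs propagate (missing, not zero).
    """
    stock_arr = np.asarray(stock, dtype=float)
    inten_arr = np.asarray(intensity, dtype=float)
    if np.any(stock_arr[~np.isnan(stock_arr)] < 0):
        raise DomainError("stock must be >= 0")
    finite = ~np.isnan(inten_arr)
    if np.any((inten_arr[finite] < 0) | (inten_arr[finite] > 100)):
        raise DomainError("intensity must be in [0, 100]")
    out = stock_arr * inten_arr / 100.0
    if np.isscalar(stock) and np.isscalar(intensity):
        return float(out)
    return out


def gap_fill(
    values: pd.Series, unit_table: pd.DataFrame
) -> tuple[pd.Series, pd.Series]:
    """Fill empty units with their ecoregion x continent group mean.

    ``values`` is indexed by unit_id with NaN marking units without data;
    ``unit_table`` supplies the grouping columns. Returns the filled series
    and a fill-status series (``observed`` / ``ecoregion_continent_mean`` /
    ``unfilled``).
    """
    table = unit_table.set_index("unit_id").loc[values.index]
    groups = list(zip(table["ecoregion"], table["continent"]))
    frame = pd.DataFrame({"value": values.to_numpy(), "group": groups}, index=values.index)
    group_means = frame.groupby("group")["value"].mean()

    observed = frame["value"].notna()
    filled = frame["value"].copy()
    borrowed = frame["group"].map(group_means)
    filled[~observed] = borrowed[~observed]

    status = pd.Series(FILL_UNFILLED, index=values.index, dtype=object)
    status[observed] = FILL_OBSERVED
    status[~observed & filled.notna()] = FILL_GROUP_MEAN
    n_filled = int((status == FILL_GROUP_MEAN).sum())
    n_unfilled = int((status == FILL_UNFILLED).sum())
    if n_filled or n_unfilled:
        logger.info(
            "gap_fill: filled %d unit(s) from group means, %d remain empty",
            n_filled,
            n_unfilled,
        )
    filled.name = values.name
    status.name = "fill_status"
    return filled, status


def _pool_universe(unit_table: pd.DataFrame) -> pd.DataFrame:
    """Every (unit, myc_type, growth_form) pool consistent with tundra routing."""
    rows = []
    for unit_id, is_tundra in zip(unit_table["unit_id"], unit_table["is_tundra"]):
        forms = [TUNDRA_POOL] if is_tundra else ["woody", "herbaceous"]
        for myc in ("AM", "EcM"):
            for form in forms:
                rows.append((unit_id, myc, form))
    return pd.DataFrame(rows, columns=["unit_id", "myc_type", "growth_form"])


def build_unit_summary(
    stock_pools: pd.DataFrame,
    unit_colonization: pd.DataFrame,
    unit_table: pd.DataFrame,
    apply_gap_fill: bool = True,
) -> pd.DataFrame:
    """Per-unit, per-pool summary joining stocks with intensities.

    ``stock_pools`` holds the zonal-mean mycorrhizal fine-root stocks
    (columns ``unit_id, myc_type, growth_form, fine_root_stock``);
    ``unit_colonization`` the per-pool intensities. The colonized stock is
    their product/100, gap-filled per pool (before growth-form combination,
    so partial data is used maximally) unless ``apply_gap_fill`` is False.
    """
    universe = _pool_universe(unit_table)
    summary = universe.merge(
        stock_pools, on=["unit_id", "myc_type", "growth_form"], how="left"
    ).merge(
        unit_colonization[
            ["unit_id", "myc_type", "growth_form", "mean_intensity", "n_plots"]
        ],
        on=["unit_id", "myc_type", "growth_form"],
        how="left",
    )
    summary = summary.rename(columns={"mean_intensity": "intensity"})
    summary["n_plots"] = summary["n_plots"].fillna(0).astype(int)
    summary["colonized_stock"] = colonized_stock(
        summary["fine_root_stock"].to_numpy(), summary["intensity"].to_numpy()
    )
    summary["fill_status"] = np.where(
        summary["colonized_stock"].notna(), FILL_OBSERVED, FILL_UNFILLED
    )
    if apply_gap_fill:
        parts = []
        for (_, _), grp in summary.groupby(["myc_type", "growth_form"], sort=False):
            values = pd.Series(
                grp["colonized_stock"].to_numpy(), index=grp["unit_id"].to_numpy()
            )
            filled, status = gap_fill(values, unit_table)
            grp = grp.copy()
            grp["colonized_stock"] = filled.to_numpy()
            grp["fill_status"] = status.to_numpy()
            parts.append(grp)
        summary = pd.concat(parts).sort_index()
    return summary.reset_index(drop=True)


def combine_pools(summary: pd.DataFrame, unit_table: pd.DataFrame) -> pd.DataFrame:
    """Per-unit, per-type totals from the pool summary.

    Ordinary units: total = woody + herbaceous; tundra units: the tundra
    pool only (the pool universe enforces this exclusivity). A pool with a
    missing value contributes 0 when the type has any observed/filled pool
    in the unit; if every pool of the type is missing the total is missing.
    """
    out_rows = []
    for (unit_id, myc), grp in summary.groupby(["unit_id", "myc_type"], sort=True):
        colonized = grp["colonized_stock"]
        stocks = grp["fine_root_stock"]
        if colonized.notna().any():
            total_col = float(colonized.sum(skipna=True))
            statuses = set(grp.loc[colonized.notna(), "fill_status"])
            status = (
                FILL_OBSERVED if statuses == {FILL_OBSERVED} else FILL_GROUP_MEAN
            )
        else:
            total_col = np.nan
            status = FILL_UNFILLED
        total_stock = (
            float(stocks.sum(skipna=True)) if stocks.notna().any() else np.nan
        )
        out_rows.append((unit_id, myc, total_stock, total_col, status))
    return pd.DataFrame(
        out_rows,
        columns=[
            "unit_id",
            "myc_type",
            "fine_root_stock",
            "colonized_stock",
            "fill_status",
        ],
    )


def rasterize_units(
    values: "pd.Series | Mapping[int, float]", units: SpatialUnitMap
) -> RasterGrid:
    """Paint per-unit values onto the unit raster.

    Every unit present in the raster must have an entry in ``values``
    (:class:`ContractError` otherwise); NaN entries (unfilled units) and
    non-unit pixels become nodata.
    """
    if not isinstance(values, pd.Series):
        values = pd.Series(dict(values), dtype=float)
    uid = units.unit_raster.values
    present = np.unique(uid[uid != UNIT_NODATA])
    missing = sorted(set(present.tolist()) - set(values.index.tolist()))
    if missing:
        raise ContractError(
            f"units present in raster but absent from values: {missing}"
        )
    max_id = int(present.max()) if len(present) else 0
    lut = np.full(max_id + 2, np.nan)
    idx = values.index.to_numpy(dtype=np.int64)
    in_range = idx <= max_id
    lut[idx[in_range]] = values.to_numpy(dtype=float)[in_range]
    out = np.full(uid.shape, np.nan)
    valid = uid != UNIT_NODATA
    out[valid] = lut[uid[valid]]
    return units.unit_raster.with_values(out, nodata=None)
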