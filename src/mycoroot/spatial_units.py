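"""Spatial-unit construction from ecoregion, land-cover and continent layers.

A *spatial unit* is the intersection of one ecoregion, one land-cover class
and one continent; it is the categorical stratum over which all stocks and
colonization intensities are averaged. Pixels carrying an excluded land-cover
class (croplands, urban, bare, water in the ESA CCI coding) or nodata in any
input layer do not belong to any unit. Unit ids are assigned 1..n in
lexicographic order of the (ecoregion, landcover, continent) triple, which
makes them stable under re-runs on identical inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .raster import RasterGrid, read_geotiff, require_same_grid, write_geotiff

__all__ = [
    "UNIT_NODATA",
    "ESA_CCI_EXCLUDED_CLASSES",
    "SpatialUnitMap",
    "build_unit_map",
]

UNIT_NODATA = -1

#: ESA CCI land-cover classes discarded when running on real-coded data:
#: no-data/burn/cloud (0), croplands (10, 20), mosaic cropland >50% (30),
#: urban (190), bare (200-202), water (210) and permanent snow/ice (220).
#: Retaining classes 40-180 leaves the 15 natural land-cover types used for
#: unit construction. The set is a parameter, never hard-coded downstream.
ESA_CCI_EXCLUDED_CLASSES = frozenset({0, 10, 20, 30, 190, 200, 201, 202, 210, 220})

UNIT_TABLE_COLUMNS = ["unit_id", "ecoregion", "landcover", "continent", "is_tundra"]


@dataclass(frozen=True)
class SpatialUnitMap:
    """Pixel->unit-id raster plus the unit lookup table.

    ``unit_raster`` holds int32 unit ids with ``UNIT_NODATA`` outside all
    units; ``unit_table`` has one row per observed
    (ecoregion, landcover, continent) triple with columns
    ``unit_id, ecoregion, landcover, continent, is_tundra``.
    """

    unit_raster: RasterGrid
    unit_table: pd.DataFrame

    @property
    def n_units(self) -> int:
        return len(self.unit_table)

    @property
    def unit_ids(self) -> np.ndarray:
        return self.unit_table["unit_id"].to_numpy()

    def footprint(self, unit_id: int) -> np.ndarray:
        return self.unit_raster.values == unit_id

    def unit_at(self, lon: float, lat: float) -> int | None:
        """Unit id of the pixel containing a point, or None."""
        px = self.unit_raster.pixel_at(lon, lat)
        if px is None:
            return None
        uid = int(self.unit_raster.values[px])
        return None if uid == UNIT_NODATA else uid

    def tundra_unit_ids(self) -> set[int]:
        t = self.unit_table
        return set(t.loc[t["is_tundra"], "unit_id"].astype(int))

    # -- persistence ------------------------------------------------------
    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_geotiff(self.unit_raster, directory / "spatial_units.tif")
        self.unit_table.to_csv(directory / "spatial_units.csv", index=False)

    @classmethod
    def read(cls, directory: str | Path) -> "SpatialUnitMap":
        directory = Path(directory)
        raster = read_geotiff(directory / "spatial_units.tif")
        table = pd.read_csv(directory / "spatial_units.csv")
        table["is_tundra"] = table["is_tundra"].astype(bool)
        return cls(raster, table)


def build_unit_map(
    ecoregion: RasterGrid,
    landcover: RasterGrid,
    continent: RasterGrid,
    excluded_classes: Iterable[int] = ESA_CCI_EXCLUDED_CLASSES,
    tundra_ecoregions: Iterable[int] = (),
) -> SpatialUnitMap:
    """Overlay the three categorical layers into a spatial-unit map.

    Pixels with nodata in any layer or an excluded land-cover class become
    unit nodata; every remaining pixel is keyed by its unique
    (ecoregion, landcover, continent) triple and only observed triples
    become units. ``tundra_ecoregions`` flags units routed through the
    growth-form-free tundra workflow.
    """
    require_same_grid(ecoregion, landcover, continent)
    excluded = sorted({int(c) for c in excluded_classes})
    tundra = {int(c) for c in tundra_ecoregions}

    valid = (
        ecoregion.valid_mask()
        & landcover.valid_mask()
        & continent.valid_mask()
        & ~np.isin(landcover.values, excluded)
    )
    triples = np.stack(
        [
            ecoregion.values[valid].astype(np.int64),
            landcover.values[valid].astype(np.int64),
            continent.values[valid].astype(np.int64),
        ],
        axis=1,
    )
    unit_values = np.full(ecoregion.shape, UNIT_NODATA, dtype=np.int32)
    if len(triples):
        uniq, inverse = np.unique(triples, axis=0, return_inverse=True)
        unit_values[valid] = inverse.astype(np.int32) + 1
    else:
        uniq = np.empty((0, 3), dtype=np.int64)

    table = pd.DataFrame(
        {
            "unit_id": np.arange(1, len(uniq) + 1, dtype=np.int64),
            "ecoregion": uniq[:, 0],
            "landcover": uniq[:, 1],
            "continent": uniq[:, 2],
        }
    )
    table["is_tundra"] = table["ecoregion"].isin(sorted(tundra))

    unit_raster = RasterGrid(
        unit_values,
        ecoregion.origin_x,
        ecoregion.origin_y,
        ecoregion.pixel_width,
        ecoregion.pixel_height,
        nodata=UNIT_NODATA,
        crs=ecoregion.crs,
    )
    return SpatialUnitMap(unit_raster, table)


def parse_code_list(text: str) -> set[int]:
    """Parse a comma-separated code list (CLI helper)."""
    text = text.strip()
    if not text:
        return set()
    try:
        return {int(tok) for tok in text.split(",")}
    except ValueError as exc:
        raise ConfigurationError(f"invalid code list {text!r}") from exc
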