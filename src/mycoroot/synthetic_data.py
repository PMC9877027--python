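"""Synthetic input worlds with known ground truth.

The generator emits every input the mapping workflow consumes — categorical
ecoregion/land-cover/continent rasters, fine-resolution belowground biomass C
layers (woody, herbaceous, tundra), AM/EcM aboveground fraction rasters per
growth form, colonization records, vegetation-plot tables split into
candidate subsets, trait tables and a coarse/fine root-mass-ratio table —
together with a :class:`GroundTruth` object holding the per-unit quantities
the pipeline is supposed to recover.

Design of the recovery guarantee: the species pool is partitioned among the
spatial units and every species in a unit's (mycorrhizal type x growth form)
pool carries that unit's configured true intensity as its species-level
mean. Community-weighted means then equal the configured truth for *any*
plot composition — species turnover between units, not abundance structure,
drives the spatial signal, exactly as in the real workflow. Observation
noise, off-season/non-natural records (biased high so that failing to
filter them is detectable), categorical records, species without
colonization data, plots on water pixels and units visible in only one plot
subset are all switchable perturbations around that exact backbone.

Biomass layers are block-constant at fine resolution (each coarse cell's
fine block holds one value), so block-mean aggregation is exact; land cover
is likewise block-constant, so nearest-neighbour coarsening recovers the
intended class. Water pixels carry an excluded land-cover class and the
nodata sentinel in every value raster, exercising the masking rules.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .colonization import TUNDRA_POOL
from .errors import ConfigurationError
from .pipeline import PipelineInputs
from .raster import RasterGrid, read_geotiff, write_geotiff
from .root_stocks import RootFractionParams, depth_fraction

__all__ = [
    "NODATA",
    "WorldConfig",
    "GroundTruth",
    "SyntheticWorld",
    "generate_world",
    "generate_categorical_colonization",
    "write_world",
    "read_world",
]

#: nodata sentinel of every synthetic value raster
NODATA = -9999.0

_POOL_FORMS = ("woody", "herbaceous")
_RASTER_FILES = [
    ("ecoregion", "ecoregions.tif"),
    ("landcover_fine", "landcover_fine.tif"),
    ("continent", "continents.tif"),
    ("bgb_woody_fine", "bgb_woody_fine.tif"),
    ("bgb_herb_fine", "bgb_herbaceous_fine.tif"),
    ("bgb_tundra_fine", "bgb_tundra_fine.tif"),
    ("am_tree", "am_tree_fraction.tif"),
    ("am_shrub", "am_shrub_fraction.tif"),
    ("am_herb", "am_herb_fraction.tif"),
    ("ecm_tree", "ecm_tree_fraction.tif"),
    ("ecm_shrub", "ecm_shrub_fraction.tif"),
    ("ecm_herb", "ecm_herb_fraction.tif"),
    ("am_total", "am_total_fraction.tif"),
    ("ecm_total", "ecm_total_fraction.tif"),
]


@dataclass(frozen=True)
class WorldConfig:
    """Configuration of a synthetic world.

    Land-cover codes run 1..n_landcover_classes; ``excluded_classes``
    (default: the two highest codes, the highest acting as water and
    carrying nodata in the value rasters) are discarded during unit
    construction. ``true_intensity_per_unit`` optionally pins the true
    colonization intensity of specific (ecoregion, landcover, continent)
    triples: a mapping triple -> {(myc_type, growth_form): %}; unspecified
    units draw their truth uniformly from ``intensity_range``.

    ``plots_per_unit`` and ``obs_per_species`` accept an int or an
    inclusive (lo, hi) range. ``intensity_noise_sd`` is the s.d. (percentage
    points) of the Gaussian observation noise added to colonization records.
    """

    n_ecoregions: int = 4
    n_landcover_classes: int = 6
    n_continents: int = 2
    excluded_classes: frozenset[int] | None = None
    grid_shape: tuple[int, int] = (40, 40)
    fine_factor: int = 4
    species_pool_size: int = 400
    fraction_woody: float = 0.5
    fraction_dual_type: float = 0.1
    fraction_am: float = 0.6
    fraction_facultative_am: float = 0.1
    fraction_unassignable: float = 0.04
    fraction_form_unknown: float = 0.03
    true_intensity_per_unit: dict | None = None
    intensity_range: tuple[float, float] = (20.0, 80.0)
    plots_per_unit: int | tuple[int, int] = 30
    obs_per_species: int | tuple[int, int] = 3
    intensity_noise_sd: float = 5.0
    fraction_records_flagged: float = 0.1
    fraction_records_unknown_meta: float = 0.2
    fraction_species_no_records: float = 0.1
    categorical_class_bounds: tuple[tuple[float, float], ...] | None = None
    fraction_categorical: float = 0.0
    n_subsets: int = 3
    fraction_units_single_subset: float = 0.1
    fraction_plots_on_nodata: float = 0.02
    fraction_water: float = 0.05
    fraction_excluded_cover: float = 0.08
    tundra_ecoregions: frozenset[int] = frozenset({1})
    origin: tuple[float, float] = (-10.0, 55.0)
    pixel_size: float = 1.0 / 6.0
    seed: int = 0

    def resolved_excluded(self) -> frozenset[int]:
        if self.excluded_classes is not None:
            return frozenset(int(c) for c in self.excluded_classes)
        n = self.n_landcover_classes
        return frozenset({n - 1, n}) if n > 2 else frozenset({n})

    @property
    def water_class(self) -> int:
        return max(self.resolved_excluded())

    def validate(self) -> None:
        counts = {
            "n_ecoregions": self.n_ecoregions,
            "n_landcover_classes": self.n_landcover_classes,
            "n_continents": self.n_continents,
            "species_pool_size": self.species_pool_size,
            "fine_factor": self.fine_factor,
            "n_subsets": self.n_subsets,
        }
        for name, v in counts.items():
            if int(v) != v or v < 1:
                raise ConfigurationError(f"{name} must be a positive integer, got {v}")
        if len(self.grid_shape) != 2 or any(s < 1 for s in self.grid_shape):
            raise ConfigurationError(f"invalid grid_shape {self.grid_shape}")
        proportions = {
            "fraction_woody": self.fraction_woody,
            "fraction_dual_type": self.fraction_dual_type,
            "fraction_am": self.fraction_am,
            "fraction_facultative_am": self.fraction_facultative_am,
            "fraction_unassignable": self.fraction_unassignable,
            "fraction_form_unknown": self.fraction_form_unknown,
            "fraction_records_flagged": self.fraction_records_flagged,
            "fraction_records_unknown_meta": self.fraction_records_unknown_meta,
            "fraction_species_no_records": self.fraction_species_no_records,
            "fraction_categorical": self.fraction_categorical,
            "fraction_units_single_subset": self.fraction_units_single_subset,
            "fraction_plots_on_nodata": self.fraction_plots_on_nodata,
            "fraction_water": self.fraction_water,
            "fraction_excluded_cover": self.fraction_excluded_cover,
        }
        for name, v in proportions.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.intensity_range
        if not (0.0 <= lo <= hi <= 100.0):
            raise ConfigurationError(f"intensity_range must lie in [0, 100], got {self.intensity_range}")
        excluded = self.resolved_excluded()
        declared = set(range(1, self.n_landcover_classes + 1))
        if not excluded <= declared:
            raise ConfigurationError(
                f"excluded classes {sorted(excluded)} not all within declared codes"
            )
        if excluded >= declared:
            raise ConfigurationError("excluded classes cover every land-cover class")
        if self.intensity_noise_sd < 0:
            raise ConfigurationError("intensity_noise_sd must be >= 0")

    # -- persistence ------------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        data = {
            f: getattr(self, f)
            for f in self.__dataclass_fields__
            if f != "true_intensity_per_unit"
        }
        data["excluded_classes"] = (
            sorted(self.excluded_classes) if self.excluded_classes is not None else None
        )
        data["tundra_ecoregions"] = sorted(self.tundra_ecoregions)
        data["grid_shape"] = list(self.grid_shape)
        data["origin"] = list(self.origin)
        data["intensity_range"] = list(self.intensity_range)
        for key in ("plots_per_unit", "obs_per_species"):
            if isinstance(data[key], tuple):
                data[key] = list(data[key])
        if self.categorical_class_bounds is not None:
            data["categorical_class_bounds"] = [list(b) for b in self.categorical_class_bounds]
        if self.true_intensity_per_unit is not None:
            data["true_intensity_per_unit"] = {
                "|".join(map(str, triple)): {
                    "|".join(pool): val for pool, val in pools.items()
                }
                for triple, pools in self.true_intensity_per_unit.items()
            }
        else:
            data["true_intensity_per_unit"] = None
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "WorldConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("grid_shape", "origin", "intensity_range"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        for key in ("plots_per_unit", "obs_per_species"):
            if isinstance(data.get(key), list):
                data[key] = tuple(data[key])
        if data.get("excluded_classes") is not None:
            data["excluded_classes"] = frozenset(data["excluded_classes"])
        if data.get("tundra_ecoregions") is not None:
            data["tundra_ecoregions"] = frozenset(data["tundra_ecoregions"])
        if data.get("categorical_class_bounds") is not None:
            data["categorical_class_bounds"] = tuple(
                tuple(b) for b in data["categorical_class_bounds"]
            )
        if data.get("true_intensity_per_unit") is not None:
            data["true_intensity_per_unit"] = {
                tuple(int(x) for x in triple.split("|")): {
                    tuple(pool.split("|")): float(val) for pool, val in pools.items()
                }
                for triple, pools in data["true_intensity_per_unit"].items()
            }
        return cls(**data)


@dataclass
class GroundTruth:
    """True per-unit quantities recoverable from the emitted files.

    ``unit_pools`` carries, per (unit, myc type, growth form) pool, the true
    intensity (%), the true mycorrhiza-capable fine-root stock and the true
    colonized stock (both MgC ha-1, as zonal means of the per-pixel
    products). ``unit_form_stocks`` holds the growth-form fine-root stocks,
    ``unit_fractions`` the zonal-mean AM/EcM fractions and
    ``species_means`` the species-level trait values the records encode.
    """

    unit_table: pd.DataFrame
    unit_pools: pd.DataFrame
    unit_form_stocks: pd.DataFrame
    unit_fractions: pd.DataFrame
    species_means: pd.DataFrame

    def pool_lookup(self, column: str) -> dict:
        return {
            (int(r.unit_id), r.myc_type, r.growth_form): getattr(r, column)
            for r in self.unit_pools.itertuples()
        }

    def to_json(self, path: str | Path) -> None:
        payload = {
            name: {
                "columns": list(frame.columns),
                "data": frame.to_numpy().tolist(),
            }
            for name, frame in (
                ("unit_table", self.unit_table),
                ("unit_pools", self.unit_pools),
                ("unit_form_stocks", self.unit_form_stocks),
                ("unit_fractions", self.unit_fractions),
                ("species_means", self.species_means),
            )
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            **{
                k: pd.DataFrame(v["data"], columns=v["columns"])
                for k, v in payload.items()
            }
        )


@dataclass
class SyntheticWorld:
    """A generated world: pipeline inputs, configuration and ground truth."""

    inputs: PipelineInputs
    truth: GroundTruth
    config: WorldConfig
    categorical_mapping: dict[str, float] = field(default_factory=dict)


# -- categorical colonization ---------------------------------------------

def generate_categorical_colonization(
    records: pd.DataFrame,
    class_bounds: "tuple[tuple[float, float], ...] | list",
    fraction: float = 1.0,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Replace a subset of numeric record values with categorical labels.

    ``class_bounds`` must partition [0, 100] into contiguous, non-overlapping
    intervals; a value falls into the class whose lower bound it reaches
    (the last class includes 100). Labels are ``class1..classN`` and the
    returned mapping records each label's class midpoint for round-trip
    conversion. An empty bounds list converts nothing.
    """
    bounds = [tuple(map(float, b)) for b in class_bounds]
    if not bounds:
        return records.copy(), {}
    bounds.sort(key=lambda b: b[0])
    if bounds[0][0] != 0.0 or bounds[-1][1] != 100.0:
        raise ConfigurationError("class bounds must span [0, 100]")
    for (lo, hi), (lo2, _) in zip(bounds, bounds[1:]):
        if hi != lo2:
            raise ConfigurationError("class bounds must be contiguous and non-overlapping")
    for lo, hi in bounds:
        if not lo < hi:
            raise ConfigurationError(f"empty class interval ({lo}, {hi})")

    mapping = {f"class{i + 1}": (lo + hi) / 2.0 for i, (lo, hi) in enumerate(bounds)}
    lows = np.array([lo for lo, _ in bounds])

    out = records.copy()
    numeric = pd.to_numeric(out["value"], errors="coerce")
    candidates = numeric.notna().to_numpy()
    if rng is None:
        rng = np.random.default_rng(0)
    chosen = candidates & (rng.random(len(out)) < fraction)
    if chosen.any():
        vals = numeric.to_numpy(dtype=float)[chosen]
        idx = np.clip(np.searchsorted(lows, vals, side="right") - 1, 0, len(bounds) - 1)
        labels = np.array([f"class{i + 1}" for i in idx], dtype=object)
        out["value"] = out["value"].astype(object)
        out.loc[chosen, "value"] = labels
    return out, mapping


# -- helpers ---------------------------------------------------------------

def _draw_count(rng: np.random.Generator, spec) -> int:
    if isinstance(spec, (tuple, list)):
        lo, hi = spec
        return int(rng.integers(int(lo), int(hi) + 1))
    return int(spec)


def _kron_fine(coarse: np.ndarray, factor: int) -> np.ndarray:
    return np.kron(coarse, np.ones((factor, factor), dtype=coarse.dtype))


def _grid(values, cfg: WorldConfig, fine: bool, nodata) -> RasterGrid:
    px = cfg.pixel_size / cfg.fine_factor if fine else cfg.pixel_size
    return RasterGrid(values, cfg.origin[0], cfg.origin[1], px, px, nodata=nodata)


# -- the generator ---------------------------------------------------------

def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Generate a full synthetic input world; see the module docstring.

    The same configuration and seed always produce bit-identical outputs.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    R, C = cfg.grid_shape
    f = cfg.fine_factor
    excluded = cfg.resolved_excluded()
    retained = sorted(set(range(1, cfg.n_landcover_classes + 1)) - excluded)
    water = cfg.water_class
    tundra_ecos = set(cfg.tundra_ecoregions) & set(range(1, cfg.n_ecoregions + 1))

    # categorical layers ---------------------------------------------------
    eco = np.broadcast_to(
        (1 + (np.arange(R) * cfg.n_ecoregions) // R)[:, None].astype(np.int32), (R, C)
    ).copy()
    cont = np.broadcast_to(
        (1 + (np.arange(C) * cfg.n_continents) // C)[None, :].astype(np.int32), (R, C)
    ).copy()
    lc = rng.choice(np.array(retained, dtype=np.int32), size=(R, C))
    non_water_excluded = sorted(excluded - {water})
    if non_water_excluded and cfg.fraction_excluded_cover > 0:
        sel = rng.random((R, C)) < cfg.fraction_excluded_cover
        lc[sel] = rng.choice(np.array(non_water_excluded, dtype=np.int32), size=int(sel.sum()))
    water_mask = np.zeros((R, C), dtype=bool)
    if cfg.fraction_water > 0:
        water_mask = rng.random((R, C)) < cfg.fraction_water
        lc[water_mask] = water
    valid = ~np.isin(lc, sorted(excluded))
    tundra_mask = np.isin(eco, sorted(tundra_ecos))

    # spatial units (definitional: sorted triples, ids 1..n) ---------------
    triples = np.stack([eco[valid], lc[valid], cont[valid]], axis=1).astype(np.int64)
    uniq = np.unique(triples, axis=0)
    unit_ids = {tuple(t): i + 1 for i, t in enumerate(map(tuple, uniq))}
    unit_raster = np.zeros((R, C), dtype=np.int64)
    for t, uid in unit_ids.items():
        unit_raster[(eco == t[0]) & (lc == t[1]) & (cont == t[2])] = uid
    unit_raster[~valid] = 0
    unit_table = pd.DataFrame(
        {
            "unit_id": np.arange(1, len(uniq) + 1, dtype=np.int64),
            "ecoregion": uniq[:, 0],
            "landcover": uniq[:, 1],
            "continent": uniq[:, 2],
        }
    )
    unit_table["is_tundra"] = unit_table["ecoregion"].isin(sorted(tundra_ecos))
    n_units = len(unit_table)

    # true intensities -----------------------------------------------------
    provided = cfg.true_intensity_per_unit or {}
    truth_intensity: dict[tuple[int, str, str], float] = {}
    for row in unit_table.itertuples():
        triple = (int(row.ecoregion), int(row.landcover), int(row.continent))
        forms = [TUNDRA_POOL] if row.is_tundra else list(_POOL_FORMS)
        for myc in ("AM", "EcM"):
            for form in forms:
                given = provided.get(triple, {}).get((myc, form))
                value = (
                    float(given)
                    if given is not None
                    else float(rng.uniform(*cfg.intensity_range))
                )
                truth_intensity[(int(row.unit_id), myc, form)] = value

    # species pool ---------------------------------------------------------
    base, rem = divmod(cfg.species_pool_size, n_units)
    seed_pools = [("AM", "woody"), ("AM", "herbaceous"), ("EcM", "woody"), ("EcM", "herbaceous")]
    trait_rows: list[tuple[str, str]] = []
    genus_rows: dict[str, str] = {}
    species_truth_rows: list[tuple[str, str, float]] = []
    unit_species: dict[int, list[str]] = {}
    record_species: list[tuple[str, str, float]] = []  # species, kind, true mean

    for u_idx, row in enumerate(unit_table.itertuples()):
        uid = int(row.unit_id)
        n_sp = base + (1 if u_idx < rem else 0)
        is_tundra = bool(row.is_tundra)
        genera = {
            "AM": f"Amgenus{uid}",
            "EcM": f"Ecmgenus{uid}",
            "dual": f"Dualgenus{uid}",
            "other": f"Othergenus{uid}",
        }
        genus_rows.setdefault(
            genera["AM"],
            "facultative_AM" if rng.random() < cfg.fraction_facultative_am else "AM",
        )
        genus_rows.setdefault(genera["EcM"], "EcM")
        genus_rows.setdefault(genera["dual"], "dual")
        genus_rows.setdefault(genera["other"], "other")
        names: list[str] = []
        for i in range(n_sp):
            if i < 2 * len(seed_pools):
                myc_class, form = seed_pools[i % len(seed_pools)]
            else:
                r = rng.random()
                if r < cfg.fraction_unassignable:
                    myc_class = "other"
                elif r < cfg.fraction_unassignable + cfg.fraction_dual_type:
                    myc_class = "dual"
                elif rng.random() < cfg.fraction_am:
                    myc_class = "AM"
                else:
                    myc_class = "EcM"
                form = "woody" if rng.random() < cfg.fraction_woody else "herbaceous"
                if rng.random() < cfg.fraction_form_unknown:
                    form = "unknown"
            species = f"{genera[myc_class]} sp{i + 1}"
            names.append(species)
            trait_rows.append((species, form))
            kinds = ("AM", "EcM") if myc_class == "dual" else (
                (myc_class,) if myc_class in ("AM", "EcM") else ()
            )
            for kind in kinds:
                if is_tundra:
                    mu = truth_intensity[(uid, kind, TUNDRA_POOL)]
                elif form in _POOL_FORMS:
                    mu = truth_intensity[(uid, kind, form)]
                else:  # unknown growth form: excluded from pools, value free
                    mu = truth_intensity[(uid, kind, "woody")]
                species_truth_rows.append((species, kind, mu))
                record_species.append((species, kind, mu))
        unit_species[uid] = names

    # colonization records -------------------------------------------------
    rec_rows: list[tuple[str, float, str, str, str]] = []
    sd = cfg.intensity_noise_sd
    for species, kind, mu in record_species:
        if rng.random() < cfg.fraction_species_no_records:
            continue
        n_obs = _draw_count(rng, cfg.obs_per_species)
        noise = rng.normal(0.0, sd, n_obs) if sd > 0 else np.zeros(n_obs)
        values = np.clip(mu + noise, 0.0, 100.0)
        for v in values:
            naturalness = "unknown" if rng.random() < cfg.fraction_records_unknown_meta else "natural"
            season = "unknown" if rng.random() < cfg.fraction_records_unknown_meta else "growing"
            rec_rows.append((species, float(v), kind, naturalness, season))
        n_flagged = int(rng.binomial(n_obs, cfg.fraction_records_flagged))
        for _ in range(n_flagged):
            v = float(np.clip(mu + 25.0 + (rng.normal(0.0, sd) if sd > 0 else 0.0), 0.0, 100.0))
            if rng.random() < 0.5:
                rec_rows.append((species, v, kind, "non_natural", "growing"))
            else:
                rec_rows.append((species, v, kind, "natural", "non_growing"))
    records = pd.DataFrame(
        rec_rows, columns=["species", "value", "unit_kind", "naturalness", "season"]
    )
    categorical_mapping: dict[str, float] = {}
    if cfg.categorical_class_bounds and cfg.fraction_categorical > 0:
        records, categorical_mapping = generate_categorical_colonization(
            records, cfg.categorical_class_bounds, cfg.fraction_categorical, rng
        )

    # value rasters --------------------------------------------------------
    bgb_woody = rng.uniform(2.0, 20.0, (R, C))
    bgb_herb = rng.uniform(0.5, 8.0, (R, C))
    bgb_tundra = rng.uniform(1.0, 10.0, (R, C))
    bgb_woody[tundra_mask] = 0.0
    bgb_herb[tundra_mask] = 0.0
    bgb_tundra[~tundra_mask] = 0.0

    total_myc = rng.uniform(0.4, 0.95, (R, C))
    am_share = rng.uniform(0.15, 0.85, (R, C))
    f_am = total_myc * am_share
    f_ecm = total_myc * (1.0 - am_share)
    form_split = rng.dirichlet(np.ones(3), size=R * C).reshape(R, C, 3)
    fractions = {
        "am_tree": f_am * form_split[..., 0],
        "am_shrub": f_am * form_split[..., 1],
        "am_herb": f_am * form_split[..., 2],
        "ecm_tree": f_ecm * form_split[..., 0],
        "ecm_shrub": f_ecm * form_split[..., 1],
        "ecm_herb": f_ecm * form_split[..., 2],
        "am_total": f_am,
        "ecm_total": f_ecm,
    }
    for arr in (bgb_woody, bgb_herb, bgb_tundra, *fractions.values()):
        arr[water_mask] = NODATA

    # plots ----------------------------------------------------------------
    px_coarse = cfg.pixel_size
    ox, oy = cfg.origin
    plot_rows: list[tuple[str, float, float, str, float, int]] = []
    plot_counter = 0

    def _emit_plot(r: int, c: int, species_pool: list[str], subset: int) -> None:
        nonlocal plot_counter
        plot_counter += 1
        plot_id = f"plot{plot_counter:06d}"
        lon = ox + (c + rng.uniform(0.05, 0.95)) * px_coarse
        lat = oy - (r + rng.uniform(0.05, 0.95)) * px_coarse
        k = int(rng.integers(min(4, len(species_pool)), min(10, len(species_pool)) + 1))
        chosen = rng.choice(len(species_pool), size=k, replace=False)
        abundances = rng.dirichlet(np.ones(k))
        for j, ab in zip(chosen, abundances):
            plot_rows.append((plot_id, lon, lat, species_pool[j], float(ab), subset))

    for row in unit_table.itertuples():
        uid = int(row.unit_id)
        pool = unit_species[uid]
        if not pool:
            continue
        pixels = np.argwhere(unit_raster == uid)
        n_plots = _draw_count(rng, cfg.plots_per_unit)
        forced = (
            int(rng.integers(1, cfg.n_subsets))
            if cfg.n_subsets > 1 and rng.random() < cfg.fraction_units_single_subset
            else None
        )
        for _ in range(n_plots):
            r, c = pixels[int(rng.integers(len(pixels)))]
            subset = forced if forced is not None else int(rng.integers(cfg.n_subsets))
            _emit_plot(int(r), int(c), pool, subset)

    water_pixels = np.argwhere(water_mask)
    if len(water_pixels) and cfg.fraction_plots_on_nodata > 0:
        all_species = [s for pool in unit_species.values() for s in pool]
        n_extra = int(round(cfg.fraction_plots_on_nodata * plot_counter))
        for _ in range(n_extra):
            r, c = water_pixels[int(rng.integers(len(water_pixels)))]
            _emit_plot(int(r), int(c), all_species, int(rng.integers(cfg.n_subsets)))

    plots = pd.DataFrame(
        plot_rows, columns=["plot_id", "lon", "lat", "species", "rel_abundance", "subset"]
    )

    # trait and ratio tables -----------------------------------------------
    growth_form_traits = pd.DataFrame(trait_rows, columns=["species", "growth_form"])
    myc_type_traits = pd.DataFrame(
        sorted(genus_rows.items()), columns=["genus", "myc_type"]
    )
    ratio_table = _ratio_table()

    # ground truth ---------------------------------------------------------
    truth = _compute_ground_truth(
        unit_table,
        unit_raster,
        truth_intensity,
        bgb_woody,
        bgb_herb,
        bgb_tundra,
        fractions,
        species_truth_rows,
    )

    inputs = PipelineInputs(
        ecoregion=_grid(eco, cfg, fine=False, nodata=0),
        landcover_fine=_grid(_kron_fine(lc, f), cfg, fine=True, nodata=0),
        continent=_grid(cont, cfg, fine=False, nodata=0),
        bgb_woody_fine=_grid(_kron_fine(bgb_woody, f), cfg, fine=True, nodata=NODATA),
        bgb_herb_fine=_grid(_kron_fine(bgb_herb, f), cfg, fine=True, nodata=NODATA),
        bgb_tundra_fine=_grid(_kron_fine(bgb_tundra, f), cfg, fine=True, nodata=NODATA),
        am_tree=_grid(fractions["am_tree"], cfg, fine=False, nodata=NODATA),
        am_shrub=_grid(fractions["am_shrub"], cfg, fine=False, nodata=NODATA),
        am_herb=_grid(fractions["am_herb"], cfg, fine=False, nodata=NODATA),
        ecm_tree=_grid(fractions["ecm_tree"], cfg, fine=False, nodata=NODATA),
        ecm_shrub=_grid(fractions["ecm_shrub"], cfg, fine=False, nodata=NODATA),
        ecm_herb=_grid(fractions["ecm_herb"], cfg, fine=False, nodata=NODATA),
        am_total=_grid(fractions["am_total"], cfg, fine=False, nodata=NODATA),
        ecm_total=_grid(fractions["ecm_total"], cfg, fine=False, nodata=NODATA),
        colonization_records=records,
        plots=plots,
        growth_form_traits=growth_form_traits,
        myc_type_traits=myc_type_traits,
        ratio_table=ratio_table,
        fine_factor=f,
        excluded_classes=excluded,
        tundra_ecoregions=frozenset(tundra_ecos),
        categorical_mapping=categorical_mapping,
    )
    return SyntheticWorld(
        inputs=inputs, truth=truth, config=cfg, categorical_mapping=categorical_mapping
    )


def _ratio_table() -> pd.DataFrame:
    """Coarse/fine root-mass ratios whose log means hit the shipped constants.

    Rows come in log-symmetric pairs around the target ratio per growth form
    (herbaceous 0.13 -> fine fraction 0.885; woody (1-0.141)/0.141 ->
    0.141), emulating the right-skewed spread of real ratio records while
    keeping the back-transformed log mean exactly on target.
    """
    rows = []
    targets = {"herbaceous": 0.13, "woody": (1.0 - 0.141) / 0.141}
    spreads = np.linspace(0.25, 1.25, 5)
    for form, r in targets.items():
        for d in spreads:
            rows.append((form, r * float(np.exp(d))))
            rows.append((form, r * float(np.exp(-d))))
    return pd.DataFrame(rows, columns=["growth_form", "coarse_fine_ratio"])


def _block_mean(fine: np.ndarray, factor: int) -> np.ndarray:
    rows = fine.shape[0] // factor
    cols = fine.shape[1] // factor
    return fine.reshape(rows, factor, cols, factor).mean(axis=(1, 3))


def _compute_ground_truth(
    unit_table: pd.DataFrame,
    unit_raster: np.ndarray,
    truth_intensity: dict,
    bgb_woody: np.ndarray,
    bgb_herb: np.ndarray,
    bgb_tundra: np.ndarray,
    fractions: dict[str, np.ndarray],
    species_truth_rows: list,
) -> GroundTruth:
    p = RootFractionParams()
    stock_px = {
        "woody": bgb_woody * (p.fine_fraction_woody * depth_fraction(p.beta_woody, p.depth_cm)),
        "herbaceous": bgb_herb * (p.fine_fraction_herb * depth_fraction(p.beta_herb, p.depth_cm)),
        TUNDRA_POOL: bgb_tundra
        * (p.fine_fraction_tundra * depth_fraction(p.beta_tundra, p.depth_cm)),
    }
    frac_px = {
        ("AM", "woody"): np.clip(fractions["am_tree"] + fractions["am_shrub"], 0.0, 1.0),
        ("EcM", "woody"): np.clip(fractions["ecm_tree"] + fractions["ecm_shrub"], 0.0, 1.0),
        ("AM", "herbaceous"): fractions["am_herb"],
        ("EcM", "herbaceous"): fractions["ecm_herb"],
        ("AM", TUNDRA_POOL): fractions["am_total"],
        ("EcM", TUNDRA_POOL): fractions["ecm_total"],
    }
    pool_rows, form_rows, frac_rows = [], [], []
    for row in unit_table.itertuples():
        uid = int(row.unit_id)
        mask = unit_raster == uid
        forms = [TUNDRA_POOL] if row.is_tundra else list(_POOL_FORMS)
        for form in forms:
            form_rows.append((uid, form, float(np.mean(stock_px[form][mask]))))
            for myc in ("AM", "EcM"):
                stock = float(np.mean((stock_px[form] * frac_px[(myc, form)])[mask]))
                intensity = truth_intensity[(uid, myc, form)]
                pool_rows.append(
                    (uid, myc, form, intensity, stock, stock * intensity / 100.0)
                )
        frac_rows.append(
            (
                uid,
                float(np.mean(fractions["am_total"][mask])),
                float(np.mean(fractions["ecm_total"][mask])),
            )
        )
    return GroundTruth(
        unit_table=unit_table.copy(),
        unit_pools=pd.DataFrame(
            pool_rows,
            columns=[
                "unit_id",
                "myc_type",
                "growth_form",
                "intensity",
                "fine_root_stock",
                "colonized_stock",
            ],
        ),
        unit_form_stocks=pd.DataFrame(
            form_rows, columns=["unit_id", "growth_form", "fine_root_stock"]
        ),
        unit_fractions=pd.DataFrame(
            frac_rows, columns=["unit_id", "am_fraction", "ecm_fraction"]
        ),
        species_means=pd.DataFrame(
            species_truth_rows, columns=["species", "unit_kind", "true_mean"]
        ),
    )


def recovery_config(seed: int = 0, noisy: bool = False) -> WorldConfig:
    """Configuration of the parameter-recovery experiment.

    A ~20-unit world on a 100x100 coarse grid (5 ecoregion bands, the first
    tundra, x 4 retained land covers, one continent). The noiseless variant
    (30 plots/unit, exact records, full coverage) must reproduce the
    configured truth to floating tolerance. The noisy variant adds 10
    percentage points of observation noise with 100 plots/unit and 25
    observations/species — sized so the species-mean standard error is
    10/sqrt(25) = 2 pp and, with ~15 species per unit pool, the unit-level
    error stays well inside 2 pp (see the methods note for the power
    argument).
    """
    base = dict(
        n_ecoregions=5,
        n_landcover_classes=6,
        n_continents=1,
        grid_shape=(100, 100),
        fine_factor=2,
        species_pool_size=1200,
        fraction_dual_type=0.1,
        fraction_unassignable=0.03,
        fraction_form_unknown=0.02,
        plots_per_unit=30,
        obs_per_species=3,
        intensity_noise_sd=0.0,
        fraction_species_no_records=0.0,
        fraction_categorical=0.0,
        fraction_water=0.04,
        fraction_excluded_cover=0.05,
        seed=seed,
    )
    if noisy:
        base.update(plots_per_unit=100, obs_per_species=25, intensity_noise_sd=10.0)
    return WorldConfig(**base)


# -- persistence ------------------------------------------------------------

def write_world(world: SyntheticWorld, directory: str | Path) -> None:
    """Write a synthetic world to disk (GeoTIFF/CSV/JSON/YAML)."""
    directory = Path(directory)
    (directory / "rasters").mkdir(parents=True, exist_ok=True)
    (directory / "tables").mkdir(parents=True, exist_ok=True)
    inp = world.inputs
    for attr, filename in _RASTER_FILES:
        write_geotiff(getattr(inp, attr), directory / "rasters" / filename)
    inp.colonization_records.to_csv(
        directory / "tables" / "colonization_records.csv", index=False
    )
    for subset in sorted(inp.plots["subset"].unique()):
        sub = inp.plots[inp.plots["subset"] == subset]
        sub[["plot_id", "lon", "lat", "species", "rel_abundance"]].to_csv(
            directory / "tables" / f"plots_subset{int(subset)}.csv", index=False
        )
    inp.growth_form_traits.to_csv(
        directory / "tables" / "growth_form_traits.csv", index=False
    )
    inp.myc_type_traits.to_csv(directory / "tables" / "myc_type_traits.csv", index=False)
    inp.ratio_table.to_csv(
        directory / "tables" / "coarse_vs_fine_roots.csv", index=False
    )
    (directory / "categorical_mapping.json").write_text(
        json.dumps(world.categorical_mapping, sort_keys=True, indent=1)
    )
    world.truth.to_json(directory / "ground_truth.json")
    world.config.to_yaml(directory / "world_config.yml")


def read_world(directory: str | Path) -> SyntheticWorld:
    """Read back a world written by :func:`write_world`."""
    directory = Path(directory)
    cfg = WorldConfig.from_yaml(directory / "world_config.yml")
    rasters = {
        attr: read_geotiff(directory / "rasters" / filename)
        for attr, filename in _RASTER_FILES
    }
    records = pd.read_csv(directory / "tables" / "colonization_records.csv")
    subsets = []
    for path in sorted((directory / "tables").glob("plots_subset*.csv")):
        subset_id = int(path.stem.replace("plots_subset", ""))
        sub = pd.read_csv(path)
        sub["subset"] = subset_id
        subsets.append(sub)
    plots = pd.concat(subsets, ignore_index=True)
    mapping = json.loads((directory / "categorical_mapping.json").read_text())
    inputs = PipelineInputs(
        **rasters,
        colonization_records=records,
        plots=plots,
        growth_form_traits=pd.read_csv(directory / "tables" / "growth_form_traits.csv"),
        myc_type_traits=pd.read_csv(directory / "tables" / "myc_type_traits.csv"),
        ratio_table=pd.read_csv(directory / "tables" / "coarse_vs_fine_roots.csv"),
        fine_factor=cfg.fine_factor,
        excluded_classes=cfg.resolved_excluded(),
        tundra_ecoregions=frozenset(cfg.tundra_ecoregions),
        categorical_mapping=mapping,
    )
    truth = GroundTruth.from_json(directory / "ground_truth.json")
    truth.unit_table["is_tundra"] = truth.unit_table["is_tundra"].astype(bool)
    return SyntheticWorld(
        inputs=inputs, truth=truth, config=cfg, categorical_mapping=mapping
    )
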