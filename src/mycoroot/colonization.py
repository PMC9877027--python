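"""Mycorrhizal colonization intensity per spatial unit.

The intensity of root colonization (% of root length colonized by AM fungi,
% of root tips colonized by EcM fungi) is treated as a species-level trait:
records from non-natural settings or outside the growing season are dropped,
categorical records are converted to percentages, and the per-species mean
over the remaining observations becomes the trait value. AM and EcM records
are distinct measurement kinds and are never pooled; a dual-colonizing
species needs records of each kind to contribute to each pool.

Plot-level estimates are community-weighted means: within each mycorrhizal
type x growth form pool of a vegetation plot, species relative abundances
are renormalized over the species that actually have colonization data and
the pool intensity is the abundance-weighted mean of the species means. The
covered share of the pool abundance is recorded as *coverage* (a quality
index input). Unit-level intensity is the unweighted mean over the plots
falling in the unit. Plots in tundra units are pooled without growth-form
distinction (pool key ``tundra_all``).

Species matching across tables is case-insensitive exact matching after
whitespace normalization; the genus is the first whitespace-delimited token
of the species name. No fuzzy matching is attempted — dropped names are
counted and logged instead.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, MissingDataError
from .spatial_units import SpatialUnitMap

__all__ = [
    "MYC_KINDS",
    "normalize_name",
    "filter_records",
    "categorical_to_percent",
    "species_mean_colonization",
    "split_dual_abundance",
    "select_plot_subset",
    "assign_plots_to_units",
    "plot_weighted_intensity",
    "plots_weighted_intensity",
    "unit_intensity",
]

logger = logging.getLogger(__name__)

MYC_KINDS = ("AM", "EcM")

#: pool key used for the growth-form-free tundra path
TUNDRA_POOL = "tundra_all"


def normalize_name(name: str) -> str:
    """Whitespace-normalized, case-folded species or genus name."""
    return " ".join(str(name).split()).casefold()


def genus_of(species: str) -> str:
    """Genus = first whitespace-delimited token of the species name."""
    parts = str(species).split()
    return parts[0] if parts else ""


def filter_records(records: pd.DataFrame) -> pd.DataFrame:
    """Drop colonization records from non-natural settings or off-season.

    Records with naturalness ``non_natural`` or season ``non_growing`` are
    removed; ``unknown`` is retained for both fields (colonization is
    normally scored in the growing season of natural habitats).
    """
    keep = (records["naturalness"] != "non_natural") & (
        records["season"] != "non_growing"
    )
    dropped = int((~keep).sum())
    if dropped:
        logger.info("filter_records: dropped %d flagged record(s)", dropped)
    return records.loc[keep].copy()


def categorical_to_percent(
    records: pd.DataFrame, mapping: Mapping[str, float] | None = None
) -> pd.DataFrame:
    """Replace categorical colonization labels with their percent values.

    ``mapping`` must cover every categorical label present (label -> %);
    numeric values pass through untouched. Raises :class:`DataError` naming
    any unmapped label.
    """
    out = records.copy()
    numeric = pd.to_numeric(out["value"], errors="coerce")
    is_label = numeric.isna() & out["value"].notna()
    if is_label.any():
        labels = set(out.loc[is_label, "value"].astype(str))
        mapping = dict(mapping or {})
        unmapped = sorted(labels - set(mapping))
        if unmapped:
            raise DataError(
                f"categorical labels without a percent mapping: {unmapped}"
            )
        numeric = numeric.copy()
        numeric.loc[is_label] = out.loc[is_label, "value"].astype(str).map(mapping)
    values = numeric.astype(float)
    bad = values.notna() & ((values < 0) | (values > 100))
    if bad.any():
        raise DataError(
            f"{int(bad.sum())} colonization value(s) outside [0, 100]"
        )
    out["value"] = values
    return out


def species_mean_colonization(records: pd.DataFrame) -> pd.DataFrame:
    """Per (species, measurement kind) mean intensity and observation count.

    Expects filtered, numeric records with columns
    ``species, value, unit_kind``. Species names are normalized so that the
    output can be joined case-insensitively against trait and plot tables.
    """
    df = records.copy()
    df["species"] = df["species"].map(normalize_name)
    df["value"] = pd.to_numeric(df["value"])
    grouped = (
        df.groupby(["species", "unit_kind"], sort=True)["value"]
        .agg(mean_intensity="mean", n_obs="size")
        .reset_index()
    )
    return grouped


def _myc_type_shares(myc_type: str) -> list[tuple[str, float]]:
    """Resolve a trait label into (kind, abundance share) contributions."""
    label = str(myc_type).strip().casefold()
    if label in ("am", "facultative_am", "facultative am"):
        return [("AM", 1.0)]
    if label in ("ecm", "em"):
        return [("EcM", 1.0)]
    if label == "dual":
        return [("AM", 0.5), ("EcM", 0.5)]
    return []  # other / unknown: excluded


def split_dual_abundance(
    plot_records: pd.DataFrame,
    myc_traits: pd.DataFrame,
    growth_form_traits: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Resolve plot abundances into per-mycorrhizal-type contributions.

    Genus-based type assignment: dual-colonizing species contribute half
    their relative abundance to each of AM and EcM; facultative AM counts as
    AM; species whose genus has no assignable type are excluded (with a
    logged count). Growth forms are joined from ``growth_form_traits`` when
    given (missing species -> ``unknown``).

    Returns one row per (plot row, resolved kind) with columns of the input
    plus ``myc_type``, ``abundance`` and ``growth_form``.
    """
    df = plot_records.copy()
    df["species"] = df["species"].map(normalize_name)
    df["_genus"] = df["species"].map(genus_of)

    traits = myc_traits.copy()
    traits["_genus"] = traits["genus"].map(normalize_name)
    traits = traits.drop_duplicates("_genus")
    df = df.merge(traits[["_genus", "myc_type"]], on="_genus", how="left")

    shares = {
        label: _myc_type_shares(label)
        for label in df["myc_type"].dropna().unique()
    }
    rows = []
    excluded = 0
    for label, share_list in shares.items():
        sub = df[df["myc_type"] == label]
        if not share_list:
            excluded += len(sub)
            continue
        for kind, share in share_list:
            part = sub.copy()
            part["myc_type"] = kind
            part["abundance"] = part["rel_abundance"] * share
            rows.append(part)
    excluded += int(df["myc_type"].isna().sum())
    if excluded:
        logger.info(
            "split_dual_abundance: excluded %d plot record(s) without an "
            "assignable mycorrhizal type",
            excluded,
        )
    if rows:
        out = pd.concat(rows, ignore_index=True)
    else:
        out = df.iloc[0:0].copy()
        out["abundance"] = pd.Series(dtype=float)
    out = out.drop(columns=["_genus"])

    if growth_form_traits is not None:
        gf = growth_form_traits.copy()
        gf["species"] = gf["species"].map(normalize_name)
        gf = gf.drop_duplicates("species")
        out = out.merge(gf[["species", "growth_form"]], on="species", how="left")
        out["growth_form"] = out["growth_form"].fillna("unknown")
    elif "growth_form" not in out.columns:
        out["growth_form"] = "unknown"
    return out


def select_plot_subset(
    subsets: Sequence[pd.DataFrame], unit_map: SpatialUnitMap
) -> tuple[pd.DataFrame, dict]:
    """Choose the plot subset covering the most spatial units, then supplement.

    Mirrors the resampled-subset logic of plot databases shipping several
    balanced subsets: the subset whose plots fall in the largest number of
    units wins (ties go to the first by input order, logged); afterwards,
    plots from the other subsets are appended for units the winner leaves
    empty. Duplicate plot_ids (subsets may overlap) are not appended twice.
    """
    if not subsets or all(len(s) == 0 for s in subsets):
        raise MissingDataError("all candidate plot subsets are empty")

    coverages: list[set[int]] = []
    for sub in subsets:
        cov: set[int] = set()
        for plot_id, lon, lat in (
            sub[["plot_id", "lon", "lat"]].drop_duplicates("plot_id").itertuples(index=False)
        ):
            uid = unit_map.unit_at(float(lon), float(lat))
            if uid is not None:
                cov.add(uid)
        coverages.append(cov)

    sizes = [len(c) for c in coverages]
    best = int(np.argmax(sizes))
    if sizes.count(sizes[best]) > 1:
        logger.info(
            "select_plot_subset: coverage tie (%d units); keeping subset %d "
            "(first by input order)",
            sizes[best],
            best,
        )
    chosen = subsets[best].copy()
    covered = set(coverages[best])
    seen_plots = set(chosen["plot_id"])
    supplements = []
    n_supplement_plots = 0
    for i, sub in enumerate(subsets):
        if i == best:
            continue
        for plot_id, grp in sub.groupby("plot_id", sort=False):
            if plot_id in seen_plots:
                continue
            lon = float(grp["lon"].iloc[0])
            lat = float(grp["lat"].iloc[0])
            uid = unit_map.unit_at(lon, lat)
            if uid is not None and uid not in covered:
                supplements.append(grp)
                covered.add(uid)
                seen_plots.add(plot_id)
                n_supplement_plots += 1
    if supplements:
        chosen = pd.concat([chosen] + supplements, ignore_index=True)
    report = {
        "chosen_subset": best,
        "subset_unit_coverage": sizes,
        "n_supplement_plots": n_supplement_plots,
        "n_units_covered": len(covered),
    }
    return chosen, report


def assign_plots_to_units(
    plots: pd.DataFrame, unit_map: SpatialUnitMap
) -> pd.DataFrame:
    """Point-in-pixel lookup of each plot's spatial unit.

    Plots falling on nodata or excluded pixels are dropped with a logged
    count. Returns one row per retained plot: ``plot_id, unit_id``.
    """
    unique = plots[["plot_id", "lon", "lat"]].drop_duplicates("plot_id")
    ids, units = [], []
    dropped = 0
    for plot_id, lon, lat in unique.itertuples(index=False):
        uid = unit_map.unit_at(float(lon), float(lat))
        if uid is None:
            dropped += 1
            continue
        ids.append(plot_id)
        units.append(uid)
    if dropped:
        logger.info(
            "assign_plots_to_units: dropped %d plot(s) on nodata/excluded pixels",
            dropped,
        )
    return pd.DataFrame({"plot_id": ids, "unit_id": pd.array(units, dtype="int64")})


def _pool_stats(df: pd.DataFrame, keys: list[str]) -> pd.DataFrame:
    """Renormalized abundance-weighted pool statistics.

    ``df`` needs columns ``abundance, mean_intensity, n_obs`` (the latter two
    NaN for species without colonization data). Pools with zero covered
    abundance are dropped (empty, excluded from unit averaging).
    """
    work = df.copy()
    covered = work["mean_intensity"].notna()
    work["_cov_ab"] = np.where(covered, work["abundance"], 0.0)
    work["_wsum"] = np.where(covered, work["abundance"] * work["mean_intensity"], 0.0)
    work["_obs"] = np.where(covered, work["n_obs"], np.nan)
    work["_ncov"] = covered.astype(int)
    grouped = work.groupby(keys, sort=True, dropna=False).agg(
        total_abundance=("abundance", "sum"),
        covered_abundance=("_cov_ab", "sum"),
        _wsum=("_wsum", "sum"),
        mean_obs_per_species=("_obs", "mean"),
        n_species_covered=("_ncov", "sum"),
    )
    grouped = grouped[grouped["covered_abundance"] > 0].reset_index()
    grouped["intensity"] = grouped["_wsum"] / grouped["covered_abundance"]
    grouped["coverage"] = (
        grouped["covered_abundance"] / grouped["total_abundance"] * 100.0
    )
    return grouped.drop(columns=["_wsum"])


def _merge_species_means(resolved: pd.DataFrame, species_means: pd.DataFrame) -> pd.DataFrame:
    sm = species_means.rename(columns={"unit_kind": "myc_type"})
    sm = sm[["species", "myc_type", "mean_intensity", "n_obs"]]
    return resolved.merge(sm, on=["species", "myc_type"], how="left")


def plot_weighted_intensity(
    plot: pd.DataFrame, species_means: pd.DataFrame, tundra: bool = False
) -> pd.DataFrame:
    """Community-weighted colonization intensity of one vegetation plot.

    ``plot`` holds type-resolved rows (``species, myc_type, growth_form,
    abundance``, e.g. from :func:`split_dual_abundance`). Within each
    mycorrhizal type x growth form pool, weights are the abundances of the
    species that have colonization data for that kind, renormalized to sum
    to one; coverage is the covered share of the pool abundance in percent.
    In a tundra plot the growth-form split is ignored (``tundra_all`` pool)
    and growth-form-unknown species are retained; elsewhere they are
    excluded from the woody/herbaceous pools.
    """
    df = plot.copy()
    if tundra:
        df["growth_form"] = TUNDRA_POOL
    else:
        df = df[df["growth_form"].isin(["woody", "herbaceous"])]
    df = _merge_species_means(df, species_means)
    out = _pool_stats(df, ["myc_type", "growth_form"])
    return out[
        [
            "myc_type",
            "growth_form",
            "intensity",
            "coverage",
            "mean_obs_per_species",
            "n_species_covered",
            "total_abundance",
            "covered_abundance",
        ]
    ]


def plots_weighted_intensity(
    resolved: pd.DataFrame,
    species_means: pd.DataFrame,
    plot_units: pd.DataFrame,
    unit_map: SpatialUnitMap,
) -> pd.DataFrame:
    """Per-plot pool intensities for every plot assigned to a unit.

    Vectorized version of :func:`plot_weighted_intensity` across all plots;
    plots in tundra units are pooled growth-form-free. Returns one row per
    (plot, myc_type, pool) with intensity, coverage and the quality-index
    raw material (mean observations per covered species, abundances).
    """
    df = resolved.merge(plot_units, on="plot_id", how="inner")
    tundra_ids = unit_map.tundra_unit_ids()
    is_tundra = df["unit_id"].isin(tundra_ids)
    df = df.copy()
    df["growth_form"] = np.where(is_tundra, TUNDRA_POOL, df["growth_form"])
    df = df[df["growth_form"].isin(["woody", "herbaceous", TUNDRA_POOL])]
    df = _merge_species_means(df, species_means)
    return _pool_stats(df, ["unit_id", "plot_id", "myc_type", "growth_form"])


def unit_intensity(plot_pools: pd.DataFrame) -> pd.DataFrame:
    """Unit-level colonization: unweighted mean over plots per pool.

    Input is the per-plot pool table of :func:`plots_weighted_intensity`.
    Units with no plots are simply absent (gap-filled downstream). Records
    per pool: mean intensity, number of contributing plots, and the plot
    means of observations-per-species and coverage for the quality indices.
    """
    grouped = (
        plot_pools.groupby(["unit_id", "myc_type", "growth_form"], sort=True)
        .agg(
            mean_intensity=("intensity", "mean"),
            n_plots=("plot_id", "size"),
            mean_obs_per_species=("mean_obs_per_species", "mean"),
            mean_coverage=("coverage", "mean"),
        )
        .reset_index()
    )
    return grouped
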