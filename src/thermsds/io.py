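"""Readers and writers for the pipeline's on-disk formats.

Trees are Newick; trait tables CSV; climate either a NetCDF cube with
dimensions (year, month, row, col) or a directory of per-month CSV rasters
with a JSON manifest; range masks either GeoJSON polygons (rasterized by
cell-centre containment on the climate grid) or CSV cell lists.  Readers
validate and reject rather than coerce; exclusions are enumerated, never
silent.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import xarray as xr
import yaml
from shapely.geometry import box, shape, mapping
from shapely.ops import unary_union

from .climate import ClimateGrid, RangeMask
from .trees import Phylogeny

__all__ = [
    "StudyConfig",
    "read_tree",
    "write_tree",
    "read_traits",
    "read_climate",
    "write_climate",
    "read_ranges",
    "write_ranges_csv",
    "write_ranges_geojson",
    "write_study",
]

REQUIRED_TRAIT_COLUMNS = ("species", "sds", "reproductive_mode",
                          "breed_start", "breed_end", "family")


class TraitTableError(ValueError):
    """A trait-table row failed validation."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------
@dataclass
class StudyConfig:
    """Paths, period bounds and analysis toggles for a pipeline run."""

    tree: str = ""
    traits: str = ""
    climate: str = ""
    ranges: str = ""
    out: str = "results"
    period_start: int | None = None
    period_end: int | None = None  # inclusive on both ends
    use_area_weights: bool = False
    oviparous_only: bool = False
    null_window_mode: str = "enumerate"
    seed: int = 0

    def __post_init__(self):
        if (self.period_start is not None and self.period_end is not None
                and self.period_start > self.period_end):
            raise ValueError("period start must not exceed period end")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------
def read_tree(path) -> Phylogeny:
    """Read and validate a Newick tree (branch lengths mandatory)."""
    return Phylogeny.from_file(path)


def write_tree(tree: Phylogeny, path) -> None:
    tree.to_file(path)


# ---------------------------------------------------------------------------
# trait tables
# ---------------------------------------------------------------------------
def read_traits(path, tree: Phylogeny | None = None
                ) -> tuple[pd.DataFrame, list[dict]]:
    """Read and validate the per-species trait CSV.

    Codings: sds and reproductive_mode in {0,1}; breeding months 1..12
    with a blank end month resolved to December.  Returns
    ``(records indexed by species, exclusion list)``; a species absent
    from the tree is excluded with a reason, not fatal.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise TraitTableError(f"missing required columns: {missing}")
    exclusions: list[dict] = []
    rows = {}
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        sp = row["species"]
        if pd.isna(sp) or not str(sp).strip():
            raise TraitTableError(f"line {line}: empty species label")
        sp = str(sp).strip()
        if sp in rows:
            raise TraitTableError(f"line {line}: duplicate species {sp!r}")
        for col in ("sds", "reproductive_mode"):
            v = row[col]
            if pd.isna(v) or float(v) not in (0.0, 1.0):
                raise TraitTableError(
                    f"line {line}: {col} must be 0 or 1, got {v!r}"
                )
        start = row["breed_start"]
        if pd.isna(start) or not 1 <= int(start) <= 12:
            raise TraitTableError(
                f"line {line}: breed_start must be a month 1..12, got {start!r}"
            )
        end = row["breed_end"]
        if pd.isna(end):
            end = 12  # open-ended season closes in December
        elif not 1 <= int(end) <= 12:
            raise TraitTableError(
                f"line {line}: breed_end must be a month 1..12 or blank, "
                f"got {end!r}"
            )
        if tree is not None and sp not in set(tree.tip_labels):
            exclusions.append({"species": sp, "line": line,
                               "reason": "not a tip of the tree"})
            continue
        rec = dict(row)
        rec["sds"] = int(row["sds"])
        rec["reproductive_mode"] = int(row["reproductive_mode"])
        rec["breed_start"] = int(start)
        rec["breed_end"] = int(end)
        rows[sp] = rec
    records = pd.DataFrame.from_dict(rows, orient="index")
    records = records.drop(columns=["species"])
    records.index.name = "species"
    return records, exclusions


# ---------------------------------------------------------------------------
# climate grids
# ---------------------------------------------------------------------------
def write_climate(grid: ClimateGrid, path, fmt: str = "netcdf") -> None:
    """Write a climate cube as NetCDF (scipy backend, NetCDF3) or as a
    directory of per-month CSV rasters plus a JSON manifest."""
    path = Path(path)
    if fmt == "netcdf":
        ds = xr.Dataset(
            {grid.variable: (("year", "month", "row", "col"), grid.values)},
            coords={
                "year": grid.years,
                "month": np.arange(1, 13),
                "row": np.arange(grid.values.shape[2]),
                "col": np.arange(grid.values.shape[3]),
            },
        )
        ds.to_netcdf(path, engine="scipy")
    elif fmt == "csvdir":
        path.mkdir(parents=True, exist_ok=True)
        manifest = {
            "variable": grid.variable,
            "years": [int(y) for y in grid.years],
            "rows": int(grid.values.shape[2]),
            "cols": int(grid.values.shape[3]),
        }
        with open(path / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        for yi, year in enumerate(grid.years):
            for m in range(1, 13):
                np.savetxt(
                    path / f"{grid.variable}_y{year}_m{m:02d}.csv",
                    grid.values[yi, m - 1], delimiter=",",
                )
    else:
        raise ValueError(f"unknown climate format {fmt!r}")


def read_climate(path, period: tuple[int, int] | None = None) -> ClimateGrid:
    """Read a climate cube from NetCDF or a CSV-raster directory.

    ``period=(start, end)`` crops to the inclusive year range.  Missing
    month files within the period are an error listing the gaps.
    """
    path = Path(path)
    if path.is_dir():
        with open(path / "manifest.json") as fh:
            manifest = json.load(fh)
        var = manifest["variable"]
        years = manifest["years"]
        gaps = []
        values = np.empty((len(years), 12, manifest["rows"], manifest["cols"]))
        for yi, year in enumerate(years):
            for m in range(1, 13):
                f = path / f"{var}_y{year}_m{m:02d}.csv"
                if not f.exists():
                    gaps.append(f.name)
                    continue
                values[yi, m - 1] = np.loadtxt(f, delimiter=",", ndmin=2)
        if gaps:
            raise ValueError(f"missing month rasters: {gaps[:10]}")
        grid = ClimateGrid(values, np.array(years), var)
    else:
        ds = xr.open_dataset(path, engine="scipy")
        var = [v for v in ds.data_vars][0]
        da = ds[var].transpose("year", "month", "row", "col")
        if da.sizes["month"] != 12:
            raise ValueError("climate cube must cover all 12 months")
        grid = ClimateGrid(da.values, ds["year"].values.astype(int), var)
        ds.close()
    if period is not None:
        grid = grid.crop_period(*period)
    return grid


# ---------------------------------------------------------------------------
# range masks
# ---------------------------------------------------------------------------
def write_ranges_csv(masks: dict[str, RangeMask], path) -> None:
    rows = [
        {"species": sp, "row": r, "col": c}
        for sp, mask in masks.items()
        for r, c in mask.cells
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_ranges_geojson(masks: dict[str, RangeMask], path) -> None:
    """Each species' mask as the union of its unit cell squares
    (x=col..col+1, y=row..row+1 in grid coordinates)."""
    features = []
    for sp, mask in masks.items():
        cells = [box(c, r, c + 1, r + 1) for r, c in mask.cells]
        geom = unary_union(cells)
        features.append({
            "type": "Feature",
            "properties": {"species": sp},
            "geometry": mapping(geom),
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_ranges(path, grid_shape: tuple[int, int]) -> tuple[dict, list[dict]]:
    """Read range masks from CSV cell lists or GeoJSON polygons.

    GeoJSON polygons are rasterized by cell-centre containment: cell
    (r, c) belongs to a species when the polygon covers the point
    (c+0.5, r+0.5).  Returns ``(masks, flags)`` where species whose
    polygon catches no cell centre are flagged and excluded.
    """
    path = Path(path)
    rows_n, cols_n = grid_shape
    flags: list[dict] = []
    masks: dict[str, RangeMask] = {}
    if path.suffix.lower() in (".geojson", ".json"):
        with open(path) as fh:
            gj = json.load(fh)
        cc, rr = np.meshgrid(np.arange(cols_n) + 0.5, np.arange(rows_n) + 0.5)
        for feat in gj["features"]:
            sp = feat["properties"]["species"]
            geom = shape(feat["geometry"])
            inside = shapely.contains_xy(geom, cc.ravel(), rr.ravel())
            idx = np.flatnonzero(inside)
            if len(idx) == 0:
                flags.append({"species": sp,
                              "reason": "polygon covers no cell centre"})
                continue
            cells = [(int(i // cols_n), int(i % cols_n)) for i in idx]
            masks[sp] = RangeMask.from_indices(cells)
    else:
        df = pd.read_csv(path)
        for col in ("species", "row", "col"):
            if col not in df.columns:
                raise ValueError(f"cell-list CSV needs column {col!r}")
        bad = df[(df["row"] < 0) | (df["row"] >= rows_n)
                 | (df["col"] < 0) | (df["col"] >= cols_n)]
        if len(bad):
            raise ValueError(
                f"cells outside the {rows_n}x{cols_n} grid at CSV rows "
                f"{list(bad.index[:5])}"
            )
        for sp, sub in df.groupby("species"):
            masks[str(sp)] = RangeMask.from_indices(
                sub[["row", "col"]].values
            )
    return masks, flags


# ---------------------------------------------------------------------------
# whole-study writer
# ---------------------------------------------------------------------------
def write_study(study, outdir, climate_fmt: str = "csvdir") -> None:
    """Write a :class:`~thermsds.synthetic.SyntheticStudy` as plain files:
    Newick tree, trait CSV, climate rasters, CSV + GeoJSON range masks and
    a JSON sidecar with the true generating parameters."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_tree(study.tree, outdir / "tree.nwk")
    study.traits.reset_index().to_csv(outdir / "traits.csv", index=False)
    write_climate(study.grid_temp, outdir / ("temperature.nc"
                  if climate_fmt == "netcdf" else "temperature"), climate_fmt)
    write_climate(study.grid_precip, outdir / ("precipitation.nc"
                  if climate_fmt == "netcdf" else "precipitation"), climate_fmt)
    write_ranges_csv(study.masks, outdir / "ranges.csv")
    write_ranges_geojson(study.masks, outdir / "ranges.geojson")
    with open(outdir / "true_params.json", "w") as fh:
        json.dump(study.true_params, fh, indent=1)
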