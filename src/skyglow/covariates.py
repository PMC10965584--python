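"""From rasters and survey records to the standardized multi-scale design table.

Landscape predictors (ALAN radiance and land-cover proportions) are measured
as buffer means around each survey station at three radii — 400 m (local),
1600 m (intermediate), 6400 m (landscape) — so every landscape covariate
appears in the design once per radius, named ``"<cov>_<radius>"``.  Temporal
covariates (sun angle, day of year, lunar illumination), geographic covariates
and the prior-count covariate enter at a single scale.

Buffer means use a center-in rule: a raster cell contributes if its center
lies within the radius of the station.  This choice is isolated in
``buffer_mean`` so an area-weighted rule could be swapped in; satellite
radiance pixels are coarse (~300-460 m) relative to the smallest buffer, so
partial-pixel weighting is second-order here.

Standardization z-scores each continuous column; quadratic columns are the
square of the standardized linear term, re-standardized.  The per-column
means and standard deviations are retained so model output can be mapped back
to natural units (radiance in nW cm^-2 sr^-1, cover proportions in [0, 1]).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_RADII = (400, 1600, 6400)

#: survey-level (single-scale) covariates with quadratic companions
QUAD_BASES = ("sun_angle", "day_of_year")

ID_COLUMNS = ("station_id", "route_id", "year", "survey_idx", "x", "y")


# ---------------------------------------------------------------------------
# Raster compositing
# ---------------------------------------------------------------------------


def compose_alan(v1: np.ndarray, v2: np.ndarray, mode: str = "mean") -> np.ndarray:
    """Combine two annual radiance composites cell-wise.

    ``mode="mean"`` averages the two versions (the headline analysis);
    ``"v1-only"`` / ``"v2-only"`` pass one version through unchanged for the
    sensitivity analysis.
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != v2.shape:
        raise ValueError(f"composite shapes differ: {v1.shape} vs {v2.shape}")
    if mode == "mean":
        return (v1 + v2) / 2.0
    if mode == "v1-only":
        return v1.copy()
    if mode == "v2-only":
        return v2.copy()
    raise ValueError(f"unknown mode {mode!r}")


def mode_composite(class_rasters_by_year: dict) -> np.ndarray:
    """Per-cell modal land-cover class across years.

    Ties are broken toward the class held in the most recent tied year, so a
    recent transition wins over an equally frequent historical class.
    """
    if not class_rasters_by_year:
        raise ValueError("no class rasters supplied")
    years = sorted(class_rasters_by_year)
    stack = np.stack([np.asarray(class_rasters_by_year[yr]) for yr in years])
    if any(r.shape != stack[0].shape for r in stack):
        raise ValueError("class rasters are not co-registered")
    classes = np.unique(stack)
    counts = np.stack([(stack == c).sum(axis=0) for c in classes])      # (C, ...)
    # last year index in which each class occurs, -1 if never
    year_idx = np.arange(len(years))[:, None, None]
    last_seen = np.stack([
        np.max(np.where(stack == c, year_idx, -1), axis=0) for c in classes
    ])
    maxcount = counts.max(axis=0)
    tied = counts == maxcount
    # among tied classes prefer the largest last-seen year; argmax over a
    # keyed score keeps it vectorised
    score = np.where(tied, last_seen, -2)
    winner = score.argmax(axis=0)
    return classes[winner]


def gap_fill_cover(primary: np.ndarray, secondary: np.ndarray,
                   primary_classes: dict, secondary_classes: dict) -> dict:
    """Merge two classified rasters into per-class 0/1 indicator rasters.

    Cells holding one of ``primary_classes`` (code -> name) keep that class;
    all other cells take the class from ``secondary`` (e.g. a vegetation
    inventory filling in sparse forest / shrubland / grassland).  Cells
    unclassified in both legends get zero in every indicator.  Buffer means of
    the indicators then give proportion covers.
    """
    primary = np.asarray(primary)
    secondary = np.asarray(secondary)
    if primary.shape != secondary.shape:
        raise ValueError("class rasters are not co-registered")
    known = set(primary_classes) | set(secondary_classes) | {0}
    for name, arr in (("primary", primary), ("secondary", secondary)):
        bad = set(np.unique(arr)) - known
        if bad:
            raise ValueError(f"{name} raster holds codes outside both legends: {sorted(bad)}")
    primary_hit = np.isin(primary, list(primary_classes))
    out = {}
    for code, name in primary_classes.items():
        out[name] = (primary_hit & (primary == code)).astype(float)
    for code, name in secondary_classes.items():
        out[name] = (~primary_hit & (secondary == code)).astype(float)
    return out


# ---------------------------------------------------------------------------
# Buffer extraction
# ---------------------------------------------------------------------------


def buffer_stats(raster: np.ndarray, station_xy, radius_m: float,
                 origin=(0.0, 0.0), resolution: float = 300.0):
    """Mean of a raster over cells whose centers lie within ``radius_m``.

    Returns ``(mean, coverage)`` where coverage is the fraction of the full
    circular neighbourhood that lies inside the raster extent.  Stations
    nearer than the radius to an edge use the available cells only.
    """
    raster = np.asarray(raster, dtype=float)
    nrow, ncol = raster.shape
    x0, y0 = origin
    sx, sy = float(station_xy[0]), float(station_xy[1])
    if not (x0 <= sx <= x0 + ncol * resolution and y0 <= sy <= y0 + nrow * resolution):
        raise ValueError(f"station {station_xy} lies outside the raster extent")
    # candidate index window
    r_cells = int(np.ceil(radius_m / resolution)) + 1
    jc = int((sx - x0) / resolution)
    ic = int((sy - y0) / resolution)
    jj = np.arange(jc - r_cells, jc + r_cells + 1)
    ii = np.arange(ic - r_cells, ic + r_cells + 1)
    cx = x0 + (jj + 0.5) * resolution
    cy = y0 + (ii + 0.5) * resolution
    dist2 = (cx[None, :] - sx) ** 2 + (cy[:, None] - sy) ** 2
    inside_disk = dist2 <= radius_m ** 2
    n_full = int(inside_disk.sum())
    in_extent = ((ii >= 0) & (ii < nrow))[:, None] & ((jj >= 0) & (jj < ncol))[None, :]
    use = inside_disk & in_extent
    if n_full == 0:
        # radius smaller than the nearest center distance: use the containing cell
        i = min(max(ic, 0), nrow - 1)
        j = min(max(jc, 0), ncol - 1)
        return float(raster[i, j]), 1.0
    if not use.any():
        raise ValueError("buffer does not overlap the raster extent")
    vals = raster[np.clip(ii, 0, nrow - 1)[:, None], np.clip(jj, 0, ncol - 1)[None, :]]
    mean = float(vals[use].mean())
    coverage = float(use.sum() / n_full)
    return mean, coverage


def buffer_mean(raster, station_xy, radius_m, origin=(0.0, 0.0),
                resolution: float = 300.0) -> float:
    """Center-in buffer mean; warns when the buffer is edge-truncated."""
    mean, coverage = buffer_stats(raster, station_xy, radius_m, origin, resolution)
    if coverage < 1.0:
        warnings.warn(
            f"buffer at {tuple(station_xy)} r={radius_m} m truncated: "
            f"coverage {coverage:.2f}", stacklevel=2)
    return mean


# ---------------------------------------------------------------------------
# Prior-count covariate
# ---------------------------------------------------------------------------


def prior_mean_count(history: pd.DataFrame, station, year: int, survey_idx: int) -> float:
    """Mean territorial count over earlier surveys at the same station.

    Qualifying surveys are at the same station and either strictly earlier in
    the same calendar year or at any time in the previous calendar year.
    Returns 0 when no survey qualifies (the first visit to a station).
    """
    h = history
    same_station = h["station_id"] == station
    earlier_same_year = (h["year"] == year) & (h["survey_idx"] < survey_idx)
    previous_year = h["year"] == year - 1
    q = h.loc[same_station & (earlier_same_year | previous_year), "count"]
    return float(q.mean()) if len(q) else 0.0


# ---------------------------------------------------------------------------
# Design table
# ---------------------------------------------------------------------------


@dataclass
class MultiScaleDesign:
    """One row per survey; each landscape covariate present at every radius.

    ``scaling`` maps column name -> (mean, sd) once standardized, so natural
    units can be recovered (``x = z * sd + mean``).
    """

    df: pd.DataFrame
    radii: tuple[int, ...] = DEFAULT_RADII
    landscape_covs: tuple[str, ...] = ()
    fixed_covs: tuple[str, ...] = ()
    quad_pairs: tuple[tuple[str, str], ...] = ()
    response: str = "count"
    scaling: dict = field(default_factory=dict)
    standardized: bool = False

    def __post_init__(self):
        self.radii = tuple(int(r) for r in self.radii)
        if list(self.radii) != sorted(set(self.radii)):
            raise ValueError("radii must be strictly increasing")
        missing = [self.column(c, r) for c in self.landscape_covs for r in self.radii
                   if self.column(c, r) not in self.df.columns]
        if missing:
            raise ValueError(f"landscape covariate columns missing: {missing}")

    def column(self, cov: str, radius) -> str:
        return f"{cov}_{int(radius)}"

    @property
    def y(self) -> np.ndarray:
        return np.asarray(self.df[self.response])

    def scaled_columns(self) -> list[str]:
        cols = [self.column(c, r) for c in self.landscape_covs for r in self.radii]
        cols += [c for c in self.fixed_covs if c not in [q for _, q in self.quad_pairs]]
        return cols

    def standardize(self) -> "MultiScaleDesign":
        """Z-score continuous columns; rebuild quadratics from standardized bases."""
        if self.df.isna().any().any():
            bad = self.df.columns[self.df.isna().any()].tolist()
            raise ValueError(f"missing values in design columns {bad}")
        df = self.df.copy()
        scaling = {}
        for col in self.scaled_columns():
            x = np.asarray(df[col], dtype=float)
            m, s = float(x.mean()), float(x.std())
            if s == 0.0:
                raise ValueError(f"column {col!r} has zero variance; cannot standardize")
            df[col] = (x - m) / s
            scaling[col] = (m, s)
        for base, sq in self.quad_pairs:
            z2 = np.asarray(df[base], dtype=float) ** 2
            m, s = float(z2.mean()), float(z2.std())
            if s == 0.0:
                raise ValueError(f"column {sq!r} has zero variance; cannot standardize")
            df[sq] = (z2 - m) / s
            scaling[sq] = (m, s)
        return replace(self, df=df, scaling=scaling, standardized=True)

    def unstandardize(self) -> "MultiScaleDesign":
        """Invert ``standardize`` (quadratics are recomputed from bases)."""
        if not self.standardized:
            return self
        df = self.df.copy()
        for col in self.scaled_columns():
            m, s = self.scaling[col]
            df[col] = np.asarray(df[col], dtype=float) * s + m
        for base, sq in self.quad_pairs:
            df[sq] = np.asarray(df[base], dtype=float) ** 2
        return replace(self, df=df, scaling={}, standardized=False)

    def to_natural(self, col: str, z) -> np.ndarray:
        """Map standardized values of ``col`` back to natural units."""
        m, s = self.scaling.get(col, (0.0, 1.0))
        return np.asarray(z, dtype=float) * s + m

    def to_standardized(self, col: str, x) -> np.ndarray:
        m, s = self.scaling.get(col, (0.0, 1.0))
        return (np.asarray(x, dtype=float) - m) / s

    # -- serialization ------------------------------------------------------

    def to_csv(self, path) -> None:
        path = Path(path)
        self.df.to_csv(path, index=False)
        meta = {
            "radii": list(self.radii),
            "landscape_covs": list(self.landscape_covs),
            "fixed_covs": list(self.fixed_covs),
            "quad_pairs": [list(p) for p in self.quad_pairs],
            "response": self.response,
            "scaling": {k: list(v) for k, v in self.scaling.items()},
            "standardized": self.standardized,
        }
        path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_csv(cls, path) -> "MultiScaleDesign":
        path = Path(path)
        meta = json.loads(path.with_suffix(".meta.json").read_text())
        return cls(
            df=pd.read_csv(path),
            radii=tuple(meta["radii"]),
            landscape_covs=tuple(meta["landscape_covs"]),
            fixed_covs=tuple(meta["fixed_covs"]),
            quad_pairs=tuple(tuple(p) for p in meta["quad_pairs"]),
            response=meta["response"],
            scaling={k: tuple(v) for k, v in meta["scaling"].items()},
            standardized=meta["standardized"],
        )


def build_design(landscape, stations: pd.DataFrame, surveys: pd.DataFrame,
                 radii=DEFAULT_RADII, landscape_covs=None,
                 geographic_covs=("elevation", "slope"),
                 include_prior_count: bool = True) -> MultiScaleDesign:
    """Assemble the (unstandardized) multi-scale design table.

    ``landscape`` is a :class:`skyglow.synthdata.Landscape`-like object with
    ``layers`` (name -> 2D array), ``origin`` and ``resolution``.  ``stations``
    has columns station_id, route_id, x, y; ``surveys`` one row per survey with
    temporal covariates and, if available, a ``count`` column (used for the
    prior-count covariate).
    """
    if landscape_covs is None:
        landscape_covs = tuple(
            c for c in ("alan", "urban", "cropland", "pasture", "water_wetland",
                        "sparse_forest", "shrubland", "grassland")
            if c in landscape.layers)
    rows = {}
    for cov in landscape_covs:
        raster = landscape.layers[cov]
        for r in radii:
            vals = {}
            for _, st in stations.iterrows():
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")  # edge truncation tolerated here
                    vals[st["station_id"]] = buffer_stats(
                        raster, (st["x"], st["y"]), r,
                        landscape.origin, landscape.resolution)[0]
            rows[f"{cov}_{int(r)}"] = vals
    geo = {}
    for cov in geographic_covs:
        raster = landscape.layers[cov]
        vals = {}
        for _, st in stations.iterrows():
            vals[st["station_id"]] = buffer_stats(
                raster, (st["x"], st["y"]), landscape.resolution,
                landscape.origin, landscape.resolution)[0]
        geo[cov] = vals

    df = surveys.merge(stations[["station_id", "x", "y"]], on="station_id", how="left")
    for col, vals in rows.items():
        df[col] = df["station_id"].map(vals)
    for col, vals in geo.items():
        df[col] = df["station_id"].map(vals)

    quad_pairs = []
    for base in QUAD_BASES:
        if base in df.columns:
            df[f"{base}_sq"] = df[base] ** 2
            quad_pairs.append((base, f"{base}_sq"))
    fixed = [c for c in ("sun_angle", "sun_angle_sq", "day_of_year",
                         "day_of_year_sq", "lunar") if c in df.columns]
    fixed += list(geographic_covs)

    if include_prior_count:
        if "count" in df.columns:
            hist = df[["station_id", "year", "survey_idx", "count"]]
            df["prior_count"] = [
                prior_mean_count(hist, r.station_id, int(r.year), int(r.survey_idx))
                for r in df.itertuples()
            ]
        else:
            df["prior_count"] = 0.0
        fixed.append("prior_count")

    return MultiScaleDesign(
        df=df, radii=tuple(radii), landscape_covs=tuple(landscape_covs),
        fixed_covs=tuple(fixed), quad_pairs=tuple(quad_pairs),
    )
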