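"""Synthetic landscapes, roadside survey designs, counts, and detections.

The generator emulates the statistical structure of a night-time roadside
point-count study of crepuscular birds:

* a metric raster landscape with point light sources, a smooth skyglow field
  (Gaussian blur of the direct emissions), and land-cover proportion layers in
  which urban cover is spatially coupled to the light sources so that
  station-level ALAN and urban cover correlate at a configurable strength;
* survey routes of 6-10 stations spaced approximately 1.6 km apart, each
  surveyed for 6 minutes split into 1-minute intervals, repeated within and
  across years;
* counts that are negative-binomial with a log link, where each landscape
  covariate acts at exactly one buffer radius (its scale of effect) and an
  ALAN x urban interaction may act at its own pair of scales;
* a per-minute Bernoulli detection process on the logit scale that can weaken
  with ALAN, yielding 6-slot detection histories per individual and observed
  counts that can fall below true counts.

Everything is deterministic given the configured seed.  A fast companion
generator (:func:`make_multiscale_design`) draws multi-scale covariate tables
directly from a correlated Gaussian model, bypassing rasters; it is the
workhorse for sampler-calibration studies (scale recovery, coverage, DIC
ordering) where landscape realism is irrelevant but run time matters.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .covariates import DEFAULT_RADII, MultiScaleDesign, build_design, prior_mean_count

COVER_CLASSES = ("urban", "cropland", "pasture", "water_wetland",
                 "sparse_forest", "shrubland", "grassland")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Study-design and landscape settings for the generator."""

    n_cells: int = 96                   # square grid side, cells
    resolution: float = 300.0           # m per cell (satellite-radiance grain)
    n_sources: int = 60                 # point light sources
    source_intensity_log_mean: float = np.log(40.0)
    source_intensity_log_sd: float = 1.0
    skyglow_bandwidth: float = 2000.0   # m; Gaussian blur of the direct field
    skyglow_strength: float = 0.5
    target_alan_urban_corr: float = 0.6
    corr_tol: float = 0.15
    n_urban_patches: int = 30
    n_routes: int = 10
    stations_per_route: tuple[int, int] = (6, 10)
    station_spacing: float = 1600.0     # m
    spacing_jitter: float = 0.05        # fractional; +-5% keeps gaps within +-10%
    surveys_per_station: int = 2        # per year
    years: int = 2
    radii: tuple[int, ...] = DEFAULT_RADII
    seed: int = 0

    def __post_init__(self):
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        if self.n_cells < 8:
            raise ValueError("degenerate grid: need at least 8x8 cells")
        if list(self.radii) != sorted(set(int(r) for r in self.radii)):
            raise ValueError("radii must be strictly increasing")
        lo, hi = self.stations_per_route
        if not 1 <= lo <= hi:
            raise ValueError("stations_per_route must be a nonempty integer range")
        if self.station_spacing <= 0:
            raise ValueError("station spacing must be > 0")

    @property
    def extent(self) -> float:
        return self.n_cells * self.resolution


@dataclass
class TrueParameters:
    """Generating parameters for counts and detections.

    ``coefficients`` maps a landscape covariate to ``(beta, radius)`` — or a
    list of two such pairs for a covariate acting at two scales with distinct
    coefficients.  ``interaction`` is ``(beta, radius_a, radius_b)`` for the
    product of the two ``interaction_covs``.  Effects are on the log scale of
    the standardized design columns; the prior-count coefficient acts on the
    natural (count) scale.  Detection slopes are per-minute logit effects
    keyed by design column name.
    """

    intercept: float = float(np.log(1.67))
    coefficients: dict = field(default_factory=dict)
    interaction: tuple | None = None
    interaction_covs: tuple[str, str] = ("alan", "urban")
    temporal: dict = field(default_factory=dict)
    geographic: dict = field(default_factory=dict)
    prior_count_coef: float = 0.0
    dispersion: float = 2.0
    zero_inflation: float = 0.0
    detection_intercept: float = 2.0
    detection_slopes: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.dispersion <= 0:
            raise ValueError("NB dispersion must be > 0")
        if not 0.0 <= self.zero_inflation < 1.0:
            raise ValueError("zero-inflation probability must lie in [0, 1)")

    def pairs(self, cov) -> list:
        v = self.coefficients[cov]
        return list(v) if isinstance(v, list) else [v]


# ---------------------------------------------------------------------------
# Landscape
# ---------------------------------------------------------------------------


@dataclass
class Landscape:
    """Co-registered raster stack on a metric grid (row 0 at the origin)."""

    layers: dict
    origin: tuple[float, float] = (0.0, 0.0)
    resolution: float = 300.0

    def __post_init__(self):
        shapes = {v.shape for v in self.layers.values()}
        if len(shapes) > 1:
            raise ValueError(f"layers are not co-registered: shapes {shapes}")
        if "alan" in self.layers and np.any(self.layers["alan"] < 0):
            raise ValueError("ALAN radiance must be nonnegative")
        cover = [self.layers[c] for c in COVER_CLASSES if c in self.layers]
        if cover and np.any(sum(cover) > 1.0 + 1e-9):
            raise ValueError("cover proportions exceed 1 in some cells")

    @property
    def shape(self):
        return next(iter(self.layers.values())).shape

    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for name, arr in self.layers.items():
            np.savetxt(path / f"{name}.txt", arr, fmt="%.6g")
        meta = {"origin": list(self.origin), "resolution": self.resolution,
                "layers": list(self.layers)}
        (path / "landscape.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_dir(cls, path) -> "Landscape":
        path = Path(path)
        meta = json.loads((path / "landscape.json").read_text())
        layers = {name: np.atleast_2d(np.loadtxt(path / f"{name}.txt"))
                  for name in meta["layers"]}
        return cls(layers=layers, origin=tuple(meta["origin"]),
                   resolution=meta["resolution"])


def _station_layout(config: SimulationConfig) -> pd.DataFrame:
    """Roadside routes: straight transects of stations ~1.6 km apart.

    Shares its sub-seed with :func:`generate_landscape`'s correlation tuning so
    the tuned coupling applies to the delivered design.
    """
    rng = np.random.default_rng([int(config.seed), 1000])
    rows = []
    margin = config.resolution  # keep stations strictly inside the raster
    lo, hi = config.stations_per_route
    for route in range(config.n_routes):
        n_st = int(rng.integers(lo, hi + 1))
        for _ in range(400):
            x0 = rng.uniform(margin, config.extent - margin)
            y0 = rng.uniform(margin, config.extent - margin)
            theta = rng.uniform(0, 2 * np.pi)
            gaps = config.station_spacing * (
                1.0 + rng.uniform(-config.spacing_jitter, config.spacing_jitter,
                                  size=n_st - 1))
            d = np.concatenate([[0.0], np.cumsum(gaps)])
            xs = x0 + d * np.cos(theta)
            ys = y0 + d * np.sin(theta)
            if (xs.min() >= margin and xs.max() <= config.extent - margin
                    and ys.min() >= margin and ys.max() <= config.extent - margin):
                break
        else:
            need = (n_st - 1) * config.station_spacing * (1 + config.spacing_jitter)
            raise ValueError(
                f"landscape extent {config.extent:.0f} m cannot hold a route of "
                f"{n_st} stations (needs ~{need:.0f} m plus margins)")
        for i in range(n_st):
            rows.append({"station_id": f"R{route:02d}S{i:02d}",
                         "route_id": f"R{route:02d}",
                         "x": xs[i], "y": ys[i]})
    return pd.DataFrame(rows, columns=["station_id", "route_id", "x", "y"])


def _buffer_means_at(raster, stations, radius, config) -> np.ndarray:
    from .covariates import buffer_stats
    return np.array([
        buffer_stats(raster, (r.x, r.y), radius, (0.0, 0.0), config.resolution)[0]
        for r in stations.itertuples()
    ])


def _realize_fields(config: SimulationConfig, attempt: int):
    """One draw of the light sources, ALAN field, and urban-patch geometry."""
    n, res = config.n_cells, config.resolution
    rng = np.random.default_rng([int(config.seed), 1, attempt])
    direct = np.zeros((n, n))
    src_xy = rng.uniform(0, config.extent, size=(config.n_sources, 2))
    intens = rng.lognormal(config.source_intensity_log_mean,
                           config.source_intensity_log_sd, size=config.n_sources)
    for (sx, sy), w in zip(src_xy, intens):
        direct[min(int(sy / res), n - 1), min(int(sx / res), n - 1)] += w
    if config.n_sources > 0:
        spread = gaussian_filter(direct, sigma=1.0)
        skyglow = gaussian_filter(direct, sigma=config.skyglow_bandwidth / res)
        alan = spread + config.skyglow_strength * skyglow
    else:
        alan = direct

    # urban patches: the brightest sources seed the source-attached patches
    # (towns are both bright and large, so their footprint scales with
    # intensity); the remainder sit at random locations.  The mix between the
    # two, k, is the coupling knob tuned to the correlation target.
    P = config.n_urban_patches
    patch_rng = np.random.default_rng([int(config.seed), 2, attempt])
    rand_radius = patch_rng.lognormal(np.log(900.0), 0.4, size=P)
    rand_xy = patch_rng.uniform(0, config.extent, size=(P, 2))
    bright = np.argsort(-intens) if config.n_sources else np.array([], dtype=int)
    cx = (np.arange(n) + 0.5) * res
    XX, YY = np.meshgrid(cx, cx)

    def realize_urban(k: int) -> np.ndarray:
        urb = np.zeros((n, n))
        for p in range(P):
            if p < k and config.n_sources > 0:
                s = bright[p % config.n_sources]
                px, py = src_xy[s]
                peak = float(np.clip(0.3 + 0.2 * np.log1p(intens[s]), 0.0, 1.0))
                radius = float(np.clip(400.0 * np.log1p(intens[s]), 500.0, 4000.0))
            else:
                px, py = rand_xy[p]
                peak, radius = 0.5, rand_radius[p]
            d = np.hypot(XX - px, YY - py)
            urb = np.maximum(urb, peak * np.clip(1.0 - d / radius, 0, 1))
        return urb

    return alan, realize_urban


def generate_landscape(config: SimulationConfig) -> Landscape:
    """Point-source ALAN plus skyglow, with urban cover coupled to the lights.

    The direct field deposits each source's intensity in its cell (lightly
    blurred to the neighbouring cells); skyglow is a wide Gaussian blur of the
    same field.  Urban patches are seeded at the brightest light sources, and
    the number of source-seeded (vs randomly placed) patches is scanned so the
    realized station-level ALAN-urban Pearson correlation at the middle radius
    lands within ``corr_tol`` of the target; if a source layout cannot reach
    the target, the sources are redrawn a bounded number of times before the
    failure is reported.  Deterministic given the configured seed.
    """
    n, res = config.n_cells, config.resolution
    P = config.n_urban_patches
    mid = config.radii[len(config.radii) // 2]
    stations = _station_layout(config)
    max_redraws = 4

    urban = alan = None
    best_err = np.inf
    for attempt in range(max_redraws + 1):
        alan, realize_urban = _realize_fields(config, attempt)
        if config.n_sources == 0 or np.ptp(alan) == 0 or len(stations) < 3:
            urban = realize_urban(0)  # no light field (or no stations) to couple to
            break
        alan_b = _buffer_means_at(alan, stations, mid, config)

        def realized_r(k):
            urb_b = _buffer_means_at(realize_urban(k), stations, mid, config)
            if np.std(urb_b) == 0 or np.std(alan_b) == 0:
                return 0.0
            return float(np.corrcoef(alan_b, urb_b)[0, 1])

        ks = list(range(0, P + 1, max(1, P // 12)))
        errs = {k: abs(realized_r(k) - config.target_alan_urban_corr) for k in ks}
        best_k = min(errs, key=errs.get)
        for k in (best_k - 1, best_k + 1):
            if 0 <= k <= P and k not in errs:
                errs[k] = abs(realized_r(k) - config.target_alan_urban_corr)
        best_k = min(errs, key=errs.get)
        best_err = min(best_err, errs[best_k])
        if errs[best_k] <= config.corr_tol:
            urban = realize_urban(best_k)
            break
    if urban is None:
        raise RuntimeError(
            f"could not reach ALAN-urban correlation "
            f"{config.target_alan_urban_corr:+.2f} within {config.corr_tol} "
            f"after {max_redraws + 1} source redraws (best |error| {best_err:.2f})")

    # elevation: smooth random surface; slope from its gradient
    rng = np.random.default_rng([int(config.seed), 6])
    elev = gaussian_filter(rng.normal(size=(n, n)), sigma=8.0)
    elev = 500.0 + 900.0 * (elev - elev.min()) / np.ptp(elev)
    gy, gx = np.gradient(elev, res)
    slope = np.degrees(np.arctan(np.hypot(gx, gy)))

    # remaining cover split among the other classes via smooth random fields
    other = {}
    wfields = [np.exp(gaussian_filter(rng.normal(size=(n, n)), sigma=5.0))
               for _ in COVER_CLASSES[1:]]
    wsum = np.sum(wfields, axis=0)
    budget = 0.9 * (1.0 - urban)
    for name, f in zip(COVER_CLASSES[1:], wfields):
        other[name] = budget * f / wsum

    layers = {"alan": alan, "urban": urban, **other,
              "elevation": elev, "slope": slope}
    return Landscape(layers=layers, origin=(0.0, 0.0), resolution=res)


def generate_survey_design(landscape: Landscape, config: SimulationConfig) -> pd.DataFrame:
    """Station/route table for the landscape (deterministic given the seed)."""
    if landscape.shape[0] * landscape.resolution < config.extent - 1e-6:
        raise ValueError("landscape extent is smaller than the configured study area")
    return _station_layout(config)


def generate_surveys(stations: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """One row per survey with temporal covariates.

    Sun angle is drawn uniformly over the crepuscular window [-9, +2] degrees,
    day of year uniformly over June-July, lunar illumination uniformly [0, 1].
    """
    rng = np.random.default_rng([int(config.seed), 3])
    rows = []
    for year in range(config.years):
        for _, st in stations.iterrows():
            for s in range(config.surveys_per_station):
                rows.append({
                    "station_id": st["station_id"], "route_id": st["route_id"],
                    "year": 2014 + year, "survey_idx": s,
                    "sun_angle": rng.uniform(-9.0, 2.0),
                    "day_of_year": rng.uniform(152, 212),
                    "lunar": rng.uniform(0.0, 1.0),
                })
    cols = ["station_id", "route_id", "year", "survey_idx",
            "sun_angle", "day_of_year", "lunar"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------


def _linear_predictor(design: MultiScaleDesign, truth: TrueParameters) -> np.ndarray:
    df = design.df
    eta = np.full(len(df), truth.intercept)

    def add(term, beta, col):
        x = np.asarray(df[col], dtype=float)
        if not np.all(np.isfinite(x * beta)):
            raise FloatingPointError(f"non-finite contribution from covariate {term!r}")
        return beta * x

    for cov in truth.coefficients:
        for beta, radius in truth.pairs(cov):
            if int(radius) not in design.radii:
                raise ValueError(
                    f"acting scale {radius} for {cov!r} not in design radii {design.radii}")
            eta += add(cov, beta, design.column(cov, radius))
    if truth.interaction is not None:
        beta, ra, rb = truth.interaction
        ca, cb = truth.interaction_covs
        for r in (ra, rb):
            if int(r) not in design.radii:
                raise ValueError(f"interaction scale {r} not in design radii")
        x = (np.asarray(df[design.column(ca, ra)], dtype=float)
             * np.asarray(df[design.column(cb, rb)], dtype=float))
        if not np.all(np.isfinite(beta * x)):
            raise FloatingPointError("non-finite contribution from the interaction term")
        eta += beta * x
    for col, beta in {**truth.temporal, **truth.geographic}.items():
        eta += add(col, beta, col)
    return eta


def simulate_counts(design: MultiScaleDesign, truth: TrueParameters,
                    seed: int) -> pd.DataFrame:
    """Negative-binomial counts from the standardized design at the true scales.

    Returns the design rows with ``true_count`` (and the latent mean ``mu``)
    attached.  With ``zero_inflation > 0`` a structural zero replaces the NB
    draw with that probability.  A nonzero prior-count coefficient makes the
    simulation sequential: surveys are ordered in time and the prior mean
    count at the station (natural units) feeds back into the linear predictor.
    """
    if not design.standardized:
        raise ValueError("simulate_counts requires the standardized design")
    rng = np.random.default_rng(seed)
    eta = _linear_predictor(design, truth)
    k = truth.dispersion
    out = design.df.copy()

    if truth.prior_count_coef == 0.0:
        mu = np.exp(eta)
        counts = rng.negative_binomial(k, k / (k + mu))
    else:
        order = out.sort_values(["year", "survey_idx"], kind="stable").index
        counts = np.zeros(len(out), dtype=int)
        mu = np.zeros(len(out))
        hist_rows = []
        hist = pd.DataFrame(columns=["station_id", "year", "survey_idx", "count"])
        for idx in order:
            row = out.loc[idx]
            prior = prior_mean_count(hist, row["station_id"],
                                     int(row["year"]), int(row["survey_idx"]))
            m = np.exp(eta[out.index.get_loc(idx)] + truth.prior_count_coef * prior)
            c = rng.negative_binomial(k, k / (k + m))
            mu[out.index.get_loc(idx)] = m
            counts[out.index.get_loc(idx)] = c
            hist_rows.append({"station_id": row["station_id"], "year": int(row["year"]),
                              "survey_idx": int(row["survey_idx"]), "count": int(c)})
            hist = pd.DataFrame(hist_rows)
    if truth.zero_inflation > 0.0:
        counts = np.where(rng.uniform(size=len(out)) < truth.zero_inflation, 0, counts)
    out["mu"] = mu
    out["true_count"] = counts
    return out


# ---------------------------------------------------------------------------
# Detection histories
# ---------------------------------------------------------------------------


def simulate_detection_histories(table: pd.DataFrame, truth: TrueParameters,
                                 seed: int) -> pd.DataFrame:
    """Six-interval Bernoulli detection histories for each present individual.

    ``logit(p_min) = detection_intercept + sum(slope * column)`` with survey-
    level covariates, so all individuals in a survey share ``p_min``.  The
    observed count is the number of individuals detected in at least one
    minute; histories are stored as 6-character 0/1 strings joined by ";".
    """
    rng = np.random.default_rng(seed)
    z = np.full(len(table), truth.detection_intercept)
    for col, slope in truth.detection_slopes.items():
        z += slope * np.asarray(table[col], dtype=float)
    p_min = expit(z)
    out = table.copy()
    histories, observed, minutes = [], [], []
    for i, t in enumerate(np.asarray(table["true_count"], dtype=int)):
        if t == 0:
            histories.append("")
            observed.append(0)
            minutes.append(0)
            continue
        slots = rng.uniform(size=(t, 6)) < p_min[i]
        seen = slots.any(axis=1)
        histories.append(";".join(
            "".join("1" if s else "0" for s in ind) for ind in slots[seen]))
        observed.append(int(seen.sum()))
        minutes.append(int(slots.sum()))
    out["p_min"] = p_min
    out["histories"] = histories
    out["observed_count"] = observed
    out["minutes_detected_total"] = minutes
    return out


def write_survey_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Fast calibration-grade design generator
# ---------------------------------------------------------------------------


def make_multiscale_design(n: int, radii=DEFAULT_RADII, inter_scale_corr: float = 0.6,
                           covs=("alan",), cross_corr: float = 0.0,
                           fixed_covs=("fix1", "fix2"), seed: int = 0) -> MultiScaleDesign:
    """Draw a standardized multi-scale design directly from a Gaussian model.

    Columns for the same covariate at different radii share pairwise
    correlation ``inter_scale_corr``; columns of different covariates share
    ``cross_corr``.  Fixed-scale covariates are independent standard normals.
    This bypasses the raster pipeline for studies of the samplers themselves,
    where only the correlation structure matters.
    """
    rng = np.random.default_rng(seed)
    radii = tuple(int(r) for r in radii)
    K, C = len(radii), len(covs)
    dim = K * C
    sigma = np.full((dim, dim), cross_corr)
    for c in range(C):
        block = slice(c * K, (c + 1) * K)
        sigma[block, block] = inter_scale_corr
    np.fill_diagonal(sigma, 1.0)
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as e:
        raise ValueError("requested correlation structure is not positive definite") from e
    z = rng.normal(size=(n, dim)) @ chol.T
    df = pd.DataFrame({"station_id": [f"S{i:04d}" for i in range(n)],
                       "route_id": "R00", "year": 2014, "survey_idx": 0})
    scaling = {}
    for c, cov in enumerate(covs):
        for j, r in enumerate(radii):
            col = f"{cov}_{r}"
            x = z[:, c * K + j]
            m, s = float(x.mean()), float(x.std())
            df[col] = (x - m) / s
            scaling[col] = (m, s)
    for fc in fixed_covs:
        x = rng.normal(size=n)
        m, s = float(x.mean()), float(x.std())
        df[fc] = (x - m) / s
        scaling[fc] = (m, s)
    return MultiScaleDesign(
        df=df, radii=radii, landscape_covs=tuple(covs), fixed_covs=tuple(fixed_covs),
        quad_pairs=(), scaling=scaling, standardized=True,
    )


# ---------------------------------------------------------------------------
# End-to-end convenience
# ---------------------------------------------------------------------------


@dataclass
class StudyBundle:
    landscape: Landscape
    stations: pd.DataFrame
    design: MultiScaleDesign     # standardized, with counts attached
    table: pd.DataFrame          # survey table incl. detection histories


def attach_prior_count(design: MultiScaleDesign, counts) -> MultiScaleDesign:
    """Compute the prior-count covariate from realized counts and standardize it."""
    from dataclasses import replace

    df = design.df.copy()
    df["count"] = np.asarray(counts, dtype=int)
    hist = df[["station_id", "year", "survey_idx", "count"]]
    prior = np.array([
        prior_mean_count(hist, r.station_id, int(r.year), int(r.survey_idx))
        for r in df.itertuples()
    ])
    scaling = dict(design.scaling)
    fixed = design.fixed_covs
    if prior.std() > 0:
        m, s = float(prior.mean()), float(prior.std())
        df["prior_count"] = (prior - m) / s
        scaling["prior_count"] = (m, s)
        if "prior_count" not in fixed:
            fixed = (*fixed, "prior_count")
    return replace(design, df=df, scaling=scaling, fixed_covs=fixed)


def simulate_study(config: SimulationConfig, truth: TrueParameters,
                   seed: int | None = None) -> StudyBundle:
    """Landscape -> design -> counts -> detection histories, end to end."""
    seed = config.seed if seed is None else seed
    landscape = generate_landscape(config)
    stations = generate_survey_design(landscape, config)
    surveys = generate_surveys(stations, config)
    design = build_design(landscape, stations, surveys, radii=config.radii,
                          include_prior_count=False)
    design = design.standardize()
    simulated = simulate_counts(design, truth, seed=np.random.default_rng(
        [int(seed), 4]).integers(2 ** 31))
    table = simulate_detection_histories(simulated, truth, seed=np.random.default_rng(
        [int(seed), 5]).integers(2 ** 31))
    design = attach_prior_count(design, table["true_count"])
    design.df["count"] = np.asarray(table["observed_count"], dtype=int)
    return StudyBundle(landscape=landscape, stations=stations,
                       design=design, table=table)
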