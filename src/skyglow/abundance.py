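"""Final fixed-scale abundance model and its derived quantities.

Once the scale of effect of each landscape covariate has been selected, the
relative-abundance model is an ordinary negative-binomial regression on the
standardized design, fit by MCMC.  This module builds that design (including
dual-scale covariates and the ALAN x urban interaction column), runs the fit,
and computes everything reported from it:

* posterior prediction curves of expected count over an ALAN gradient at a
  fixed urban-cover level, with the grid capped at the conditional 99th
  percentile of ALAN so curves are never read beyond the data's support;
* percent change in expected count between two ALAN values (negative =
  decline), summarized over posterior draws;
* the interaction sign-switch threshold: the urban proportion at which the
  marginal effect of ALAN changes sign, ``u* = -beta_ALAN / beta_int``
  mapped back to natural units;
* posterior correlations between coefficients (a multicollinearity check);
* the post-hoc refits — dropping named stations, and entering one covariate
  at two scales simultaneously (optionally on a filtered survey subset).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .covariates import MultiScaleDesign
from .mcmc import ChainConfig, DICResult, ModelSpec, PosteriorSamples, compute_dic, run_mcmc

logger = logging.getLogger("skyglow")


class MissingTermError(KeyError):
    """A derived quantity needs a model term the fit does not contain."""


@dataclass
class AbundanceFit:
    """Posterior for the final model plus the design needed to use it."""

    samples: PosteriorSamples
    spec: ModelSpec
    design: MultiScaleDesign
    term_cols: dict                  # model term -> design column (or pair, for products)
    dic: DICResult | None = None

    def coef(self, term: str) -> np.ndarray:
        return self.samples.get(term)

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in self.samples.names:
            d = self.samples.get(name)
            rows.append({"param": name, "mean": d.mean(), "sd": d.std(),
                         "lo95": np.quantile(d, 0.025), "hi95": np.quantile(d, 0.975)})
        return pd.DataFrame(rows).set_index("param")


def _resolve_scales(design: MultiScaleDesign, scales: dict) -> dict:
    out = {}
    for cov, r in scales.items():
        rs = list(r) if isinstance(r, (list, tuple)) else [r]
        for radius in rs:
            if int(radius) not in design.radii:
                raise ValueError(f"scale {radius} for {cov!r} not in design radii")
        out[cov] = [int(x) for x in rs]
    return out


def fit_final(design: MultiScaleDesign, scales: dict, cfg: ChainConfig,
              interaction: tuple | None = ("alan", "urban"),
              interaction_scales: tuple[int, int] | None = None,
              family: str = "negbin", priors: dict | None = None,
              compute_dic_flag: bool = True) -> AbundanceFit:
    """Fit the abundance model with every covariate at its selected scale(s).

    ``scales`` maps landscape covariate -> radius, or a pair of radii for a
    dual-scale covariate (two separate columns).  ``interaction_scales`` gives
    the (possibly different) selected scales of the two interaction parents;
    the product column is built from the standardized parent columns.
    """
    if not design.standardized:
        raise ValueError("fit_final requires a standardized design")
    scales = _resolve_scales(design, scales)
    df = design.df.copy()
    terms, term_cols = [], {}
    for cov, rs in scales.items():
        if len(rs) != len(set(rs)):
            raise ValueError(f"duplicate scale for {cov!r}: same covariate, same radius twice")
        for radius in rs:
            col = design.column(cov, radius)
            term = f"{cov}@{radius}" if len(rs) > 1 else cov
            terms.append(term)
            term_cols[term] = col
            df[term] = df[col]
    if interaction is not None:
        ca, cb = interaction
        if interaction_scales is None:
            ra = scales[ca][0]
            rb = scales[cb][0]
        else:
            ra, rb = interaction_scales
        name = f"{ca}:{cb}"
        df[name] = (np.asarray(df[design.column(ca, ra)], dtype=float)
                    * np.asarray(df[design.column(cb, rb)], dtype=float))
        terms.append(name)
        term_cols[name] = (design.column(ca, ra), design.column(cb, rb))
    terms += list(design.fixed_covs)
    for t in design.fixed_covs:
        term_cols[t] = t
    spec = ModelSpec(family=family, terms=tuple(terms),
                     priors=priors or {})
    y = np.asarray(df[design.response])
    samples = run_mcmc(spec, df, y, cfg)
    dic = compute_dic(samples, spec, df, y) if compute_dic_flag else None
    fit_design = replace(design, df=df)
    return AbundanceFit(samples=samples, spec=spec, design=fit_design,
                        term_cols=term_cols, dic=dic)


# ---------------------------------------------------------------------------
# Prediction support
# ---------------------------------------------------------------------------


def nearest_rank_percentile(values, q: float) -> float:
    """Nearest-rank quantile: the ceil(q*n)-th order statistic."""
    v = np.sort(np.asarray(values, dtype=float))
    if len(v) == 0:
        raise ValueError("empty sample")
    rank = int(np.ceil(q * len(v)))
    return float(v[min(max(rank, 1), len(v)) - 1])


def alan_cap(design: MultiScaleDesign, urban_level: float, scale: int,
             alan_cov: str = "alan", urban_cov: str = "urban",
             urban_scale: int | None = None, q: float = 0.99) -> float:
    """Conditional ALAN cap: the empirical ``q`` percentile of natural-unit
    ALAN over surveys whose urban cover is at or below ``urban_level``.

    Keeps prediction curves inside the range of ALAN values that actually
    occur at the referenced urbanization level.
    """
    urban_scale = scale if urban_scale is None else urban_scale
    acol = design.column(alan_cov, scale)
    ucol = design.column(urban_cov, urban_scale)
    alan_nat = design.to_natural(acol, design.df[acol])
    urban_nat = design.to_natural(ucol, design.df[ucol])
    mask = urban_nat <= urban_level + 1e-12
    if mask.sum() < 10:
        raise ValueError(
            f"only {int(mask.sum())} surveys with urban <= {urban_level}; need >= 10")
    return nearest_rank_percentile(alan_nat[mask], q)


@dataclass
class PredictionSummary:
    """Expected-count curve over an ALAN gradient at one urban level."""

    curve: pd.DataFrame          # columns alan, mean, lo95, hi95
    urban_level: float
    alan_term: str
    percent_change: "PercentChange | None" = None

    def __post_init__(self):
        c = self.curve
        if np.any(c["mean"] <= 0):
            raise ValueError("expected counts must be positive")
        tol = 1e-12 * np.maximum(1.0, np.abs(c["mean"]))
        if np.any(c["lo95"] > c["mean"] + tol) or np.any(c["mean"] > c["hi95"] + tol):
            raise ValueError("credible bounds must bracket the mean pointwise")


def _eta_draws(fit: AbundanceFit, alan_values, urban_level,
               alan_term: str = "alan", urban_term: str = "urban"):
    """Linear-predictor draws over an ALAN grid, other covariates at their
    (standardized) means, i.e. zero."""
    if alan_term not in fit.samples.names:
        raise MissingTermError(f"fit has no term {alan_term!r}")
    acol = fit.term_cols[alan_term]
    za = fit.design.to_standardized(acol, np.asarray(alan_values, dtype=float))
    eta = fit.samples.get("intercept")[:, None] \
        + np.outer(fit.coef(alan_term), za)
    int_name = f"{alan_term}:{urban_term}"
    if urban_term in fit.samples.names or int_name in fit.samples.names:
        ucol = fit.term_cols.get(urban_term, None)
        if ucol is None and int_name in fit.samples.names:
            ucol = fit.term_cols[int_name][1]
        zu = float(fit.design.to_standardized(ucol, urban_level))
        if urban_term in fit.samples.names:
            eta += fit.coef(urban_term)[:, None] * zu
        if int_name in fit.samples.names:
            # the interaction may use its own parent scales
            ia_col, iu_col = fit.term_cols[int_name]
            za_int = fit.design.to_standardized(ia_col, np.asarray(alan_values, dtype=float))
            zu_int = float(fit.design.to_standardized(iu_col, urban_level))
            eta += fit.coef(int_name)[:, None] * (za_int * zu_int)
    return eta


def predict_curve(fit: AbundanceFit, alan_grid, urban_level: float,
                  alan_term: str = "alan", urban_term: str = "urban",
                  cap: float | None = None, force: bool = False) -> PredictionSummary:
    """Posterior mean and 95% CI of the expected count along an ALAN gradient.

    Non-focal covariates sit at their standardized means (zero).  If ``cap``
    is given, grid points beyond it are rejected unless ``force``.
    """
    alan_grid = np.asarray(alan_grid, dtype=float)
    if cap is not None and not force and np.any(alan_grid > cap + 1e-9):
        raise ValueError(f"ALAN grid exceeds the conditional cap {cap:.3g}; "
                         "pass force=True to override")
    eta = _eta_draws(fit, alan_grid, urban_level, alan_term, urban_term)
    mu = np.exp(eta)
    if fit.spec.family == "zip":
        mu = mu * (1.0 - fit.samples.get("pi")[:, None])
    curve = pd.DataFrame({
        "alan": alan_grid,
        "mean": mu.mean(axis=0),
        "lo95": np.quantile(mu, 0.025, axis=0),
        "hi95": np.quantile(mu, 0.975, axis=0),
    })
    return PredictionSummary(curve=curve, urban_level=urban_level, alan_term=alan_term)


@dataclass
class PercentChange:
    mean: float
    lo95: float
    hi95: float
    draws: np.ndarray

    def __str__(self):
        return f"{self.mean:+.1f}% ({self.lo95:+.1f}%, {self.hi95:+.1f}%)"


def percent_change(fit: AbundanceFit, alan0: float, alan1: float,
                   urban_level: float, alan_term: str = "alan",
                   urban_term: str = "urban") -> PercentChange:
    """Percent change in expected count as ALAN moves ``alan0 -> alan1``.

    Computed per posterior draw as ``100 * (E[y|alan1] / E[y|alan0] - 1)`` and
    summarized by the across-draw mean and 2.5/97.5 percentiles; negative
    values are declines.  Because the ratio cancels everything not involving
    ALAN, the result is invariant to the standardization constants and to the
    level of the remaining covariates.
    """
    eta = _eta_draws(fit, [alan0, alan1], urban_level, alan_term, urban_term)
    ratio = np.exp(eta[:, 1] - eta[:, 0])
    pc = 100.0 * (ratio - 1.0)
    return PercentChange(mean=float(pc.mean()), lo95=float(np.quantile(pc, 0.025)),
                         hi95=float(np.quantile(pc, 0.975)), draws=pc)


@dataclass
class SignSwitch:
    mean: float
    lo95: float
    hi95: float
    draws: np.ndarray            # unclipped natural-unit thresholds
    clipped: tuple[float, float, float]   # report values clipped to [0, 1]


def sign_switch(fit: AbundanceFit, alan_term: str = "alan",
                urban_term: str = "urban") -> SignSwitch:
    """Urban proportion at which the marginal ALAN effect changes sign.

    Per draw, ``d eta / d alan = 0`` at the standardized urban level
    ``-beta_alan / beta_int``, mapped to a natural proportion through the
    urban column's standardization constants.  Draws whose interaction sign
    admits no switch inside [0, 1] are retained untruncated; the percentile
    CI absorbs them.  The clipped triple is for reporting on the proportion
    scale.
    """
    int_name = f"{alan_term}:{urban_term}"
    if int_name not in fit.samples.names:
        raise MissingTermError(
            f"fit has no interaction term {int_name!r}; no sign switch exists")
    beta_a = fit.coef(alan_term)
    beta_i = fit.coef(int_name)
    zu_star = -beta_a / beta_i
    ucol = fit.term_cols[int_name][1]
    u_star = fit.design.to_natural(ucol, zu_star)
    mean = float(u_star.mean())
    lo, hi = float(np.quantile(u_star, 0.025)), float(np.quantile(u_star, 0.975))
    clip = tuple(float(np.clip(v, 0.0, 1.0)) for v in (mean, lo, hi))
    return SignSwitch(mean=mean, lo95=lo, hi95=hi, draws=u_star, clipped=clip)


def posterior_coef_correlation(fit: AbundanceFit, pairs) -> dict:
    """Pearson correlation of coefficient draws for each named pair.

    |r| > 0.9 logs a multicollinearity advisory: the model cannot separate the
    two effects, and dropping one term (as done for the interaction in poorly
    identified fits) should be considered.
    """
    out = {}
    for a, b in pairs:
        da, db = fit.samples.get(a), fit.samples.get(b)
        r = float(np.corrcoef(da, db)[0, 1])
        out[(a, b)] = r
        if abs(r) > 0.9:
            logger.warning(
                "posterior correlation r=%.2f between %r and %r: "
                "multicollinearity advisory — consider dropping one term", r, a, b)
    return out


# ---------------------------------------------------------------------------
# Post-hoc refits
# ---------------------------------------------------------------------------


@dataclass
class RefitComparison:
    fit: AbundanceFit
    deltas: pd.DataFrame     # per-term mean before/after, delta, CI-overlap flags


def _compare(before: AbundanceFit, after: AbundanceFit) -> pd.DataFrame:
    rows = []
    for name in before.samples.names:
        if name not in after.samples.names:
            continue
        b, a = before.samples.get(name), after.samples.get(name)
        lo_b, hi_b = np.quantile(b, [0.025, 0.975])
        lo_a, hi_a = np.quantile(a, [0.025, 0.975])
        rows.append({
            "param": name, "mean_before": b.mean(), "mean_after": a.mean(),
            "delta": a.mean() - b.mean(),
            "sd_before": b.std(), "sd_after": a.std(),
            "ci_overlaps_zero_before": bool(lo_b <= 0 <= hi_b),
            "ci_overlaps_zero_after": bool(lo_a <= 0 <= hi_a),
        })
    return pd.DataFrame(rows).set_index("param")


def drop_stations_refit(fit: AbundanceFit, station_ids, cfg: ChainConfig) -> RefitComparison:
    """Refit after removing all surveys at the named stations.

    Used to check whether a coefficient is carried by a small cluster of
    heavily surveyed stations (e.g. a handful of stations on a city's
    outskirts dominating the high-urban tail).
    """
    design = fit.design
    mask = ~design.df["station_id"].isin(list(station_ids))
    if not mask.any():
        raise ValueError("removing these stations leaves no surveys")
    sub_design = replace(design, df=design.df.loc[mask].reset_index(drop=True))
    y = np.asarray(sub_design.df[design.response])
    samples = run_mcmc(fit.spec, sub_design.df, y, cfg)
    refit = AbundanceFit(samples=samples, spec=fit.spec, design=sub_design,
                         term_cols=fit.term_cols,
                         dic=compute_dic(samples, fit.spec, sub_design.df, y))
    return RefitComparison(fit=refit, deltas=_compare(fit, refit))


def dual_scale_marginal(design: MultiScaleDesign, covariate: str,
                        scales: tuple[int, int], cfg: ChainConfig,
                        other_scales: dict | None = None,
                        interaction: tuple | None = None,
                        filter_predicate=None, family: str = "negbin") -> AbundanceFit:
    """Fit with one covariate entered at two scales simultaneously.

    ``filter_predicate`` (row-wise boolean function of the design frame)
    optionally restricts the surveys first — e.g. keeping only stations with
    no light within the intermediate buffer, to probe the marginal effect of
    landscape-scale light in otherwise-dark places.
    """
    if filter_predicate is not None:
        mask = np.asarray(filter_predicate(design.df), dtype=bool)
        if not mask.any():
            raise ValueError("filter predicate removes every survey")
        design = replace(design, df=design.df.loc[mask].reset_index(drop=True))
    all_scales = dict(other_scales or {})
    all_scales[covariate] = list(scales)
    return fit_final(design, all_scales, cfg, interaction=interaction, family=family)
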