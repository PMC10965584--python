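"""Likelihoods, samplers, and model-comparison utilities for count models.

This module is the numerical engine shared by the scale-selection sampler
(:mod:`skyglow.bliss`) and the final abundance model (:mod:`skyglow.abundance`).
It provides:

* per-observation log-likelihoods for Poisson, negative-binomial (NB), and
  zero-inflated-Poisson (ZIP) count regressions with a log link;
* an adaptive random-walk Metropolis-within-Gibbs sampler (``run_mcmc``);
* the deviance information criterion (``compute_dic``) and split-chain
  potential scale reduction (``rhat``);
* maximum-likelihood GLM helpers (``fit_glm_ml``) and an all-subsets AIC
  search (``dredge``) used for the preliminary geographic-covariate screen.

The negative binomial is parameterised throughout by its mean ``mu`` and
dispersion (size) ``k``, so that ``Var[y] = mu + mu**2 / k`` and the Poisson
model is recovered as ``k -> inf``.  The ZIP mass function is
``pi * 1[y == 0] + (1 - pi) * Poisson(y; mu)``.

Default priors (all configurable through :class:`ModelSpec`): Normal(0, 2.5^2)
on coefficients of standardized covariates, Gamma(0.1, 0.1) on the NB
dispersion, Uniform(0, 1) on the ZIP inflation probability.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

logger = logging.getLogger("skyglow")

FAMILIES = ("poisson", "negbin", "zip")

DEFAULT_PRIORS = {
    "beta_sd": 2.5,       # sd of the Normal prior on coefficients
    "k_shape": 0.1,       # Gamma prior on NB dispersion k
    "k_rate": 0.1,
}

# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------


@dataclass
class ModelSpec:
    """A count-regression specification: likelihood family, terms, priors.

    ``terms`` are column names of the design table; an intercept is always
    included and must not be listed.  Interaction columns are ordinary
    (pre-computed product) columns.
    """

    family: str
    terms: tuple[str, ...] = ()
    priors: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        self.terms = tuple(self.terms)
        merged = dict(DEFAULT_PRIORS)
        merged.update(self.priors)
        self.priors = merged

    @property
    def param_names(self) -> list[str]:
        names = ["intercept", *self.terms]
        if self.family == "negbin":
            names.append("k")
        elif self.family == "zip":
            names.append("pi")
        return names


@dataclass
class ChainConfig:
    """MCMC run settings.

    Defaults mirror the full-length runs used for final inference: 3 chains of
    12,000 iterations with 3,000 discarded as burn-in, retaining all remaining
    draws without thinning (27,000 joint-posterior samples).
    """

    chains: int = 3
    iterations: int = 12_000
    burn_in: int = 3_000
    seed: int = 0
    adapt_window: int = 50

    def __post_init__(self):
        if not 0 <= self.burn_in < self.iterations:
            raise ValueError("burn_in must satisfy 0 <= burn_in < iterations")
        if self.chains < 1:
            raise ValueError("need at least one chain")

    @property
    def retained(self) -> int:
        return self.chains * (self.iterations - self.burn_in)


@dataclass
class PosteriorSamples:
    """Retained MCMC draws: a (draws x parameters) matrix plus bookkeeping."""

    draws: np.ndarray
    names: list[str]
    loglik: np.ndarray          # per-draw total log-likelihood
    chain: np.ndarray           # chain label per draw
    accept_rates: dict = field(default_factory=dict)

    def __post_init__(self):
        if not np.all(np.isfinite(self.draws)):
            raise ValueError("non-finite entries in posterior draws")

    def get(self, name: str) -> np.ndarray:
        try:
            j = self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown parameter {name!r}") from None
        return self.draws[:, j]

    def mean(self) -> pd.Series:
        return pd.Series(self.draws.mean(axis=0), index=self.names)

    def interval(self, name: str, level: float = 0.95) -> tuple[float, float]:
        a = (1.0 - level) / 2.0
        x = self.get(name)
        return float(np.quantile(x, a)), float(np.quantile(x, 1.0 - a))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.draws, columns=self.names)
        df["chain"] = self.chain
        return df

    def save(self, prefix: str) -> None:
        import json
        from pathlib import Path

        prefix = Path(prefix)
        self.to_frame().to_csv(prefix.with_suffix(".draws.csv"), index=False)
        meta = {"names": self.names, "accept_rates": self.accept_rates}
        prefix.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))


# ---------------------------------------------------------------------------
# Log-likelihoods
# ---------------------------------------------------------------------------


def _poisson_ll(y, eta):
    return y * eta - np.exp(eta) - gammaln(y + 1.0)


def _negbin_ll(y, eta, k):
    if k <= 0:
        raise ValueError("NB dispersion k must be > 0")
    mu = np.exp(eta)
    return (
        gammaln(y + k) - gammaln(k) - gammaln(y + 1.0)
        + k * np.log(k) + y * eta - (y + k) * np.log(k + mu)
    )


def _zip_ll(y, eta, pi):
    if not 0.0 <= pi < 1.0:
        raise ValueError("ZIP inflation pi must lie in [0, 1)")
    mu = np.exp(eta)
    pois = y * eta - mu - gammaln(y + 1.0)
    if pi == 0.0:
        return pois
    out = np.log1p(-pi) + pois
    zero = y == 0
    if np.any(zero):
        out = np.where(zero, np.logaddexp(np.log(pi), np.log1p(-pi) - mu), out)
    return out


def build_design_matrix(spec: ModelSpec, design: pd.DataFrame) -> np.ndarray:
    """Intercept-first dense design matrix for ``spec.terms``."""
    missing = [t for t in spec.terms if t not in design.columns]
    if missing:
        raise KeyError(f"terms not found in design: {missing}")
    n = len(design)
    X = np.empty((n, 1 + len(spec.terms)))
    X[:, 0] = 1.0
    for j, t in enumerate(spec.terms, start=1):
        X[:, j] = np.asarray(design[t], dtype=float)
    return X


def loglik(spec: ModelSpec, params: dict, design: pd.DataFrame, y) -> np.ndarray:
    """Per-observation log-likelihood at ``params``.

    ``params`` holds ``"beta"`` (intercept first, aligned with ``spec.terms``)
    plus ``"k"`` (negbin) or ``"pi"`` (zip).
    """
    y = np.asarray(y, dtype=float)
    X = build_design_matrix(spec, design)
    beta = np.asarray(params["beta"], dtype=float)
    if beta.shape != (X.shape[1],):
        raise ValueError(f"beta has shape {beta.shape}, expected ({X.shape[1]},)")
    eta = X @ beta
    if spec.family == "poisson":
        ll = _poisson_ll(y, eta)
    elif spec.family == "negbin":
        ll = _negbin_ll(y, eta, float(params["k"]))
    else:
        ll = _zip_ll(y, eta, float(params["pi"]))
    if not np.all(np.isfinite(ll)):
        raise FloatingPointError("non-finite log-likelihood contribution")
    return ll


def _total_ll(family, y, eta, k, pi):
    if family == "poisson":
        return float(np.sum(_poisson_ll(y, eta)))
    if family == "negbin":
        return float(np.sum(_negbin_ll(y, eta, k)))
    return float(np.sum(_zip_ll(y, eta, pi)))


# ---------------------------------------------------------------------------
# Sampler
# ---------------------------------------------------------------------------


def run_mcmc(spec: ModelSpec, design: pd.DataFrame, y, cfg: ChainConfig) -> PosteriorSamples:
    """Adaptive random-walk Metropolis-within-Gibbs sampler.

    Coefficients are updated one at a time with scalar Gaussian proposals whose
    step sizes adapt toward a 25-40% acceptance rate during burn-in only; the
    NB dispersion (ZIP inflation) is updated on the log (logit) scale.  The
    linear predictor is maintained incrementally, so each update costs one
    O(n) likelihood evaluation.  Draw accounting is exact:
    ``chains * (iterations - burn_in)`` rows are retained, unthinned.
    """
    y = np.asarray(y)
    if np.any(y < 0) or not np.allclose(y, np.round(y)):
        raise ValueError("y must be nonnegative integers")
    y = y.astype(float)
    X = build_design_matrix(spec, design)
    n, p = X.shape
    fam = spec.family
    beta_sd = float(spec.priors["beta_sd"])
    k_shape = float(spec.priors["k_shape"])
    k_rate = float(spec.priors["k_rate"])

    n_extra = 1 if fam in ("negbin", "zip") else 0
    keep = cfg.iterations - cfg.burn_in
    all_draws = np.empty((cfg.retained, p + n_extra))
    all_ll = np.empty(cfg.retained)
    all_chain = np.empty(cfg.retained, dtype=int)
    acc_report = {}

    for c in range(cfg.chains):
        rng = np.random.default_rng([int(cfg.seed), c])
        beta = np.zeros(p)
        beta[0] = np.log(max(y.mean(), 0.05))
        k, pi = 1.0, 0.05
        eta = X @ beta
        ll = _total_ll(fam, y, eta, k, pi)
        step = np.full(p, 0.1)
        step_aux = 0.4
        acc = np.zeros(p + 1)
        tries = np.zeros(p + 1)
        total_acc = np.zeros(p + 1)
        total_tries = np.zeros(p + 1)

        for it in range(cfg.iterations):
            for j in range(p):
                prop = rng.normal(0.0, step[j])
                eta_new = eta + prop * X[:, j]
                b_new = beta[j] + prop
                ll_new = _total_ll(fam, y, eta_new, k, pi)
                logr = ll_new - ll + (beta[j] ** 2 - b_new ** 2) / (2.0 * beta_sd ** 2)
                tries[j] += 1
                if np.log(rng.uniform()) < logr:
                    beta[j], eta, ll = b_new, eta_new, ll_new
                    acc[j] += 1
            if fam == "negbin":
                lk_new = np.log(k) + rng.normal(0.0, step_aux)
                k_new = np.exp(lk_new)
                ll_new = _total_ll(fam, y, eta, k_new, pi)
                # Gamma(a, b) prior on k plus log-scale Jacobian -> a*log k - b*k
                logr = (ll_new - ll
                        + k_shape * (lk_new - np.log(k)) - k_rate * (k_new - k))
                tries[p] += 1
                if np.log(rng.uniform()) < logr:
                    k, ll = k_new, ll_new
                    acc[p] += 1
            elif fam == "zip":
                z_new = np.log(pi / (1 - pi)) + rng.normal(0.0, step_aux)
                pi_new = float(expit(z_new))
                ll_new = _total_ll(fam, y, eta, k, pi_new)
                # Uniform(0,1) prior with logit-scale Jacobian pi(1-pi)
                logr = (ll_new - ll
                        + np.log(pi_new * (1 - pi_new)) - np.log(pi * (1 - pi)))
                tries[p] += 1
                if np.log(rng.uniform()) < logr:
                    pi, ll = pi_new, ll_new
                    acc[p] += 1

            in_burn = it < cfg.burn_in
            if in_burn and (it + 1) % cfg.adapt_window == 0:
                rate = np.divide(acc, tries, out=np.zeros_like(acc), where=tries > 0)
                adj = np.exp(np.clip(rate - 0.3, -0.3, 0.3))
                step = np.clip(step * adj[:p], 1e-5, 10.0)
                if n_extra:
                    step_aux = float(np.clip(step_aux * adj[p], 1e-5, 10.0))
                acc[:] = 0
                tries[:] = 0
            if not in_burn:
                total_acc += acc
                total_tries += tries
                row = c * keep + (it - cfg.burn_in)
                all_draws[row, :p] = beta
                if fam == "negbin":
                    all_draws[row, p] = k
                elif fam == "zip":
                    all_draws[row, p] = pi
                all_ll[row] = ll
                all_chain[row] = c
        with np.errstate(invalid="ignore"):
            acc_report[f"chain{c}"] = np.where(
                total_tries > 0, total_acc / np.maximum(total_tries, 1), np.nan
            ).round(3).tolist()

    return PosteriorSamples(
        draws=all_draws, names=spec.param_names, loglik=all_ll,
        chain=all_chain, accept_rates=acc_report,
    )


# ---------------------------------------------------------------------------
# Model comparison and diagnostics
# ---------------------------------------------------------------------------


@dataclass
class DICResult:
    dic: float
    pd: float
    dbar: float
    dhat: float


def compute_dic(samples: PosteriorSamples, spec: ModelSpec, design: pd.DataFrame,
                y, pd_form: str = "spiegelhalter") -> DICResult:
    """Deviance information criterion.

    ``DIC = Dbar + pD`` with ``D = -2 log L``.  By default
    ``pD = Dbar - D(theta_bar)`` evaluated at the posterior mean
    (Spiegelhalter form); ``pd_form="half_var"`` uses ``Var(D) / 2`` instead.
    """
    dbar = float(np.mean(-2.0 * samples.loglik))
    post_mean = samples.mean()
    beta = np.array([post_mean["intercept"], *[post_mean[t] for t in spec.terms]])
    params = {"beta": beta}
    if spec.family == "negbin":
        params["k"] = post_mean["k"]
    elif spec.family == "zip":
        params["pi"] = post_mean["pi"]
    dhat = float(-2.0 * loglik(spec, params, design, y).sum())
    if not np.isfinite(dhat):
        raise FloatingPointError("deviance at the posterior mean is not finite")
    if pd_form == "half_var":
        pD = float(np.var(-2.0 * samples.loglik) / 2.0)
    else:
        pD = dbar - dhat
    return DICResult(dic=dbar + pD, pd=pD, dbar=dbar, dhat=dhat)


def rhat(samples: PosteriorSamples) -> pd.Series:
    """Split-chain potential scale reduction factor per parameter.

    Each chain is split in half so within-chain trends register as
    between-chain variance.  Parameters with zero variance get NaN.
    """
    labels = np.unique(samples.chain)
    if len(labels) < 2:
        raise ValueError("rhat requires at least two chains")
    halves = []
    for c in labels:
        block = samples.draws[samples.chain == c]
        m = len(block) // 2
        halves.extend([block[:m], block[m: 2 * m]])
    arr = np.stack(halves)                       # (2C, m, P)
    m = arr.shape[1]
    cm = arr.mean(axis=1)                        # per-half means
    cv = arr.var(axis=1, ddof=1)
    W = cv.mean(axis=0)
    B = m * cm.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_plus = (m - 1) / m * W + B / m
        r = np.sqrt(var_plus / W)
    r = np.where(W > 0, r, np.nan)
    return pd.Series(r, index=samples.names)


# ---------------------------------------------------------------------------
# Frequentist helpers (preliminary covariate screen)
# ---------------------------------------------------------------------------


@dataclass
class GlmFit:
    family: str
    params: pd.Series
    llf: float
    aic: float
    n_params: int


def fit_glm_ml(family: str, design: pd.DataFrame, y, terms=None) -> GlmFit:
    """Maximum-likelihood Poisson or NB GLM with ``AIC = 2p - 2 logL``.

    The NB dispersion counts as a parameter in ``p``.  Fitting is delegated to
    statsmodels; a rank-deficient design raises ``np.linalg.LinAlgError``.
    """
    import statsmodels.api as sm
    from statsmodels.discrete.discrete_model import NegativeBinomial

    if terms is None:
        terms = tuple(design.columns)
    spec = ModelSpec(family="poisson", terms=tuple(terms))
    X = build_design_matrix(spec, design)
    y = np.asarray(y, dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError(
            f"singular design matrix for terms {list(terms)}")
    names = ["intercept", *terms]
    if family == "poisson":
        res = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        p = X.shape[1]
        params = pd.Series(np.asarray(res.params), index=names)
    elif family == "negbin":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # boundary alpha -> 0 is legitimate
            res = NegativeBinomial(y, X).fit(disp=0, maxiter=500, method="bfgs")
        p = X.shape[1] + 1
        params = pd.Series(np.asarray(res.params), index=names + ["alpha"])
    else:
        raise ValueError("family must be 'poisson' or 'negbin'")
    llf = float(res.llf)
    return GlmFit(family=family, params=params, llf=llf,
                  aic=2.0 * p - 2.0 * llf, n_params=p)


@dataclass
class DredgeResult:
    table: pd.DataFrame            # all candidate subsets, AIC-sorted
    best: pd.DataFrame             # the delta-AIC < 2 set

    @property
    def top_terms(self) -> tuple[str, ...]:
        return tuple(self.table.iloc[0]["terms"])


def dredge(candidate_terms, design: pd.DataFrame, y, max_terms: int = 4,
           family: str = "poisson") -> DredgeResult:
    """All-subsets AIC search over candidate terms (sizes 0..max_terms).

    Quadratic columns are treated as candidates in their own right, so a
    square can enter without its linear term.  More than 20 candidates is
    rejected as a combinatorial guard.
    """
    candidate_terms = list(candidate_terms)
    if len(candidate_terms) > 20:
        raise ValueError("more than 20 candidate terms; refusing the 2^20+ subsets")
    rows = []
    for size in range(0, max_terms + 1):
        for combo in itertools.combinations(candidate_terms, size):
            fit = fit_glm_ml(family, design, y, terms=combo)
            rows.append({"terms": combo, "n_terms": size, "aic": fit.aic})
    table = pd.DataFrame(rows).sort_values("aic", kind="stable").reset_index(drop=True)
    table["delta_aic"] = table["aic"] - table["aic"].iloc[0]
    return DredgeResult(table=table, best=table[table["delta_aic"] < 2.0].copy())
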