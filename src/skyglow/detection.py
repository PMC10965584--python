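"""Per-minute detection modelling, the detection filter, and recovery checks.

Each individual present during a 6-minute survey leaves a 6-slot 0/1 history;
the number of minutes in which it was detected (out of six) is modelled as a
binomial GLM on the logit scale with ALAN and temporal covariates as
predictors.  The per-minute probability ``p_min`` converts to a whole-survey
detection probability via

    p_survey = 1 - (1 - p_min) ** 6

(six independent one-minute trials).  Relative-abundance inference assumes
roughly equal detection across surveys; the sensitivity filter removes surveys
whose predicted ``p_survey`` falls below a threshold (default 90%) and refits
the abundance model, so the analyst can see whether an apparent ALAN effect on
counts is really an ALAN effect on detectability.

The module also houses the simulate-refit validation harness: simulate counts
from a fitted model's posterior-mean coefficients at the selected scales, fit
the model again on the simulated counts, and check that the generating values
sit inside the refitted 95% credible intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .covariates import MultiScaleDesign
from .mcmc import ChainConfig, PosteriorSamples, run_mcmc

N_MINUTES = 6

DETECTION_COVARIATES = ("sun_angle", "sun_angle_sq", "day_of_year",
                        "day_of_year_sq", "lunar")


# ---------------------------------------------------------------------------
# Individuals from survey histories
# ---------------------------------------------------------------------------


def individuals_from_table(table: pd.DataFrame) -> pd.DataFrame:
    """Explode ';'-joined 6-slot histories into one row per individual.

    Each row keeps its survey's covariate columns and gains
    ``minutes_detected`` (0..6).  Surveys with no detected individuals
    contribute no rows.
    """
    rows = []
    for i, hist in enumerate(table["histories"]):
        if not isinstance(hist, str) or hist == "":
            continue
        for h in hist.split(";"):
            if len(h) != N_MINUTES or set(h) - {"0", "1"}:
                raise ValueError(f"malformed minute history {h!r} in row {i}")
            rows.append((i, h.count("1")))
    if not rows:
        return table.iloc[0:0].assign(minutes_detected=pd.Series(dtype=int))
    idx, minutes = zip(*rows)
    out = table.iloc[list(idx)].copy().reset_index(drop=True)
    out["minutes_detected"] = list(minutes)
    return out


# ---------------------------------------------------------------------------
# Binomial detection GLM
# ---------------------------------------------------------------------------


@dataclass
class DetectionFit:
    """ML binomial GLM for minutes-detected out of six, logit link."""

    params: pd.Series               # intercept first
    cov_params: pd.DataFrame
    covariate_cols: tuple[str, ...]
    group: str = ""

    def p_min(self, covariates: pd.DataFrame) -> np.ndarray:
        """Predicted per-minute detection probability, in (0, 1)."""
        z = np.full(len(covariates), self.params["intercept"])
        for c in self.covariate_cols:
            z += self.params[c] * np.asarray(covariates[c], dtype=float)
        return expit(z)


def fit_detection_glm(individuals: pd.DataFrame, covariate_cols,
                      group: str = "") -> DetectionFit:
    """Fit the per-minute detection model to individual minute counts.

    ``individuals`` is one row per detected individual with
    ``minutes_detected`` and survey-level covariates.  All-zero or all-six
    responses leave the intercept unbounded (complete separation) and raise.
    """
    import statsmodels.api as sm

    covariate_cols = tuple(covariate_cols)
    m = np.asarray(individuals["minutes_detected"], dtype=float)
    if len(m) == 0:
        raise ValueError("no individuals to fit")
    if np.all(m == 0) or np.all(m == N_MINUTES):
        raise ValueError(
            "all individuals detected in 0 or 6 minutes: the logit intercept "
            "is unbounded (complete separation)")
    X = np.column_stack([np.ones(len(m))]
                        + [np.asarray(individuals[c], dtype=float) for c in covariate_cols])
    endog = np.column_stack([m, N_MINUTES - m])
    res = sm.GLM(endog, X, family=sm.families.Binomial()).fit()
    names = ["intercept", *covariate_cols]
    return DetectionFit(
        params=pd.Series(np.asarray(res.params), index=names),
        cov_params=pd.DataFrame(np.asarray(res.cov_params()), index=names, columns=names),
        covariate_cols=covariate_cols, group=group,
    )


def survey_prob_from_p_min(p_min) -> np.ndarray:
    """Whole-survey detection probability from the per-minute probability."""
    p = np.asarray(p_min, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("per-minute probabilities must lie in [0, 1]")
    return 1.0 - (1.0 - p) ** N_MINUTES


def survey_detection_prob(fit: DetectionFit, survey_covariates: pd.DataFrame) -> np.ndarray:
    """Probability an individual, if present, is detected at least once in a
    survey: ``1 - (1 - p_min)^6``, strictly increasing in ``p_min``."""
    return survey_prob_from_p_min(fit.p_min(survey_covariates))


# ---------------------------------------------------------------------------
# Detection-probability filter + refit
# ---------------------------------------------------------------------------


@dataclass
class FilterRefit:
    kept: np.ndarray                 # boolean mask over surveys
    n_removed: int
    fit_full: "object"               # AbundanceFit
    fit_filtered: "object"
    deltas: pd.DataFrame


def filter_surveys(p_survey, threshold: float = 0.90) -> np.ndarray:
    """Boolean keep-mask: surveys with ``p_survey >= threshold`` are retained
    (the filter removes surveys strictly below the threshold)."""
    p = np.asarray(p_survey, dtype=float)
    return p >= threshold


def filter_by_detection(fit_full, p_survey, cfg: ChainConfig,
                        threshold: float = 0.90) -> FilterRefit:
    """Drop low-detectability surveys and refit the abundance model.

    ``fit_full`` is the :class:`~skyglow.abundance.AbundanceFit` on all
    surveys; ``p_survey`` the predicted whole-survey detection probability per
    row of its design.  Returns the refit plus per-coefficient deltas and
    CI-overlap flags so sign/scale conclusions can be compared.
    """
    from .abundance import AbundanceFit, _compare
    from .mcmc import compute_dic

    design = fit_full.design
    kept = filter_surveys(p_survey, threshold)
    if not kept.any():
        raise ValueError(f"threshold {threshold} removes every survey")
    sub = replace(design, df=design.df.loc[kept].reset_index(drop=True))
    y = np.asarray(sub.df[design.response])
    samples = run_mcmc(fit_full.spec, sub.df, y, cfg)
    refit = AbundanceFit(samples=samples, spec=fit_full.spec, design=sub,
                         term_cols=fit_full.term_cols,
                         dic=compute_dic(samples, fit_full.spec, sub.df, y))
    return FilterRefit(kept=kept, n_removed=int((~kept).sum()),
                       fit_full=fit_full, fit_filtered=refit,
                       deltas=_compare(fit_full, refit))


# ---------------------------------------------------------------------------
# Simulate-refit validation
# ---------------------------------------------------------------------------


def simulate_from_fit(fit, design: MultiScaleDesign, seed: int,
                      use_draws: bool = False) -> pd.DataFrame:
    """Simulate counts over the design rows from a fitted abundance model.

    By default the generating coefficients are the posterior means (the
    fitted "coefficient values"); ``use_draws=True`` instead draws one
    posterior sample per replicate for a fully Bayesian check.  Returns the
    design rows with ``sim_count`` attached.
    """
    from .mcmc import build_design_matrix

    rng = np.random.default_rng(seed)
    samples: PosteriorSamples = fit.samples
    if use_draws:
        row = rng.integers(len(samples.draws))
        values = pd.Series(samples.draws[row], index=samples.names)
    else:
        values = samples.mean()
    spec = fit.spec
    out = (fit.design.df if design is None else design.df).copy()
    for term, col in getattr(fit, "term_cols", {}).items():
        if term in out.columns:
            continue
        if isinstance(col, tuple):        # interaction: product of parent columns
            out[term] = (np.asarray(out[col[0]], dtype=float)
                         * np.asarray(out[col[1]], dtype=float))
        else:
            out[term] = out[col]
    X = build_design_matrix(spec, out)
    beta = np.array([values["intercept"], *[values[t] for t in spec.terms]])
    mu = np.exp(X @ beta)
    if spec.family == "negbin":
        k = float(values["k"])
        counts = rng.negative_binomial(k, k / (k + mu))
    elif spec.family == "poisson":
        counts = rng.poisson(mu)
    else:
        counts = np.where(rng.uniform(size=len(mu)) < float(values["pi"]),
                          0, rng.poisson(mu))
    out["sim_count"] = counts
    out["sim_mu"] = mu
    return out


@dataclass
class RecoveryReport:
    table: pd.DataFrame              # per-parameter truth, estimate, CI, inside flag
    scale_table: pd.DataFrame | None  # per-covariate true vs modal scale
    coverage: float                  # fraction of parameters inside their 95% CI

    @property
    def all_scales_match(self) -> bool:
        if self.scale_table is None or self.scale_table.empty:
            return True
        return bool(self.scale_table["match"].all())


def recovery_report(refit, truth: dict, true_scales: dict | None = None,
                    selected_scales: dict | None = None) -> RecoveryReport:
    """Did the refit recover the generating parameters?

    ``truth`` maps parameter name -> generating value; every named parameter
    must exist in the refit.  ``true_scales`` / ``selected_scales`` map
    covariate -> radius for the scale-match flags.
    """
    samples: PosteriorSamples = refit.samples if hasattr(refit, "samples") else refit
    rows = []
    for name, true_val in truth.items():
        if name not in samples.names:
            raise KeyError(f"parameter {name!r} missing from the refit")
        d = samples.get(name)
        lo, hi = np.quantile(d, [0.025, 0.975])
        rows.append({"param": name, "truth": float(true_val),
                     "post_mean": float(d.mean()),
                     "lo95": float(lo), "hi95": float(hi),
                     "inside": bool(lo <= true_val <= hi)})
    table = pd.DataFrame(rows).set_index("param")
    scale_table = None
    if true_scales:
        srows = []
        for cov, true_r in true_scales.items():
            sel = (selected_scales or {}).get(cov)
            srows.append({"covariate": cov, "true_scale": int(true_r),
                          "selected_scale": None if sel is None else int(sel),
                          "match": sel is not None and int(sel) == int(true_r)})
        scale_table = pd.DataFrame(srows).set_index("covariate")
    return RecoveryReport(table=table, scale_table=scale_table,
                          coverage=float(table["inside"].mean()))
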