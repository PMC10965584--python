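import numpy as np
import pandas as pd
import pytest

from skyglow.abundance import AbundanceFit
from skyglow.covariates import MultiScaleDesign
from skyglow.mcmc import ChainConfig, ModelSpec, PosteriorSamples


@pytest.fixture(scope="session")
def quick_cfg():
    """Short chains for unit tests of sampler-backed operations."""
    return ChainConfig(chains=3, iterations=1200, burn_in=300, seed=42)


def identity_design(n_rows: int = 1, radii=(400, 1600, 6400)) -> MultiScaleDesign:
    """A standardized design whose scaling constants are the identity, so
    model coefficients act directly on natural units."""
    df = pd.DataFrame({"station_id": [f"S{i}" for i in range(n_rows)],
                       "count": np.zeros(n_rows, dtype=int)})
    for r in radii:
        df[f"alan_{r}"] = 0.0
        df[f"urban_{r}"] = 0.0
    scaling = {c: (0.0, 1.0) for c in df.columns if c not in ("station_id", "count")}
    return MultiScaleDesign(df=df, radii=radii, landscape_covs=("alan", "urban"),
                            fixed_covs=(), quad_pairs=(), scaling=scaling,
                            standardized=True)


def degenerate_fit(beta_alan, beta_int=None, beta_urban=None, intercept=0.0,
                   n_draws=1, k=5.0, scale=1600) -> AbundanceFit:
    """An AbundanceFit whose posterior is a point mass, for closed-form checks."""
    design = identity_design()
    names = ["intercept", "alan"]
    row = [intercept, beta_alan]
    term_cols = {"alan": f"alan_{scale}"}
    terms = ["alan"]
    if beta_urban is not None:
        names.append("urban")
        row.append(beta_urban)
        term_cols["urban"] = f"urban_{scale}"
        terms.append("urban")
    if beta_int is not None:
        names.append("alan:urban")
        row.append(beta_int)
        term_cols["alan:urban"] = (f"alan_{scale}", f"urban_{scale}")
        terms.append("alan:urban")
    names.append("k")
    row.append(k)
    draws = np.tile(np.asarray(row, dtype=float), (n_draws, 1))
    samples = PosteriorSamples(draws=draws, names=names,
                               loglik=np.zeros(n_draws),
                               chain=np.zeros(n_draws, dtype=int))
    spec = ModelSpec(family="negbin", terms=tuple(terms))
    return AbundanceFit(samples=samples, spec=spec, design=design,
                        term_cols=term_cols, dic=None)
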