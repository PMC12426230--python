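"""Median-regression sensitivity analysis (check-loss minimization, tau=0.5).

Applied on the identity-scale outcome with the linear covariate structure;
confidence intervals come from the asymptotic kernel-based covariance of the
quantile-regression estimator, with a seeded bootstrap fallback for
degenerate designs. The CI method used is recorded on the result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import ConfigurationError, FitInfeasibleError
from .association_models import FitResult, ModelSpec, Z_95, build_design


@dataclass
class QuantileConfig:
    tau: float = 0.5
    max_iterations: int = 2000
    tolerance: float = 1e-6
    bootstrap_resamples: int = 999
    bootstrap_seed: int = 0

    def validate(self) -> None:
        if not 0 < self.tau < 1:
            raise ConfigurationError("tau must lie in (0, 1)")
        if self.max_iterations < 1:
            raise ConfigurationError("max_iterations must be >= 1")


def fit_median_regression(
    frame: pd.DataFrame,
    spec: ModelSpec | None = None,
    config: QuantileConfig | None = None,
) -> FitResult:
    """Quantile regression of the protein outcome on statin use + covariates."""
    import statsmodels.api as sm

    spec = spec or ModelSpec()
    config = config or QuantileConfig()
    config.validate()
    # identity scale, linear covariates: the non-parametric reading
    lin_spec = replace(spec, outcome_transform="identity", spline_spec={})
    X, y = build_design(frame, lin_spec)
    n, k = X.shape
    if n <= k:
        raise FitInfeasibleError(f"{n} rows for {k} parameters")
    j = X.columns.get_loc("statin_use")

    model = sm.QuantReg(y, X.to_numpy())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(q=config.tau, max_iter=config.max_iterations, p_tol=config.tolerance)
    beta = float(res.params[j])
    se = float(res.bse[j])
    ci_method = "asymptotic_kernel"
    if not np.isfinite(se) or se <= 0:
        beta, se = _bootstrap(X.to_numpy(), y, j, config)
        ci_method = f"bootstrap_{config.bootstrap_resamples}"
        warnings.warn("degenerate quantile-regression covariance; bootstrap CI used")
    if se > 0:
        p = float(2.0 * stats.norm.sf(abs(beta / se)))
    else:
        p = 1.0
    return FitResult(
        beta=beta,
        se=se,
        ci_low=beta - Z_95 * se,
        ci_high=beta + Z_95 * se,
        p_value=p,
        n_used=n,
        spec=lin_spec,
        outcome_sd=float(np.std(y, ddof=1)),
        model_type=f"quantile_{config.tau:g}",
        ci_method=ci_method,
    )


def _bootstrap(X: np.ndarray, y: np.ndarray, j: int, config: QuantileConfig):
    import statsmodels.api as sm

    rng = np.random.default_rng(config.bootstrap_seed)
    n = len(y)
    betas = []
    for _ in range(config.bootstrap_resamples):
        idx = rng.integers(0, n, n)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.QuantReg(y[idx], X[idx]).fit(
                    q=config.tau, max_iter=config.max_iterations, p_tol=config.tolerance
                )
            betas.append(float(res.params[j]))
        except Exception:
            continue
    betas = np.asarray(betas)
    point = float(np.median(betas)) if betas.size else float("nan")
    se = float(np.std(betas, ddof=1)) if betas.size > 1 else float("nan")
    return point, se
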