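"""Per-protein multivariable modelling.

For each protein that survives QC and outlier screening: build a
complete-case model frame, decide whether to log-transform the outcome,
test each continuous covariate for nonlinearity with restricted cubic
splines, fit OLS with the statin indicator, audit influence via Cook's
distance, and record diagnostics (VIF, Durbin-Watson, residual-normality
proxies, Breusch-Pagan).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import ConfigurationError, DataError, FitInfeasibleError
from .assay import CATEGORICAL_LEVELS, CONTINUOUS_COVARIATES, Cohort, ProteinAssay
from .outlier_filter import OutlierConfig, detect_outliers
from .qc_proteins import QCConfig, apply_qc
from .splines import default_knots, rcs_basis

logger = logging.getLogger(__name__)

Z_95 = 1.959963984540054  # Gaussian 97.5% critical value

DEFAULT_COVARIATES = (
    "age", "sex", "bmi", "systolic_bp", "alcohol",
    "diabetes", "smoking", "physical_activity", "education",
)


@dataclass
class ModelSpec:
    outcome_transform: str = "identity"  # "identity" | "log"
    covariates: tuple = DEFAULT_COVARIATES
    spline_spec: dict = field(default_factory=dict)  # continuous covariate -> 0/3/4/5
    cooks_threshold_rule: str = "four_over_n"  # "four_over_n" | "one"

    def validate(self) -> None:
        if self.outcome_transform not in ("identity", "log"):
            raise ConfigurationError(f"unknown outcome_transform {self.outcome_transform!r}")
        if self.cooks_threshold_rule not in ("four_over_n", "one"):
            raise ConfigurationError(f"unknown cooks_threshold_rule {self.cooks_threshold_rule!r}")
        for cov, k in self.spline_spec.items():
            if cov not in CONTINUOUS_COVARIATES:
                raise ConfigurationError(f"spline_spec for non-continuous covariate {cov!r}")
            if k not in (0, 3, 4, 5):
                raise ConfigurationError(f"knot count for {cov!r} must be 0, 3, 4 or 5")


@dataclass
class DiagnosticsReport:
    vif: dict = field(default_factory=dict)
    durbin_watson: float = float("nan")
    residual_normality: tuple = (float("nan"),) * 3  # skew, excess kurtosis, AD stat
    heteroscedasticity: float = float("nan")  # Breusch-Pagan p
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "vif": self.vif,
            "durbin_watson": self.durbin_watson,
            "residual_normality": list(self.residual_normality),
            "heteroscedasticity": self.heteroscedasticity,
            "warnings": list(self.warnings),
        }


@dataclass
class FitResult:
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    n_used: int
    n_outliers_removed: int = 0
    n_influential_removed: int = 0
    spec: ModelSpec = field(default_factory=ModelSpec)
    diagnostics: DiagnosticsReport = field(default_factory=DiagnosticsReport)
    outcome_sd: float = float("nan")  # SD of the analyzed outcome (modeled scale)
    model_type: str = "ols"
    ci_method: str = "wald_normal"

    def to_row(self) -> dict:
        knots = ";".join(f"{c}={k}" for c, k in sorted(self.spec.spline_spec.items()) if k)
        return {
            "model_type": self.model_type,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "n_used": self.n_used,
            "transform": self.spec.outcome_transform,
            "knots": knots,
            "n_outliers_removed": self.n_outliers_removed,
            "n_influential_removed": self.n_influential_removed,
            "outcome_sd": self.outcome_sd,
            "display": f"{self.beta:.2f} [{self.ci_low:.2f}; {self.ci_high:.2f}]",
        }


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def build_model_frame(
    cohort: Cohort,
    protein: ProteinAssay,
    outlier_flags: Optional[np.ndarray] = None,
    covariates: tuple = DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Complete-case frame: outcome column ``y`` plus raw covariates.

    Rows with any missing covariate, a missing outcome, or an
    outlier-flagged outcome are dropped.
    """
    df = cohort.participants
    y = protein.values.astype(float).copy()
    if outlier_flags is not None:
        y = np.where(np.asarray(outlier_flags, dtype=bool), np.nan, y)
    frame = df.loc[:, ["statin_use", *covariates]].copy()
    frame.insert(0, "y", y)
    frame = frame.dropna()
    n_params = _n_parameters(ModelSpec(covariates=covariates))
    if len(frame) < n_params + 10:
        raise FitInfeasibleError(
            f"{protein.protein_name}: {len(frame)} complete rows for {n_params} parameters"
        )
    return frame.reset_index(drop=True)


def _n_parameters(spec: ModelSpec) -> int:
    k = 2  # intercept + statin
    for cov in spec.covariates:
        if cov in CONTINUOUS_COVARIATES:
            knots = spec.spline_spec.get(cov, 0)
            k += 1 + max(knots - 2, 0)
        elif cov in CATEGORICAL_LEVELS:
            k += len(CATEGORICAL_LEVELS[cov]) - 1
        else:
            k += 1  # binary flag (e.g. diabetes)
    return k


def build_design(frame: pd.DataFrame, spec: ModelSpec) -> tuple[pd.DataFrame, np.ndarray]:
    """Expand the model frame into (X, y); first declared level of every
    categorical covariate is the reference."""
    spec.validate()
    n = len(frame)
    cols: dict[str, np.ndarray] = {"const": np.ones(n)}
    cols["statin_use"] = frame["statin_use"].to_numpy(dtype=float)
    for cov in spec.covariates:
        if cov in CONTINUOUS_COVARIATES:
            x = frame[cov].to_numpy(dtype=float)
            knots = spec.spline_spec.get(cov, 0)
            if knots:
                basis = rcs_basis(x, default_knots(x, knots))
                cols[cov] = basis[:, 0]
                for j in range(1, basis.shape[1]):
                    cols[f"{cov}_rcs{j}"] = basis[:, j]
            else:
                cols[cov] = x
        elif cov in CATEGORICAL_LEVELS:
            levels = CATEGORICAL_LEVELS[cov]
            col = frame[cov].to_numpy()
            for lvl in levels[1:]:
                cols[f"{cov}_{lvl}"] = (col == lvl).astype(float)
        else:
            cols[cov] = frame[cov].to_numpy(dtype=float)  # binary flag
    X = pd.DataFrame(cols)
    y = frame["y"].to_numpy(dtype=float)
    if spec.outcome_transform == "log":
        if (y <= 0).any():
            raise DataError("log transform requested but outcome has values <= 0")
        y = np.log(y)
    return X, y


# ---------------------------------------------------------------------------
# OLS core (numpy; also powers the batched panel fit)
# ---------------------------------------------------------------------------

def _ols(X: np.ndarray, y: np.ndarray):
    """Least squares with covariance; raises on rank deficiency."""
    n, k = X.shape
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(n, k) * np.finfo(float).eps if diag.size else 0.0
    if (diag <= tol).any():
        bad = np.flatnonzero(diag <= tol)
        raise FitInfeasibleError(f"rank-deficient design; collinear column indices {bad.tolist()}")
    beta = np.linalg.solve(r, q.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    dof = n - k
    sigma2 = rss / dof if dof > 0 else float("nan")
    rinv = np.linalg.solve(r, np.eye(k))
    xtx_inv = rinv @ rinv.T
    return beta, resid, rss, sigma2, xtx_inv


def _loglik(n: int, rss: float) -> float:
    if rss <= 0:
        return float("inf")
    return -0.5 * n * (np.log(2.0 * np.pi * rss / n) + 1.0)


def fast_panel_ols(X: np.ndarray, Y: np.ndarray, coef_index: int = 1):
    """Vectorized OLS of many outcomes on one shared design.

    ``Y`` is n x m; returns ``(betas, ses, p_values)`` for the coefficient at
    ``coef_index`` (default: the statin column). Same Wald-normal inference
    as :func:`fit_linear_model`; used for panel-scale null simulations.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n, k = X.shape
    q, r = np.linalg.qr(X)
    B = np.linalg.solve(r, q.T @ Y)
    resid = Y - X @ B
    rss = (resid * resid).sum(axis=0)
    sigma2 = rss / (n - k)
    rinv = np.linalg.solve(r, np.eye(k))
    xtx_inv_diag = (rinv @ rinv.T)[coef_index, coef_index]
    betas = B[coef_index]
    ses = np.sqrt(sigma2 * xtx_inv_diag)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = betas / ses
    p = 2.0 * stats.norm.sf(np.abs(z))
    return betas, ses, p


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------

def select_transformation(frame: pd.DataFrame, spec: ModelSpec | None = None) -> str:
    """Pick ``log`` only if it both improves residual normality
    (Anderson-Darling) and does not worsen the Jacobian-corrected
    log-likelihood; any non-positive outcome forces ``identity``."""
    spec = spec or ModelSpec()
    y_raw = frame["y"].to_numpy(dtype=float)
    if (y_raw <= 0).any():
        return "identity"
    X, y = build_design(frame, replace(spec, outcome_transform="identity"))
    Xm = X.to_numpy()
    _, resid_id, rss_id, _, _ = _ols(Xm, y)
    ll_id = _loglik(len(y), rss_id)
    ylog = np.log(y_raw)
    _, resid_log, rss_log, _, _ = _ols(Xm, ylog)
    ll_log = _loglik(len(y), rss_log) - float(np.sum(np.log(y_raw)))
    ad_id = _anderson_stat(resid_id)
    ad_log = _anderson_stat(resid_log)
    if ad_log < ad_id and ll_log >= ll_id:
        return "log"
    return "identity"


def select_spline_spec(
    frame: pd.DataFrame,
    candidate_knots=(3, 4, 5),
    alpha: float = 0.05,
    base_spec: ModelSpec | None = None,
) -> ModelSpec:
    """Per continuous covariate: likelihood-ratio test of the 3-knot
    restricted cubic spline against the linear term; if p < alpha, pick the
    knot count minimizing BIC (ties -> fewer knots); otherwise stay linear.
    Covariates with fewer than 10 distinct values are forced linear."""
    spec = base_spec or ModelSpec()
    chosen: dict[str, int] = {}
    linear_spec = replace(spec, spline_spec={})
    X_lin, y = build_design(frame, linear_spec)
    Xm = X_lin.to_numpy()
    n = len(y)
    # QR of the linear design once; each spline trial only adds columns, so
    # its RSS follows from residualizing those columns against Q (block update)
    q_lin, _r_lin = np.linalg.qr(Xm)
    resid_lin = y - q_lin @ (q_lin.T @ y)
    rss_lin = float(resid_lin @ resid_lin)
    ll_lin = _loglik(n, rss_lin)
    for cov in spec.covariates:
        if cov not in CONTINUOUS_COVARIATES:
            continue
        x = frame[cov].to_numpy(dtype=float)
        if np.unique(x).size < 10:
            logger.warning("covariate %s has < 10 distinct values; forced linear", cov)
            chosen[cov] = 0
            continue
        lls = {}
        for k in sorted(candidate_knots):
            try:
                extra = rcs_basis(x, default_knots(x, k))[:, 1:]
            except DataError:
                continue  # degenerate knots: knot count unavailable
            e_perp = extra - q_lin @ (q_lin.T @ extra)
            norms = np.linalg.norm(e_perp, axis=0)
            scale = np.linalg.norm(extra, axis=0)
            if (norms <= 1e-10 * np.maximum(scale, 1.0)).any():
                continue  # spline terms collinear with the linear design
            qe, _re = np.linalg.qr(e_perp)
            proj = qe.T @ resid_lin
            rss_k = max(rss_lin - float(proj @ proj), 0.0)
            lls[k] = (_loglik(n, rss_k), Xm.shape[1] + extra.shape[1])
        if 3 not in lls:
            chosen[cov] = 0
            continue
        ll3, k3 = lls[3]
        lr = 2.0 * (ll3 - ll_lin)
        df = k3 - Xm.shape[1]
        p = float(stats.chi2.sf(max(lr, 0.0), df))
        if p >= alpha:
            chosen[cov] = 0
            continue
        bics = {k: np.log(n) * kk - 2.0 * ll for k, (ll, kk) in lls.items()}
        best = min(sorted(bics), key=lambda k: (round(bics[k], 12), k))
        chosen[cov] = best
    return replace(spec, spline_spec={c: k for c, k in chosen.items() if k})


# ---------------------------------------------------------------------------
# fitting + diagnostics
# ---------------------------------------------------------------------------

def _anderson_stat(resid: np.ndarray) -> float:
    """Anderson-Darling normality statistic (scipy's p-value machinery is
    deliberately unused; only the statistic is compared)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        return float(stats.anderson(resid).statistic)


def _compute_diagnostics(X: pd.DataFrame, resid: np.ndarray) -> DiagnosticsReport:
    from statsmodels.stats.diagnostic import het_breuschpagan
    from statsmodels.stats.outliers_influence import variance_inflation_factor
    from statsmodels.stats.stattools import durbin_watson

    Xm = X.to_numpy()
    vif = {}
    for j, name in enumerate(X.columns):
        if name == "const":
            continue
        try:
            vif[name] = float(variance_inflation_factor(Xm, j))
        except Exception:  # pragma: no cover - degenerate aux regression
            vif[name] = float("inf")
    dw = float(durbin_watson(resid))
    skew = float(stats.skew(resid))
    exkurt = float(stats.kurtosis(resid))
    ad = _anderson_stat(resid) if np.std(resid) > 0 else 0.0
    try:
        bp_p = float(het_breuschpagan(resid, Xm)[1])
    except Exception:
        bp_p = float("nan")
    warns = []
    high_vif = {k: v for k, v in vif.items() if v > 5}
    if high_vif:
        warns.append(f"VIF > 5 for {sorted(high_vif)}")
    if not 1.5 <= dw <= 2.5:
        warns.append(f"Durbin-Watson {dw:.3f} outside [1.5, 2.5]")
    return DiagnosticsReport(
        vif=vif,
        durbin_watson=dw,
        residual_normality=(skew, exkurt, ad),
        heteroscedasticity=bp_p,
        warnings=warns,
    )


def fit_linear_model(
    frame: pd.DataFrame,
    spec: ModelSpec | None = None,
    compute_diagnostics: bool = True,
) -> FitResult:
    """OLS fit of the protein outcome on statin use + covariates.

    The statin coefficient gets a Wald 95% CI and two-sided p-value with the
    Gaussian critical value (immaterial vs t at these n, recorded choice).
    """
    spec = spec or ModelSpec()
    X, y = build_design(frame, spec)
    n, k = X.shape
    if n <= k:
        raise FitInfeasibleError(f"{n} rows for {k} parameters")
    beta_vec, resid, rss, sigma2, xtx_inv = _ols(X.to_numpy(), y)
    j = X.columns.get_loc("statin_use")
    beta = float(beta_vec[j])
    se = float(np.sqrt(max(sigma2, 0.0) * xtx_inv[j, j]))
    if se > 0:
        z = beta / se
        p = float(2.0 * stats.norm.sf(abs(z)))
    else:
        p = 0.0 if beta != 0 else 1.0
    diagnostics = _compute_diagnostics(X, resid) if compute_diagnostics else DiagnosticsReport()
    return FitResult(
        beta=beta,
        se=se,
        ci_low=beta - Z_95 * se,
        ci_high=beta + Z_95 * se,
        p_value=p,
        n_used=n,
        spec=spec,
        diagnostics=diagnostics,
        outcome_sd=float(np.std(y, ddof=1)),
    )


def cooks_distance(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Cook's distance per observation for an OLS fit."""
    n, k = X.shape
    q, r = np.linalg.qr(X)
    h = np.einsum("ij,ij->i", q, q)  # leverage
    beta = np.linalg.solve(r, q.T @ y)
    resid = y - X @ beta
    dof = n - k
    s2 = float(resid @ resid) / dof
    if s2 <= 0:
        return np.zeros(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (resid**2 / (k * s2)) * (h / (1.0 - h) ** 2)
    return np.nan_to_num(d, nan=np.inf, posinf=np.inf)


def refit_without_influential(
    frame: pd.DataFrame,
    spec: ModelSpec,
    fit: FitResult,
    compute_diagnostics: bool = True,
) -> FitResult:
    """Single influence pass: drop rows with Cook's D above the threshold
    (4/n by default, or 1) and refit once; if nothing exceeds the threshold
    or the refit would be infeasible, the original fit is returned."""
    X, y = build_design(frame, spec)
    Xm = X.to_numpy()
    d = cooks_distance(Xm, y)
    n, k = Xm.shape
    threshold = 4.0 / n if spec.cooks_threshold_rule == "four_over_n" else 1.0
    drop = d > threshold
    n_drop = int(drop.sum())
    if n_drop == 0:
        return replace(fit, n_influential_removed=0)
    if n - n_drop < k + 10:
        warnings.warn(
            f"influence pass would leave {n - n_drop} rows for {k} parameters; keeping original fit"
        )
        return replace(fit, n_influential_removed=0)
    sub = frame.loc[~drop].reset_index(drop=True)
    refit = fit_linear_model(sub, spec, compute_diagnostics=compute_diagnostics)
    return replace(
        refit,
        n_outliers_removed=fit.n_outliers_removed,
        n_influential_removed=n_drop,
    )


# ---------------------------------------------------------------------------
# panel orchestration
# ---------------------------------------------------------------------------

@dataclass
class SkippedProtein:
    protein: str
    reason: str


def run_panel(
    cohort: Cohort,
    qc_config: QCConfig | None = None,
    outlier_config: OutlierConfig | None = None,
    select_transform: bool = True,
    select_splines: bool = True,
    compute_diagnostics: bool = True,
    influence_refit: bool = True,
):
    """QC -> outlier screen -> model selection -> fit -> influence refit,
    per retained protein. Returns
    ``(results, skipped, qc_report, outlier_traces)`` where ``results`` is a
    list of pre-inference :class:`pleioscan.inference.AssociationResult`
    (q-values and E-values not yet filled)."""
    from .inference import AssociationResult  # runtime import avoids a cycle

    retained, qc_report = apply_qc(cohort.panel, qc_config)
    outlier_config = outlier_config or OutlierConfig()
    results: list[AssociationResult] = []
    skipped: list[SkippedProtein] = []
    traces: dict[str, list] = {}
    for assay in retained:
        try:
            flags, trace = detect_outliers(assay.values, outlier_config)
            traces[assay.protein_name] = trace
            frame = build_model_frame(cohort, assay, outlier_flags=flags)
            spec = ModelSpec()
            if select_transform:
                spec = replace(spec, outcome_transform=select_transformation(frame, spec))
            if select_splines:
                spec = select_spline_spec(frame, base_spec=spec)
            fit = fit_linear_model(frame, spec, compute_diagnostics=compute_diagnostics)
            fit = replace(fit, n_outliers_removed=int(flags.sum()))
            if influence_refit:
                fit = refit_without_influential(
                    frame, spec, fit, compute_diagnostics=compute_diagnostics
                )
            results.append(
                AssociationResult(
                    protein=assay.protein_name,
                    study_label=cohort.study_label,
                    fit=fit,
                )
            )
        except (DataError, FitInfeasibleError) as exc:
            skipped.append(SkippedProtein(protein=assay.protein_name, reason=str(exc)))
    return results, skipped, qc_report, traces
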