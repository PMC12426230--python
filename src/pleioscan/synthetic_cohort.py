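"""Synthetic two-cohort generator.

Produces cohorts with the statistical structure the downstream analysis
assumes: confounded binary statin exposure, ~90 log2-scale protein outcomes
with planted effects for a named subset, left-censoring at a limit of
detection, duplicate assays, heavy-tail contamination and MCAR missingness.
Everything is deterministic given the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from ._errors import ConfigurationError, DataError
from .assay import (
    BINARY_FLAGS,
    CATEGORICAL_LEVELS,
    CONTINUOUS_COVARIATES,
    PARTICIPANT_COLUMNS,
    Cohort,
    ProteinAssay,
)

# Proteins reported as signal-bearing get real names so the default configs
# read naturally; the rest of the panel is filled with generic labels.
NAMED_PROTEINS = (
    "TRANCE", "TRAIL", "SCF", "NT-3", "MMP-10", "uPA", "CD244", "GDNF", "PDL1",
    "IL6", "IL8", "CXCL9",
)

#: features that may carry confounding weight in the statin-assignment logit
LOGIT_FEATURES = (
    "age", "bmi", "systolic_bp", "alcohol",
    "sex_female", "diabetes", "hypertension", "myocardial_infarction",
    "stroke", "cancer",
    "smoking_previous", "smoking_current",
    "education_middle", "education_high",
    "physical_activity_irregular_1h", "physical_activity_regular_1h",
    "physical_activity_regular_2h",
)

#: features the downstream models adjust for; random per-protein covariate
#: effects are restricted to this set so adjustment removes all confounding
#: (clinical flags may still drive exposure, mimicking indication)
ADJUSTED_FEATURES = (
    "age", "bmi", "systolic_bp", "alcohol",
    "sex_female", "diabetes",
    "smoking_previous", "smoking_current",
    "education_middle", "education_high",
    "physical_activity_irregular_1h", "physical_activity_regular_1h",
    "physical_activity_regular_2h",
)


def default_covariate_spec() -> dict:
    """Marginals loosely matched to the discovery cohort's baseline table."""
    return {
        "age": {"mean": 63.0, "sd": 7.0, "min": 40.0},
        "bmi": {"log_mean": math.log(27.4), "log_sd": 0.16},
        "systolic_bp": {"mean": 124.0, "sd": 15.0, "min": 70.0},
        "alcohol": {"p_zero": 0.25, "log_mean": math.log(10.0), "log_sd": 1.0},
        "sex": {"female": 0.52},
        "diabetes": {"p": 0.084},
        "smoking": {"never": 0.43, "previous": 0.43, "current": 0.14},
        "physical_activity": {
            "little_or_not": 0.17, "irregular_1h": 0.13,
            "regular_1h": 0.33, "regular_2h": 0.37,
        },
        "education": {"low": 0.36, "middle": 0.43, "high": 0.21},
        "hypertension": {"p": 0.47},
        "myocardial_infarction": {"p": 0.03},
        "stroke": {"p": 0.027},
        "cancer": {"p": 0.12},
    }


def default_confounding_weights() -> dict:
    """Log-odds increments producing Table-like imbalance (older, more often
    male/diabetic/post-infarction statin users)."""
    return {
        "age": 0.55,
        "bmi": 0.30,
        "sex_female": -0.45,
        "diabetes": 1.30,
        "hypertension": 0.90,
        "myocardial_infarction": 2.20,
        "stroke": 1.80,
    }


@dataclass
class CohortConfig:
    """Full recipe for one synthetic cohort."""

    study_label: str = "discovery"
    n_participants: int = 855
    statin_prevalence: float = 0.161
    covariate_spec: dict = field(default_factory=default_covariate_spec)
    confounding_weights: dict = field(default_factory=default_confounding_weights)
    n_proteins: int = 90
    effect_map: dict = field(default_factory=dict)
    protein_noise_sd: float = 1.0
    protein_intercept_sd: float = 0.5
    covariate_effect_sd: float = 0.15
    # optional fixed protein->feature->coefficient map overriding the random
    # per-protein covariate effects (used to plant structural confounding)
    covariate_effect_map: Optional[dict] = None
    lod_quantile_map: dict = field(default_factory=dict)
    duplicate_spec: list = field(default_factory=list)
    contamination: tuple = (0.0, 0.0)
    missing_fraction: float = 0.0
    seed: int = 0

    def protein_names(self) -> list[str]:
        names = list(NAMED_PROTEINS[: self.n_proteins])
        names += [f"PROT_{i:03d}" for i in range(len(names) + 1, self.n_proteins + 1)]
        return names

    def validate(self) -> None:
        if not (isinstance(self.n_participants, int) and self.n_participants >= 1):
            raise ConfigurationError("n_participants must be a positive integer")
        if not 0 < self.statin_prevalence < 1:
            raise ConfigurationError("statin_prevalence must lie in (0, 1)")
        if not (isinstance(self.n_proteins, int) and self.n_proteins >= 1):
            raise ConfigurationError("n_proteins must be a positive integer")
        if self.protein_noise_sd < 0:
            raise ConfigurationError("protein_noise_sd must be >= 0")
        frac, _offset = self.contamination
        if not 0 <= frac <= 1:
            raise ConfigurationError("contamination fraction must lie in [0, 1]")
        if not 0 <= self.missing_fraction < 1:
            raise ConfigurationError("missing_fraction must lie in [0, 1)")
        names = set(self.protein_names())
        for key in self.effect_map:
            if key not in names:
                raise ConfigurationError(f"effect_map names unknown protein {key!r}")
        for key, q in self.lod_quantile_map.items():
            if key not in names:
                raise ConfigurationError(f"lod_quantile_map names unknown protein {key!r}")
            if not 0 <= q <= 1:
                raise ConfigurationError(f"lod_quantile_map[{key!r}] must lie in [0, 1]")
        for entry in self.duplicate_spec:
            if len(entry) != 5:
                raise ConfigurationError(
                    "duplicate_spec entries are (protein, cv_a, cv_b, n_below_a, n_below_b)"
                )
            if entry[0] not in names:
                raise ConfigurationError(f"duplicate_spec names unknown protein {entry[0]!r}")
        for key in self.confounding_weights:
            if key not in LOGIT_FEATURES:
                raise ConfigurationError(f"confounding weight for unknown feature {key!r}")


def discovery_default_config(**overrides) -> CohortConfig:
    """Discovery-arm defaults: n=855, 16.1% statin prevalence, planted
    TRANCE/TRAIL/SCF effects, censoring above and below the 25% rule."""
    cfg = CohortConfig(
        study_label="discovery",
        n_participants=855,
        statin_prevalence=0.161,
        effect_map={"TRANCE": 0.21, "TRAIL": 0.09, "SCF": -0.11},
        protein_noise_sd=0.2,
        lod_quantile_map={"IL6": 0.40, "CXCL9": 0.30, "IL8": 0.10, "GDNF": 0.05},
        duplicate_spec=[("IL8", 8.0, 12.0, 3, 9)],
        contamination=(0.01, 8.0),
        missing_fraction=0.04,
        seed=0,
    )
    return _prune_to_panel(replace(cfg, **overrides))


def replication_default_config(**overrides) -> CohortConfig:
    cfg = CohortConfig(
        study_label="replication",
        n_participants=1079,
        statin_prevalence=0.274,
        effect_map={"TRANCE": 0.13, "TRAIL": 0.09, "SCF": -0.11},
        protein_noise_sd=0.2,
        lod_quantile_map={"IL6": 0.35, "IL8": 0.08, "GDNF": 0.05},
        duplicate_spec=[("IL8", 9.0, 7.0, 6, 6)],
        contamination=(0.01, 8.0),
        missing_fraction=0.032,
        seed=1,
    )
    cfg.covariate_spec["age"] = {"mean": 76.0, "sd": 6.5, "min": 65.0}
    return _prune_to_panel(replace(cfg, **overrides))


def _prune_to_panel(cfg: CohortConfig) -> CohortConfig:
    """Drop default map entries that name proteins outside a shrunken panel
    (keeps ``n_proteins=3`` style overrides ergonomic in tests/scripts)."""
    names = set(cfg.protein_names())
    return replace(
        cfg,
        effect_map={k: v for k, v in cfg.effect_map.items() if k in names},
        lod_quantile_map={k: v for k, v in cfg.lod_quantile_map.items() if k in names},
        duplicate_spec=[e for e in cfg.duplicate_spec if e[0] in names],
    )


# ---------------------------------------------------------------------------
# covariate + exposure sampling
# ---------------------------------------------------------------------------

def _draw_covariates(cfg: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_participants
    spec = cfg.covariate_spec
    out = {}
    a = spec["age"]
    out["age"] = np.maximum(rng.normal(a["mean"], a["sd"], n), a.get("min", 18.0))
    b = spec["bmi"]
    out["bmi"] = np.exp(rng.normal(b["log_mean"], b["log_sd"], n))
    s = spec["systolic_bp"]
    out["systolic_bp"] = np.maximum(rng.normal(s["mean"], s["sd"], n), s.get("min", 70.0))
    al = spec["alcohol"]
    drinks = rng.random(n) >= al["p_zero"]
    out["alcohol"] = np.where(drinks, np.exp(rng.normal(al["log_mean"], al["log_sd"], n)), 0.0)
    out["sex"] = np.where(rng.random(n) < spec["sex"]["female"], "female", "male")
    for flag in BINARY_FLAGS:
        out[flag] = (rng.random(n) < spec[flag]["p"]).astype(int)
    for cat in ("smoking", "physical_activity", "education"):
        levels = CATEGORICAL_LEVELS[cat]
        probs = np.array([spec[cat][lvl] for lvl in levels], dtype=float)
        probs = probs / probs.sum()
        out[cat] = rng.choice(levels, size=n, p=probs)
    return pd.DataFrame(out)


def _feature_matrix(cov: pd.DataFrame) -> pd.DataFrame:
    """Standardized continuous covariates plus 0/1 indicators, keyed by the
    names used in ``confounding_weights`` and ``covariate_effect_map``."""
    feats = {}
    for c in CONTINUOUS_COVARIATES:
        x = cov[c].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        feats[c] = (x - x.mean()) / (sd if sd > 0 else 1.0)
    feats["sex_female"] = (cov["sex"] == "female").astype(float).to_numpy()
    for flag in BINARY_FLAGS:
        feats[flag] = cov[flag].to_numpy(dtype=float)
    for cat in ("smoking", "physical_activity", "education"):
        for lvl in CATEGORICAL_LEVELS[cat][1:]:
            feats[f"{cat}_{lvl}"] = (cov[cat] == lvl).astype(float).to_numpy()
    return pd.DataFrame(feats)


def _calibrate_intercept(eta: np.ndarray, prevalence: float) -> float:
    """Bisection for the logit intercept hitting the target mean probability."""
    def mean_p(a: float) -> float:
        return float((1.0 / (1.0 + np.exp(-(a + eta)))).mean())

    lo, hi = -30.0, 30.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mean_p(mid) < prevalence:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# panel-level operations (also used standalone by tests)
# ---------------------------------------------------------------------------

def censor_at_lod(assay: ProteinAssay, target_fraction: float) -> ProteinAssay:
    """Set the assay LOD at the empirical target quantile of the values and
    mark everything strictly below it; values themselves are untouched."""
    if not 0 <= target_fraction <= 1:
        raise ConfigurationError("target_fraction must lie in [0, 1]")
    finite = assay.values[~np.isnan(assay.values)]
    if finite.size == 0:
        raise DataError(f"censor_at_lod: assay {assay.protein_name} has no values")
    out = assay.copy()
    out.lod = float(np.quantile(finite, target_fraction))
    with np.errstate(invalid="ignore"):
        out.below_lod_mask = assay.values < out.lod
    out.below_lod_mask[np.isnan(assay.values)] = False
    return out


def inject_outliers(
    assay: ProteinAssay, fraction: float, offset_sd: float, seed: int
) -> ProteinAssay:
    """Shift ceil(fraction*n) randomly chosen entries by offset_sd sample SDs;
    the chosen indices are recorded on the returned assay for test oracles."""
    if not 0 <= fraction < 0.5:
        raise ConfigurationError("outlier fraction must lie in [0, 0.5)")
    out = assay.copy()
    k = math.ceil(fraction * assay.n)
    if k == 0:
        out.modified_idx = np.array([], dtype=int)
        return out
    rng = np.random.default_rng(seed)
    finite = assay.values[~np.isnan(assay.values)]
    sd = float(np.std(finite, ddof=1)) if finite.size > 1 else 0.0
    idx = rng.choice(assay.n, size=k, replace=False)
    out.values[idx] = out.values[idx] + offset_sd * sd
    out.modified_idx = np.sort(idx)
    return out


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

def generate_cohort(config: CohortConfig) -> Cohort:
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants

    cov = _draw_covariates(config, rng)
    feats = _feature_matrix(cov)

    eta = np.zeros(n)
    for name, w in config.confounding_weights.items():
        eta += w * feats[name].to_numpy()
    intercept = _calibrate_intercept(eta, config.statin_prevalence)
    p_statin = 1.0 / (1.0 + np.exp(-(intercept + eta)))
    statin = rng.binomial(1, p_statin)

    names = config.protein_names()
    feat_mat = feats.to_numpy()
    panel: list[ProteinAssay] = []
    contam_frac, contam_offset = config.contamination
    contamination_indices: dict[str, list[int]] = {}
    for name in names:
        b0 = rng.normal(0.0, config.protein_intercept_sd)
        g = np.zeros(feat_mat.shape[1])
        if config.covariate_effect_map is not None and name in config.covariate_effect_map:
            for feat, coef in config.covariate_effect_map[name].items():
                g[feats.columns.get_loc(feat)] = coef
        else:
            draws = rng.normal(0.0, config.covariate_effect_sd, len(ADJUSTED_FEATURES))
            for feat, coef in zip(ADJUSTED_FEATURES, draws):
                g[feats.columns.get_loc(feat)] = coef
        beta = config.effect_map.get(name, 0.0)
        noise = (
            rng.normal(0.0, config.protein_noise_sd, n)
            if config.protein_noise_sd > 0
            else np.zeros(n)
        )
        y = b0 + feat_mat @ g + beta * statin + noise
        if contam_frac > 0:
            k = math.ceil(contam_frac * n)
            idx = rng.choice(n, size=k, replace=False)
            y[idx] = y[idx] + contam_offset * config.protein_noise_sd
            contamination_indices[name] = sorted(int(i) for i in idx)
        assay = ProteinAssay(protein_name=name, values=y)
        q = config.lod_quantile_map.get(name, 0.0)
        assay = censor_at_lod(assay, q) if q > 0 else assay
        panel.append(assay)

    # duplicate assays: the original plus a technical replicate in one group
    by_name = {a.protein_name: a for a in panel}
    for protein, cv_a, cv_b, n_below_a, n_below_b in config.duplicate_spec:
        base = by_name[protein]
        rep_values = base.values + rng.normal(0.0, 0.25 * config.protein_noise_sd or 0.05, n)
        rep = ProteinAssay(protein_name=f"{protein}_dup", values=rep_values)
        base.duplicate_group = protein
        rep.duplicate_group = protein
        base.inter_assay_cv = float(cv_a)
        rep.inter_assay_cv = float(cv_b)
        for target, n_below in ((base, n_below_a), (rep, n_below_b)):
            frac = min(max(n_below / n, 0.0), 1.0)
            censored = censor_at_lod(target, frac)
            target.lod = censored.lod
            target.below_lod_mask = censored.below_lod_mask
        panel.append(rep)

    participants = cov.copy()
    participants.insert(0, "statin_use", statin)
    prefix = config.study_label[:3].upper()
    participants.insert(0, "participant_id", [f"{prefix}-{i:05d}" for i in range(1, n + 1)])
    participants = participants.loc[:, list(PARTICIPANT_COLUMNS)]

    if config.missing_fraction > 0:
        covariate_cols = [c for c in PARTICIPANT_COLUMNS if c not in ("participant_id", "statin_use")]
        mask = rng.random((n, len(covariate_cols))) < config.missing_fraction
        for j, col in enumerate(covariate_cols):
            col_mask = mask[:, j]
            if col_mask.any():
                if participants[col].dtype == object:
                    participants.loc[col_mask, col] = None
                else:
                    participants[col] = participants[col].astype(float)
                    participants.loc[col_mask, col] = np.nan

    truth = {name: config.effect_map.get(name, 0.0) for name in names}
    return Cohort(
        study_label=config.study_label,
        participants=participants,
        panel=panel,
        truth=truth,
        provenance={
            "seed": config.seed,
            "statin_logit_intercept": intercept,
            "contamination_indices": contamination_indices,
        },
    )
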