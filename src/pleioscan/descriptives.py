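"""Baseline-table machinery: median/IQR summaries, Wilcoxon rank-sum and
Pearson chi-square tests stratified by statin use."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import ConfigurationError, DataError
from .assay import BINARY_FLAGS, CATEGORICAL_LEVELS, CONTINUOUS_COVARIATES, Cohort

VARIABLE_KIND = {
    **{c: "continuous" for c in CONTINUOUS_COVARIATES},
    **{c: "categorical" for c in CATEGORICAL_LEVELS},
    **{c: "categorical" for c in BINARY_FLAGS},
}

DEFAULT_TABLE_VARIABLES = (
    "age", "bmi", "alcohol", "systolic_bp",
    "sex", "education", "smoking", "physical_activity",
    "hypertension", "diabetes", "myocardial_infarction", "stroke", "cancer",
)


def median_iqr(values) -> tuple[float, float, float]:
    """Median and quartiles with the h = (n-1)p + 1 linear-interpolation rule."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise DataError("median_iqr: no non-missing values")
    med, q1, q3 = np.percentile(v, [50, 25, 75])
    return float(med), float(q1), float(q3)


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact enumeration when both groups have <= 50 observations and there are
    no ties; otherwise the normal approximation with tie-corrected variance
    and continuity correction. Returns ``(U, p)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if x.size == 0 or y.size == 0:
        raise DataError("wilcoxon_rank_sum: both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        warnings.warn("wilcoxon_rank_sum: zero variance in pooled sample; p = 1")
        return float(x.size * y.size / 2.0), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size <= 50 and y.size <= 50 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def pearson_chi_square(table) -> tuple[float, int, float]:
    """Classical Pearson chi-square test of independence, no continuity
    correction. ``table`` is an r x c array of counts (c = 2 strata here).

    Returns ``(statistic, df, p)``.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise DataError("pearson_chi_square: need an r x c table with r, c >= 2")
    if (obs < 0).any():
        raise DataError("pearson_chi_square: negative counts")
    total = obs.sum()
    if total <= 0:
        raise DataError("pearson_chi_square: empty table")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any():
        bad = int(np.flatnonzero(row == 0)[0])
        raise DataError(f"pearson_chi_square: row margin zero at level index {bad}")
    if (col == 0).any():
        bad = int(np.flatnonzero(col == 0)[0])
        raise DataError(f"pearson_chi_square: column margin zero at stratum index {bad}")
    expected = np.outer(row, col) / total
    statistic = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(stats.chi2.sf(statistic, df))
    return statistic, df, p


@dataclass
class BaselineRow:
    variable: str
    statin_summary: str
    no_statin_summary: str
    test: str  # "wilcoxon" | "chi_square"
    statistic: float
    p_value: float
    n_used: int


@dataclass
class BaselineTable:
    study_label: str
    rows: list[BaselineRow] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.rows])

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"study_label": self.study_label, "rows": [r.__dict__ for r in self.rows]},
                fh,
                indent=2,
            )
            fh.write("\n")


def _fmt(v: float) -> str:
    return f"{v:.3f}".rstrip("0").rstrip(".") if np.isfinite(v) else ""


def build_baseline_table(cohort: Cohort, variables=DEFAULT_TABLE_VARIABLES) -> BaselineTable:
    """One row per variable, stratified by statin use: continuous variables
    get median (IQR) + Wilcoxon, categorical get counts (fractions) +
    chi-square. Denominators are per-variable complete cases."""
    df = cohort.participants
    strat = df["statin_use"].to_numpy()
    if set(np.unique(strat[~pd.isna(strat)])) != {0, 1}:
        raise DataError("build_baseline_table: statin_use stratifier is degenerate")

    table = BaselineTable(study_label=cohort.study_label)
    for var in variables:
        if var not in VARIABLE_KIND:
            raise ConfigurationError(f"unknown baseline variable {var!r}")
        col = df[var]
        ok = ~pd.isna(col)
        n_used = int(ok.sum())
        if VARIABLE_KIND[var] == "continuous":
            x = col[ok & (strat == 1)].to_numpy(dtype=float)
            y = col[ok & (strat == 0)].to_numpy(dtype=float)
            stat, p = wilcoxon_rank_sum(x, y)
            mx, q1x, q3x = median_iqr(x)
            my, q1y, q3y = median_iqr(y)
            row = BaselineRow(
                variable=var,
                statin_summary=f"{_fmt(mx)} ({_fmt(q1x)}; {_fmt(q3x)})",
                no_statin_summary=f"{_fmt(my)} ({_fmt(q1y)}; {_fmt(q3y)})",
                test="wilcoxon",
                statistic=stat,
                p_value=p,
                n_used=n_used,
            )
        else:
            levels = (
                CATEGORICAL_LEVELS.get(var)
                or tuple(sorted(pd.unique(col[ok])))
            )
            counts = np.array(
                [
                    [int(((col == lvl) & ok & (strat == g)).sum()) for g in (1, 0)]
                    for lvl in levels
                ]
            )
            observed = counts[counts.sum(axis=1) > 0]  # drop empty levels
            if observed.shape[0] < 2:
                raise DataError(f"build_baseline_table: variable {var!r} is degenerate")
            stat, _df, p = pearson_chi_square(observed)
            n1 = counts[:, 0].sum()
            n0 = counts[:, 1].sum()
            def cell(c, tot):
                return "; ".join(
                    f"{lvl}: {cnt} ({cnt / tot:.3f})" for lvl, cnt in zip(levels, c) if tot
                )
            row = BaselineRow(
                variable=var,
                statin_summary=cell(counts[:, 0], n1),
                no_statin_summary=cell(counts[:, 1], n0),
                test="chi_square",
                statistic=stat,
                p_value=p,
                n_used=n_used,
            )
        table.rows.append(row)
    return table
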