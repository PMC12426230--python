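"""Multiple-testing adjustment, E-value robustness quantification, and
cross-cohort replication classification.

FDR scope is per study (the two panels are adjusted separately). E-values
convert the standardized mean difference d = beta / SD(outcome) to an
approximate risk ratio exp(0.91 * d) and then apply the closed form
EV = rr* + sqrt(rr* * (rr* - 1)) with rr* the ratio moved away from 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from ._errors import ConfigurationError, DataError
from .association_models import FitResult


@dataclass
class InferenceConfig:
    alpha: float = 0.05
    fdr_scope: str = "per_study"
    evalue_effect_scale: str = "standardized_outcome"

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if self.fdr_scope != "per_study":
            raise ConfigurationError("fdr_scope is fixed to 'per_study'")
        if self.evalue_effect_scale != "standardized_outcome":
            raise ConfigurationError("evalue_effect_scale is fixed to 'standardized_outcome'")


@dataclass
class EValueResult:
    rr_approx: float
    ev_point: float
    ev_ci: float


@dataclass
class AssociationResult:
    protein: str
    study_label: str
    fit: FitResult
    quantile_fit: Optional[FitResult] = None
    q_value: Optional[float] = None
    evalue: Optional[EValueResult] = None
    notable: bool = False

    def to_row(self) -> dict:
        row = {"protein": self.protein, "study_label": self.study_label}
        row.update(self.fit.to_row())
        row["q_value"] = self.q_value
        row["notable"] = int(self.notable)
        if self.evalue is not None:
            row["rr_approx"] = self.evalue.rr_approx
            row["ev_point"] = self.evalue.ev_point
            row["ev_ci"] = self.evalue.ev_ci
        else:
            row["rr_approx"] = row["ev_point"] = row["ev_ci"] = None
        return row


@dataclass
class ReplicationVerdict:
    protein: str
    category: str  # replicated | suggestive | inconsistent | null
    discovery: Optional[AssociationResult] = None
    replication: Optional[AssociationResult] = None
    single_study: bool = False


def adjust_fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise DataError("adjust_fdr_bh: p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def _ev_from_rr(rr: float) -> float:
    rr_star = max(rr, 1.0 / rr)
    return rr_star + np.sqrt(rr_star * (rr_star - 1.0))


def evalue_from_continuous(
    beta: float, ci_low: float, ci_high: float, outcome_sd: float
) -> EValueResult:
    """E-values for a continuous-outcome effect via the standardized-
    difference / approximate-risk-ratio route (factor 0.91).

    ``ev_ci`` uses the CI limit closer to the null and is 1 whenever the CI
    spans zero.
    """
    if not outcome_sd > 0:
        raise DataError("evalue_from_continuous: outcome_sd must be > 0")
    if not ci_low <= beta <= ci_high:
        raise DataError("evalue_from_continuous: require ci_low <= beta <= ci_high")
    d = beta / outcome_sd
    rr = float(np.exp(0.91 * d))
    ev_point = float(_ev_from_rr(rr)) if rr != 1.0 else 1.0
    if ci_low <= 0.0 <= ci_high:
        ev_ci = 1.0
    else:
        limit = ci_low if beta > 0 else ci_high
        rr_limit = float(np.exp(0.91 * limit / outcome_sd))
        ev_ci = float(_ev_from_rr(rr_limit))
    return EValueResult(rr_approx=rr, ev_point=ev_point, ev_ci=ev_ci)


def annotate_inference(
    results: list[AssociationResult], config: InferenceConfig | None = None
) -> list[AssociationResult]:
    """Fill q-values, notability flags and E-values in place (per study)."""
    config = config or InferenceConfig()
    config.validate()
    if not results:
        return results
    labels = {r.study_label for r in results}
    if len(labels) > 1:
        raise DataError("annotate_inference: results span multiple studies; adjust per study")
    q = adjust_fdr_bh([r.fit.p_value for r in results])
    for r, qv in zip(results, q):
        r.q_value = float(qv)
        r.notable = bool(qv <= config.alpha)
        r.evalue = evalue_from_continuous(
            r.fit.beta, r.fit.ci_low, r.fit.ci_high, r.fit.outcome_sd
        )
    return results


def classify_replication(
    discovery: list[AssociationResult],
    replication: list[AssociationResult],
    config: InferenceConfig | None = None,
) -> list[ReplicationVerdict]:
    """Cross-cohort verdict per protein.

    replicated: notable in both with equal beta sign; suggestive: notable in
    exactly one, other study's sign agrees; inconsistent: signs differ and at
    least one notable; null otherwise. Proteins present in only one study are
    classified from that study alone and flagged.
    """
    config = config or InferenceConfig()
    by_disc = _index_by_protein(discovery, "discovery")
    by_repl = _index_by_protein(replication, "replication")
    verdicts = []
    for protein in sorted(set(by_disc) | set(by_repl)):
        d = by_disc.get(protein)
        r = by_repl.get(protein)
        if d is None or r is None:
            only = d or r
            category = "suggestive" if only.notable else "null"
            verdicts.append(
                ReplicationVerdict(
                    protein=protein, category=category,
                    discovery=d, replication=r, single_study=True,
                )
            )
            continue
        same_sign = np.sign(d.fit.beta) == np.sign(r.fit.beta)
        n_notable = int(d.notable) + int(r.notable)
        if not same_sign and n_notable >= 1:
            category = "inconsistent"
        elif n_notable == 2 and same_sign:
            category = "replicated"
        elif n_notable == 1 and same_sign:
            category = "suggestive"
        else:
            category = "null"
        verdicts.append(
            ReplicationVerdict(protein=protein, category=category, discovery=d, replication=r)
        )
    return verdicts


def _index_by_protein(results: list[AssociationResult], label: str) -> dict:
    out: dict[str, AssociationResult] = {}
    for r in results:
        if r.protein in out:
            raise DataError(f"duplicate protein key {r.protein!r} in {label} results")
        out[r.protein] = r
    return out


def verdicts_to_dataframe(verdicts: list[ReplicationVerdict]) -> pd.DataFrame:
    rows = []
    for v in verdicts:
        row = {"protein": v.protein, "category": v.category, "single_study": int(v.single_study)}
        for tag, res in (("discovery", v.discovery), ("replication", v.replication)):
            if res is None:
                continue
            row[f"{tag}_beta"] = res.fit.beta
            row[f"{tag}_ci_low"] = res.fit.ci_low
            row[f"{tag}_ci_high"] = res.fit.ci_high
            row[f"{tag}_p"] = res.fit.p_value
            row[f"{tag}_q"] = res.q_value
            if res.evalue is not None:
                row[f"{tag}_ev_point"] = res.evalue.ev_point
                row[f"{tag}_ev_ci"] = res.evalue.ev_ci
        rows.append(row)
    return pd.DataFrame(rows)


def verdict_summary(verdicts: list[ReplicationVerdict]) -> dict:
    counts: dict[str, int] = {}
    for v in verdicts:
        counts[v.category] = counts.get(v.category, 0) + 1
    return counts


def write_verdicts(verdicts: list[ReplicationVerdict], tsv_path: str | Path, json_path: str | Path) -> None:
    verdicts_to_dataframe(verdicts).to_csv(tsv_path, sep="\t", index=False)
    with open(json_path, "w") as fh:
        json.dump(verdict_summary(verdicts), fh, indent=2, sort_keys=True)
        fh.write("\n")
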