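"""Panel-level quality control.

Rules applied per cohort: drop proteins whose below-LOD fraction (among
non-missing values) strictly exceeds the threshold, drop all-missing
proteins, resolve duplicate assays (fewer below-LOD values first, lower
inter-assay CV as tie-break), then substitute remaining below-LOD values
with the LOD itself.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._errors import ConfigurationError, DataError
from .assay import ProteinAssay

logger = logging.getLogger(__name__)


@dataclass
class QCConfig:
    max_below_lod_fraction: float = 0.25
    substitute_with_lod: bool = True

    def validate(self) -> None:
        if not 0 < self.max_below_lod_fraction < 1:
            raise ConfigurationError("max_below_lod_fraction must lie in (0, 1)")


@dataclass
class QCReport:
    n_input: int
    n_retained: int
    excluded: list = field(default_factory=list)  # (protein_name, reason)
    duplicate_decisions: list = field(default_factory=list)  # (group, kept, dropped, criterion)

    def __post_init__(self) -> None:
        if self.n_input != self.n_retained + len(self.excluded):
            raise DataError("QCReport inconsistent: n_input != n_retained + |excluded|")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "excluded": [list(e) for e in self.excluded],
            "duplicate_decisions": [list(d) for d in self.duplicate_decisions],
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


def _below_lod_count(assay: ProteinAssay) -> int:
    ok = ~np.isnan(assay.values)
    return int(assay.below_lod_mask[ok].sum())


def filter_panel(panel: list[ProteinAssay], config: QCConfig | None = None):
    """Apply the exclusion and duplicate-resolution rules.

    Returns ``(retained_panel, QCReport)``. Exclusion reasons are one of
    ``lod_fraction``, ``all_missing``, ``duplicate_dropped``; every decision
    is enumerated in the report. Idempotent.
    """
    config = config or QCConfig()
    config.validate()
    if not panel:
        raise DataError("filter_panel: empty panel")

    excluded: list[tuple[str, str]] = []
    survivors: list[ProteinAssay] = []
    for assay in panel:
        ok = ~np.isnan(assay.values)
        if not ok.any():
            excluded.append((assay.protein_name, "all_missing"))
            continue
        frac = assay.below_lod_fraction()
        if frac > config.max_below_lod_fraction:
            excluded.append((assay.protein_name, "lod_fraction"))
            continue
        survivors.append(assay)

    # duplicate resolution among survivors only
    groups: dict[str, list[ProteinAssay]] = {}
    for assay in survivors:
        if assay.duplicate_group:
            groups.setdefault(assay.duplicate_group, []).append(assay)

    duplicate_decisions = []
    dropped_names = set()
    for group, members in groups.items():
        if len(members) < 2:
            continue
        ranked = sorted(
            members,
            key=lambda a: (_below_lod_count(a), _cv_key(a), a.protein_name),
        )
        keep = ranked[0]
        runner = ranked[1]
        if _below_lod_count(keep) < _below_lod_count(runner):
            criterion = "fewer_below_lod"
        elif _cv_key(keep) < _cv_key(runner):
            criterion = "lower_cv"
        else:
            criterion = "lexicographic"
            logger.warning(
                "duplicate group %s: tied below-LOD counts and CVs; keeping %s by name",
                group, keep.protein_name,
            )
        for other in ranked[1:]:
            excluded.append((other.protein_name, "duplicate_dropped"))
            dropped_names.add(other.protein_name)
            duplicate_decisions.append((group, keep.protein_name, other.protein_name, criterion))

    retained = [a for a in survivors if a.protein_name not in dropped_names]
    report = QCReport(
        n_input=len(panel),
        n_retained=len(retained),
        excluded=excluded,
        duplicate_decisions=duplicate_decisions,
    )
    return retained, report


def _cv_key(assay: ProteinAssay) -> float:
    cv = assay.inter_assay_cv
    return float("inf") if cv is None or math.isnan(cv) else float(cv)


def impute_below_lod(assay: ProteinAssay) -> ProteinAssay:
    """Replace every masked value by the LOD; the mask is kept for provenance."""
    if not math.isfinite(assay.lod):
        raise DataError(f"impute_below_lod: {assay.protein_name} has non-finite LOD")
    out = assay.copy()
    out.values[out.below_lod_mask] = out.lod
    return out


def apply_qc(panel: list[ProteinAssay], config: QCConfig | None = None):
    """filter_panel + LOD substitution in one call (pipeline convenience)."""
    config = config or QCConfig()
    retained, report = filter_panel(panel, config)
    if config.substitute_with_lod:
        retained = [
            impute_below_lod(a) if math.isfinite(a.lod) and a.below_lod_mask.any() else a
            for a in retained
        ]
    return retained, report
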