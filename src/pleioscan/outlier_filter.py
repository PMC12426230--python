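"""Iterative SD-ratio outlier detection.

Each iteration removes the most extreme value at whichever end shrinks the
sample standard deviation the most, provided the post/pre SD ratio
s_{n-1}/s_n falls below the threshold (default 0.95); iteration stops when
neither end qualifies, or when safeguards (minimum n, maximum removal
fraction) would be violated. A single-pass mean±3·SD comparator is provided
as the alternative the main method is benchmarked against.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Literal, Optional

import numpy as np

from ._errors import ConfigurationError, DataError


@dataclass
class OutlierConfig:
    ratio_threshold: float = 0.95
    min_n: int = 50
    max_removal_fraction: float = 0.05
    comparator: Literal["sd_ratio", "mean_3sd"] = "sd_ratio"

    def validate(self) -> None:
        if not 0 < self.ratio_threshold < 1:
            raise ConfigurationError("ratio_threshold must lie in (0, 1)")
        if not 0 < self.max_removal_fraction < 0.5:
            raise ConfigurationError("max_removal_fraction must lie in (0, 0.5)")
        if self.min_n < 3:
            raise ConfigurationError("min_n must be >= 3")
        if self.comparator not in ("sd_ratio", "mean_3sd"):
            raise ConfigurationError(f"unknown comparator {self.comparator!r}")


@dataclass
class OutlierStep:
    iteration: int
    end_tested: str  # "min" | "max"
    s_n: float
    s_n_minus_1: float
    ratio: float
    flagged_value: Optional[float]

    def to_json_line(self) -> str:
        return json.dumps(asdict(self))


def sd_ratio_step(values, end: str) -> OutlierStep:
    """SD before vs after removing the single extreme at the stated end.

    Sample SDs use the n-1 denominator. If the values are constant the ratio
    is 1 and nothing is flagged.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise DataError("sd_ratio_step needs at least 3 values")
    if not np.isfinite(v).all():
        raise DataError("sd_ratio_step: non-finite values")
    if end not in ("min", "max"):
        raise ConfigurationError(f"end must be 'min' or 'max', got {end!r}")
    s_n = float(np.std(v, ddof=1))
    if s_n == 0.0:
        return OutlierStep(0, end, 0.0, 0.0, 1.0, None)
    idx = int(np.argmin(v)) if end == "min" else int(np.argmax(v))
    rest = np.delete(v, idx)
    s_nm1 = float(np.std(rest, ddof=1))
    return OutlierStep(0, end, s_n, s_nm1, s_nm1 / s_n, float(v[idx]))


def detect_outliers(values, config: OutlierConfig | None = None):
    """Return ``(flags, trace)`` with flags aligned to the input positions.

    Missing values (NaN) are ignored and never flagged. Safeguards: the
    retained count never falls below ``min_n`` and at most
    ``floor(max_removal_fraction * n_initial)`` points are removed.
    """
    config = config or OutlierConfig()
    config.validate()
    v = np.asarray(values, dtype=float)
    flags = np.zeros(v.shape, dtype=bool)
    present = ~np.isnan(v)
    if not np.isfinite(v[present]).all():
        raise DataError("detect_outliers: infinite values in input")
    idx_map = np.flatnonzero(present)
    work = v[present].copy()

    if config.comparator == "mean_3sd":
        if work.size < 2:
            return flags, []
        mu = work.mean()
        sd = work.std(ddof=1)
        if sd > 0:
            out = np.abs(work - mu) > 3.0 * sd
            flags[idx_map[out]] = True
        return flags, []

    n_initial = work.size
    max_removals = int(np.floor(config.max_removal_fraction * n_initial))
    trace: list[OutlierStep] = []
    removed = 0
    iteration = 0
    while (
        removed < max_removals
        and work.size - 1 >= config.min_n
        and work.size >= 3
    ):
        iteration += 1
        step_min = sd_ratio_step(work, "min")
        step_max = sd_ratio_step(work, "max")
        # smaller ratio = larger SD reduction; ties go to the max end
        step = step_max if step_max.ratio <= step_min.ratio else step_min
        step.iteration = iteration
        trace.append(step)
        if step.flagged_value is None or step.ratio >= config.ratio_threshold:
            break
        end_idx = int(np.argmin(work)) if step.end_tested == "min" else int(np.argmax(work))
        flags[idx_map[end_idx]] = True
        work = np.delete(work, end_idx)
        idx_map = np.delete(idx_map, end_idx)
        removed += 1
    return flags, trace


def write_trace(trace: list[OutlierStep], path: str | Path, protein: str | None = None) -> None:
    """Append one JSON line per step (audit trail)."""
    with open(path, "a") as fh:
        for step in trace:
            rec = asdict(step)
            if protein is not None:
                rec["protein"] = protein
            fh.write(json.dumps(rec) + "\n")
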