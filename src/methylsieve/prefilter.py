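"""Biomarker-assumption prefilter for two-group percent-methylation data.

Before the (expensive) bootstrap selection loop, each probe is screened
against three per-group criteria, evaluated for both groups (six tests):

1. the 95% confidence interval of the group spans less than 40 percent
   points of methylation (default reading: CI of the group mean,
   ``2 * z_{0.975} * SD / sqrt(n)``; a config flag switches to the 95%
   population-spread reading ``2 * z * SD``);
2. the group mean is extreme: below 10% or above 90% methylation;
3. the group SD is below 40 percent points.

A probe survives when at least 4 of the 6 tests pass **and** the absolute
between-group mean difference is at least 10 percent points.

With cohort-sized groups the mean-CI reading makes criterion 1 easy to
pass, so the 10% mean-difference rule carries most of the screening
(roughly three quarters of uniform-noise probes fail it).  This weak
screen is deliberate: the surviving noise probes anchor the zero mode of
the downstream bootstrap score distribution, which is what lets Otsu's
threshold split signal from background rather than splitting the signal
tiers apart.  The population-spread reading is much stricter (it removes
the background entirely) and is available for probe-economical screening
outside the validation design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import MethylationDataset

logger = logging.getLogger(__name__)

__all__ = ["PrefilterConfig", "CriterionChecks", "criterion_checks",
           "biomarker_prefilter"]


@dataclass(frozen=True)
class PrefilterConfig:
    ci_level: float = 0.95
    ci_span_limit: float = 40.0       # percent points
    extreme_mean_low: float = 10.0    # percent
    extreme_mean_high: float = 90.0   # percent
    sd_limit: float = 40.0            # percent points
    min_criteria_passes: int = 4      # of the 6 group-wise tests
    min_mean_diff: float = 10.0       # percent points, absolute
    ci_mode: str = "mean"             # "mean" (2*z*SD/sqrt(n)) or "population" (2*z*SD)

    def __post_init__(self) -> None:
        for name in ("ci_span_limit", "extreme_mean_low", "extreme_mean_high",
                     "sd_limit"):
            v = getattr(self, name)
            if not (0.0 < v < 100.0):
                raise ValueError(f"{name} must lie in (0, 100), got {v}")
        if not (1 <= self.min_criteria_passes <= 6):
            raise ValueError("min_criteria_passes must be in 1..6")
        if self.ci_mode not in ("population", "mean"):
            raise ValueError("ci_mode must be 'population' or 'mean'")

    @property
    def z(self) -> float:
        return float(stats.norm.ppf(0.5 + self.ci_level / 2.0))


@dataclass(frozen=True)
class CriterionChecks:
    """The six boolean tests for one probe (three per group)."""

    control: tuple[bool, bool, bool]   # (narrow spread, extreme mean, low SD)
    positive: tuple[bool, bool, bool]

    @property
    def n_passes(self) -> int:
        return sum(self.control) + sum(self.positive)


def _group_criteria(values: np.ndarray, config: PrefilterConfig, axis: int = -1
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = values.mean(axis=axis)
    sd = values.std(axis=axis, ddof=1)
    n = values.shape[axis]
    span = 2.0 * config.z * sd
    if config.ci_mode == "mean":
        span = span / np.sqrt(n)
    c1 = span < config.ci_span_limit
    c2 = (mean < config.extreme_mean_low) | (mean > config.extreme_mean_high)
    c3 = sd < config.sd_limit
    return c1, c2, c3


def criterion_checks(control_values, positive_values,
                     config: PrefilterConfig | None = None) -> CriterionChecks:
    """Evaluate the six biomarker criteria for a single probe."""
    config = config or PrefilterConfig()
    out = []
    for vals in (control_values, positive_values):
        arr = np.asarray(vals, dtype=float)
        if arr.size < 2:
            raise ValueError("each group needs at least 2 values")
        c1, c2, c3 = _group_criteria(arr, config)
        out.append((bool(c1), bool(c2), bool(c3)))
    return CriterionChecks(control=out[0], positive=out[1])


def biomarker_prefilter(dataset: MethylationDataset,
                        config: PrefilterConfig | None = None
                        ) -> tuple[MethylationDataset, pd.DataFrame]:
    """Screen all probes of a two-group percent-scale dataset.

    Returns the surviving dataset and a per-probe report with the six
    criterion booleans, the pass count, the absolute group mean difference
    and the keep decision.
    """
    config = config or PrefilterConfig()
    if dataset.scale != "percent":
        raise ValueError("biomarker_prefilter expects percent-scale data")
    groups = dataset.group_names()
    if len(groups) != 2:
        raise ValueError(f"prefilter needs exactly two groups, got {groups}")
    ga, gb = groups
    X = dataset.values.to_numpy(dtype=float)
    mask_a = (dataset.groups == ga).to_numpy()
    mask_b = (dataset.groups == gb).to_numpy()
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError("each group needs at least 2 samples")

    a1, a2, a3 = _group_criteria(X[:, mask_a], config)
    b1, b2, b3 = _group_criteria(X[:, mask_b], config)
    n_passes = (a1.astype(int) + a2 + a3 + b1 + b2 + b3)
    mean_diff = np.abs(X[:, mask_a].mean(axis=1) - X[:, mask_b].mean(axis=1))
    kept = (n_passes >= config.min_criteria_passes) & (mean_diff >= config.min_mean_diff)

    report = pd.DataFrame({
        f"c1_{ga}": a1, f"c2_{ga}": a2, f"c3_{ga}": a3,
        f"c1_{gb}": b1, f"c2_{gb}": b2, f"c3_{gb}": b3,
        "n_passes": n_passes, "mean_diff": mean_diff, "kept": kept,
    }, index=dataset.probe_ids)
    logger.info("prefilter kept %d / %d probes", int(kept.sum()), len(kept))
    out = dataset.subset_probes(dataset.probe_ids[kept])
    out.metadata["prefilter_kept"] = int(kept.sum())
    return out, report
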