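"""Synthetic methylome generation for validating probe selection.

The validation design plants a handful of truly differential CpG probes in
a large uniform background and asks the selection pipeline to recover them:

* background probes draw every sample's percent-methylation i.i.d. uniform
  on [0, 100] — pure noise with no group structure;
* signal probes come in three discriminability tiers, each defined by a
  range for the between-group mean difference and a range for the
  within-group standard deviation (percent points):

  ========  ===========  =========  ========
  tier      mean diff    group SD   n probes
  ========  ===========  =========  ========
  high      25-40        6-8        5
  medium    15-30        8-10       10
  low       10-20        10-12      15
  ========  ===========  =========  ========

The cohort is 25 control + 25 positive samples.  This module also
generates the uniform "variance-stress" samples used for model sensitivity
analysis: for each probe and group, values uniform on
``[mu - A*sigma, mu + A*sigma]`` in M-value units, where ``A`` scales how
far samples may stray from the group mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import BACKGROUND, MethylationDataset, TruthTable

logger = logging.getLogger(__name__)

__all__ = [
    "SignalSpec", "SyntheticConfig", "SensitivitySampleSpec",
    "DEFAULT_SIGNAL_SPECS", "generate_background", "generate_signal_probes",
    "generate_validation_dataset", "generate_sensitivity_samples",
]


@dataclass(frozen=True)
class SignalSpec:
    """One tier of planted differential probes."""

    tier: str
    diff_range: tuple[float, float]   # between-group mean difference, % points
    sd_range: tuple[float, float]     # within-group SD, % points
    n_probes: int

    def __post_init__(self) -> None:
        lo, hi = self.diff_range
        if not (0.0 < lo <= hi < 100.0):
            raise ValueError(f"diff_range must satisfy 0 < lo <= hi < 100, got ({lo}, {hi})")
        lo, hi = self.sd_range
        # a degenerate SD of 0 is allowed (noise-free probes, useful for tests)
        if not (0.0 <= lo <= hi < 100.0):
            raise ValueError(f"sd_range must satisfy 0 <= lo <= hi < 100, got ({lo}, {hi})")
        if self.n_probes < 1:
            raise ValueError("n_probes must be positive")
        # group means are placed in [3s, 100-3s]; both means must fit
        if self.diff_range[1] + 6.0 * self.sd_range[1] > 100.0:
            raise ValueError(
                f"tier {self.tier!r}: diff up to {self.diff_range[1]} with SD up to "
                f"{self.sd_range[1]} cannot place both group means inside [3s, 100-3s]")


DEFAULT_SIGNAL_SPECS: tuple[SignalSpec, ...] = (
    SignalSpec("high", (25.0, 40.0), (6.0, 8.0), 5),
    SignalSpec("medium", (15.0, 30.0), (8.0, 10.0), 10),
    SignalSpec("low", (10.0, 20.0), (10.0, 12.0), 15),
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Layout of the full validation methylome."""

    n_background: int = 1_000_000
    n_per_group: int = 25
    signal_specs: tuple[SignalSpec, ...] = DEFAULT_SIGNAL_SPECS


def _sample_ids(n_per_group: int) -> tuple[list[str], pd.Series]:
    ids = [f"ctrl_{i + 1:03d}" for i in range(n_per_group)] + \
          [f"pos_{i + 1:03d}" for i in range(n_per_group)]
    groups = pd.Series(["control"] * n_per_group + ["positive"] * n_per_group,
                       index=ids, name="group")
    return ids, groups


def generate_background(n_probes: int, n_per_group: int = 25,
                        seed: int | None = None,
                        rng: np.random.Generator | None = None
                        ) -> MethylationDataset:
    """Uniform-noise probes: every value i.i.d. U(0, 100)."""
    if n_probes < 1:
        raise ValueError("n_probes must be >= 1")
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if rng is None:
        rng = np.random.default_rng(seed)
    ids, groups = _sample_ids(n_per_group)
    vals = rng.uniform(0.0, 100.0, size=(n_probes, 2 * n_per_group))
    probes = pd.Index([f"bg_{i + 1:07d}" for i in range(n_probes)])
    df = pd.DataFrame(vals, index=probes, columns=ids)
    return MethylationDataset(df, "percent", groups,
                              metadata={"seed": seed, "kind": "background"})


def generate_signal_probes(spec: SignalSpec, n_per_group: int = 25,
                           seed: int | None = None,
                           rng: np.random.Generator | None = None
                           ) -> tuple[MethylationDataset, TruthTable]:
    """Planted differential probes for one tier.

    Per probe, a target mean difference ``d`` and a shared group SD ``s``
    are drawn uniformly from the tier's ranges.  The lower group mean is
    placed uniformly so that both means lie in ``[3s, 100-3s]`` (keeping
    normal draws effectively clear of the bounds), the direction of the
    difference is randomized, and per-sample values are normal with the
    group mean and SD, truncated to (0, 100).  Truncation resamples rather
    than clips: an atom at exactly 0 or 100 would become an infinite
    M-value downstream and discard the probe wholesale, which is not what
    a planted biomarker is meant to emulate.  With the 3s placement rule
    truncation perturbs the target moments negligibly.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if rng is None:
        rng = np.random.default_rng(seed)
    ids, groups = _sample_ids(n_per_group)
    n = spec.n_probes
    d = rng.uniform(*spec.diff_range, size=n)
    s = rng.uniform(*spec.sd_range, size=n)
    lo = 3.0 * s
    hi = 100.0 - 3.0 * s - d
    base = rng.uniform(lo, hi)
    flip = rng.random(n) < 0.5
    mean_control = np.where(flip, base + d, base)
    mean_positive = np.where(flip, base, base + d)

    vals = np.empty((n, 2 * n_per_group))
    vals[:, :n_per_group] = rng.normal(mean_control[:, None], s[:, None],
                                       size=(n, n_per_group))
    vals[:, n_per_group:] = rng.normal(mean_positive[:, None], s[:, None],
                                       size=(n, n_per_group))
    means = np.concatenate([np.repeat(mean_control[:, None], n_per_group, axis=1),
                            np.repeat(mean_positive[:, None], n_per_group, axis=1)],
                           axis=1)
    sds = np.repeat(s[:, None], 2 * n_per_group, axis=1)
    # truncation by resampling (rare: means sit >= 3 SD from the bounds);
    # zero-SD probes sit exactly at their means and are left alone
    out_of_range = ((vals <= 0.0) | (vals >= 100.0)) & (sds > 0.0)
    while out_of_range.any():
        idx = np.where(out_of_range)
        vals[idx] = rng.normal(means[idx], sds[idx])
        out_of_range = ((vals <= 0.0) | (vals >= 100.0)) & (sds > 0.0)

    probes = pd.Index([f"sig_{spec.tier}_{i + 1:03d}" for i in range(n)])
    df = pd.DataFrame(vals, index=probes, columns=ids)
    ds = MethylationDataset(df, "percent", groups,
                            metadata={"seed": seed, "kind": f"signal_{spec.tier}"})
    truth = TruthTable(pd.Series(spec.tier, index=probes))
    return ds, truth


def generate_validation_dataset(config: SyntheticConfig | None = None,
                                seed: int | None = None
                                ) -> tuple[MethylationDataset, TruthTable]:
    """Full validation methylome: uniform background + all signal tiers.

    A single RNG stream (from ``seed``) drives the whole dataset, so the
    same seed reproduces it bit for bit.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(seed)
    parts: list[pd.DataFrame] = []
    tiers: list[pd.Series] = []
    groups = None
    for spec in config.signal_specs:
        ds, truth = generate_signal_probes(spec, config.n_per_group, rng=rng)
        parts.append(ds.values)
        tiers.append(truth.tiers)
        groups = ds.groups
    if config.n_background > 0:
        bg = generate_background(config.n_background, config.n_per_group, rng=rng)
        parts.append(bg.values)
        tiers.append(pd.Series(BACKGROUND, index=bg.values.index))
        groups = bg.groups
    if groups is None:
        raise ValueError("empty synthetic configuration")
    values = pd.concat(parts)
    if not values.index.is_unique:
        raise RuntimeError("duplicate probe IDs in synthetic dataset")
    truth = TruthTable(pd.concat(tiers))
    logger.info("synthetic validation dataset: %d probes x %d samples",
                values.shape[0], values.shape[1])
    return (MethylationDataset(values, "percent", groups,
                               metadata={"seed": seed, "kind": "validation"}),
            truth)


@dataclass
class SensitivitySampleSpec:
    """Per-probe, per-group location/scale for variance-stress sampling.

    ``mu`` and ``sigma`` are probe x group DataFrames in M-value units;
    ``width`` is the SD multiplier A; ``n_per_group`` samples are drawn per
    group.
    """

    mu: pd.DataFrame
    sigma: pd.DataFrame
    width: float
    n_per_group: int = 30

    def __post_init__(self) -> None:
        if self.width < 0:
            raise ValueError("width multiplier A must be >= 0")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if not self.mu.shape == self.sigma.shape:
            raise ValueError("mu and sigma must have identical shape")
        if (self.sigma.to_numpy() < 0).any():
            raise ValueError("sigma must be non-negative")


def generate_sensitivity_samples(spec: SensitivitySampleSpec,
                                 seed: int | None = None,
                                 rng: np.random.Generator | None = None
                                 ) -> MethylationDataset:
    """Uniform samples on ``[mu - A*sigma, mu + A*sigma]`` per probe/group."""
    if rng is None:
        rng = np.random.default_rng(seed)
    n = spec.n_per_group
    cols: list[str] = []
    labels: list[str] = []
    blocks: list[np.ndarray] = []
    for g, group in enumerate(spec.mu.columns):
        mu = spec.mu[group].to_numpy()[:, None]
        half = spec.width * spec.sigma[group].to_numpy()[:, None]
        block = rng.uniform(mu - half, mu + half, size=(spec.mu.shape[0], n))
        blocks.append(block)
        cols.extend(f"sens_{group}_{i + 1:03d}" for i in range(n))
        labels.extend([group] * n)
    values = pd.DataFrame(np.hstack(blocks), index=spec.mu.index, columns=cols)
    groups = pd.Series(labels, index=cols, name="group")
    return MethylationDataset(values, "mvalue", groups,
                              metadata={"seed": seed, "kind": "sensitivity",
                                        "width": spec.width})
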