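"""Preprocessing of methylation matrices.

Pipeline order for array data: annotation-based probe exclusion (SNPs,
sex chromosomes, undetected probes) on the measurement scale, log-odds
transform to M-values, removal of non-finite rows, empirical-Bayes batch
correction (ComBat), and another non-finite sweep.  Benjamini-Hochberg FDR
correction lives here too since both the selection loop and reporting use
it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .dataset import MethylationDataset

logger = logging.getLogger(__name__)

__all__ = ["ProbeAnnotation", "to_mvalues", "filter_probes", "drop_nonfinite",
           "combat_adjust", "bh_fdr"]


@dataclass
class ProbeAnnotation:
    """External per-probe annotation used for exclusion rules.

    ``table`` is indexed by probe ID with columns ``is_snp`` (bool) and
    ``chromosome`` (str); ``detection_p`` is an optional probe x sample
    DataFrame of Illumina detection p-values (large p = signal not above
    background).
    """

    table: pd.DataFrame
    detection_p: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        for col in ("is_snp", "chromosome"):
            if col not in self.table.columns:
                raise ValueError(f"annotation table lacks column {col!r}")
        if self.detection_p is not None:
            arr = self.detection_p.to_numpy()
            if np.nanmin(arr) < 0.0 or np.nanmax(arr) > 1.0:
                raise ValueError("detection p-values must lie in [0, 1]")


_SEX_CHROMS = {"x", "y", "chrx", "chry"}


def to_mvalues(dataset: MethylationDataset) -> MethylationDataset:
    """Log-odds transform: M = log2(beta / (1 - beta)).

    Percent values are divided by 100 first.  Fully (un)methylated probes
    produce ±inf, which downstream :func:`drop_nonfinite` removes.
    """
    if dataset.scale == "mvalue":
        warnings.warn("dataset already on M-value scale; returning unchanged copy")
        return dataset.with_values(dataset.values.copy())
    beta = dataset.values.to_numpy(dtype=float)
    if dataset.scale == "percent":
        beta = beta / 100.0
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.log2(beta / (1.0 - beta))
    n_nonfinite = int((~np.isfinite(m)).sum())
    if n_nonfinite:
        logger.info("M-value transform produced %d non-finite cells", n_nonfinite)
    out = pd.DataFrame(m, index=dataset.values.index, columns=dataset.values.columns)
    return dataset.with_values(out, scale="mvalue")


def filter_probes(dataset: MethylationDataset, annotation: ProbeAnnotation,
                  detect_alpha: float = 0.05) -> MethylationDataset:
    """Remove SNP-overlapping, sex-linked, and undetected probes.

    A probe is dropped if it is flagged as a SNP, sits on chromosome X/Y,
    or (when detection p-values are supplied) fails detection at
    ``detect_alpha`` in **any** sample — the strictest reading of "not
    statistically significantly detected".  Probes without an annotation
    row are kept with a warning.  Removal counts per rule are logged and
    recorded in ``metadata['filter_counts']``.
    """
    probes = dataset.probe_ids
    ann = annotation.table.reindex(probes)
    unannotated = ann["is_snp"].isna()
    if unannotated.any():
        logger.warning("%d probes lack annotation and are kept", int(unannotated.sum()))

    is_snp = ann["is_snp"].fillna(False).astype(bool).to_numpy()
    chrom = ann["chromosome"].fillna("").astype(str).str.lower()
    is_sex = chrom.isin(_SEX_CHROMS).to_numpy()
    undetected = np.zeros(len(probes), dtype=bool)
    if annotation.detection_p is not None:
        dp = annotation.detection_p.reindex(index=probes,
                                            columns=dataset.sample_ids)
        undetected = (dp.to_numpy() >= detect_alpha).any(axis=1)
        undetected &= ~dp.isna().all(axis=1).to_numpy()

    drop = is_snp | is_sex | undetected
    counts = {"snp": int(is_snp.sum()), "sex_linked": int(is_sex.sum()),
              "undetected": int(undetected.sum()),
              "removed_total": int(drop.sum()),
              "retained": int((~drop).sum())}
    logger.info("probe filtering: %s", counts)
    out = dataset.subset_probes(probes[~drop])
    out.metadata["filter_counts"] = counts
    return out


def drop_nonfinite(dataset: MethylationDataset) -> MethylationDataset:
    """Remove probe rows containing any non-finite M-value."""
    if dataset.scale != "mvalue":
        raise ValueError("drop_nonfinite expects an M-value dataset")
    finite = np.isfinite(dataset.values.to_numpy()).all(axis=1)
    n_drop = int((~finite).sum())
    if n_drop:
        logger.info("dropping %d probes with non-finite M-values", n_drop)
    out = dataset.subset_probes(dataset.probe_ids[finite])
    out.metadata["nonfinite_removed"] = n_drop
    return out


def combat_adjust(dataset: MethylationDataset,
                  batches: pd.Series | None = None,
                  max_iter: int = 500, conv: float = 1e-4
                  ) -> MethylationDataset:
    """Parametric empirical-Bayes batch correction (ComBat).

    Per probe the matrix is standardized against the grand mean and pooled
    variance; per-batch location and scale estimates are then shrunk toward
    batch-level priors (normal prior on locations, inverse-gamma on scales,
    hyperparameters by method of moments) and divided out.  With a single
    batch the data are returned unchanged.

    Group labels are deliberately not part of the model (no covariates):
    batches are assumed not to be confounded with the comparison of
    interest.
    """
    if dataset.scale != "mvalue":
        raise ValueError("combat_adjust expects an M-value dataset")
    if batches is None:
        batches = dataset.batches
    if batches is None:
        raise ValueError("no batch labels available")
    batches = pd.Series(batches).loc[dataset.sample_ids]
    levels = sorted(batches.unique())
    if len(levels) < 2:
        warnings.warn("single batch; ComBat is a no-op")
        return dataset.with_values(dataset.values.copy())
    sizes = batches.value_counts()
    small = sizes[sizes < 2]
    if len(small):
        raise ValueError(f"batches with fewer than 2 samples: {list(small.index)}")

    X = dataset.values.to_numpy(dtype=float)
    n_probes, n_samples = X.shape
    masks = [np.asarray(batches == b) for b in levels]
    n_b = np.array([m.sum() for m in masks])

    batch_mean = np.column_stack([X[:, m].mean(axis=1) for m in masks])
    grand = batch_mean @ (n_b / n_samples)
    fitted = np.zeros_like(X)
    for j, m in enumerate(masks):
        fitted[:, m] = batch_mean[:, [j]]
    var_pooled = ((X - fitted) ** 2).mean(axis=1)
    var_pooled = np.where(var_pooled <= 0, np.finfo(float).tiny, var_pooled)
    sd_pooled = np.sqrt(var_pooled)

    Z = (X - grand[:, None]) / sd_pooled[:, None]

    adjusted = np.empty_like(Z)
    for j, m in enumerate(masks):
        Zb = Z[:, m]
        n = n_b[j]
        gamma_hat = Zb.mean(axis=1)
        delta_hat = Zb.var(axis=1, ddof=1)
        gamma_bar = gamma_hat.mean()
        tau2 = gamma_hat.var(ddof=1)
        m_d = delta_hat.mean()
        s2_d = delta_hat.var(ddof=1)
        # method-of-moments inverse-gamma hyperparameters
        a_prior = (2.0 * s2_d + m_d ** 2) / s2_d if s2_d > 0 else 2.0
        b_prior = (m_d * s2_d + m_d ** 3) / s2_d if s2_d > 0 else m_d

        gamma_star = gamma_hat.copy()
        delta_star = delta_hat.copy()
        for _ in range(max_iter):
            g_new = (n * tau2 * gamma_hat + delta_star * gamma_bar) \
                / (n * tau2 + delta_star)
            sum2 = ((Zb - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (0.5 * sum2 + b_prior) / (n / 2.0 + a_prior - 1.0)
            change = max(np.max(np.abs(g_new - gamma_star) / np.maximum(np.abs(gamma_star), 1e-12)),
                         np.max(np.abs(d_new - delta_star) / np.maximum(np.abs(delta_star), 1e-12)))
            gamma_star, delta_star = g_new, d_new
            if change < conv:
                break
        adjusted[:, m] = (Zb - gamma_star[:, None]) / np.sqrt(delta_star)[:, None]

    out = adjusted * sd_pooled[:, None] + grand[:, None]
    df = pd.DataFrame(out, index=dataset.values.index, columns=dataset.values.columns)
    logger.info("ComBat adjusted %d probes across %d batches", n_probes, len(levels))
    return dataset.with_values(df)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
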