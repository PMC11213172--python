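"""Bootstrap-scored probe selection with Otsu extraction and dip stopping.

The selection loop identifies CpG probes that both discriminate groups
statistically and carry predictive power for a classifier:

1.  Repeat over many stratified train/test splits: F-test every probe on
    the training samples, BH-correct, and keep probes with q below a strict
    gate (0.001).  Splits yielding fewer than 2 candidates are discarded
    (a model needs at least two features).  Fit the chosen classifier on
    the candidate probes and score each candidate
    ``F1_weighted * -log10(p_uncorrected)`` using the model's weighted
    one-vs-rest F1 on the held-out samples.
2.  Average scores over the usable splits (a probe scores 0 whenever it
    missed the gate), producing a multi-modal score distribution: truly
    informative probes populate the upper mode(s).
3.  Extract the upper part with an exact 1-D Otsu threshold, then test the
    extracted scores for remaining multimodality with a dip test.  While
    the dip test rejects unimodality, rerun the whole bootstrap on the
    extracted subset (the FDR correction then applies to the smaller set).
4.  Once unimodal, prune collinear probes: for any pair with a variance
    inflation factor 1/(1-r^2) above 5, keep only the higher-scoring one.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import MethylationDataset
from .dip import dip_test
from .models import ClassifierSpec, predict, train, weighted_ovr_f1
from .preprocess import bh_fdr

logger = logging.getLogger(__name__)

__all__ = [
    "SplitPlan", "SelectionConfig", "ScoreTable", "SelectionRound",
    "SelectionResult", "stratified_split", "f_test", "probe_score",
    "iteration_score", "bootstrap_scores", "otsu_threshold", "vif_prune",
    "select_probes",
]

# cohort group labels used by the study design presets
CP_GROUPS = frozenset({"cp", "cp_epilepsy"})
COHORT_GROUPS = ("control", "cp", "epilepsy", "cp_epilepsy")

_P_FLOOR = 1e-300  # guards -log10 against p == 0 from zero within-group variance


@dataclass(frozen=True)
class SplitPlan:
    """Per-group (n_train, n_test) counts for stratified splitting."""

    per_group: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        for g, (tr, te) in self.per_group.items():
            if tr < 0 or te < 0:
                raise ValueError(f"negative counts for group {g!r}")

    @classmethod
    def from_fractions(cls, groups: pd.Series, train_frac: float = 0.8
                       ) -> "SplitPlan":
        """Roughly ``train_frac`` of each group to training, rest to test."""
        plan = {}
        for g, n in groups.value_counts().items():
            tr = int(round(train_frac * n))
            tr = min(max(tr, 1), n - 1) if n > 1 else n
            plan[g] = (tr, n - tr)
        return cls(plan)

    @classmethod
    def cohort_four_class(cls) -> "SplitPlan":
        """22 train / 8 test over the four diagnostic groups."""
        return cls({"control": (6, 2), "cp": (8, 2), "epilepsy": (2, 2),
                    "cp_epilepsy": (6, 2)})

    @classmethod
    def cohort_binary(cls) -> "SplitPlan":
        """23 train / 7 test: the epilepsy group contributes 3/1."""
        return cls({"control": (6, 2), "cp": (8, 2), "epilepsy": (3, 1),
                    "cp_epilepsy": (6, 2)})

    def validate(self, groups: pd.Series) -> None:
        sizes = groups.value_counts()
        for g, (tr, te) in self.per_group.items():
            if g not in sizes:
                raise ValueError(f"plan group {g!r} absent from data")
            if tr + te > sizes[g]:
                raise ValueError(f"plan for group {g!r} needs {tr + te} samples, "
                                 f"only {sizes[g]} available")
        missing = set(sizes.index) - set(self.per_group)
        if missing:
            raise ValueError(f"groups without a split plan: {sorted(missing)}")


def stratified_split(groups: pd.Series, plan: SplitPlan,
                     rng: np.random.Generator) -> tuple[list[str], list[str]]:
    """Sample train/test IDs per group without replacement."""
    plan.validate(groups)
    train: list[str] = []
    test: list[str] = []
    for g in sorted(plan.per_group):
        tr, te = plan.per_group[g]
        ids = np.array(sorted(groups.index[groups == g]))
        perm = rng.permutation(len(ids))
        train.extend(ids[perm[:tr]])
        test.extend(ids[perm[tr:tr + te]])
    return train, test


def f_test(matrix_a: np.ndarray, matrix_b: np.ndarray
           ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-group one-way ANOVA per probe (row).

    Returns (F, p) with df (1, n_a + n_b - 2).  Degenerate probes: zero
    within-group variance with non-zero between gives p = 0; all-constant
    gives F = 0, p = 1.
    """
    a = np.atleast_2d(np.asarray(matrix_a, dtype=float))
    b = np.atleast_2d(np.asarray(matrix_b, dtype=float))
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("each contrast group needs at least 2 samples")
    ma = a.mean(axis=1)
    mb = b.mean(axis=1)
    grand = (na * ma + nb * mb) / (na + nb)
    ss_between = na * (ma - grand) ** 2 + nb * (mb - grand) ** 2
    ss_within = ((a - ma[:, None]) ** 2).sum(axis=1) + \
                ((b - mb[:, None]) ** 2).sum(axis=1)
    df_within = na + nb - 2
    ms_within = ss_within / df_within
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ss_between / ms_within
    p = np.empty_like(F)
    ok = ms_within > 0
    p[ok] = stats.f.sf(F[ok], 1, df_within)
    degenerate = ~ok
    if degenerate.any():
        sep = degenerate & (ss_between > 0)
        F[sep] = np.inf
        p[sep] = 0.0
        flat = degenerate & (ss_between <= 0)
        F[flat] = 0.0
        p[flat] = 1.0
        logger.debug("f_test: %d degenerate probes", int(degenerate.sum()))
    return F, p


@dataclass(frozen=True)
class SelectionConfig:
    """All thresholds of the selection algorithm."""

    n_iterations: int = 10_000
    fdr_gate: float = 0.001
    min_probes_per_iteration: int = 2
    dip_alpha: float = 0.05
    dip_n_null: int = 2000
    vif_limit: float = 5.0
    comparison: str = "binary"            # or "four_class"
    model: ClassifierSpec = field(default_factory=ClassifierSpec)
    split_plan: SplitPlan | None = None   # derived from group sizes when None
    score_denominator: str = "used"       # "used" or "all" iterations
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.fdr_gate < 1.0):
            raise ValueError("fdr_gate must lie in (0, 1)")
        if self.vif_limit <= 1.0:
            raise ValueError("vif_limit must exceed 1")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.comparison not in ("binary", "four_class"):
            raise ValueError("comparison must be 'binary' or 'four_class'")
        if self.score_denominator not in ("used", "all"):
            raise ValueError("score_denominator must be 'used' or 'all'")


def _comparison_labels(groups: pd.Series, comparison: str
                       ) -> tuple[pd.Series, str, str, pd.Series]:
    """Resolve model labels and the two-group F-test contrast.

    Returns (model_labels, contrast_a, contrast_b, contrast_labels) where
    contrast_labels maps each sample to a contrast side or NaN when the
    sample does not take part in the F-test (epilepsy-involved samples in
    the four-class comparison).
    """
    names = set(groups.unique())
    if comparison == "binary":
        if len(names) == 2:
            a, b = sorted(names)
            return groups, a, b, groups
        if names == set(COHORT_GROUPS):
            model = groups.map(lambda g: "cp" if g in CP_GROUPS else "non_cp")
            return model, "cp", "non_cp", model
        raise ValueError(f"binary comparison undefined for groups {sorted(names)}")
    # four_class: all groups feed the model; F statistic contrasts
    # CP-without-epilepsy against control only
    if not {"cp", "control"} <= names:
        raise ValueError("four_class comparison needs 'cp' and 'control' groups")
    contrast = groups.where(groups.isin(["cp", "control"]))
    return groups, "cp", "control", contrast


def probe_score(f1_weighted: float, p_uncorrected: float) -> float:
    """Per-probe, per-iteration score: F1_weighted * -log10(p)."""
    return f1_weighted * -math.log10(max(p_uncorrected, _P_FLOOR))


@dataclass
class IterationOutcome:
    """Result of a single bootstrap iteration.

    ``scores`` is per-probe (0 outside the candidate set) and None when the
    iteration is discarded; ``status`` is "ok", "too_few_candidates" or
    "model_failure".
    """

    scores: np.ndarray | None
    candidate_mask: np.ndarray
    pvalues: np.ndarray
    f1: float | None
    status: str


def iteration_score(dataset: MethylationDataset, train_ids: list[str],
                    test_ids: list[str], config: SelectionConfig
                    ) -> IterationOutcome:
    """One bootstrap iteration: F-test gate, model fit, per-probe scores."""
    if dataset.scale != "mvalue":
        raise ValueError("selection operates on M-values")
    X = dataset.values.to_numpy()
    probe_ids = dataset.probe_ids.to_numpy()
    model_labels, ca, cb, contrast = _comparison_labels(dataset.groups,
                                                        config.comparison)
    train_a = [s for s in train_ids if contrast.get(s) == ca]
    train_b = [s for s in train_ids if contrast.get(s) == cb]
    col = {s: i for i, s in enumerate(dataset.sample_ids)}
    _, p = f_test(X[:, [col[s] for s in train_a]],
                  X[:, [col[s] for s in train_b]])
    q = bh_fdr(p)
    cand = q < config.fdr_gate
    if int(cand.sum()) < config.min_probes_per_iteration:
        return IterationOutcome(None, cand, p, None, "too_few_candidates")
    # canonical (ID-sorted) feature order keeps results invariant to the
    # probe row order of the input matrix
    cand_idx = np.flatnonzero(cand)
    cand_idx = cand_idx[np.argsort(probe_ids[cand_idx], kind="stable")]
    tr_cols = [col[s] for s in train_ids]
    te_cols = [col[s] for s in test_ids]
    try:
        clf = train(config.model, X[np.ix_(cand_idx, tr_cols)].T,
                    model_labels.loc[train_ids].to_numpy())
        pred = predict(clf, X[np.ix_(cand_idx, te_cols)].T)
    except Exception as exc:  # noqa: BLE001 - model failure discards the iteration
        logger.warning("iteration discarded, model failure: %s", exc)
        return IterationOutcome(None, cand, p, None, "model_failure")
    f1 = weighted_ovr_f1(model_labels.loc[test_ids].to_numpy(), pred)
    scores = np.zeros(X.shape[0])
    with np.errstate(divide="ignore"):
        scores[cand] = f1 * -np.log10(np.maximum(p[cand], _P_FLOOR))
    return IterationOutcome(scores, cand, p, f1, "ok")


@dataclass
class ScoreTable:
    """Per-probe bootstrap score summary.

    ``table`` has columns ``mean_score`` (average of the per-iteration
    scores with 0 for unselected iterations), ``n_selected`` (iterations
    where the probe passed the FDR gate) and ``mean_uncorrected_p`` among
    those iterations.
    """

    table: pd.DataFrame
    n_usable_iterations: int
    n_discarded: int

    @property
    def mean_score(self) -> pd.Series:
        return self.table["mean_score"]


def bootstrap_scores(dataset: MethylationDataset, config: SelectionConfig,
                     seed=None) -> ScoreTable:
    """Average per-probe scores over many stratified splits.

    Discarded iterations (too few candidates, model failure) are excluded
    from the averaging denominator unless ``config.score_denominator`` is
    "all".  Fully deterministic for a given seed.
    """
    if dataset.scale != "mvalue":
        raise ValueError("selection operates on M-values")
    seq = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(config.seed if seed is None else seed)
    children = seq.spawn(config.n_iterations)
    # splits stratify on the original group labels (the study design's
    # split table), regardless of how the comparison collapses them
    plan = config.split_plan or SplitPlan.from_fractions(dataset.groups)

    n_probes = dataset.n_probes
    score_sum = np.zeros(n_probes)
    p_sum = np.zeros(n_probes)
    n_sel = np.zeros(n_probes, dtype=np.int64)
    n_used = 0
    n_discarded = 0

    for child in children:
        rng = np.random.default_rng(child)
        train_ids, test_ids = stratified_split(dataset.groups, plan, rng)
        out = iteration_score(dataset, train_ids, test_ids, config)
        if out.status != "ok":
            n_discarded += 1
            continue
        n_used += 1
        score_sum += out.scores
        p_sum[out.candidate_mask] += out.pvalues[out.candidate_mask]
        n_sel[out.candidate_mask] += 1

    if n_used == 0:
        raise RuntimeError(
            "all bootstrap iterations were discarded; consider a larger "
            "fdr_gate or more samples")
    denom = n_used if config.score_denominator == "used" else len(children)
    with np.errstate(invalid="ignore"):
        mean_p = np.where(n_sel > 0, p_sum / np.maximum(n_sel, 1), np.nan)
    table = pd.DataFrame({
        "mean_score": score_sum / denom,
        "n_selected": n_sel,
        "mean_uncorrected_p": mean_p,
    }, index=dataset.probe_ids)
    return ScoreTable(table, n_usable_iterations=n_used, n_discarded=n_discarded)


def otsu_threshold(scores) -> tuple[float, np.ndarray]:
    """Exact 1-D Otsu split of a score distribution.

    Candidate thresholds are midpoints between consecutive sorted unique
    values; the one maximizing the between-class variance wins (ties break
    toward the smallest threshold, which keeps more probes).  Returns the
    threshold and a boolean mask of scores strictly above it.
    """
    arr = np.asarray(scores, dtype=float)
    uniq, counts = np.unique(arr, return_counts=True)
    if uniq.size < 2:
        raise ValueError("Otsu needs at least 2 distinct values")
    n = arr.size
    w0 = np.cumsum(counts)[:-1]               # class sizes below each cut
    sum0 = np.cumsum(uniq * counts)[:-1]
    total = float((uniq * counts).sum())
    mu0 = sum0 / w0
    mu1 = (total - sum0) / (n - w0)
    bcv = w0 * (n - w0) * (mu0 - mu1) ** 2    # proportional form
    best = int(np.argmax(bcv))                # first max = smallest threshold
    thr = 0.5 * (uniq[best] + uniq[best + 1])
    return float(thr), arr > thr


def vif_prune(values: pd.DataFrame, scores: pd.Series, vif_limit: float = 5.0
              ) -> list[str]:
    """Drop the lower-scoring member of collinear probe pairs.

    Pairwise VIF = 1/(1 - r^2) with r the correlation of the two probes'
    M-values across all samples.  Probes are scanned in descending score
    order (probe ID breaks ties); a candidate is dropped as soon as it
    exceeds ``vif_limit`` against any retained higher-scoring probe.
    Zero-variance probes have undefined correlation and are dropped.
    """
    order = sorted(values.index, key=lambda pid: (-scores[pid], pid))
    X = values.loc[order].to_numpy(dtype=float)
    sd = X.std(axis=1)
    kept: list[int] = []
    kept_ids: list[str] = []
    centered = X - X.mean(axis=1, keepdims=True)
    for i, pid in enumerate(order):
        if sd[i] == 0.0:
            warnings.warn(f"probe {pid!r} has zero variance; dropped in VIF pruning")
            continue
        collinear = False
        for j in kept:
            r = float(centered[i] @ centered[j] / (len(X[i]) * sd[i] * sd[j]))
            r2 = min(r * r, 1.0)
            vif = np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
            if vif > vif_limit:
                collinear = True
                break
        if not collinear:
            kept.append(i)
            kept_ids.append(pid)
    return kept_ids


@dataclass
class SelectionRound:
    """History record for one bootstrap/Otsu/dip round."""

    score_table: ScoreTable
    otsu_threshold: float | None
    kept_probe_ids: list[str]
    dip_statistic: float
    dip_pvalue: float


@dataclass
class SelectionResult:
    rounds: list[SelectionRound]
    final_probes_pre_vif: list[str]
    final_probes: list[str]
    config: SelectionConfig

    def to_dict(self) -> dict:
        return {
            "final_probes": list(self.final_probes),
            "final_probes_pre_vif": list(self.final_probes_pre_vif),
            "rounds": [
                {
                    "n_probes": len(r.score_table.table),
                    "otsu_threshold": r.otsu_threshold,
                    "kept_probe_ids": list(r.kept_probe_ids),
                    "dip_statistic": r.dip_statistic,
                    "dip_pvalue": r.dip_pvalue,
                    "n_usable_iterations": r.score_table.n_usable_iterations,
                    "n_discarded": r.score_table.n_discarded,
                }
                for r in self.rounds
            ],
            "config": {
                "n_iterations": self.config.n_iterations,
                "fdr_gate": self.config.fdr_gate,
                "dip_alpha": self.config.dip_alpha,
                "vif_limit": self.config.vif_limit,
                "comparison": self.config.comparison,
                "model": self.config.model.kind,
                "seed": self.config.seed,
            },
        }


def select_probes(dataset: MethylationDataset, config: SelectionConfig
                  ) -> SelectionResult:
    """Full selection loop: bootstrap scores, Otsu, dip stopping, VIF pruning.

    Each round reruns the bootstrap on the current subset (so the FDR
    correction adapts to the subset size), extracts the upper Otsu class
    and dip-tests its scores; rounds repeat while multimodality is
    detected.  The loop also terminates when the subset becomes too small
    to analyse further (fewer than 2 probes, or too few distinct scores
    for Otsu/dip), with a warning.
    """
    seq = np.random.SeedSequence(config.seed)
    subset = list(dataset.probe_ids)
    rounds: list[SelectionRound] = []
    final: list[str] = subset
    last_scores: pd.Series | None = None

    while True:
        bs_seed, dip_seed = seq.spawn(2)
        ds_sub = dataset.subset_probes(subset)
        st = bootstrap_scores(ds_sub, config, seed=bs_seed)
        scores = st.mean_score
        last_scores = scores
        if scores.nunique() < 2:
            warnings.warn("score distribution degenerate; stopping selection")
            rounds.append(SelectionRound(st, None, list(subset), math.nan, math.nan))
            final = list(subset)
            break
        thr, upper_mask = otsu_threshold(scores.to_numpy())
        upper = list(scores.index[upper_mask])
        upper_scores = scores[upper_mask]
        if len(upper) < 2:
            # extraction collapsed; keep the set that entered this round
            warnings.warn("Otsu subset collapsed below 2 probes; "
                          "returning the current set")
            rounds.append(SelectionRound(st, thr, list(subset), math.nan,
                                         math.nan))
            final = list(subset)
            break
        if upper_scores.nunique() < 4:
            # too few distinct scores for a dip test: accept as unimodal
            rounds.append(SelectionRound(st, thr, upper, math.nan, math.nan))
            final = upper
            break
        dres = dip_test(upper_scores.to_numpy(), n_null=config.dip_n_null,
                        rng=np.random.default_rng(dip_seed))
        rounds.append(SelectionRound(st, thr, upper, dres.statistic, dres.pvalue))
        final = upper
        if dres.pvalue >= config.dip_alpha:
            break
        subset = upper
        logger.info("dip rejected unimodality (p=%.4f); rerunning on %d probes",
                    dres.pvalue, len(subset))

    assert last_scores is not None
    pruned = vif_prune(dataset.values.loc[final], last_scores,
                       config.vif_limit) if final else []
    logger.info("selection finished: %d probes pre-VIF, %d final",
                len(final), len(pruned))
    return SelectionResult(rounds=rounds, final_probes_pre_vif=list(final),
                           final_probes=pruned, config=config)
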