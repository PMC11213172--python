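"""Post-selection performance evaluation.

Once a probe set is fixed, four questions remain:

* how well do the models classify on repeated stratified splits
  (:func:`performance_bootstrap` — median weighted one-vs-rest F1 over the
  bootstrap, no p-values in this phase);
* how robust is a trained model to growing within-group variance
  (:func:`sensitivity_curve` — uniform synthetic samples spreading A group
  SDs around each group mean, A on an integer grid);
* for synthetic validation runs, how many planted probes of each tier were
  recovered and how many background probes leaked in
  (:func:`score_detection`);
* how separable are the groups visually
  (:func:`pca_project_heldout` — PCA fitted without an under-represented
  group, onto which that group is then projected).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .dataset import BACKGROUND, TIERS, MethylationDataset, TruthTable
from .models import ClassifierSpec, predict, train, weighted_ovr_f1
from .selection import SelectionResult, SplitPlan, _comparison_labels, \
    stratified_split
from .synthetic import SensitivitySampleSpec, generate_sensitivity_samples

logger = logging.getLogger(__name__)

__all__ = ["PerformanceSummary", "SensitivityCurve", "DetectionReport",
           "performance_bootstrap", "sensitivity_curve", "score_detection",
           "pca_project_heldout"]


@dataclass
class PerformanceSummary:
    """Bootstrap F1 distribution for a fixed probe set."""

    f1_values: np.ndarray
    model_kind: str
    comparison: str
    n_iterations: int

    @property
    def median(self) -> float:
        return float(np.median(self.f1_values))

    @property
    def fraction_perfect(self) -> float:
        return float(np.mean(self.f1_values == 1.0))


def performance_bootstrap(dataset: MethylationDataset, probe_set,
                          spec: ClassifierSpec | None = None,
                          comparison: str = "binary",
                          plan: SplitPlan | None = None,
                          n_iterations: int = 10_000,
                          seed: int | None = None) -> PerformanceSummary:
    """Median weighted one-vs-rest F1 over stratified bootstrap splits.

    Each iteration draws a stratified train/test split, fits the model on
    the training samples restricted to ``probe_set`` and scores the test
    samples.  No statistical testing happens here — the probe set is fixed.
    """
    probe_set = list(probe_set)
    if not probe_set:
        raise ValueError("probe_set must be non-empty")
    missing = set(probe_set) - set(dataset.probe_ids)
    if missing:
        raise ValueError(f"probes absent from dataset: {sorted(missing)[:5]}")
    spec = spec or ClassifierSpec()
    ds = dataset.subset_probes(sorted(probe_set))
    model_labels, *_ = _comparison_labels(ds.groups, comparison)
    plan = plan or SplitPlan.from_fractions(ds.groups)
    X = ds.values.to_numpy()
    col = {s: i for i, s in enumerate(ds.sample_ids)}
    seq = np.random.SeedSequence(seed)
    f1s: list[float] = []
    for child in seq.spawn(n_iterations):
        rng = np.random.default_rng(child)
        train_ids, test_ids = stratified_split(ds.groups, plan, rng)
        tr = [col[s] for s in train_ids]
        te = [col[s] for s in test_ids]
        try:
            clf = train(spec, X[:, tr].T, model_labels.loc[train_ids].to_numpy())
            pred = predict(clf, X[:, te].T)
        except Exception as exc:  # noqa: BLE001
            logger.warning("evaluation iteration failed: %s", exc)
            continue
        f1s.append(weighted_ovr_f1(model_labels.loc[test_ids].to_numpy(), pred))
    return PerformanceSummary(np.asarray(f1s), spec.kind, comparison, len(f1s))


@dataclass
class SensitivityCurve:
    """Median F1 per SD-multiplier A."""

    table: pd.DataFrame  # index A, columns: median_f1, plus one column per replicate
    model_kind: str

    @property
    def median_f1(self) -> pd.Series:
        return self.table["median_f1"]


def sensitivity_curve(dataset: MethylationDataset, probe_set,
                      spec: ClassifierSpec | None = None,
                      comparison: str = "binary",
                      a_grid=None, n_per_group: int = 30,
                      n_replicates: int = 20,
                      seed: int | None = None) -> SensitivityCurve:
    """Classification performance under widening synthetic variance.

    The model is trained once on the full dataset restricted to
    ``probe_set``.  For each width multiplier A, synthetic test samples are
    drawn uniform on [mu - A*sigma, mu + A*sigma] per probe and group (mu,
    sigma estimated from the training data in M-value units) and the
    weighted one-vs-rest F1 of the model's predictions is recorded; the
    median over replicate draws is reported.
    """
    a_grid = np.asarray(list(a_grid) if a_grid is not None else range(1, 11),
                        dtype=float)
    if a_grid.size == 0:
        raise ValueError("A grid must be non-empty")
    if np.any(np.diff(a_grid) <= 0):
        raise ValueError("A grid must be strictly increasing")
    probe_set = sorted(probe_set)
    if not probe_set:
        raise ValueError("probe_set must be non-empty")
    spec = spec or ClassifierSpec()
    ds = dataset.subset_probes(probe_set)
    if ds.scale != "mvalue":
        raise ValueError("sensitivity analysis operates on M-values")
    model_labels, *_ = _comparison_labels(ds.groups, comparison)
    label_names = sorted(model_labels.unique())
    mu = pd.DataFrame({g: ds.values.loc[:, model_labels == g].mean(axis=1)
                       for g in label_names})
    sigma = pd.DataFrame({g: ds.values.loc[:, model_labels == g].std(axis=1, ddof=1)
                          for g in label_names})
    for g in label_names:
        if (model_labels == g).sum() < 2:
            raise ValueError(f"group {g!r} needs >= 2 samples to estimate sigma")

    clf = train(spec, ds.values.to_numpy().T, model_labels.to_numpy())
    seq = np.random.SeedSequence(seed)
    rows = {}
    for a in a_grid:
        reps = []
        for child in seq.spawn(n_replicates):
            samp = generate_sensitivity_samples(
                SensitivitySampleSpec(mu=mu, sigma=sigma, width=float(a),
                                      n_per_group=n_per_group),
                rng=np.random.default_rng(child))
            pred = predict(clf, samp.values.to_numpy().T)
            reps.append(weighted_ovr_f1(samp.groups.to_numpy(), pred))
        rows[float(a)] = reps
    table = pd.DataFrame.from_dict(rows, orient="index",
                                   columns=[f"rep_{i + 1}" for i in range(n_replicates)])
    table.index.name = "A"
    table.insert(0, "median_f1", table.median(axis=1))
    return SensitivityCurve(table, spec.kind)


@dataclass
class DetectionReport:
    """Tier-wise recovery of planted probes plus background leakage."""

    n_planted: dict[str, int]
    n_detected: dict[str, int]
    n_false_positive: int

    def detection_fraction(self, tier: str) -> float:
        n = self.n_planted.get(tier, 0)
        return self.n_detected.get(tier, 0) / n if n else float("nan")

    def to_dict(self) -> dict:
        return {"n_planted": dict(self.n_planted),
                "n_detected": dict(self.n_detected),
                "n_false_positive": self.n_false_positive}


def score_detection(result: SelectionResult | list, truth: TruthTable,
                    stage: str = "pre_vif") -> DetectionReport:
    """Count selected probes per planted tier; background counts as FP.

    Given a :class:`SelectionResult`, detection is scored on the set
    before VIF pruning by default: planted differential probes all
    separate the same two groups and are therefore mutually correlated by
    construction, so the collinearity prune may discard a probe that the
    algorithm did identify.  That is a parsimony decision, not a detection
    failure.  Pass ``stage="final"`` to score the pruned set instead.
    """
    if isinstance(result, SelectionResult):
        if stage == "pre_vif":
            selected = result.final_probes_pre_vif
        elif stage == "final":
            selected = result.final_probes
        else:
            raise ValueError("stage must be 'pre_vif' or 'final'")
    else:
        selected = list(result)
    missing = set(selected) - set(truth.tiers.index)
    if missing:
        raise ValueError(f"selected probes missing from truth table: "
                         f"{sorted(missing)[:5]}")
    counts = truth.counts()
    detected = {t: 0 for t in TIERS}
    fp = 0
    for pid in selected:
        tier = truth.tier_of(pid)
        if tier == BACKGROUND:
            fp += 1
        else:
            detected[tier] += 1
    return DetectionReport(
        n_planted={t: counts[t] for t in TIERS},
        n_detected=detected,
        n_false_positive=fp)


def pca_project_heldout(dataset: MethylationDataset, probe_set,
                        heldout_group: str | None = None,
                        n_components: int = 3
                        ) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA fitted without a held-out group, with that group projected on.

    Returns per-sample coordinates (all samples, including the held-out
    group transformed with the fitted axes and centering) and the
    explained-variance fractions of the fitted axes.  Centering only, no
    scaling — standard practice for M-values.
    """
    probe_set = sorted(probe_set)
    if len(probe_set) < n_components:
        raise ValueError("probe_set smaller than the requested component count")
    ds = dataset.subset_probes(probe_set)
    X = ds.values.to_numpy().T  # samples x probes
    if heldout_group is not None:
        if heldout_group not in set(ds.groups):
            raise ValueError(f"held-out group {heldout_group!r} not present")
        fit_mask = (ds.groups != heldout_group).to_numpy()
    else:
        fit_mask = np.ones(X.shape[0], dtype=bool)
    if fit_mask.sum() < 2:
        raise ValueError("need at least 2 samples to fit the PCA")
    pca = PCA(n_components=min(n_components, int(fit_mask.sum()), len(probe_set)))
    pca.fit(X[fit_mask])
    coords = pca.transform(X)
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return (pd.DataFrame(coords, index=ds.sample_ids, columns=cols),
            pca.explained_variance_ratio_)
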