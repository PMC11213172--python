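"""End-to-end validation workflow and run provenance.

``run_validation_workflow`` chains the full synthetic validation:
generate methylome -> biomarker prefilter -> M-values -> drop non-finite
-> selection loop (binary comparison) -> tier detection report.  Every
stage is logged with probe counts and wall time; artifacts can be written
to an output directory together with a machine-readable provenance record
(config snapshot + seed + package version).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .models import ClassifierSpec
from .dataset import MethylationDataset, TruthTable
from .evaluation import DetectionReport, score_detection
from .prefilter import PrefilterConfig, biomarker_prefilter
from .preprocess import drop_nonfinite, to_mvalues
from .selection import SelectionConfig, SelectionResult, select_probes
from .synthetic import SyntheticConfig, generate_validation_dataset

logger = logging.getLogger(__name__)

__all__ = ["ValidationWorkflowConfig", "WorkflowResult",
           "run_validation_workflow", "write_provenance", "load_run_config"]


@dataclass
class ValidationWorkflowConfig:
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    prefilter: PrefilterConfig = field(default_factory=PrefilterConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    seed: int = 0
    out_dir: Path | None = None

    def snapshot(self) -> dict:
        return {
            "seed": self.seed,
            "synthetic": {
                "n_background": self.synthetic.n_background,
                "n_per_group": self.synthetic.n_per_group,
                "signal_specs": [
                    {"tier": s.tier, "diff_range": list(s.diff_range),
                     "sd_range": list(s.sd_range), "n_probes": s.n_probes}
                    for s in self.synthetic.signal_specs],
            },
            "prefilter": {
                "ci_span_limit": self.prefilter.ci_span_limit,
                "ci_mode": self.prefilter.ci_mode,
                "min_criteria_passes": self.prefilter.min_criteria_passes,
                "min_mean_diff": self.prefilter.min_mean_diff,
            },
            "selection": {
                "n_iterations": self.selection.n_iterations,
                "fdr_gate": self.selection.fdr_gate,
                "dip_alpha": self.selection.dip_alpha,
                "vif_limit": self.selection.vif_limit,
                "comparison": self.selection.comparison,
                "model": self.selection.model.kind,
            },
        }


@dataclass
class WorkflowResult:
    detection: DetectionReport
    selection: SelectionResult
    truth: TruthTable
    n_prefiltered: int
    n_after_mvalues: int
    timings: dict[str, float]


def load_run_config(path: str | Path, **overrides) -> ValidationWorkflowConfig:
    """Build a workflow config from a YAML/JSON document.

    The document mirrors :class:`ValidationWorkflowConfig` (top-level keys
    ``seed``, ``out_dir``, and nested ``synthetic``, ``prefilter``,
    ``selection`` sections; ``selection.model`` is a classifier kind
    string).  Keyword ``overrides`` — typically CLI flags — take
    precedence over file values.
    """
    doc = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(doc, dict):
        raise ValueError(f"run config {path} must be a mapping")
    doc.update({k: v for k, v in overrides.items() if v is not None})

    syn = dict(doc.get("synthetic", {}))
    if "signal_specs" in syn:
        from .synthetic import SignalSpec
        syn["signal_specs"] = tuple(
            SignalSpec(s["tier"], tuple(s["diff_range"]),
                       tuple(s["sd_range"]), s["n_probes"])
            for s in syn["signal_specs"])
    sel = dict(doc.get("selection", {}))
    if isinstance(sel.get("model"), str):
        sel["model"] = ClassifierSpec(kind=sel["model"])
    out_dir = doc.get("out_dir")
    return ValidationWorkflowConfig(
        synthetic=SyntheticConfig(**syn),
        prefilter=PrefilterConfig(**doc.get("prefilter", {})),
        selection=SelectionConfig(**sel),
        seed=int(doc.get("seed", 0)),
        out_dir=Path(out_dir) if out_dir else None)


def write_provenance(out_dir: Path, config_snapshot: dict) -> Path:
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "provenance.json"
    record = {"package": "methylsieve", "version": __version__,
              "config": config_snapshot}
    path.write_text(json.dumps(record, indent=2))
    return path


def _timed(timings: dict, name: str, fn, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        result = fn(*args, **kwargs)
    except Exception as exc:
        raise RuntimeError(f"workflow stage {name!r} failed: {exc}") from exc
    timings[name] = time.perf_counter() - t0
    logger.info("stage %s finished in %.2fs", name, timings[name])
    return result


def run_validation_workflow(config: ValidationWorkflowConfig | None = None
                            ) -> WorkflowResult:
    """Run the full synthetic validation and report tier detection."""
    config = config or ValidationWorkflowConfig()
    timings: dict[str, float] = {}
    out = config.out_dir
    if out is not None:
        out = Path(out)
        write_provenance(out, config.snapshot())

    dataset: MethylationDataset
    truth: TruthTable
    dataset, truth = _timed(timings, "simulate", generate_validation_dataset,
                            config.synthetic, config.seed)
    logger.info("simulated %d probes x %d samples", dataset.n_probes,
                dataset.n_samples)
    if out is not None:
        truth.write(out / "truth.csv")

    kept, report = _timed(timings, "prefilter", biomarker_prefilter,
                          dataset, config.prefilter)
    logger.info("prefilter: %d -> %d probes", dataset.n_probes, kept.n_probes)
    if out is not None:
        report.loc[report["kept"]].to_csv(out / "prefilter_report.csv")

    mvals = _timed(timings, "to_mvalues", to_mvalues, kept)
    mvals = _timed(timings, "drop_nonfinite", drop_nonfinite, mvals)
    logger.info("M-value matrix: %d probes", mvals.n_probes)

    sel_config = config.selection
    if sel_config.seed != config.seed:
        sel_config = SelectionConfig(**{**sel_config.__dict__, "seed": config.seed})
    selection = _timed(timings, "select", select_probes, mvals, sel_config)

    detection = _timed(timings, "score_detection", score_detection,
                       selection, truth)
    logger.info("detection: %s, false positives %d", detection.n_detected,
                detection.n_false_positive)
    if out is not None:
        (out / "selection_result.json").write_text(
            json.dumps(selection.to_dict(), indent=2))
        (out / "detection_report.json").write_text(
            json.dumps(detection.to_dict(), indent=2))
        (out / "selected_probes.txt").write_text(
            "\n".join(selection.final_probes) + "\n")

    return WorkflowResult(detection=detection, selection=selection, truth=truth,
                          n_prefiltered=kept.n_probes,
                          n_after_mvalues=mvals.n_probes, timings=timings)
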