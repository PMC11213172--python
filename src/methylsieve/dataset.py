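"""Core data containers and plain-text I/O.

A :class:`MethylationDataset` is a probe x sample matrix of methylation
measurements carrying an explicit scale tag:

``percent``
    percent methylation load in [0, 100] (100·beta),
``beta``
    fraction methylated in [0, 1],
``mvalue``
    log2-odds of methylation, unbounded (may contain ±inf before cleaning).

Matrices are stored as pandas DataFrames (probes in rows, samples in
columns) together with a per-sample group assignment and an optional batch
assignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SCALES = ("percent", "beta", "mvalue")

#: canonical tier labels for planted synthetic signal probes
TIERS = ("high", "medium", "low")
BACKGROUND = "background"


@dataclass
class MethylationDataset:
    """Probe x sample methylation matrix with group/batch labels."""

    values: pd.DataFrame
    scale: str
    groups: pd.Series
    batches: pd.Series | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if not self.values.index.is_unique:
            raise ValueError("probe IDs must be unique")
        if not self.values.columns.is_unique:
            raise ValueError("sample IDs must be unique")
        self.groups = pd.Series(self.groups)
        missing = self.values.columns.difference(self.groups.index)
        if len(missing):
            raise ValueError(f"samples without a group label: {list(missing)[:5]}")
        self.groups = self.groups.loc[self.values.columns]
        if self.batches is not None:
            self.batches = pd.Series(self.batches).loc[self.values.columns]
        self._check_scale_bounds()

    def _check_scale_bounds(self) -> None:
        if self.values.size == 0 or self.scale == "mvalue":
            return
        arr = self.values.to_numpy()
        hi = 1.0 if self.scale == "beta" else 100.0
        mn, mx = np.nanmin(arr), np.nanmax(arr)
        if mn < 0.0 or mx > hi:
            bad = np.argwhere((arr < 0.0) | (arr > hi))
            r, c = bad[0]
            raise ValueError(
                f"{self.scale} value {arr[r, c]!r} out of [0, {hi}] at probe "
                f"{self.values.index[r]!r}, sample {self.values.columns[c]!r}"
            )

    # -- basic geometry ---------------------------------------------------
    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def group_names(self) -> list[str]:
        return sorted(self.groups.unique())

    def samples_in_group(self, group: str) -> list[str]:
        return sorted(self.groups.index[self.groups == group])

    # -- subsetting -------------------------------------------------------
    def subset_probes(self, probe_ids: Iterable[str]) -> "MethylationDataset":
        sub = self.values.loc[list(probe_ids)]
        return MethylationDataset(sub, self.scale, self.groups, self.batches,
                                  dict(self.metadata))

    def subset_samples(self, sample_ids: Iterable[str]) -> "MethylationDataset":
        ids = list(sample_ids)
        sub = self.values[ids]
        return MethylationDataset(sub, self.scale, self.groups.loc[ids],
                                  None if self.batches is None else self.batches.loc[ids],
                                  dict(self.metadata))

    def with_values(self, values: pd.DataFrame, scale: str | None = None
                    ) -> "MethylationDataset":
        return MethylationDataset(values, scale or self.scale, self.groups,
                                  self.batches, dict(self.metadata))

    # -- I/O ---------------------------------------------------------------
    def write(self, out_dir: str | Path, stem: str = "methylation",
              compress: bool = True) -> dict[str, Path]:
        """Write matrix (TSV, optionally gzipped) and sample sheet (CSV)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        suffix = ".tsv.gz" if compress else ".tsv"
        matrix_path = out / f"{stem}{suffix}"
        self.values.to_csv(matrix_path, sep="\t", index_label="probe_id")
        sheet = pd.DataFrame({"sample_id": self.sample_ids,
                              "group": self.groups.values})
        if self.batches is not None:
            sheet["batch"] = self.batches.values
        sheet_path = out / f"{stem}_samples.csv"
        sheet.to_csv(sheet_path, index=False)
        logger.info("wrote %d probes x %d samples to %s", self.n_probes,
                    self.n_samples, matrix_path)
        return {"matrix": matrix_path, "sheet": sheet_path}


@dataclass
class TruthTable:
    """Planted-signal tier per synthetic probe (``background`` for noise)."""

    tiers: pd.Series  # probe_id -> tier

    def __post_init__(self) -> None:
        self.tiers = pd.Series(self.tiers)
        if not self.tiers.index.is_unique:
            raise ValueError("truth table probe IDs must be unique")
        bad = set(self.tiers.unique()) - set(TIERS) - {BACKGROUND}
        if bad:
            raise ValueError(f"unknown tiers: {sorted(bad)}")

    def counts(self) -> dict[str, int]:
        c = self.tiers.value_counts().to_dict()
        return {t: int(c.get(t, 0)) for t in (*TIERS, BACKGROUND)}

    def tier_of(self, probe_id: str) -> str:
        return self.tiers[probe_id]

    def probes_in_tier(self, tier: str) -> list[str]:
        return sorted(self.tiers.index[self.tiers == tier])

    def write(self, path: str | Path) -> None:
        pd.DataFrame({"probe_id": self.tiers.index, "tier": self.tiers.values}
                     ).to_csv(path, index=False)

    @classmethod
    def read(cls, path: str | Path) -> "TruthTable":
        df = pd.read_csv(path)
        return cls(pd.Series(df["tier"].values, index=df["probe_id"].values))

    @classmethod
    def concat(cls, tables: Iterable["TruthTable"]) -> "TruthTable":
        return cls(pd.concat([t.tiers for t in tables]))


def infer_scale(values: pd.DataFrame) -> str:
    """Guess the measurement scale from the value range.

    Negative values mean M-values; anything above 1 means percent;
    otherwise beta.
    """
    arr = values.to_numpy()
    finite = arr[np.isfinite(arr)]
    if finite.size == 0:
        return "mvalue"
    if finite.min() < 0.0:
        return "mvalue"
    if finite.max() > 1.0:
        return "percent"
    return "beta"


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a probe x sample matrix from CSV/TSV (gzip-aware)."""
    path = Path(path)
    name = path.name[:-3] if path.name.endswith(".gz") else path.name
    sep = "\t" if name.endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    df.index.name = None
    return df


def load_dataset(matrix_path: str | Path, sheet_path: str | Path,
                 scale: str | None = None) -> MethylationDataset:
    """Load matrix + sample sheet into a typed dataset.

    Sample sheet columns: ``sample_id``, ``group``, optional ``batch``.
    Sheet samples must all exist in the matrix; matrix columns missing from
    the sheet are dropped with a warning.
    """
    values = read_matrix(matrix_path)
    sheet = pd.read_csv(sheet_path)
    for col in ("sample_id", "group"):
        if col not in sheet.columns:
            raise ValueError(f"sample sheet lacks required column {col!r}")
    sheet = sheet.set_index("sample_id")
    unknown = sheet.index.difference(values.columns)
    if len(unknown):
        raise ValueError(f"sample sheet names samples absent from the matrix: "
                         f"{sorted(unknown)}")
    extra = values.columns.difference(sheet.index)
    if len(extra):
        logger.warning("matrix columns without sheet entry excluded: %s",
                       sorted(extra))
        values = values[sheet.index.tolist()]
    else:
        values = values[sheet.index.tolist()]
    batches = sheet["batch"] if "batch" in sheet.columns else None
    if scale is None:
        scale = infer_scale(values)
        logger.info("inferred scale %r", scale)
    return MethylationDataset(values, scale, sheet["group"], batches)
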