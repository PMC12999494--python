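"""Shared domain containers.

Tabular data ride in pandas objects; the dataclasses here only add the
identity and invariants that a bare DataFrame cannot carry (gene-set
membership, tumour/non-tumour labels, label-image semantics).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_CNA_TYPES = ("gain", "loss")


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): order preserved, names unique."""

    name: str
    sets: dict[str, list[str]]

    def __post_init__(self) -> None:
        for set_name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {set_name!r} is empty")
            if any((not isinstance(g, str)) or g == "" for g in genes):
                raise ValueError(f"gene set {set_name!r} contains empty identifiers")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, set_name: str) -> list[str]:
        return self.sets[set_name]


@dataclass
class SignaturePair:
    """Paired UP/DN gene sets; their combined score proxies pathway activity."""

    up: list[str]
    dn: list[str]
    name: str = "signature"

    def __post_init__(self) -> None:
        overlap = set(self.up) & set(self.dn)
        if overlap:
            raise ValueError(f"up and dn sets overlap: {sorted(overlap)[:5]}")


@dataclass
class ExpressionCohort:
    """Genes x samples expression matrix with per-sample group labels.

    ``expr`` is indexed by gene id (unique) with sample ids as columns;
    ``groups`` maps sample id -> 'tumour' | 'non-tumour'.
    """

    expr: pd.DataFrame
    groups: pd.Series | None = None
    dataset: str = "cohort"

    def __post_init__(self) -> None:
        if self.expr.index.duplicated().any():
            dups = self.expr.index[self.expr.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if self.expr.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if self.groups is not None:
            self.groups = self.groups.reindex(self.expr.columns)
            if self.groups.isna().any():
                raise ValueError("groups missing for some samples")

    @property
    def n_genes(self) -> int:
        return self.expr.shape[0]

    @property
    def n_samples(self) -> int:
        return self.expr.shape[1]

    def samples_in_group(self, group: str) -> list[str]:
        if self.groups is None:
            raise ValueError("cohort has no group labels")
        return self.groups.index[self.groups == group].tolist()


@dataclass
class LabelImage:
    """Single-plane integer segmentation mask; 0 = background."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 2:
            raise ValueError(f"label image must be 2-D, got {arr.ndim}-D")
        if not np.issubdtype(arr.dtype, np.integer):
            if np.issubdtype(arr.dtype, np.floating) and np.all(arr == np.floor(arr)):
                arr = arr.astype(np.int64)
            else:
                raise ValueError("label image pixels must be integers")
        if (arr < 0).any():
            raise ValueError("label image contains negative labels")
        self.labels = arr

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def object_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_objects(self) -> int:
        return int(self.object_ids.size)


def validate_regions(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a BED-like CNA region table (0-based half-open intervals)."""
    required = ["chrom", "start", "end", "cna_type"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"region table missing columns: {missing}")
    if (df["start"] >= df["end"]).any():
        bad = df.loc[df["start"] >= df["end"]].index.tolist()
        raise ValueError(f"regions with start >= end at rows {bad[:5]}")
    unknown = set(df["cna_type"]) - set(VALID_CNA_TYPES)
    if unknown:
        raise ValueError(
            f"unknown cna_type values {sorted(unknown)}; expected {VALID_CNA_TYPES}"
        )
    if "frequency" in df.columns:
        freq = df["frequency"].dropna()
        if ((freq < 0) | (freq > 1)).any():
            raise ValueError("carrier frequencies must lie in [0, 1]")
    return df


def validate_survival(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a survival table (time_months >= 0 finite, event in {0,1})."""
    for col in ("time_months", "event"):
        if col not in df.columns:
            raise ValueError(f"survival table missing column {col!r}")
    t = df["time_months"].to_numpy(dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("survival times must be finite")
    if (t < 0).any():
        raise ValueError("negative survival time")
    ev = df["event"].to_numpy()
    if not np.isin(ev, (0, 1)).all():
        raise ValueError("event flags must be 0 or 1")
    return df
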