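"""Readers/writers for the formats the pipeline touches, plus run configuration.

GMT gene sets, delimited expression matrices, BED-like CNA region tables and
single-plane integer label images (TIFF or plain text). All stochastic stages
draw from one seeded ``numpy.random.Generator`` built by :class:`RunConfig`;
no global random state is ever used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .datatypes import ExpressionCohort, GeneSetCollection, LabelImage, validate_regions

logger = logging.getLogger("atf6scope")


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


# ---------------------------------------------------------------- gene sets


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: per line ``name<TAB>description<TAB>gene...``.

    Gene order is preserved; duplicate genes within a set are collapsed
    keeping the first occurrence; duplicate set names are an error.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path.name}:{lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name = fields[0]
            if name in sets:
                raise ParseError(f"{path.name}:{lineno}: duplicate set name {name!r}")
            genes: list[str] = []
            seen: set[str] = set()
            for g in fields[2:]:
                if g and g not in seen:
                    genes.append(g)
                    seen.add(g)
            if not genes:
                raise ParseError(f"{path.name}:{lineno}: set {name!r} has no genes")
            sets[name] = genes
    return GeneSetCollection(name=path.stem, sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, collection.name, *genes]) + "\n")


# ------------------------------------------------------------------ matrices


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_matrix(path: str | Path) -> ExpressionCohort:
    """Read a delimited genes x samples matrix (first column = gene ids)."""
    path = Path(path)
    if path.stat().st_size == 0:
        raise ParseError(f"{path.name}: empty file")
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.shape[1] == 0:
        raise ParseError(f"{path.name}: no sample columns")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path.name}: duplicate gene ids {dups[:5]}")
    if df.isna().any().any():
        raise ParseError(f"{path.name}: missing values in matrix")
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        raise ParseError(f"{path.name}: non-numeric columns {non_numeric[:5]}")
    df = df.astype(float)
    df.index.name = None
    return ExpressionCohort(expr=df, dataset=path.stem)


def write_matrix(cohort: ExpressionCohort, path: str | Path) -> None:
    path = Path(path)
    cohort.expr.to_csv(path, sep=_sep_for(path), index_label="gene")


# ------------------------------------------------------------------- regions

_REGION_COLS = ["chrom", "start", "end", "cna_type", "frequency"]


def read_regions(path: str | Path) -> pd.DataFrame:
    """Read a BED-like CNA region table.

    Columns: chrom, start, end, cna_type, frequency (optional). Intervals are
    0-based half-open; cna_type must be 'gain' or 'loss'.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(
                    f"{path.name}:{lineno}: expected >=4 fields, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path.name}:{lineno}: non-integer coordinate") from exc
            freq = float(fields[4]) if len(fields) > 4 and fields[4] != "" else np.nan
            rows.append((fields[0], start, end, fields[3], freq))
    df = pd.DataFrame(rows, columns=_REGION_COLS)
    try:
        validate_regions(df)
    except ValueError as exc:
        raise ParseError(f"{path.name}: {exc}") from exc
    return df


def write_regions(df: pd.DataFrame, path: str | Path) -> None:
    validate_regions(df)
    cols = [c for c in _REGION_COLS if c in df.columns]
    df.to_csv(path, sep="\t", header=False, index=False, columns=cols)


# -------------------------------------------------------------- label images


def read_label_image(path: str | Path) -> LabelImage:
    """Read a single-plane integer label image (TIFF or delimited text)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.loadtxt(path, dtype=float, ndmin=2)
        if not np.all(arr == np.floor(arr)):
            raise ParseError(f"{path.name}: non-integer pixels in label image")
        arr = arr.astype(np.int64)
    if arr.ndim != 2:
        raise ParseError(f"{path.name}: expected single-plane image, got {arr.ndim}-D")
    try:
        return LabelImage(labels=np.asarray(arr))
    except ValueError as exc:
        raise ParseError(f"{path.name}: {exc}") from exc


def write_label_image(image: LabelImage, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image.labels.astype(np.int32))
    else:
        np.savetxt(path, image.labels, fmt="%d", delimiter="\t")


# ------------------------------------------------------------- configuration

_KNOWN_CONFIG_KEYS = {
    "seed",
    "inputs",
    "outputs",
    "params",
}


@dataclass
class RunConfig:
    """Run configuration: a seed plus per-stage parameters and paths.

    Unknown top-level keys are rejected so that typos fail loudly.
    """

    seed: int
    params: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in raw:
            raise ValueError("config must define a seed")
        return cls(
            seed=int(raw["seed"]),
            params=raw.get("params", {}) or {},
            inputs=raw.get("inputs", {}) or {},
            outputs=raw.get("outputs", {}) or {},
        )

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
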