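"""MIBI single-cell quality control, normalization and group comparisons.

Cells are filtered on segmentation-geometry and nuclear-signal criteria
(area 71-3,318 px, nuclear sum intensity >= 9.21 a.u., nuclear proportion
0.3-99.8%); retained marker intensities are capped at the 99.9th percentile
across retained cells, scaled by 10 and arcsinh-transformed. Distribution
comparisons use the two-sided Mann-Whitney U and two-sample
Kolmogorov-Smirnov tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

REQUIRED_COLUMNS = ("area_px", "nuclear_sum_au", "nuclear_prop_pct")

QC_RULES = ("area_low", "area_high", "nuclear_dim", "prop_low", "prop_high")


@dataclass
class QCThresholds:
    """Cell-level QC cut-offs; defaults are the fixed pixel/a.u. values."""

    area_min_px: float = 71.0
    area_max_px: float = 3318.0
    nuclear_sum_min_au: float = 9.21
    nuclear_prop_min_pct: float = 0.3
    nuclear_prop_max_pct: float = 99.8
    cap_percentile: float = 99.9
    scale_factor: float = 10.0

    def __post_init__(self) -> None:
        if not self.area_min_px < self.area_max_px:
            raise ValueError("area_min must be below area_max")
        if not 0 < self.nuclear_prop_min_pct < self.nuclear_prop_max_pct < 100:
            raise ValueError("nuclear proportion bounds must satisfy 0 < min < max < 100")
        if not 0 < self.cap_percentile <= 100:
            raise ValueError("cap percentile must lie in (0, 100]")


def qc_filter_cells(
    features: pd.DataFrame, th: QCThresholds | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Exclude cells outside the acceptable QC ranges.

    A cell is dropped iff area < area_min OR area > area_max OR nuclear sum
    below the minimum (strict) OR nuclear proportion outside
    [prop_min, prop_max]. Boundary values are kept. Returns the retained
    table and per-rule exclusion counts (a cell tripping several rules counts
    once per rule and once in the total).
    """
    th = th or QCThresholds()
    missing = [c for c in REQUIRED_COLUMNS if c not in features.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    area = features["area_px"]
    nsum = features["nuclear_sum_au"]
    prop = features["nuclear_prop_pct"]
    trips = {
        "area_low": area < th.area_min_px,
        "area_high": area > th.area_max_px,
        "nuclear_dim": nsum < th.nuclear_sum_min_au,
        "prop_low": prop < th.nuclear_prop_min_pct,
        "prop_high": prop > th.nuclear_prop_max_pct,
    }
    excluded = pd.Series(False, index=features.index)
    counts: dict[str, int] = {}
    for rule, mask in trips.items():
        counts[rule] = int(mask.sum())
        excluded |= mask
    counts["total_excluded"] = int(excluded.sum())
    return features.loc[~excluded].copy(), counts


def normalize_transform(
    intensities: pd.DataFrame, th: QCThresholds | None = None
) -> pd.DataFrame:
    """Cap, scale and arcsinh-transform marker intensities of retained cells.

    Per marker: values are capped at that marker's ``cap_percentile`` across
    all retained cells, multiplied by ``scale_factor`` and arcsinh-transformed.
    Output is finite and monotone in the input below the cap.
    """
    th = th or QCThresholds()
    if intensities.empty:
        raise ValueError("no retained cells to transform")
    caps = intensities.quantile(th.cap_percentile / 100.0)
    capped = intensities.clip(upper=caps, axis=1)
    return np.arcsinh(capped * th.scale_factor)


def compare_distributions(a, b) -> dict[str, float]:
    """Two-sided Mann-Whitney U and two-sample Kolmogorov-Smirnov tests."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each sample needs at least 3 values")
    mwu = stats.mannwhitneyu(a, b, alternative="two-sided")
    ks = stats.ks_2samp(a, b)
    return {
        "n_a": int(a.size),
        "n_b": int(b.size),
        "mwu_u": float(mwu.statistic),
        "mwu_p": float(mwu.pvalue),
        "ks_stat": float(ks.statistic),
        "ks_p": float(ks.pvalue),
    }
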