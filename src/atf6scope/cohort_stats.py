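"""Cohort-level statistics: effect pooling and survival stratification.

Per-dataset tumour/non-tumour contrasts are summarized as Hedges-corrected
standardized mean differences and pooled with a DerSimonian-Laird
random-effects model (the forest-plot machinery). Survival stratification
is a median split of the activation score followed by Kaplan-Meier
estimation and the Mantel-Cox log-rank test, with administrative censoring
at a fixed follow-up horizon (60 months by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import validate_survival


# ------------------------------------------------------------ effect sizes


@dataclass
class EffectEstimate:
    dataset: str
    g: float
    var_g: float
    n_tumour: int
    n_control: int


def hedges_g(
    scores_tumour, scores_control, dataset: str = "dataset"
) -> EffectEstimate:
    """Hedges-corrected standardized mean difference tumour - control.

    g = J * (mean_t - mean_c) / s_pooled with J = 1 - 3/(4 df - 1),
    df = n_t + n_c - 2; var_g = (n_t + n_c)/(n_t n_c) + g^2 / (2 (n_t + n_c)).
    """
    t = np.asarray(scores_tumour, dtype=float)
    c = np.asarray(scores_control, dtype=float)
    if t.size < 2 or c.size < 2:
        raise ValueError("each group needs at least 2 values")
    nt, nc = t.size, c.size
    df = nt + nc - 2
    s_pooled = np.sqrt(((nt - 1) * t.var(ddof=1) + (nc - 1) * c.var(ddof=1)) / df)
    if s_pooled == 0:
        raise ValueError("zero pooled standard deviation")
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    g = j * (t.mean() - c.mean()) / s_pooled
    var_g = (nt + nc) / (nt * nc) + g**2 / (2.0 * (nt + nc))
    return EffectEstimate(dataset=dataset, g=float(g), var_g=float(var_g), n_tumour=nt, n_control=nc)


@dataclass
class MetaResult:
    pooled: float
    se: float
    ci_low: float
    ci_high: float
    tau2: float
    q: float
    weights: np.ndarray
    k: int


def dl_pool(effects: list[EffectEstimate]) -> MetaResult:
    """DerSimonian-Laird random-effects pooling of per-dataset effects.

    Moment estimator: fixed weights w_i = 1/v_i give Cochran's Q;
    tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)); random-effects
    weights w*_i = 1/(v_i + tau^2); pooled = weighted mean with 95% normal CI.
    """
    if not effects:
        raise ValueError("no effects to pool")
    y = np.array([e.g for e in effects], dtype=float)
    v = np.array([e.var_g for e in effects], dtype=float)
    if (v <= 0).any():
        raise ValueError("non-positive sampling variance")
    k = y.size
    w = 1.0 / v
    y_fe = (w * y).sum() / w.sum()
    q = float((w * (y - y_fe) ** 2).sum())
    if k > 1:
        denom = w.sum() - (w**2).sum() / w.sum()
        tau2 = max(0.0, (q - (k - 1)) / denom)
    else:
        tau2 = 0.0
    w_star = 1.0 / (v + tau2)
    pooled = float((w_star * y).sum() / w_star.sum())
    se = float(w_star.sum() ** -0.5)
    return MetaResult(
        pooled=pooled,
        se=se,
        ci_low=pooled - 1.96 * se,
        ci_high=pooled + 1.96 * se,
        tau2=float(tau2),
        q=q,
        weights=w_star,
        k=k,
    )


# -------------------------------------------------------------- median split


def median_split(scores) -> pd.Series:
    """Split samples into 'high' (> median) and 'low' (<= median) groups.

    Ties at the median go to 'low', keeping 'high' strictly above the median;
    with all-distinct scores and even n the groups have equal size.
    """
    s = pd.Series(scores, dtype=float)
    if s.size < 2:
        raise ValueError("need at least 2 scores for a median split")
    med = s.median()
    return pd.Series(np.where(s > med, "high", "low"), index=s.index, name="group")


# ------------------------------------------------------------------ survival


def administrative_censor(tbl: pd.DataFrame, cutoff_months: float = 60.0) -> pd.DataFrame:
    """Treat events after the follow-up horizon as alive at the horizon.

    Records with time > cutoff become (cutoff, event=0); records at or below
    the cutoff are unchanged. Idempotent.
    """
    if cutoff_months <= 0:
        raise ValueError("cutoff must be positive")
    validate_survival(tbl)
    out = tbl.copy()
    late = out["time_months"] > cutoff_months
    out.loc[late, "time_months"] = cutoff_months
    out.loc[late, "event"] = 0
    return out


@dataclass
class KMCurve:
    """Product-limit survival curve: step function over event times."""

    times: np.ndarray  # event-time grid (distinct times with >=1 event)
    survival: np.ndarray  # S(t) just after each grid time
    at_risk: np.ndarray

    def at(self, t: float) -> float:
        """S(t) for arbitrary t (right-continuous step function)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(tbl: pd.DataFrame) -> KMCurve:
    """Kaplan-Meier product-limit estimator S(t) = prod(1 - d_i/n_i).

    Censored-only times shrink the risk set without producing a step.
    """
    validate_survival(tbl)
    if tbl.empty:
        raise ValueError("empty survival table")
    t = tbl["time_months"].to_numpy(dtype=float)
    e = tbl["event"].to_numpy(dtype=int)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    times, survival, at_risk = [], [], []
    s = 1.0
    n = t.size
    i = 0
    while i < n:
        ti = t[i]
        j = i
        d = 0
        while j < n and t[j] == ti:
            d += e[j]
            j += 1
        if d > 0:
            s *= 1.0 - d / (n - i)
            times.append(ti)
            survival.append(s)
            at_risk.append(n - i)
        i = j
    return KMCurve(
        times=np.array(times), survival=np.array(survival), at_risk=np.array(at_risk)
    )


def logrank_test(tbl: pd.DataFrame, group_col: str = "group") -> tuple[float, float]:
    """Two-group Mantel-Cox log-rank test.

    At each distinct event time the expected events in group 1 come from the
    hypergeometric distribution given the risk sets; the statistic
    (O - E)^2 / V is referred to chi-square with 1 df (two-sided p).
    """
    validate_survival(tbl)
    groups = tbl[group_col].unique()
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {list(groups)}")
    g1 = groups[0]
    t = tbl["time_months"].to_numpy(dtype=float)
    e = tbl["event"].to_numpy(dtype=int)
    in1 = (tbl[group_col] == g1).to_numpy()
    if in1.all() or not in1.any():
        raise ValueError("a group has zero subjects")
    stat = _logrank_statistic(t, e, in1)
    p = float(stats.chi2.sf(stat, df=1))
    return float(stat), p


def _logrank_statistic(t: np.ndarray, e: np.ndarray, in1: np.ndarray) -> float:
    """Chi-square log-rank statistic for membership vector ``in1``."""
    event_times = np.unique(t[e == 1])
    o_minus_e = 0.0
    var = 0.0
    for ti in event_times:
        at_risk = t >= ti
        n = at_risk.sum()
        n1 = (at_risk & in1).sum()
        d = ((t == ti) & (e == 1)).sum()
        d1 = ((t == ti) & (e == 1) & in1).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0
    return float(o_minus_e**2 / var)


def logrank_permutation_p(
    tbl: pd.DataFrame,
    group_col: str = "group",
    n_perm: int = 10_000,
    rng: np.random.Generator | None = None,
) -> float:
    """Permutation-null p-value for the log-rank statistic (label shuffles)."""
    rng = rng or np.random.default_rng(0)
    t = tbl["time_months"].to_numpy(dtype=float)
    e = tbl["event"].to_numpy(dtype=int)
    in1 = (tbl[group_col] == tbl[group_col].unique()[0]).to_numpy()
    obs = _logrank_statistic(t, e, in1)
    exceed = 0
    for _ in range(n_perm):
        if _logrank_statistic(t, e, rng.permutation(in1)) >= obs:
            exceed += 1
    return (1.0 + exceed) / (n_perm + 1.0)


# ------------------------------------------------------- TMA count summaries


def positivity_percentage(n_scored_positive: int, n_total: int, decimals: int = 1) -> float:
    """Percentage of scored-positive samples among all samples (e.g. TMA cores)."""
    if n_total <= 0 or n_scored_positive < 0 or n_scored_positive > n_total:
        raise ValueError("invalid counts")
    return round(100.0 * n_scored_positive / n_total, decimals)


def sum_strata(strata: dict[str, int]) -> int:
    """Total patients across grade strata (consistency check for printed counts)."""
    counts = list(strata.values())
    if any(c < 0 for c in counts):
        raise ValueError("negative stratum count")
    return int(sum(counts))
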