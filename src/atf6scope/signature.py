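"""Signature construction and per-sample enrichment scoring.

The activation signature is a pair of UP/DN gene sets selected from a
differential-expression table (|log2FC| >= 1, BH-adjusted p < 0.05 by
default). Per-sample enrichment uses the single-sample GSEA (ssGSEA)
running-sum statistic; the combined activation score is
``score_combined = score_up - score_dn``. Samples are called high/low by
nearest-template prediction (NTP) with a random-gene-set permutation null,
and score-phenotype association uses the information coefficient (IC), a
signed mutual-information correlate bounded in [-1, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionCohort, SignaturePair

logger = logging.getLogger("atf6scope.signature")

DEFAULT_ALPHA = 0.25


# ------------------------------------------------------------- construction


def build_signature(
    de: pd.DataFrame,
    lfc_cut: float = 1.0,
    fdr_cut: float = 0.05,
    name: str = "signature",
) -> SignaturePair:
    """Select UP/DN gene sets from a differential-expression table.

    ``de`` needs columns ``gene``, ``log2fc``, ``p_adj``. A gene enters UP if
    log2fc >= lfc_cut (inclusive) and p_adj < fdr_cut (strict); DN mirrors
    with log2fc <= -lfc_cut. Empty result sets are legal and logged.
    """
    if de.empty:
        raise ValueError("differential-expression table is empty")
    for col in ("gene", "log2fc", "p_adj"):
        if col not in de.columns:
            raise ValueError(f"DE table missing column {col!r}")
    if de["gene"].duplicated().any():
        raise ValueError("duplicate gene ids in DE table")
    p = de["p_adj"].to_numpy(dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p_adj outside [0, 1]")
    sig = de.loc[p < fdr_cut]
    up = sig.loc[sig["log2fc"] >= lfc_cut, "gene"].tolist()
    dn = sig.loc[sig["log2fc"] <= -lfc_cut, "gene"].tolist()
    if not up or not dn:
        logger.warning("signature %s has empty set(s): up=%d dn=%d", name, len(up), len(dn))
    return SignaturePair(up=up, dn=dn, name=name)


# ----------------------------------------------------------------- ranking


def rank_normalize(cohort: ExpressionCohort) -> pd.DataFrame:
    """Per-sample descending ranks (1 = highest expression).

    Ties break by ascending gene-id lexicographic order, making the ranking
    deterministic for constant or discretized samples.
    """
    expr = cohort.expr.sort_index()
    x = expr.to_numpy(dtype=float)
    # stable argsort of -x keeps the id-ascending row order within ties
    order = np.argsort(-x, axis=0, kind="stable")
    ranks = np.empty_like(order)
    n = x.shape[0]
    rows = np.arange(1, n + 1)[:, None]
    np.put_along_axis(ranks, order, np.broadcast_to(rows, order.shape), axis=0)
    return pd.DataFrame(ranks, index=expr.index, columns=expr.columns)


def _present_genes(cohort: ExpressionCohort, genes) -> list[str]:
    index = set(cohort.expr.index)
    present = [g for g in genes if g in index]
    dropped = len(list(genes)) - len(present)
    if dropped:
        logger.warning("%d signature gene(s) absent from matrix, dropped", dropped)
    return present


def ssgsea_score(
    cohort: ExpressionCohort,
    gene_set,
    alpha: float = DEFAULT_ALPHA,
) -> pd.Series:
    """Single-sample GSEA enrichment score for one gene set, per sample.

    Within each sample, genes are ordered by descending expression (ties by
    ascending gene id). Walking down that ordering, the in-set running sum
    accumulates rank-statistic weights ``r**alpha`` (r = N at the top of the
    list, 1 at the bottom) normalized to total 1, while the out-of-set sum
    accumulates uniform mass 1/(N-m). The score is the sum over all list
    positions of (P_in - P_out). Genes absent from the matrix are dropped;
    if the set spans every gene the out-of-set term is defined as zero.
    """
    present = _present_genes(cohort, gene_set)
    if not present:
        raise ValueError("no gene of the set is present in the matrix")
    expr = cohort.expr.sort_index()
    x = expr.to_numpy(dtype=float)
    n, n_samples = x.shape
    m = len(present)

    in_set = expr.index.isin(present)
    order = np.argsort(-x, axis=0, kind="stable")
    in_sorted = in_set[order]  # (n, n_samples) membership along each ordering

    rstat = np.arange(n, 0, -1, dtype=float)[:, None]  # N at top position
    w = np.where(in_sorted, rstat**alpha, 0.0)
    p_in = np.cumsum(w, axis=0) / np.sum(w, axis=0, keepdims=True)
    if m < n:
        p_out = np.cumsum(np.where(in_sorted, 0.0, 1.0 / (n - m)), axis=0)
    else:
        p_out = np.zeros_like(p_in)
    scores = (p_in - p_out).sum(axis=0)
    return pd.Series(scores, index=expr.columns, name="es")


def combined_score(es_up: pd.Series, es_dn: pd.Series) -> pd.Series:
    """Combined activation score: UP enrichment minus DN enrichment."""
    if set(es_up.index) != set(es_dn.index):
        raise ValueError("up/dn scores cover different samples")
    return (es_up - es_dn.reindex(es_up.index)).rename("es_combined")


def score_signature(
    cohort: ExpressionCohort,
    sig: SignaturePair,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Score a cohort against an UP/DN signature pair.

    Returns a per-sample table with es_up, es_dn and es_combined.
    """
    es_up = ssgsea_score(cohort, sig.up, alpha=alpha)
    es_dn = ssgsea_score(cohort, sig.dn, alpha=alpha)
    return pd.DataFrame(
        {"es_up": es_up, "es_dn": es_dn, "es_combined": combined_score(es_up, es_dn)}
    )


# --------------------------------------------------------------------- NTP


@dataclass
class NTPResult:
    """Per-sample nearest-template calls with permutation FDR."""

    calls: pd.DataFrame  # columns: class, dist_high, dist_low, p_value, fdr, significant
    n_perm: int
    fdr_cut: float


def _template_distances(values: np.ndarray, template: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between each sample column and the template."""
    v = values - values.mean(axis=0, keepdims=True)
    t = template - template.mean()
    denom = np.sqrt((v**2).sum(axis=0)) * np.sqrt((t**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (v * t[:, None]).sum(axis=0) / denom
    corr = np.where(np.isfinite(corr), corr, 0.0)
    return 1.0 - corr


def ntp_classify(
    cohort: ExpressionCohort,
    sig: SignaturePair,
    n_perm: int = 1000,
    fdr_cut: float = 0.05,
    rng: np.random.Generator | None = None,
) -> NTPResult:
    """Nearest-template prediction of high/low signature activation.

    The high template is +1 on UP genes and -1 on DN genes; the low template
    is its negation. Expression is gene-wise standardized across the cohort
    (so shared per-gene baselines cannot pull every sample toward one
    template); each sample is then assigned the template with the smaller
    correlation distance. Significance comes from ``n_perm`` random gene sets
    of matched sizes: p = fraction of null distances <= the observed distance
    to the assigned template, BH-adjusted across samples.
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    if n_perm < 100:
        logger.warning("n_perm=%d is small; permutation p-values will be coarse", n_perm)
    rng = rng or np.random.default_rng(0)

    up = _present_genes(cohort, sig.up)
    dn = _present_genes(cohort, sig.dn)
    if len(up) + len(dn) < 2:
        raise ValueError("fewer than 2 signature genes present in the matrix")
    raw = cohort.expr
    mu = raw.mean(axis=1)
    sd = raw.std(axis=1, ddof=0).replace(0.0, 1.0)
    expr = raw.sub(mu, axis=0).div(sd, axis=0)
    sig_values = expr.loc[up + dn].to_numpy(dtype=float)
    template_high = np.concatenate([np.ones(len(up)), -np.ones(len(dn))])

    d_high = _template_distances(sig_values, template_high)
    d_low = _template_distances(sig_values, -template_high)
    assigned_high = d_high <= d_low
    d_obs = np.where(assigned_high, d_high, d_low)

    all_genes = expr.index.to_numpy()
    x = expr.to_numpy(dtype=float)
    k = len(up) + len(dn)
    null = np.empty((n_perm, x.shape[1]))
    for b in range(n_perm):
        idx = rng.choice(len(all_genes), size=k, replace=False)
        null[b] = _template_distances(x[idx], template_high)
    # each sample's p: how often a random-set distance is at least as small
    p = (1.0 + (null <= d_obs[None, :]).sum(axis=0)) / (n_perm + 1.0)
    fdr = bh_adjust(p)

    calls = pd.DataFrame(
        {
            "class": np.where(assigned_high, "high", "low"),
            "dist_high": d_high,
            "dist_low": d_low,
            "p_value": p,
            "fdr": fdr,
            "significant": fdr < fdr_cut,
        },
        index=expr.columns,
    )
    return NTPResult(calls=calls, n_perm=n_perm, fdr_cut=fdr_cut)


# ---------------------------------------------------------------------- IC


def _silverman_bw(v: np.ndarray) -> float:
    n = v.size
    sd = v.std(ddof=1)
    iqr = np.subtract(*np.percentile(v, [75, 25]))
    scale = min(sd, iqr / 1.349) if iqr > 0 else sd
    if scale == 0:
        scale = 1.0
    return 0.9 * scale * n ** (-1 / 5)


def _kde_mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Leave-one-out Gaussian-KDE mutual information (diagonal bandwidths)."""
    n = x.size
    hx, hy = _silverman_bw(x), _silverman_bw(y)
    dx = (x[:, None] - x[None, :]) / hx
    dy = (y[:, None] - y[None, :]) / hy
    kx = np.exp(-0.5 * dx**2)
    ky = np.exp(-0.5 * dy**2)
    np.fill_diagonal(kx, 0.0)
    np.fill_diagonal(ky, 0.0)
    # joint kernel is the product of the marginals' kernels (diagonal bandwidth)
    fxy = (kx * ky).sum(axis=1) / ((n - 1) * 2 * np.pi * hx * hy)
    fx = kx.sum(axis=1) / ((n - 1) * np.sqrt(2 * np.pi) * hx)
    fy = ky.sum(axis=1) / ((n - 1) * np.sqrt(2 * np.pi) * hy)
    eps = np.finfo(float).tiny
    return float(np.mean(np.log((fxy + eps) / (fx * fy + eps))))


@dataclass
class AssociationResult:
    ic: float
    p_value: float
    n_perm: int


def information_coefficient(
    x,
    y,
    n_perm: int = 100,
    rng: np.random.Generator | None = None,
) -> AssociationResult:
    """Information coefficient: sign(rho) * sqrt(1 - exp(-2 I)).

    ``rho`` is the Pearson correlation and ``I`` a kernel-density mutual
    information estimate, so |IC| <= 1 with the sign of the linear trend.
    Significance is an empirical permutation test shuffling ``y``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y differ in length")
    if x.size < 8:
        raise ValueError("need at least 8 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    rng = rng or np.random.default_rng(0)

    def _ic(xv: np.ndarray, yv: np.ndarray) -> float:
        if xv.std() == 0 or yv.std() == 0:
            logger.warning("constant vector; IC defined as 0")
            return 0.0
        rho = np.corrcoef(xv, yv)[0, 1]
        mi = max(0.0, _kde_mutual_information(xv, yv))
        return float(np.sign(rho) * np.sqrt(1.0 - np.exp(-2.0 * mi)))

    ic_obs = _ic(x, y)
    exceed = 0
    for _ in range(n_perm):
        if abs(_ic(x, rng.permutation(y))) >= abs(ic_obs):
            exceed += 1
    p = (1.0 + exceed) / (n_perm + 1.0)
    return AssociationResult(ic=ic_obs, p_value=p, n_perm=n_perm)


# ------------------------------------------------------------------- BH FDR


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
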