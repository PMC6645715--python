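"""Negative-binomial differential expression between temporal states.

A deliberately compact NB Wald stage: median-of-ratios library-size
normalisation, method-of-moments gene-wise dispersions shrunk toward a
fitted mean-dispersion trend, a delta-method Wald statistic on the log2
fold change of state means, and Benjamini-Hochberg adjustment.  Counts are
modelled as NB with Var = mu + alpha * mu^2 (alpha the dispersion).
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .counting import CountMatrix

__all__ = [
    "size_factors",
    "estimate_dispersions",
    "nb_wald_test",
    "call_degs",
]

_LN2 = np.log(2.0)
_DISP_FLOOR = 1e-8


def size_factors(matrix: CountMatrix, pseudocount: float = 0.0) -> pd.Series:
    """Median-of-ratios library size factors, normalised to geometric mean 1.

    Each sample's factor is the median, over genes with all-positive counts,
    of that sample's count divided by the gene's geometric mean across
    samples.  ``pseudocount`` > 0 rescues matrices where no gene is observed
    in every sample (sparse, low-depth data).
    """
    counts = matrix.counts.to_numpy(dtype=float) + pseudocount
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has positive counts in every sample; "
            "retry with a pseudocount (size_factors(matrix, pseudocount=0.5))"
        )
    log_counts = np.log(counts[positive])
    log_geomean = log_counts.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(log_counts - log_geomean, axis=0))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=matrix.counts.columns, name="size_factor")


def _fit_dispersion_trend(mean: np.ndarray, disp_raw: np.ndarray) -> Tuple[float, float]:
    """Fit alpha(mu) = a0 + a1/mu over gene-wise moment estimates.

    Individual estimates are extremely noisy at few replicates, so the fit
    uses per-quantile-bin means of the *raw* (possibly negative) estimates:
    the sample variance is unbiased, hence so are the bin means, where
    trimming or flooring first would bias the trend.
    """
    keep = mean > 0
    if keep.sum() < 20:
        pos = disp_raw[disp_raw > 0]
        return (float(np.median(pos)) if pos.size else 0.01), 0.0
    x, y = mean[keep], disp_raw[keep]
    order = np.argsort(x)
    n_bins = min(20, max(2, len(x) // 50))
    bins = np.array_split(order, n_bins)
    bx = np.array([x[b].mean() for b in bins])
    by = np.array([y[b].mean() for b in bins])
    design = np.column_stack([np.ones_like(bx), 1.0 / bx])
    coef, *_ = np.linalg.lstsq(design, by, rcond=None)
    return float(max(coef[0], _DISP_FLOOR)), float(max(coef[1], 0.0))


def estimate_dispersions(
    norm: pd.DataFrame,
    groups: Sequence[Sequence[str]],
    shrink_weight: float = 0.25,
) -> pd.Series:
    """Per-gene NB dispersions from normalised counts.

    Gene-wise method of moments on the pooled within-group residuals, then
    shrinkage in log space toward the fitted mean-dispersion trend with
    weight ``shrink_weight`` on the gene-wise value.  With only a few
    replicates the gene-wise moments are very noisy, so the trend dominates.
    """
    values = norm.to_numpy(dtype=float)
    n_total = sum(len(g) for g in groups)
    df = n_total - len(groups)
    if df < 1:
        raise ValueError("need at least one residual degree of freedom")
    ss = np.zeros(values.shape[0])
    grand = np.zeros(values.shape[0])
    for cols in groups:
        sub = norm[list(cols)].to_numpy(dtype=float)
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        grand += sub.sum(axis=1)
    grand /= n_total
    s2 = ss / df
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(grand > 0, (s2 - grand) / np.maximum(grand, 1e-300) ** 2, 0.0)
    a0, a1 = _fit_dispersion_trend(grand, raw)
    trend = a0 + a1 / np.maximum(grand, 1e-300)
    trend = np.maximum(trend, _DISP_FLOOR)
    # under-dispersed moment estimates are floored relative to the trend, not
    # to zero: a log-space average with a near-zero term would otherwise
    # collapse the shrunk value and inflate the Wald statistic
    genewise = np.maximum(raw, 0.25 * trend)
    log_alpha = shrink_weight * np.log(genewise) + (1 - shrink_weight) * np.log(trend)
    return pd.Series(np.exp(log_alpha), index=norm.index, name="dispersion")


def nb_wald_test(
    matrix: CountMatrix,
    contrast: Tuple[str, str],
    pseudocount: float = 0.5,
    shrink_weight: float = 0.25,
    factors: Optional[pd.Series] = None,
    size_factor_pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Wald test of ``contrast = (state_a, state_b)``; log2fc is b over a.

    Returns a table indexed by gene with columns ``baseMean, log2fc, se, p,
    padj, tested`` plus per-state RPM columns ``rpm_<state>`` for every state
    in the matrix.  All-zero genes get log2fc 0, p 1 and ``tested`` False;
    BH adjustment runs over tested genes only.
    """
    state_a, state_b = contrast
    matrix.require_replicates(2)
    for state in contrast:
        if state not in matrix.states:
            raise ValueError(f"state {state!r} not present in matrix")
    if factors is None:
        factors = size_factors(matrix, pseudocount=size_factor_pseudocount)
    norm = matrix.counts / factors

    cols_a = matrix.samples_of_state(state_a)
    cols_b = matrix.samples_of_state(state_b)
    n_a, n_b = len(cols_a), len(cols_b)
    mean_a = norm[cols_a].mean(axis=1).to_numpy()
    mean_b = norm[cols_b].mean(axis=1).to_numpy()

    alpha = estimate_dispersions(
        norm[cols_a + cols_b], [cols_a, cols_b], shrink_weight=shrink_weight
    ).to_numpy()

    log2fc = np.log2(mean_b + pseudocount) - np.log2(mean_a + pseudocount)
    # delta method on log2 of the state mean of NB counts
    var_a = (mean_a + alpha * mean_a**2) / n_a
    var_b = (mean_b + alpha * mean_b**2) / n_b
    se = np.sqrt(
        var_a / (mean_a + pseudocount) ** 2 + var_b / (mean_b + pseudocount) ** 2
    ) / _LN2
    tested = (matrix.counts[cols_a + cols_b].sum(axis=1) > 0).to_numpy()

    z = np.zeros_like(log2fc)
    np.divide(log2fc, se, out=z, where=se > 0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(tested, p, 1.0)
    log2fc = np.where(tested, log2fc, 0.0)

    padj = np.full_like(p, np.nan)
    if tested.any():
        padj[tested] = multipletests(p[tested], method="fdr_bh")[1]

    result = pd.DataFrame(
        {
            "baseMean": (mean_a * n_a + mean_b * n_b) / (n_a + n_b),
            "log2fc": log2fc,
            "se": se,
            "p": p,
            "padj": padj,
            "tested": tested,
        },
        index=matrix.gene_ids,
    )
    state_rpm = matrix.state_rpm()
    for state in matrix.states:
        result[f"rpm_{state}"] = state_rpm[state]
    result.attrs["contrast"] = (state_a, state_b)
    return result


def call_degs(
    result: pd.DataFrame,
    fdr: float = 0.05,
    lfc: float = 1.0,
    rpm_min: float = 10.0,
    per_replicate_rpm: Optional[pd.DataFrame] = None,
) -> pd.Index:
    """Differentially expressed genes at the study's thresholds.

    A gene passes when padj < ``fdr``, |log2fc| > ``lfc`` and its maximum
    state-level RPM exceeds ``rpm_min``.  Passing ``per_replicate_rpm``
    switches the RPM criterion to the per-replicate maximum instead of the
    state means.
    """
    rpm_cols = [c for c in result.columns if c.startswith("rpm_")]
    if not rpm_cols:
        raise ValueError("result table has no rpm_<state> columns")
    if per_replicate_rpm is not None:
        max_rpm = per_replicate_rpm.reindex(result.index).max(axis=1)
    else:
        max_rpm = result[rpm_cols].max(axis=1)
    passing = (
        (result["padj"] < fdr)
        & (result["log2fc"].abs() > lfc)
        & (max_rpm > rpm_min)
        & result["tested"]
    )
    return result.index[passing.fillna(False)]
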