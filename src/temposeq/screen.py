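"""Temporal-switch candidate screen and stage-profile clustering.

The screen looks for genes with dynamic expression across the D -> Grh ->
Ey progression: a log2 fold change above a major threshold in one of the
two transitions, at least a minor threshold in the other, and a minimum
expression level (RPM) in at least one state.  The sign pattern of the two
transition fold changes classifies the temporal shape; the flagship shape
is high-low-high (down into Grh, back up into Ey).
"""

from __future__ import annotations

import logging
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

__all__ = [
    "classify_pattern",
    "build_transition_profiles",
    "candidate_filter",
    "cluster_profiles",
]

PATTERNS = ("high_low_high", "low_high_low", "monotone_up", "monotone_down", "other")


def classify_pattern(lfc_dg: float, lfc_ge: float) -> str:
    """Temporal shape from the signs of the two transition fold changes."""
    if lfc_dg == 0 or lfc_ge == 0 or not (np.isfinite(lfc_dg) and np.isfinite(lfc_ge)):
        return "other"
    if lfc_dg < 0 < lfc_ge:
        return "high_low_high"
    if lfc_ge < 0 < lfc_dg:
        return "low_high_low"
    return "monotone_up" if lfc_dg > 0 else "monotone_down"


def build_transition_profiles(
    de_dg: pd.DataFrame, de_ge: pd.DataFrame
) -> pd.DataFrame:
    """Join the two transition DE tables into one per-gene profile table.

    ``de_dg`` is the D -> Grh contrast, ``de_ge`` Grh -> Ey (each as returned
    by :func:`temposeq.de.nb_wald_test`).  Genes missing from either table
    are skipped with a warning.
    """
    shared = de_dg.index.intersection(de_ge.index)
    dropped = len(de_dg.index.union(de_ge.index)) - len(shared)
    if dropped:
        logger.warning("%d genes missing from one transition table: skipped", dropped)
    rpm_cols = [c for c in de_dg.columns if c.startswith("rpm_")]
    profiles = pd.DataFrame(
        {
            "lfc_DG": de_dg.loc[shared, "log2fc"],
            "lfc_GE": de_ge.loc[shared, "log2fc"],
            "padj_DG": de_dg.loc[shared, "padj"],
            "padj_GE": de_ge.loc[shared, "padj"],
        }
    )
    for c in rpm_cols:
        profiles[c] = de_dg.loc[shared, c]
    return profiles


def candidate_filter(
    profiles: pd.DataFrame,
    lfc_major: float = 1.0,
    lfc_minor: float = 0.5,
    rpm_min: float = 50.0,
    require_deg: bool = False,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Temporal-dynamics candidate filter.

    A gene passes when |lfc| > ``lfc_major`` in at least one transition,
    |lfc| >= ``lfc_minor`` in the other, and its maximum state RPM exceeds
    ``rpm_min``.  ``require_deg`` additionally demands padj < ``fdr`` in at
    least one transition.  Returns the passing genes with their pattern
    class and a rank key (magnitude of the qualifying fold change),
    descending.
    """
    rpm_cols = [c for c in profiles.columns if c.startswith("rpm_")]
    if not rpm_cols:
        raise ValueError("profiles need rpm_<state> columns")
    finite = profiles[["lfc_DG", "lfc_GE"]].notna().all(axis=1)
    skipped = (~finite).sum()
    if skipped:
        logger.warning("%d genes with a missing transition lfc: skipped", skipped)
    prof = profiles[finite]
    abs_dg = prof["lfc_DG"].abs()
    abs_ge = prof["lfc_GE"].abs()
    major = (abs_dg > lfc_major) | (abs_ge > lfc_major)
    minor = ((abs_dg > lfc_major) | (abs_dg >= lfc_minor)) & (
        (abs_ge > lfc_major) | (abs_ge >= lfc_minor)
    )
    expressed = prof[rpm_cols].max(axis=1) > rpm_min
    passing = major & minor & expressed
    if require_deg:
        passing &= (prof["padj_DG"] < fdr) | (prof["padj_GE"] < fdr)
    hits = prof[passing].copy()
    qualifying = np.where(
        abs_dg[passing] > lfc_major,
        np.where(
            abs_ge[passing] > lfc_major,
            np.maximum(abs_dg[passing], abs_ge[passing]),
            abs_dg[passing],
        ),
        abs_ge[passing],
    )
    hits["pattern"] = [
        classify_pattern(dg, ge) for dg, ge in zip(hits["lfc_DG"], hits["lfc_GE"])
    ]
    hits["rank_key"] = qualifying
    return hits.sort_values(["rank_key", "lfc_DG"], ascending=[False, True], kind="mergesort")


def _correlation_distance(profiles: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson distances with a zero-variance guard.

    A constant profile has undefined correlation; it is treated as
    uncorrelated (distance 1) with any varying profile and identical
    (distance 0) to another constant one.
    """
    centered = profiles - profiles.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    safe = norms > 1e-12
    unit = np.zeros_like(centered)
    unit[safe] = centered[safe] / norms[safe, None]
    corr = unit @ unit.T
    both_flat = ~safe[:, None] & ~safe[None, :]
    corr[both_flat] = 1.0
    np.fill_diagonal(corr, 1.0)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    return squareform(dist, checks=False)


def cluster_profiles(
    state_rpm: pd.DataFrame,
    de_tables: Optional[list] = None,
    lfc_threshold: float = 1.0,
    padj_threshold: float = 0.05,
    rpm_min: float = 10.0,
    k: int = 4,
    method: str = "average",
) -> Tuple[pd.Series, np.ndarray]:
    """Hierarchical clustering of per-state expression profiles.

    Genes are filtered to those with |log2fc| > ``lfc_threshold`` and
    padj < ``padj_threshold`` in at least one pairwise comparison (from
    ``de_tables``) and a maximum state RPM >= ``rpm_min``; their z-scored
    log2(RPM + 1) profiles are clustered with 1 - Pearson distances and the
    tree cut into ``k`` clusters.  Genes are processed in sorted-id order so
    the labels do not depend on input row order; labels are renumbered by
    first appearance.  Returns (labels, linkage matrix).
    """
    keep = state_rpm.max(axis=1) >= rpm_min
    if de_tables:
        any_de = pd.Series(False, index=state_rpm.index)
        for table in de_tables:
            sig = (table["log2fc"].abs() > lfc_threshold) & (
                table["padj"] < padj_threshold
            )
            any_de |= sig.reindex(state_rpm.index, fill_value=False)
        keep &= any_de
    genes = sorted(state_rpm.index[keep])
    if len(genes) < k:
        raise ValueError(f"only {len(genes)} genes pass the filter; need >= k={k}")
    values = np.log2(state_rpm.loc[genes].to_numpy(dtype=float) + 1.0)
    sd = values.std(axis=1, keepdims=True)
    z = np.where(sd > 1e-12, (values - values.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1), 0.0)
    condensed = _correlation_distance(z)
    linkage = hierarchy.linkage(condensed, method=method)
    raw = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    relabel: dict = {}
    labels = []
    for r in raw:
        if r not in relabel:
            relabel[r] = len(relabel) + 1
        labels.append(relabel[r])
    return pd.Series(labels, index=pd.Index(genes, name="gene_id"), name="cluster"), linkage
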