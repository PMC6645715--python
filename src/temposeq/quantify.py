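"""Small quantification formulas: CTCF, 2^-ddCt, summary-statistic t-tests.

These reproduce the arithmetic used to quantify immunofluorescence
intensities (corrected total cell fluorescence), qPCR relative expression
(the 2^-ddCt method with Act5c as reference gene), and the unpaired
two-tailed Student's t-tests computed from group means, SDs and sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CellIntensity",
    "CtRecord",
    "GroupSummary",
    "ctcf",
    "group_intensity_ratio",
    "ddct",
    "t_from_summary",
]

REFERENCE_GENE = "Act5c"


@dataclass(frozen=True)
class CellIntensity:
    """One circled region of an image: a cell or a background reading.

    ``integrated_density`` is the sum of pixel gray values over the region,
    ``area`` the pixel count.  ``marker_positive`` records whether the cell
    expresses the temporal identity marker being scored.
    """

    cell_id: str
    brain_id: str
    marker_positive: bool
    integrated_density: float
    area: float
    role: str = "cell"  # or "background"

    def __post_init__(self):
        if self.role not in ("cell", "background"):
            raise ValueError(f"role must be 'cell' or 'background', got {self.role!r}")
        if self.area <= 0:
            raise ValueError(f"{self.cell_id}: area must be positive")
        if self.integrated_density < 0:
            raise ValueError(f"{self.cell_id}: integrated density must be >= 0")

    @property
    def mean_fluorescence(self) -> float:
        return self.integrated_density / self.area


@dataclass(frozen=True)
class CtRecord:
    """One qPCR threshold-cycle observation."""

    sample_id: str
    group: str
    gene: str
    ct: float

    def __post_init__(self):
        if not np.isfinite(self.ct):
            raise ValueError(f"{self.sample_id}/{self.gene}: Ct must be finite")

    @property
    def is_reference(self) -> bool:
        return self.gene == REFERENCE_GENE


@dataclass(frozen=True)
class GroupSummary:
    """Mean +- SD summary of one experimental group, as printed in legends."""

    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n < 2:
            raise ValueError("need n >= 2 observations")


def ctcf(cell: CellIntensity, mean_background_fluorescence: float) -> float:
    """Corrected total cell fluorescence.

    integrated density - area x mean background fluorescence; negative values
    are reported as-is.
    """
    if cell.role != "cell":
        raise ValueError(f"{cell.cell_id}: CTCF is defined for cells, not background")
    return cell.integrated_density - cell.area * mean_background_fluorescence


def group_intensity_ratio(cells: Sequence[CellIntensity]) -> pd.DataFrame:
    """Per-brain marker-positive vs -negative CTCF means, background-normalised.

    For each brain: mean background fluorescence from its background regions,
    CTCF per cell, then the means of positive and negative cells, each
    divided by that brain's background mean.  Returns one row per brain with
    columns ``positive_norm, negative_norm, ratio``.
    """
    by_brain: Dict[str, List[CellIntensity]] = {}
    for c in cells:
        by_brain.setdefault(c.brain_id, []).append(c)
    rows = {}
    for brain, items in by_brain.items():
        backgrounds = [c for c in items if c.role == "background"]
        pos = [c for c in items if c.role == "cell" and c.marker_positive]
        neg = [c for c in items if c.role == "cell" and not c.marker_positive]
        if not backgrounds:
            raise ValueError(f"brain {brain!r}: no background readings")
        if not pos or not neg:
            raise ValueError(f"brain {brain!r}: need both positive and negative cells")
        bg_mean = float(np.mean([c.mean_fluorescence for c in backgrounds]))
        if bg_mean <= 0:
            raise ValueError(f"brain {brain!r}: non-positive background mean")
        pos_mean = float(np.mean([ctcf(c, bg_mean) for c in pos]))
        neg_mean = float(np.mean([ctcf(c, bg_mean) for c in neg]))
        rows[brain] = {
            "positive_norm": pos_mean / bg_mean,
            "negative_norm": neg_mean / bg_mean,
            "ratio": pos_mean / neg_mean if neg_mean != 0 else np.nan,
        }
    out = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    out.index.name = "brain_id"
    return out


def ddct(
    records: Sequence[CtRecord],
    control_group: str,
    target_group: str,
    gene: str,
    reference: str = REFERENCE_GENE,
    per_sample: bool = False,
) -> float:
    """Relative expression of ``gene`` in target vs control by 2^-ddCt.

    dCt = Ct_gene - Ct_reference per sample; ddCt = mean dCt(target) -
    mean dCt(control); returns 2**(-ddCt).  ``per_sample`` instead averages
    per-sample fold changes 2**-(dCt - mean control dCt) within the target
    group (geometrically equivalent only when dCts are balanced).
    """
    table: Dict[Tuple[str, str], Dict[str, float]] = {}
    for r in records:
        table.setdefault((r.group, r.sample_id), {})[r.gene] = r.ct
    dct: Dict[str, List[float]] = {control_group: [], target_group: []}
    for (group, sample), cts in table.items():
        if group not in dct:
            continue
        if reference not in cts:
            raise ValueError(f"sample {sample!r}: no Ct for reference gene {reference!r}")
        if gene in cts:
            dct[group].append(cts[gene] - cts[reference])
    for group, values in dct.items():
        if not values:
            raise ValueError(f"group {group!r}: no Ct observations for gene {gene!r}")
    control_mean = float(np.mean(dct[control_group]))
    if per_sample:
        return float(np.mean([2.0 ** -(v - control_mean) for v in dct[target_group]]))
    ddct_value = float(np.mean(dct[target_group])) - control_mean
    return float(2.0**-ddct_value)


def t_from_summary(
    a: GroupSummary, b: GroupSummary, mode: str = "pooled"
) -> Tuple[float, float, float]:
    """Two-sample t-test from summary statistics; returns (t, df, p).

    ``pooled`` is the classical Student test with pooled variance; ``welch``
    uses the Welch-Satterthwaite approximation.  p is two-sided.
    """
    if mode == "pooled":
        df = a.n + b.n - 2
        sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
        denom = np.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
    elif mode == "welch":
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        denom = np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    else:
        raise ValueError(f"mode must be 'pooled' or 'welch', got {mode!r}")
    if denom == 0:
        t = 0.0 if a.mean == b.mean else np.inf * np.sign(a.mean - b.mean)
    else:
        t = (a.mean - b.mean) / denom
    p = 2.0 * stats.t.sf(abs(t), df) if np.isfinite(t) else 0.0
    return float(t), float(df), float(p)
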