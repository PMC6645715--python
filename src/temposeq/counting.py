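"""Gene models, biotype masking, read-to-gene assignment and RPM.

Counting follows intersection-nonempty semantics: for every aligned base of a
read, collect the set of genes whose (merged) exons cover it; intersect the
non-empty per-base sets; the read is counted to a gene only when that
intersection contains exactly one gene.  Reads with no exonic overlap are
"no feature", reads whose intersection is empty or has several genes are
ambiguous.  Strand is ignored by default (unstranded library).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .dedup import TaggedRead

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "CountMatrix",
    "AssignmentResult",
    "DEFAULT_MASKED_BIOTYPES",
    "merge_intervals",
    "mask_biotypes",
    "assign_reads",
    "rpm",
]

#: Biotypes removed from the gene model before counting.
DEFAULT_MASKED_BIOTYPES = frozenset({"snRNA", "rRNA", "tRNA", "snoRNA", "pseudogene"})

#: Labels we recognise; anything else triggers a warning but is kept.
KNOWN_BIOTYPES = DEFAULT_MASKED_BIOTYPES | {
    "protein_coding",
    "ncRNA",
    "lincRNA",
    "miRNA",
    "antisense",
}


def merge_intervals(intervals: Iterable[Tuple[int, int]]) -> Tuple[Tuple[int, int], ...]:
    """Merge overlapping/adjacent 0-based half-open intervals."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    merged: List[Tuple[int, int]] = []
    for s, e in ivs:
        if e <= s:
            raise ValueError(f"empty or inverted interval ({s}, {e})")
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return tuple(merged)


@dataclass(frozen=True)
class GeneModel:
    """One gene: merged exon intervals (0-based half-open) plus a biotype."""

    gene_id: str
    chrom: str
    strand: str
    exons: Tuple[Tuple[int, int], ...]
    biotype: str = "protein_coding"

    def __post_init__(self):
        object.__setattr__(self, "exons", merge_intervals(self.exons))

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)


def mask_biotypes(
    models: Sequence[GeneModel],
    masked: Iterable[str] = DEFAULT_MASKED_BIOTYPES,
) -> List[GeneModel]:
    """Drop genes whose biotype is in ``masked``; unknown labels are kept."""
    masked = set(masked)
    for label in sorted({m.biotype for m in models} - KNOWN_BIOTYPES - masked):
        logger.warning("unknown biotype label %r: genes kept", label)
    return [m for m in models if m.biotype not in masked]


@dataclass
class CountMatrix:
    """Genes x samples integer counts with temporal-state sample labels.

    ``samples`` maps sample id -> (state, replicate); ``mapped_totals`` holds
    the per-sample mapped-read totals used for RPM (defaults to column sums).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    mapped_totals: Optional[pd.Series] = None

    def __post_init__(self):
        self.counts = self.counts.astype(np.int64)
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples without state labels: {sorted(missing)}")
        if "state" not in self.samples.columns:
            raise ValueError("samples table needs a 'state' column")
        if self.mapped_totals is None:
            self.mapped_totals = self.counts.sum(axis=0).astype(float)
        else:
            self.mapped_totals = self.mapped_totals.reindex(self.counts.columns).astype(float)
            if self.mapped_totals.isna().any() or (self.mapped_totals <= 0).any():
                raise ValueError("mapped totals must be positive for every sample")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def states(self) -> List[str]:
        seen: List[str] = []
        for s in self.samples.loc[self.counts.columns, "state"]:
            if s not in seen:
                seen.append(s)
        return seen

    def samples_of_state(self, state: str) -> List[str]:
        sel = self.samples.loc[self.counts.columns]
        return list(sel.index[sel["state"] == state])

    def require_replicates(self, minimum: int = 2) -> None:
        for state in self.states:
            n = len(self.samples_of_state(state))
            if n < minimum:
                raise ValueError(f"state {state!r} has {n} replicates; need >= {minimum}")

    def rpm(self) -> pd.DataFrame:
        return rpm(self)

    def state_rpm(self) -> pd.DataFrame:
        """Per-state RPM: mean over that state's replicate columns."""
        table = self.rpm()
        return pd.DataFrame(
            {state: table[self.samples_of_state(state)].mean(axis=1) for state in self.states}
        )


def rpm(matrix: CountMatrix) -> pd.DataFrame:
    """Reads per million mapped reads, per gene and sample."""
    return matrix.counts / matrix.mapped_totals * 1e6


@dataclass
class AssignmentResult:
    """Per-gene counts plus the read-fate bookkeeping of one sample."""

    counts: pd.Series
    mapped_total: int
    n_counted: int
    n_ambiguous: int
    n_no_feature: int

    def __post_init__(self):
        assert self.n_counted + self.n_ambiguous + self.n_no_feature == self.mapped_total


def _chrom_index(models: Sequence[GeneModel]):
    """Per-chromosome sorted exon arrays for interval stabbing."""
    by_chrom: Dict[str, List[Tuple[int, int, str]]] = {}
    for m in models:
        for s, e in m.exons:
            by_chrom.setdefault(m.chrom, []).append((s, e, m.gene_id))
    index = {}
    for chrom, exons in by_chrom.items():
        exons.sort()
        starts = np.array([x[0] for x in exons])
        ends = np.array([x[1] for x in exons])
        genes = [x[2] for x in exons]
        index[chrom] = (starts, ends, genes)
    return index


def assign_reads(
    reads: Sequence[TaggedRead],
    models: Sequence[GeneModel],
    chrom_lengths: Optional[Dict[str, int]] = None,
) -> AssignmentResult:
    """Count non-duplicate reads to genes with intersection-nonempty rules.

    ``models`` should already be biotype-masked; exons are merged per gene by
    construction.  The mapped total equals the number of input reads.
    """
    index = _chrom_index(models)
    gene_ids = [m.gene_id for m in models]
    counts = pd.Series(0, index=pd.Index(gene_ids, name="gene_id"), dtype=np.int64)
    n_counted = n_ambiguous = n_no_feature = 0

    for read in reads:
        rstart, rend = read.pos, read.pos + read.read_length
        if chrom_lengths is not None:
            length = chrom_lengths.get(read.chrom)
            if length is None or rstart < 0 or rend > length:
                raise ValueError(
                    f"read {read.read_id} at {read.chrom}:{rstart}-{rend} "
                    "outside chromosome bounds"
                )
        hit = index.get(read.chrom)
        overlaps: List[Tuple[str, int, int]] = []
        if hit is not None:
            starts, ends, genes = hit
            # exons sorted by start; candidates are those starting before rend
            hi = int(np.searchsorted(starts, rend, side="left"))
            for i in range(hi):
                if ends[i] > rstart:
                    overlaps.append((genes[i], max(starts[i], rstart), min(ends[i], rend)))
        if not overlaps:
            n_no_feature += 1
            continue
        # per-base gene sets over the read, then intersect the non-empty ones
        length = rend - rstart
        covered = np.zeros(length, dtype=bool)
        per_gene: Dict[str, np.ndarray] = {}
        for gene, s, e in overlaps:
            mask = per_gene.setdefault(gene, np.zeros(length, dtype=bool))
            mask[s - rstart : e - rstart] = True
            covered[s - rstart : e - rstart] = True
        winners = [g for g, mask in per_gene.items() if np.all(mask[covered])]
        if len(winners) == 1:
            counts[winners[0]] += 1
            n_counted += 1
        else:
            n_ambiguous += 1

    return AssignmentResult(
        counts=counts,
        mapped_total=len(reads),
        n_counted=n_counted,
        n_ambiguous=n_ambiguous,
        n_no_feature=n_no_feature,
    )
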