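"""Molecular-tag based duplicate marking for aligned reads.

Library protocols that attach a short random tag (UMI / DigiTag) to each cDNA
molecule allow PCR duplicates to be separated from genuine biological copies:
reads carrying the same tag at the same genomic position derive from one
original molecule.  This module implements the per-position collapse:

1. group reads by (chrom, strand, pos);
2. within a group, rank distinct tags by descending read count, ties broken
   byte-wise lexicographically;
3. walk tags in rank order, maintaining a pool of accepted tags.  A tag within
   Hamming distance 1 of any accepted tag is collapsed: all its reads are
   duplicates.  Otherwise the tag is accepted and its highest-mean-PHRED read
   (ties by read id) is the unique non-duplicate representative.

The result is invariant to permutation of the input read list.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

__all__ = [
    "TaggedRead",
    "DedupResult",
    "TagLengthError",
    "group_by_position",
    "rank_tags",
    "mark_duplicates",
    "dedup_stats",
]


class TagLengthError(ValueError):
    """Raised when tags of unequal length meet within one position group."""


@dataclass(frozen=True)
class TaggedRead:
    """One aligned single-end read carrying a molecular tag.

    ``pos`` is the 0-based leftmost aligned coordinate.  ``mean_phred`` is
    the arithmetic mean of the per-base PHRED qualities; if omitted it is
    computed from ``quals``.
    """

    read_id: str
    chrom: str
    pos: int
    strand: str
    tag: str
    quals: Tuple[int, ...]
    mean_phred: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if not self.tag:
            raise ValueError(f"read {self.read_id}: empty tag")
        if not self.quals:
            raise ValueError(f"read {self.read_id}: empty quality string")
        if self.strand not in ("+", "-"):
            raise ValueError(f"read {self.read_id}: strand must be '+' or '-'")
        object.__setattr__(self, "quals", tuple(self.quals))
        mp = float(sum(self.quals)) / len(self.quals)
        if self.mean_phred is None:
            object.__setattr__(self, "mean_phred", mp)
        elif not math.isclose(self.mean_phred, mp, abs_tol=1e-9):
            raise ValueError(
                f"read {self.read_id}: mean_phred {self.mean_phred} does not "
                f"match mean of quals {mp}"
            )

    @property
    def read_length(self) -> int:
        return len(self.quals)


@dataclass
class DedupResult:
    """Duplicate flags plus the accepted-tag bookkeeping per position."""

    duplicate: Dict[str, bool]
    accepted_tags: Dict[Tuple[str, str, int], List[str]]
    representative: Dict[Tuple[Tuple[str, str, int], str], str]

    @property
    def n_reads(self) -> int:
        return len(self.duplicate)

    @property
    def n_duplicates(self) -> int:
        return sum(self.duplicate.values())

    @property
    def n_unique(self) -> int:
        return self.n_reads - self.n_duplicates

    @property
    def duplicate_fraction(self) -> float:
        return self.n_duplicates / self.n_reads if self.n_reads else 0.0


def position_key(read: TaggedRead, ignore_strand: bool = False) -> Tuple[str, str, int]:
    strand = "." if ignore_strand else read.strand
    return (read.chrom, strand, read.pos)


def group_by_position(
    reads: Iterable[TaggedRead], ignore_strand: bool = False
) -> Dict[Tuple[str, str, int], List[TaggedRead]]:
    """Partition reads into (chrom, strand, pos) groups, input order kept."""
    groups: Dict[Tuple[str, str, int], List[TaggedRead]] = {}
    for read in reads:
        groups.setdefault(position_key(read, ignore_strand), []).append(read)
    return groups


def rank_tags(group: Sequence[TaggedRead]) -> List[Tuple[str, List[TaggedRead]]]:
    """Order a position group's tags by count (desc), ties lexicographically.

    Within each tag, reads are ordered by mean PHRED descending, ties broken
    by read id ascending, so the first read of each tag is the candidate
    representative.
    """
    if not group:
        raise ValueError("rank_tags requires a non-empty group")
    by_tag: Dict[str, List[TaggedRead]] = {}
    for read in group:
        by_tag.setdefault(read.tag, []).append(read)
    for reads in by_tag.values():
        reads.sort(key=lambda r: (-r.mean_phred, r.read_id))
    return sorted(by_tag.items(), key=lambda item: (-len(item[1]), item[0]))


def hamming1(a: str, b: str) -> bool:
    """True if tags differ at exactly one base.

    'N' (or any non-ACGT symbol) counts as a mismatch against every base,
    including another 'N'.
    """
    if len(a) != len(b):
        raise TagLengthError(f"tags of unequal length: {a!r} vs {b!r}")
    acgt = frozenset("ACGT")
    mismatches = 0
    for x, y in zip(a, b):
        if x != y or x not in acgt:
            mismatches += 1
            if mismatches > 1:
                return False
    return mismatches == 1


def mark_duplicates(
    reads: Sequence[TaggedRead],
    ignore_strand: bool = False,
    discard_n_tags: bool = False,
) -> DedupResult:
    """Flag PCR duplicates across all position groups.

    Tags containing ambiguous bases mismatch every base in the one-mismatch
    comparison; with ``discard_n_tags`` their reads are flagged duplicate
    outright instead of being allowed to form an accepted tag.
    """
    duplicate: Dict[str, bool] = {}
    accepted: Dict[Tuple[str, str, int], List[str]] = {}
    representative: Dict[Tuple[Tuple[str, str, int], str], str] = {}

    for read in reads:
        if read.read_id in duplicate:
            raise ValueError(f"duplicate read id in input: {read.read_id}")
        duplicate[read.read_id] = True  # default; representatives cleared below

    for key, group in group_by_position(reads, ignore_strand).items():
        lengths = {len(r.tag) for r in group}
        if len(lengths) > 1:
            raise TagLengthError(
                f"position {key}: tags of unequal length {sorted(lengths)}"
            )
        pool: List[str] = []
        for tag, tag_reads in rank_tags(group):
            if discard_n_tags and any(b not in "ACGT" for b in tag):
                continue
            if any(hamming1(tag, seen) for seen in pool):
                continue  # collapsed into an accepted tag: all reads stay duplicates
            pool.append(tag)
            best = tag_reads[0]  # highest mean PHRED, tie read_id
            duplicate[best.read_id] = False
            representative[(key, tag)] = best.read_id
        accepted[key] = pool
    return DedupResult(duplicate=duplicate, accepted_tags=accepted, representative=representative)


def dedup_stats(
    result: DedupResult,
    truth: Optional[object] = None,
) -> Dict[str, float]:
    """Summary statistics, optionally scored against simulation ground truth.

    ``truth`` is a ``temposeq.sim.ReadGroundTruth`` (anything exposing
    ``is_pcr_duplicate`` as a read_id -> bool mapping and ``n_molecules``).
    Precision/recall are at the read level: a predicted non-duplicate is
    correct when it is the truth's representative read of its molecule.
    """
    stats: Dict[str, float] = {
        "n_reads": float(result.n_reads),
        "n_unique": float(result.n_unique),
        "n_duplicates": float(result.n_duplicates),
        "duplicate_fraction": result.duplicate_fraction,
    }
    if truth is not None:
        truth_dup = truth.is_pcr_duplicate
        pred_unique = {rid for rid, dup in result.duplicate.items() if not dup}
        true_unique = {rid for rid, dup in truth_dup.items() if not dup}
        tp = len(pred_unique & true_unique)
        stats["molecule_count_true"] = float(len(true_unique))
        stats["molecule_count_pred"] = float(len(pred_unique))
        stats["precision"] = tp / len(pred_unique) if pred_unique else 1.0
        stats["recall"] = tp / len(true_unique) if true_unique else 1.0
        stats["molecule_count_rel_error"] = (
            abs(len(pred_unique) - len(true_unique)) / len(true_unique)
            if true_unique
            else 0.0
        )
    return stats
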