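"""Synthetic data with ground truth for every pipeline stage.

The generators emulate the statistical structure of a FACS-sorted
intermediate-neural-progenitor RNA-seq experiment: three temporal states
(D, Grh, Ey) with three replicates each; negative-binomially distributed
gene counts built from archetypal temporal profiles (state-specific,
monotone, high-low-high, flat); and tagged aligned reads with PCR
duplication and tag sequencing errors.  Everything is bit-reproducible
under a fixed seed and ships its own ground truth so each stage can be
scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .counting import CountMatrix, GeneModel
from .dedup import TaggedRead
from .quantify import REFERENCE_GENE, CellIntensity, CtRecord

__all__ = [
    "SimConfig",
    "CountGroundTruth",
    "ReadGroundTruth",
    "ARCHETYPES",
    "simulate_counts",
    "make_gene_models",
    "place_molecules_in_genes",
    "simulate_tagged_reads",
    "simulate_intensity_fixture",
    "simulate_ct_table",
]

STATE_LABELS = ("D", "Grh", "Ey")
ARCHETYPES = ("state_specific_up", "monotone", "high_low_high", "flat")
_BASES = np.frombuffer(b"ACGT", dtype="S1")


class ConfigurationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study-shaped simulation parameters.

    Defaults mirror the experimental design being emulated: 3 temporal
    states x 3 replicates, an 8-base molecular tag, a mean of 3 PCR copies
    per molecule and a 1% per-base tag error.  ``archetype_mix`` gives the
    proportion of genes drawn from each temporal archetype;
    ``base_mean_log_range`` is the log2 range of baseline expression means.
    """

    seed: int = 0
    n_genes: int = 2000
    n_states: int = 3
    n_reps: int = 3
    archetype_mix: Dict[str, float] = field(
        default_factory=lambda: {
            "state_specific_up": 0.10,
            "monotone": 0.10,
            "high_low_high": 0.10,
            "flat": 0.70,
        }
    )
    nb_dispersion: float = 0.05
    base_mean_log_range: Tuple[float, float] = (2.0, 9.0)
    libsize_factors: Optional[Sequence[float]] = None
    tag_length: int = 8
    dup_rate_mean: float = 3.0
    tag_error_rate: float = 0.01
    genome: Tuple[Tuple[str, int], ...] = (
        ("2L", 1_000_000),
        ("2R", 1_000_000),
        ("3L", 1_000_000),
    )
    n_molecules: int = 20_000
    read_length: int = 50
    fold_step: float = 2.0
    hlh_fold: float = 4.0
    phred_mean: float = 32.0
    phred_sd: float = 6.0

    def __post_init__(self):
        mix = {a: float(self.archetype_mix.get(a, 0.0)) for a in ARCHETYPES}
        unknown = set(self.archetype_mix) - set(ARCHETYPES)
        if unknown:
            raise ConfigurationError(f"unknown archetypes: {sorted(unknown)}")
        if any(v < 0 for v in mix.values()):
            raise ConfigurationError("archetype proportions must be >= 0")
        if not math.isclose(sum(mix.values()), 1.0, abs_tol=1e-9):
            raise ConfigurationError("archetype_mix must sum to 1")
        self.archetype_mix = mix
        if self.n_states != len(STATE_LABELS):
            raise ConfigurationError("the temporal design has exactly 3 states (D, Grh, Ey)")
        if self.n_reps < 2:
            raise ConfigurationError("need >= 2 replicates per state for DE")
        if self.nb_dispersion < 0 or self.tag_error_rate < 0:
            raise ConfigurationError("rates must be >= 0")
        if self.tag_error_rate > 1:
            raise ConfigurationError("tag_error_rate is a probability")
        if self.tag_length < 1:
            raise ConfigurationError("tag_length must be >= 1")
        if self.dup_rate_mean < 1:
            raise ConfigurationError("dup_rate_mean must be >= 1 (each molecule is read once)")
        if self.libsize_factors is not None:
            facs = np.asarray(self.libsize_factors, dtype=float)
            if len(facs) != self.n_samples or (facs <= 0).any():
                raise ConfigurationError(
                    f"libsize_factors must be {self.n_samples} positive values"
                )
            self.libsize_factors = tuple(facs)

    @property
    def n_samples(self) -> int:
        return self.n_states * self.n_reps

    @property
    def sample_ids(self) -> List[str]:
        return [f"{s}_r{r + 1}" for s in STATE_LABELS for r in range(self.n_reps)]

    def sample_table(self) -> pd.DataFrame:
        rows = [
            {"sample_id": f"{s}_r{r + 1}", "state": s, "replicate": r + 1}
            for s in STATE_LABELS
            for r in range(self.n_reps)
        ]
        return pd.DataFrame(rows).set_index("sample_id")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one simulation stage."""
        return np.random.default_rng([self.seed, stream])


@dataclass
class CountGroundTruth:
    """Truth for a simulated count matrix."""

    archetype: pd.Series  # gene_id -> archetype label
    state_means: pd.DataFrame  # genes x states, the noise-free means

    def genes_of(self, archetype: str) -> pd.Index:
        return self.archetype.index[self.archetype == archetype]


def _archetype_labels(cfg: SimConfig) -> List[str]:
    """Deterministic largest-remainder allocation of archetype labels."""
    quotas = {a: cfg.archetype_mix[a] * cfg.n_genes for a in ARCHETYPES}
    counts = {a: int(math.floor(q)) for a, q in quotas.items()}
    short = cfg.n_genes - sum(counts.values())
    for a in sorted(ARCHETYPES, key=lambda a: (-(quotas[a] - counts[a]), a))[:short]:
        counts[a] += 1
    labels: List[str] = []
    for a in ARCHETYPES:
        labels.extend([a] * counts[a])
    return labels


def _state_means(cfg: SimConfig, archetype: str, base: float, rng: np.random.Generator) -> np.ndarray:
    s = cfg.fold_step
    if archetype == "flat":
        return np.array([base, base, base])
    if archetype == "monotone":
        up = bool(rng.integers(0, 2))
        means = np.array([base, base * s, base * s * s])
        return means if up else means[::-1]
    if archetype == "state_specific_up":
        k = int(rng.integers(0, 3))
        means = np.array([base, base, base])
        means[k] *= s * s  # the specific state clearly clears the DE threshold
        return means
    if archetype == "high_low_high":
        return np.array([base * cfg.hlh_fold, base, base * cfg.hlh_fold])
    raise ConfigurationError(f"unknown archetype {archetype!r}")


def simulate_counts(cfg: SimConfig) -> Tuple[CountMatrix, CountGroundTruth]:
    """NB-distributed gene x sample counts from archetypal temporal profiles.

    Counts are NB with mean = archetype state mean x per-sample library
    factor and dispersion ``cfg.nb_dispersion`` (Poisson at dispersion 0).
    """
    rng = cfg.rng(1)
    gene_ids = pd.Index([f"g{i:05d}" for i in range(cfg.n_genes)], name="gene_id")
    labels = _archetype_labels(cfg)
    base = 2.0 ** rng.uniform(*cfg.base_mean_log_range, size=cfg.n_genes)
    means = np.vstack(
        [_state_means(cfg, labels[i], base[i], rng) for i in range(cfg.n_genes)]
    )
    factors = (
        np.ones(cfg.n_samples)
        if cfg.libsize_factors is None
        else np.asarray(cfg.libsize_factors, dtype=float)
    )
    samples = cfg.sample_table()
    mu = means[:, [STATE_LABELS.index(s) for s in samples["state"]]] * factors
    if cfg.nb_dispersion > 0:
        n = 1.0 / cfg.nb_dispersion
        counts = rng.negative_binomial(n, n / (n + mu))
    else:
        counts = rng.poisson(mu)
    matrix = CountMatrix(
        counts=pd.DataFrame(counts, index=gene_ids, columns=samples.index),
        samples=samples,
    )
    truth = CountGroundTruth(
        archetype=pd.Series(labels, index=gene_ids, name="archetype"),
        state_means=pd.DataFrame(means, index=gene_ids, columns=list(STATE_LABELS)),
    )
    return matrix, truth


def make_gene_models(
    cfg: SimConfig,
    exon_length: int = 300,
    spacing: int = 200,
    n_masked: int = 0,
) -> List[GeneModel]:
    """Non-overlapping single-exon gene models tiled across the genome.

    ``n_masked`` appends extra genes carrying maskable biotypes (rRNA, tRNA,
    snRNA, snoRNA, pseudogene in rotation) after the expression genes, so a
    pipeline run exercises biotype masking.
    """
    if exon_length < cfg.read_length:
        raise ConfigurationError("exons must be at least one read long")
    masked_cycle = ("rRNA", "tRNA", "snRNA", "snoRNA", "pseudogene")
    total = cfg.n_genes + n_masked
    models: List[GeneModel] = []
    chrom_iter = iter(cfg.genome)
    chrom, length = next(chrom_iter)
    pos = 0
    for i in range(total):
        if pos + exon_length > length:
            try:
                chrom, length = next(chrom_iter)
            except StopIteration:
                raise ConfigurationError(
                    f"genome too small for {total} genes of {exon_length} bp"
                ) from None
            pos = 0
        if i < cfg.n_genes:
            gene_id, biotype = f"g{i:05d}", "protein_coding"
        else:
            j = i - cfg.n_genes
            gene_id, biotype = f"masked{j:03d}", masked_cycle[j % len(masked_cycle)]
        models.append(
            GeneModel(
                gene_id=gene_id,
                chrom=chrom,
                strand="+" if i % 2 == 0 else "-",
                exons=((pos, pos + exon_length),),
                biotype=biotype,
            )
        )
        pos += exon_length + spacing
    return models


def place_molecules_in_genes(
    models: Sequence[GeneModel],
    molecules_per_gene: Mapping[str, int],
    rng: np.random.Generator,
    read_length: int = 50,
) -> List[Tuple[str, str, int, str]]:
    """Random molecule start positions fully inside single exons.

    Returns (gene_id, chrom, pos, strand) per molecule so counting can be
    scored against the placement truth.
    """
    by_id = {m.gene_id: m for m in models}
    placements: List[Tuple[str, str, int, str]] = []
    for gene_id, n in molecules_per_gene.items():
        if n <= 0:
            continue
        model = by_id[gene_id]
        starts: List[int] = []
        for s, e in model.exons:
            if e - s >= read_length:
                starts.extend(range(s, e - read_length + 1))
        if not starts:
            raise ConfigurationError(f"gene {gene_id}: no exon fits a read")
        chosen = rng.choice(len(starts), size=int(n), replace=True)
        for c in chosen:
            placements.append((gene_id, model.chrom, starts[int(c)], model.strand))
    return placements


@dataclass
class ReadGroundTruth:
    """Truth for simulated tagged reads.

    Every read maps to exactly one molecule; per molecule exactly one read
    is the true non-duplicate (the copy with the best mean PHRED, matching
    the representative criterion deduplication uses).
    """

    molecule_of: Dict[str, int]
    is_pcr_duplicate: Dict[str, bool]
    copies: np.ndarray  # per-molecule PCR copy number
    molecule_tag: List[str]
    molecule_key: List[Tuple[str, str, int]]  # (chrom, strand, pos)
    molecule_gene: Optional[List[str]] = None

    @property
    def n_molecules(self) -> int:
        return len(self.copies)

    @property
    def n_reads(self) -> int:
        return int(self.copies.sum())

    def duplicate_fraction(self) -> float:
        return 1.0 - self.n_molecules / self.n_reads

    def collision_molecule_ids(self) -> List[int]:
        """Molecules whose tag is within Hamming distance 1 of another
        molecule's tag at the same position key (same-tag collisions
        included)."""
        by_key: Dict[Tuple[str, str, int], List[int]] = {}
        for mi, key in enumerate(self.molecule_key):
            by_key.setdefault(key, []).append(mi)
        clashed: List[int] = []
        for mols in by_key.values():
            if len(mols) < 2:
                continue
            for i, mi in enumerate(mols):
                for mj in mols[i + 1 :]:
                    ti, tj = self.molecule_tag[mi], self.molecule_tag[mj]
                    if sum(a != b for a, b in zip(ti, tj)) <= 1:
                        clashed.extend((mi, mj))
        return sorted(set(clashed))


def _random_tags(rng: np.random.Generator, n: int, length: int) -> List[str]:
    draws = rng.integers(0, 4, size=(n, length))
    return [_BASES[row].tobytes().decode() for row in draws]


def _mutate_tag(tag: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return tag
    hits = rng.random(len(tag)) < rate
    if not hits.any():
        return tag
    out = list(tag)
    for i in np.nonzero(hits)[0]:
        choices = [b for b in "ACGT" if b != out[i]]
        out[i] = choices[int(rng.integers(0, 3))]
    return "".join(out)


def simulate_tagged_reads(
    cfg: SimConfig,
    placements: Optional[Sequence[Tuple[str, str, int, str]]] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[List[TaggedRead], ReadGroundTruth]:
    """Tagged aligned reads with PCR duplication and tag sequencing errors.

    Molecules are placed uniformly on the genome (or at the supplied
    ``placements`` of (gene_id, chrom, pos, strand)); each receives a random
    tag and 1 + Poisson(dup_rate_mean - 1) PCR copies; each copy's tag is
    mutated per base at ``tag_error_rate`` and its per-base PHRED values are
    drawn from a normal truncated to [2, 40].
    """
    if rng is None:
        rng = cfg.rng(2)
    if placements is None:
        chroms = [c for c, _ in cfg.genome]
        lengths = np.array([l for _, l in cfg.genome], dtype=float)
        probs = lengths / lengths.sum()
        idx = rng.choice(len(chroms), size=cfg.n_molecules, p=probs)
        genes: Optional[List[str]] = None
        keys = []
        for ci in idx:
            chrom, length = cfg.genome[ci]
            pos = int(rng.integers(0, max(1, length - cfg.read_length)))
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            keys.append((chrom, strand, pos))
    else:
        genes = [p[0] for p in placements]
        keys = [(chrom, strand, pos) for _, chrom, pos, strand in placements]

    n_mol = len(keys)
    tags = _random_tags(rng, n_mol, cfg.tag_length)
    copies = 1 + rng.poisson(cfg.dup_rate_mean - 1.0, size=n_mol)

    a = (2.0 - cfg.phred_mean) / cfg.phred_sd
    b = (40.0 - cfg.phred_mean) / cfg.phred_sd
    total_bases = int(copies.sum()) * cfg.read_length
    qual_pool = sps.truncnorm.rvs(
        a, b, loc=cfg.phred_mean, scale=cfg.phred_sd, size=total_bases, random_state=rng
    )
    qual_pool = np.rint(qual_pool).astype(int).clip(2, 40)

    reads: List[TaggedRead] = []
    molecule_of: Dict[str, int] = {}
    is_dup: Dict[str, bool] = {}
    base_cursor = 0
    for mi in range(n_mol):
        chrom, strand, pos = keys[mi]
        best_id, best_phred = None, -1.0
        copy_ids = []
        for ci in range(copies[mi]):
            rid = f"m{mi:07d}_c{ci}"
            quals = tuple(
                int(q) for q in qual_pool[base_cursor : base_cursor + cfg.read_length]
            )
            base_cursor += cfg.read_length
            read = TaggedRead(
                read_id=rid,
                chrom=chrom,
                pos=pos,
                strand=strand,
                tag=_mutate_tag(tags[mi], rng, cfg.tag_error_rate),
                quals=quals,
            )
            reads.append(read)
            molecule_of[rid] = mi
            copy_ids.append(rid)
            if (
                best_id is None
                or read.mean_phred > best_phred
                or (read.mean_phred == best_phred and rid < best_id)
            ):
                best_id, best_phred = rid, read.mean_phred
        for rid in copy_ids:
            is_dup[rid] = rid != best_id
    truth = ReadGroundTruth(
        molecule_of=molecule_of,
        is_pcr_duplicate=is_dup,
        copies=copies,
        molecule_tag=tags,
        molecule_key=keys,
        molecule_gene=genes,
    )
    return reads, truth


def simulate_intensity_fixture(
    seed: int,
    n_brains: int = 3,
    n_pos: int = 5,
    n_neg: int = 5,
    n_background: int = 3,
    pos_signal: float = 200.0,
    neg_signal: float = 100.0,
    bg_level: float = 50.0,
    area: float = 100.0,
    noise_sd: float = 0.0,
) -> Tuple[List[CellIntensity], Dict[str, float]]:
    """Imaging fixture: per-cell true signal plus additive background.

    Mirrors the scoring design of 5 marker-positive + 5 marker-negative
    cells and 3 background circles per brain.  With ``noise_sd`` 0 the CTCF
    of a positive cell is exactly ``area * pos_signal``.
    """
    rng = np.random.default_rng(seed)
    cells: List[CellIntensity] = []
    for b in range(n_brains):
        brain = f"brain{b + 1}"
        for role, count, signal, positive in (
            ("cell", n_pos, pos_signal, True),
            ("cell", n_neg, neg_signal, False),
            ("background", n_background, 0.0, False),
        ):
            for i in range(count):
                level = signal + bg_level + (rng.normal(0, noise_sd) if noise_sd else 0.0)
                cells.append(
                    CellIntensity(
                        cell_id=f"{brain}_{'pos' if positive else 'neg' if role == 'cell' else 'bg'}{i + 1}",
                        brain_id=brain,
                        marker_positive=positive,
                        integrated_density=max(area * level, 0.0),
                        area=area,
                        role=role,
                    )
                )
    truth = {
        "pos_signal": pos_signal,
        "neg_signal": neg_signal,
        "bg_level": bg_level,
        "area": area,
    }
    return cells, truth


def simulate_ct_table(
    seed: int,
    true_fold_changes: Mapping[str, float],
    n_reps: int = 3,
    noise_sd: float = 0.0,
    baseline: float = 24.0,
    control_group: str = "control",
    target_group: str = "target",
) -> List[CtRecord]:
    """qPCR fixture: Ct = baseline - log2(expression) + noise.

    The reference gene (Act5c) has expression 1 in every sample; each gene in
    ``true_fold_changes`` has expression 1 in the control group and the given
    fold in the target group, so 2^-ddCt recovers the fold exactly at zero
    noise.
    """
    rng = np.random.default_rng(seed)
    records: List[CtRecord] = []
    for group in (control_group, target_group):
        for r in range(n_reps):
            sample = f"{group}_r{r + 1}"
            noise = rng.normal(0, noise_sd) if noise_sd else 0.0
            records.append(CtRecord(sample, group, REFERENCE_GENE, baseline + noise))
            for gene, fold in true_fold_changes.items():
                expr = fold if group == target_group else 1.0
                noise = rng.normal(0, noise_sd) if noise_sd else 0.0
                records.append(
                    CtRecord(sample, group, gene, baseline - math.log2(expr) + noise)
                )
    return records
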