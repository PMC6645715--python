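"""End-to-end orchestration: simulate -> dedup -> count -> DE -> screen -> cluster.

A single seeded configuration drives every stage; identical config + seed
give byte-identical output tables.  Each stage writes its TSVs into the
output directory and the run ends with a machine-readable manifest.  A
failing stage aborts the run with the stage named and leaves a FAILED
marker next to the partial outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .counting import CountMatrix, assign_reads, mask_biotypes
from .de import call_degs, nb_wald_test, size_factors
from .dedup import mark_duplicates
from .io import read_counts, read_gtf, read_reads_sam, read_reads_tsv, write_counts, write_gtf, write_table
from .screen import build_transition_profiles, candidate_filter, cluster_profiles
from .sim import SimConfig, make_gene_models, place_molecules_in_genes, simulate_counts, simulate_tagged_reads

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "StageError", "run_pipeline", "validate_inputs"]

CONTRASTS = (("D", "Grh"), ("Grh", "Ey"), ("D", "Ey"))
DE_COLUMNS = ["baseMean", "log2fc", "p", "padj", "rpm_D", "rpm_Grh", "rpm_Ey"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """One structured configuration for a full run."""

    outdir: str = "temposeq_run"
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    molecules_per_sample: int = 7400
    dedup_enabled: bool = True
    n_masked_genes: int = 5
    fdr: float = 0.05
    de_lfc: float = 1.0
    de_rpm_min: float = 10.0
    screen_lfc_major: float = 1.0
    screen_lfc_minor: float = 0.5
    screen_rpm_min: float = 50.0
    cluster_k: int = 4
    cluster_rpm_min: float = 10.0
    cluster_lfc: float = 1.0
    size_factor_pseudocount: float = 0.5

    def __post_init__(self):
        if isinstance(self.sim, dict):
            self.sim = SimConfig(**self.sim)
        self.sim.seed = self.seed
        for name in ("fdr", "de_lfc", "de_rpm_min", "screen_lfc_major",
                     "screen_lfc_minor", "screen_rpm_min", "cluster_rpm_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        return cls(**data)

    def to_dict(self) -> Dict:
        data = dataclasses.asdict(self)
        data["sim"]["genome"] = [list(g) for g in self.sim.genome]
        return data


def _scaled_molecules(column: pd.Series, target: int) -> Dict[str, int]:
    total = int(column.sum())
    if total == 0:
        return {}
    scale = target / total
    scaled = (column * scale).round().astype(int)
    return {g: int(n) for g, n in scaled.items() if n > 0}


def run_pipeline(cfg: PipelineConfig) -> Dict:
    """Execute all stages and return the run manifest."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    failed_marker = outdir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    manifest: Dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "stages": {},
    }
    stage = "simulate"
    try:
        t0 = time.perf_counter()
        matrix, count_truth = simulate_counts(cfg.sim)
        models = make_gene_models(cfg.sim, n_masked=cfg.n_masked_genes)
        write_counts(matrix, outdir / "true_counts.tsv", outdir / "samples.tsv")
        write_gtf(models, outdir / "genes.gtf")
        write_table(count_truth.archetype.to_frame(), outdir / "archetypes.tsv")
        manifest["stages"][stage] = {"n_genes": int(cfg.sim.n_genes),
                                     "n_samples": int(cfg.sim.n_samples)}
        logger.info("stage %s done in %.1fs", stage, time.perf_counter() - t0)

        stage = "dedup_count"
        t0 = time.perf_counter()
        masked = mask_biotypes(models)
        columns: Dict[str, pd.Series] = {}
        totals: Dict[str, float] = {}
        n_reads_total = 0
        n_dup_total = 0
        for si, sample in enumerate(matrix.counts.columns):
            rng = cfg.sim.rng(100 + si)
            placements = place_molecules_in_genes(
                masked, _scaled_molecules(matrix.counts[sample], cfg.molecules_per_sample),
                rng, read_length=cfg.sim.read_length,
            )
            reads, _truth = simulate_tagged_reads(cfg.sim, placements=placements, rng=rng)
            n_reads_total += len(reads)
            if cfg.dedup_enabled:
                result = mark_duplicates(reads)
                kept = [r for r in reads if not result.duplicate[r.read_id]]
                n_dup_total += result.n_duplicates
            else:
                kept = list(reads)
            assignment = assign_reads(kept, masked)
            columns[sample] = assignment.counts
            totals[sample] = float(assignment.mapped_total)
        observed = CountMatrix(
            counts=pd.DataFrame(columns)[list(matrix.counts.columns)],
            samples=matrix.samples,
            mapped_totals=pd.Series(totals),
        )
        write_counts(observed, outdir / "counts.tsv", outdir / "samples_observed.tsv")
        manifest["stages"][stage] = {
            "n_reads": n_reads_total,
            "n_duplicates_marked": n_dup_total,
            "dedup_enabled": cfg.dedup_enabled,
        }
        logger.info("stage %s done in %.1fs", stage, time.perf_counter() - t0)

        stage = "de"
        t0 = time.perf_counter()
        factors = size_factors(observed, pseudocount=cfg.size_factor_pseudocount)
        de_tables = {}
        deg_counts = {}
        for a, b in CONTRASTS:
            table = nb_wald_test(observed, (a, b), factors=factors)
            de_tables[(a, b)] = table
            degs = call_degs(table, fdr=cfg.fdr, lfc=cfg.de_lfc, rpm_min=cfg.de_rpm_min)
            deg_counts[f"{a}_vs_{b}"] = len(degs)
            ordered = table[[c for c in DE_COLUMNS if c in table.columns]]
            write_table(ordered, outdir / f"de_{a}_vs_{b}.tsv")
        manifest["stages"][stage] = {"degs": deg_counts}
        logger.info("stage %s done in %.1fs", stage, time.perf_counter() - t0)

        stage = "screen"
        t0 = time.perf_counter()
        profiles = build_transition_profiles(de_tables[("D", "Grh")], de_tables[("Grh", "Ey")])
        hits = candidate_filter(
            profiles,
            lfc_major=cfg.screen_lfc_major,
            lfc_minor=cfg.screen_lfc_minor,
            rpm_min=cfg.screen_rpm_min,
        )
        write_table(hits, outdir / "screen_hits.tsv")
        manifest["stages"][stage] = {
            "n_hits": len(hits),
            "n_high_low_high": int((hits["pattern"] == "high_low_high").sum()),
        }
        logger.info("stage %s done in %.1fs", stage, time.perf_counter() - t0)

        stage = "cluster"
        t0 = time.perf_counter()
        labels, _linkage = cluster_profiles(
            observed.state_rpm(),
            de_tables=list(de_tables.values()),
            lfc_threshold=cfg.cluster_lfc,
            padj_threshold=cfg.fdr,
            rpm_min=cfg.cluster_rpm_min,
            k=cfg.cluster_k,
        )
        write_table(labels.to_frame(), outdir / "clusters.tsv")
        manifest["stages"][stage] = {
            "n_genes": len(labels),
            "k": int(labels.max()),
        }
        logger.info("stage %s done in %.1fs", stage, time.perf_counter() - t0)

        stage = "manifest"
        manifest["completed"] = list(manifest["stages"])
        with open(outdir / "manifest.json", "w") as handle:
            json.dump(manifest, handle, indent=2, sort_keys=True)
            handle.write("\n")
        return manifest
    except Exception as exc:  # noqa: BLE001 - the stage name is the payload
        failed_marker.write_text(f"{stage}: {exc}\n")
        raise StageError(stage, exc) from exc


def validate_inputs(paths: Dict[str, str]) -> List[str]:
    """Schema-check declared inputs; returns a list of violations (empty = ok).

    ``paths`` maps a dialect name to a file path.  Recognised dialects:
    ``counts`` (value is ``(counts_tsv, samples_tsv)``), ``reads_tsv``,
    ``sam``, ``gtf``, ``bed``.
    """
    report: List[str] = []
    for kind, target in paths.items():
        try:
            if kind == "counts":
                counts_path, samples_path = target
                matrix = read_counts(counts_path, samples_path)
                if matrix.counts.isna().any().any():
                    report.append(f"{counts_path}: missing count values")
            elif kind == "reads_tsv":
                read_reads_tsv(target)
            elif kind == "sam":
                read_reads_sam(target)
            elif kind == "gtf":
                read_gtf(target)
            elif kind == "bed":
                from .io import read_bed

                read_bed(target)
            else:
                report.append(f"unknown input dialect {kind!r}")
        except FileNotFoundError:
            report.append(f"{kind}: file not found: {target}")
        except Exception as exc:  # noqa: BLE001 - collect, do not crash
            report.append(f"{kind}: {exc}")
    return report
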