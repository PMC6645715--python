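"""Synthetic generators: determinism, archetype structure, NB moments."""

import numpy as np
import pandas as pd
import pytest

from temposeq.quantify import REFERENCE_GENE
from temposeq.sim import (
    ConfigurationError,
    SimConfig,
    make_gene_models,
    place_molecules_in_genes,
    simulate_counts,
    simulate_ct_table,
    simulate_intensity_fixture,
    simulate_tagged_reads,
)


class TestConfig:
    def test_bad_mix_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(archetype_mix={"flat": 0.5})

    def test_negative_rate_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(tag_error_rate=-0.1)

    def test_tag_length_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(tag_length=0)

    def test_libsize_factor_length_checked(self):
        with pytest.raises(ConfigurationError):
            SimConfig(libsize_factors=[1.0, 2.0])


class TestSimulateCounts:
    def test_deterministic_under_seed(self):
        a, _ = simulate_counts(SimConfig(seed=1, n_genes=300))
        b, _ = simulate_counts(SimConfig(seed=1, n_genes=300))
        assert a.counts.equals(b.counts)

    def test_flat_truth_means_equal_across_states(self):
        _, truth = simulate_counts(
            SimConfig(seed=2, n_genes=50, archetype_mix={"flat": 1.0})
        )
        sm = truth.state_means
        assert (sm["D"] == sm["Grh"]).all() and (sm["Grh"] == sm["Ey"]).all()

    def test_archetype_fractions_exact(self):
        _, truth = simulate_counts(
            SimConfig(
                seed=3,
                n_genes=200,
                archetype_mix={"flat": 0.8, "high_low_high": 0.1,
                               "monotone": 0.05, "state_specific_up": 0.05},
            )
        )
        counts = truth.archetype.value_counts()
        assert counts["high_low_high"] == 20
        assert counts["flat"] == 160

    def test_high_low_high_means_dip_and_recover(self):
        _, truth = simulate_counts(
            SimConfig(seed=4, n_genes=40, archetype_mix={"high_low_high": 1.0})
        )
        sm = truth.state_means
        assert (sm["D"] / sm["Grh"] >= 2).all()
        assert (sm["Ey"] / sm["Grh"] >= 2).all()

    def test_nb_moments_match_target(self):
        """Empirical mean and variance agree with NB(mu, alpha) within 3 SE."""
        cfg = SimConfig(
            seed=5, n_genes=2000, archetype_mix={"flat": 1.0},
            base_mean_log_range=(6.0, 6.0), nb_dispersion=0.1,
        )
        matrix, _ = simulate_counts(cfg)
        draws = matrix.counts.to_numpy(dtype=float).ravel()
        mu, alpha = 64.0, 0.1
        target_var = mu + alpha * mu**2
        n = draws.size
        se_mean = np.sqrt(target_var / n)
        assert abs(draws.mean() - mu) < 3 * se_mean
        # empirical SE of the variance from 20 disjoint chunks
        chunk_vars = [c.var(ddof=1) for c in np.array_split(draws, 20)]
        se_var = np.std(chunk_vars, ddof=1) / np.sqrt(20)
        assert abs(draws.var(ddof=1) - target_var) < 3 * se_var

    def test_zero_dispersion_is_poisson(self):
        cfg = SimConfig(seed=6, n_genes=500, archetype_mix={"flat": 1.0},
                        base_mean_log_range=(5.0, 5.0), nb_dispersion=0.0)
        matrix, _ = simulate_counts(cfg)
        draws = matrix.counts.to_numpy(dtype=float).ravel()
        assert abs(draws.var(ddof=1) / draws.mean() - 1.0) < 0.1

    def test_libsize_factors_scale_means(self):
        factors = [0.5] * 3 + [1.0] * 3 + [2.0] * 3
        cfg = SimConfig(seed=7, n_genes=800, archetype_mix={"flat": 1.0},
                        base_mean_log_range=(6.0, 6.0), libsize_factors=factors)
        matrix, _ = simulate_counts(cfg)
        col_means = matrix.counts.mean(axis=0)
        assert col_means["Ey_r1"] / col_means["D_r1"] == pytest.approx(4.0, rel=0.1)


class TestSimulateTaggedReads:
    def test_no_duplication_all_unique(self):
        cfg = SimConfig(seed=1, n_molecules=200, dup_rate_mean=1.0, tag_error_rate=0.0)
        reads, truth = simulate_tagged_reads(cfg)
        assert len(reads) == truth.n_molecules == 200
        assert not any(truth.is_pcr_duplicate.values())

    def test_read_total_matches_copy_numbers(self):
        cfg = SimConfig(seed=7, n_molecules=500)
        reads, truth = simulate_tagged_reads(cfg)
        assert len(reads) == truth.copies.sum() == truth.n_reads

    def test_each_molecule_one_true_representative(self):
        cfg = SimConfig(seed=8, n_molecules=300)
        reads, truth = simulate_tagged_reads(cfg)
        uniques = {}
        for rid, dup in truth.is_pcr_duplicate.items():
            if not dup:
                mi = truth.molecule_of[rid]
                assert mi not in uniques
                uniques[mi] = rid
        assert len(uniques) == truth.n_molecules

    def test_duplicate_fraction_approaches_limit(self):
        """Truth duplicate fraction ~ 1 - 1/m for mean copy number m."""
        for m in (2.0, 5.0):
            cfg = SimConfig(seed=10, n_molecules=5000, dup_rate_mean=m)
            _, truth = simulate_tagged_reads(cfg)
            assert truth.duplicate_fraction() == pytest.approx(1 - 1 / m, abs=0.02)

    def test_qualities_within_phred_bounds(self):
        cfg = SimConfig(seed=11, n_molecules=50)
        reads, _ = simulate_tagged_reads(cfg)
        for r in reads:
            assert all(2 <= q <= 40 for q in r.quals)
            assert len(r.quals) == cfg.read_length

    def test_deterministic_under_seed(self):
        cfg = SimConfig(seed=12, n_molecules=100)
        a, _ = simulate_tagged_reads(cfg)
        b, _ = simulate_tagged_reads(SimConfig(seed=12, n_molecules=100))
        assert [(r.read_id, r.tag, r.quals) for r in a] == [
            (r.read_id, r.tag, r.quals) for r in b
        ]


class TestGeneModels:
    def test_models_tile_without_overlap(self):
        cfg = SimConfig(n_genes=100)
        models = make_gene_models(cfg, n_masked=5)
        assert len(models) == 105
        by_chrom = {}
        for m in models:
            by_chrom.setdefault(m.chrom, []).append(m)
        for chrom_models in by_chrom.values():
            spans = sorted((m.start, m.end) for m in chrom_models)
            assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))

    def test_too_small_genome_rejected(self):
        cfg = SimConfig(n_genes=100, genome=(("2L", 1000),))
        with pytest.raises(ConfigurationError):
            make_gene_models(cfg)

    def test_placements_land_inside_exons(self):
        cfg = SimConfig(n_genes=20)
        models = make_gene_models(cfg)
        rng = np.random.default_rng(0)
        placements = place_molecules_in_genes(
            models, {m.gene_id: 5 for m in models}, rng, read_length=cfg.read_length
        )
        by_id = {m.gene_id: m for m in models}
        for gene_id, chrom, pos, strand in placements:
            m = by_id[gene_id]
            assert m.chrom == chrom and m.strand == strand
            assert any(s <= pos and pos + cfg.read_length <= e for s, e in m.exons)


class TestFixtures:
    def test_intensity_truth_recoverable_at_zero_noise(self):
        cells, truth = simulate_intensity_fixture(seed=0, noise_sd=0.0)
        bg = [c for c in cells if c.role == "background"][0]
        assert bg.mean_fluorescence == truth["bg_level"]

    def test_ct_table_has_reference_everywhere(self):
        records = simulate_ct_table(seed=0, true_fold_changes={"opa": 4.0})
        samples = {r.sample_id for r in records}
        refs = {r.sample_id for r in records if r.gene == REFERENCE_GENE}
        assert refs == samples
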