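"""Mark PCR duplicates among tagged reads and score against ground truth.

Each cDNA molecule carries an 8-base molecular tag; PCR copies share the
tag and position. Deduplication keeps one representative per accepted tag
(highest mean PHRED) and collapses tags within Hamming distance 1.
"""

from temposeq import SimConfig, mark_duplicates, dedup_stats, simulate_tagged_reads

cfg = SimConfig(seed=1, n_molecules=5000, dup_rate_mean=3.0, tag_error_rate=0.01)
reads, truth = simulate_tagged_reads(cfg)
result = mark_duplicates(reads)
stats = dedup_stats(result, truth)

print(f"{len(reads)} reads from {truth.n_molecules} molecules")
print(f"marked {result.n_duplicates} duplicates; kept {result.n_unique} unique reads")
print(f"molecule-count error: {100 * stats['molecule_count_rel_error']:.2f}%")
print(f"representative precision {stats['precision']:.3f}, recall {stats['recall']:.3f}")
# At a 1% per-base tag error the recovered molecule count stays within ~2%
# of the truth: single-base tag errors are absorbed by the one-mismatch pool.
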