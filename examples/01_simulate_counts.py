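"""Simulate a temporally patterned count matrix with known ground truth.

Three temporal states (D, Grh, Ey) x three replicates; each gene follows one
of four archetypes (state-specific, monotone, high-low-high, flat).
"""

from temposeq import SimConfig, simulate_counts

cfg = SimConfig(seed=1, n_genes=1000)
matrix, truth = simulate_counts(cfg)

print("count matrix:", matrix.counts.shape, "genes x samples")
print(matrix.counts.iloc[:3, :6])
print("\narchetype composition:")
print(truth.archetype.value_counts())
hlh = truth.genes_of("high_low_high")[0]
print(f"\n{hlh} true state means (a high-low-high gene):")
print(truth.state_means.loc[hlh].round(1))
# The dip into Grh and recovery into Ey is the temporal signature the screen
# is built to find; flat genes provide the null background.
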