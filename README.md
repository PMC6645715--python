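# temposeq

Temporal transcriptome analysis for FACS-sorted neural progenitors.

Intermediate neural progenitors (INPs) in the *Drosophila* larval brain pass
through three sequential temporal identities, marked by the transcription
factors Dichaete (D), Grainyhead (Grh) and Eyeless (Ey). Genes that switch the
progenitors from one identity to the next show a characteristic expression
signature across the three FACS-sorted states — most notably *high–low–high*:
on in D⁺ cells, silenced in Grh⁺ cells, re-expressed in Ey⁺ cells. `temposeq`
implements the complete computational path from tagged sequencing reads to
such candidate temporal-switch genes, for anyone analysing shallow, tag-based
(UMI/DigiTag) RNA-seq of small sorted cell populations:

1. **Tag deduplication** (`temposeq.dedup`) — per genomic position
   (chrom, strand, pos), tags are ranked by read count (ties broken
   lexicographically); each accepted tag keeps its highest–mean-PHRED read as
   the unique non-duplicate, and any tag within Hamming distance 1 of an
   accepted tag is collapsed entirely.
2. **Counting** (`temposeq.counting`) — maskable gene models (snRNA, rRNA,
   tRNA, snoRNA, pseudogene removed by default) and intersection-nonempty
   read→gene assignment; expression in RPM (reads per million mapped).
3. **Differential expression** (`temposeq.de`) — median-of-ratios size
   factors, NB dispersions by method of moments shrunk toward a fitted
   mean–dispersion trend, Wald test on log₂ fold changes of state means
   (delta method, Var = μ + αμ²), Benjamini–Hochberg adjustment, and DEG
   calling at padj < 0.05, |log₂fc| > 1, RPM > 10 in ≥ 1 state.
4. **Temporal screen** (`temposeq.screen`) — candidates need |log₂fc| > 1 in
   one of the D→Grh / Grh→Ey transitions, ≥ 0.5 in the other and RPM > 50 in
   some state; the sign pair (lfc_DG, lfc_GE) classifies the temporal shape;
   stage profiles (z-scored log₂(RPM+1)) are clustered hierarchically
   (1 − Pearson, average linkage, tree cut into 4 clusters).
5. **Quantification formulas** (`temposeq.quantify`) — corrected total cell
   fluorescence CTCF = IntDen − Area × mean background; relative qPCR
   expression 2^(−ΔΔCt) normalised to Act5c; unpaired two-tailed Student's
   *t*-tests computed directly from printed mean ± SD, *n* summaries.
6. **Synthetic data** (`temposeq.sim`) — seeded generators for every input
   (NB counts from temporal archetypes, tagged reads with PCR duplication and
   tag errors, gene models, imaging and qPCR fixtures), each with ground
   truth, so the whole pipeline is testable without any external data.

## Worked example

```python
from temposeq import (SimConfig, simulate_counts, nb_wald_test,
                      build_transition_profiles, candidate_filter)

matrix, truth = simulate_counts(SimConfig(seed=3, n_genes=2000))
de_dg = nb_wald_test(matrix, ("D", "Grh"))
de_ge = nb_wald_test(matrix, ("Grh", "Ey"))
hits = candidate_filter(build_transition_profiles(de_dg, de_ge),
                        lfc_major=1.0, lfc_minor=0.5, rpm_min=50.0)
print(hits["pattern"].value_counts())
```

prints

```
pattern
high_low_high    202
monotone_up       83
monotone_down     70
low_high_low      69
```

The generator planted 200 high–low–high genes among 2000 (10%); the screen
recovers essentially all of them (202 called, including a couple of noisy
borderline genes), because their 4× dip into Grh and 4× recovery into Ey
clear both fold-change thresholds, while monotone 2×-per-step genes sit at
the |log₂fc| = 1 boundary and pass only when noise pushes them over.
Deduplication on the same conditions (`examples/02_deduplicate_reads.py`)
reports a 1.4% molecule-count error at a 1% per-base tag error and mean PCR
duplication 3.

Each capability has a short narrative script under `examples/`; the
`temposeq` command exposes the same stages as subcommands
(`simulate`, `dedup`, `count`, `de`, `screen`, `cluster`, `ttest`, `run`,
`validate`), e.g.

```sh
temposeq ttest --mean1 12.44 --sd1 1.42 --n1 10 --mean2 34.66 --sd2 1.02 --n2 12
# t=-42.6566  df=20.00  p=4.07e-21
```

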