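# Methods

## The problem being modelled

Transit-amplifying intermediate neural progenitors (INPs) in the *Drosophila*
larval brain progress through three temporal identities — Dichaete⁺ (D),
Grainyhead⁺ (Grh), Eyeless⁺ (Ey) — and genes driving the transitions show
dynamic expression across FACS-sorted populations of the three states.
Because sorted populations are small (thousands of cells), libraries are
shallow and tag-based: every cDNA molecule carries a short random molecular
tag so that PCR duplicates can be removed before counting. `temposeq`
implements that analysis path end to end and ships a synthetic-data module
that emulates the experiment's statistical structure, so every stage is
scored against known ground truth.

## Deduplication

Reads are grouped by (chromosome, strand, 0-based leftmost position). The
position key includes strand by convention of standard duplicate marking;
`ignore_strand=True` drops it. Within a group:

* distinct tags are ranked by read count, descending; ties broken by
  byte-wise lexicographic order of the tag;
* tags are visited in rank order against a pool of accepted tags. A tag
  within Hamming distance 1 of **any** accepted tag is collapsed — all its
  reads become duplicates and no representative is kept;
* an accepted tag contributes exactly one non-duplicate: its read with the
  highest mean PHRED quality, ties broken by read id.

The comparison is per position only, not genome-wide. Tags must have equal
length within a group (unequal lengths raise an input-format error rather
than being skipped); ambiguous bases mismatch every base, including another
`N`, and `discard_n_tags=True` removes such tags outright. The procedure is
invariant to permutation of the input, which the tests check by property.

Error behaviour: a single-base tag sequencing error lands at Hamming
distance 1 from the true tag and is absorbed by the pool rule; two or more
errors in one tag create a spurious "molecule". At the defaults (8-base
tags, 1% per-base error, mean duplication 3) the expected overcount is of
order 1–2%, which is what the acceptance checks measure. Two molecules at
one position whose tags collide within distance 1 are merged (undercount);
the simulation's ground truth records such collisions so tests can select
collision-free configurations when asserting exact recovery.

## Counting

Gene models are exon interval sets merged per gene; genes with biotypes
snRNA, rRNA, tRNA, snoRNA or pseudogene are masked before counting (unknown
biotype labels are kept with a logged warning). Assignment follows
intersection-nonempty semantics on the read's aligned interval: per-base
overlapping gene sets are collected, the non-empty ones intersected, and the
read is counted only when the intersection is a single gene; empty or
multi-gene intersections are ambiguous, reads without exonic overlap are
unassigned. Reads are conserved: counted + ambiguous + unassigned = input,
and the mapped total (the RPM denominator) is the number of input reads.
Strand is ignored, matching an unstranded library protocol.

RPM = count / mapped_total × 10⁶; state-level RPM is the mean over that
state's replicates.

## Differential expression

The NB stage is deliberately compact and fully specified (it is implemented
here, not delegated to an external DE package, whose exact numerics are not
a goal):

* **Size factors** — median-of-ratios: per sample, the median over genes
  with all-positive counts of count / (gene's geometric mean across
  samples), normalised to geometric mean 1. A matrix with no all-positive
  gene raises an error suggesting the pseudocount mode (used by default in
  the low-depth pipeline demo, pseudocount 0.5).
* **Dispersion** — per gene, method of moments on normalised counts pooled
  over the two contrasted states' residuals: α̂ = (s² − μ̄)/μ̄². A trend
  α(μ) = a₀ + a₁/μ is fitted by least squares to per-quantile-bin means of
  the *raw* (possibly negative) estimates — the sample variance is unbiased,
  so bin means are too, where flooring or trimming first would bias the
  trend down and inflate type-I error. Final dispersions are log-space
  weighted combinations, weight 0.25 on the gene-wise value (floored at a
  quarter of the trend so near-zero moment estimates cannot collapse the
  shrunk value) and 0.75 on the trend: with 2–3 replicates the gene-wise
  estimator carries little information.
* **Wald test** — log₂fc = log₂(mean_B + 0.5) − log₂(mean_A + 0.5) on
  size-factor-normalised state means (pseudocount 0.5 keeps zero-containing
  genes finite); SE by the delta method with Var = (μ + αμ²)/n per state;
  two-sided normal p; BH adjustment over genes with at least one nonzero
  count in the contrasted samples. All-zero genes are reported untested with
  log₂fc 0 and p 1.
* **DEG thresholds** — padj < 0.05, |log₂fc| > 1, and RPM > 10 in at least
  one of the three temporal-state means ("in one state" is read as the state
  means; a per-replicate-maximum variant is available via the
  `per_replicate_rpm` argument).

Under the flat-archetype null (2000 genes, dispersion 0.05, 3 vs 3) the raw
p < 0.05 fraction averages ≈ 0.055 over ten seeds, and planted 4-fold genes
at mean 100 are recovered with median |log₂fc| within ~0.15 of 2 — both
verified by the acceptance checks at exactly those problem sizes.

## Temporal screen and clustering

Transition fold changes are oriented later-over-earlier (lfc_DG = Grh/D,
lfc_GE = Ey/Grh). The candidate filter takes absolute values throughout —
thresholds are magnitude criteria, so a gene strongly *down* in the first
transition qualifies exactly like one strongly up. A gene passes when
|lfc| > 1 in at least one transition, ≥ 0.5 in the other and max state
RPM > 50; an optional `require_deg` flag additionally demands padj < 0.05
in a transition (off by default). The sign pair classifies the pattern:
(−, +) high_low_high, (+, −) low_high_low, (+, +)/(−, −) monotone, any
zero or missing value → other. Hits are ranked by the magnitude of the
qualifying fold change. The filter is monotone: loosening any threshold
never removes a passing gene (property-tested).

Clustering filters genes to |log₂fc| above a threshold and padj < 0.05 in
≥ 1 pairwise comparison plus ≥ 10 RPM in some state, z-scores the
log₂(RPM + 1) three-state profile, and applies average-linkage hierarchical
clustering with 1 − Pearson distances, cutting the tree into k = 4 clusters.
Distance and linkage are this package's choice (none is canonical for
three-point profiles); both are exposed. Constant profiles, whose
correlation is undefined, are treated as distance 1 to varying profiles and
0 to each other. Genes are processed in sorted-id order and cluster labels
renumbered by first appearance, making the labelling invariant to input row
order.

## Quantification formulas

* CTCF = integrated density − area × mean background fluorescence; negative
  values are reported as-is. Group comparison: per brain (scored as 5
  marker-positive cells, 5 negative, 3 background circles), the positive
  and negative CTCF means are each normalised to that brain's background
  mean.
* 2^(−ΔΔCt): ΔCt = Ct_gene − Ct_Act5c per sample; ΔΔCt = mean ΔCt(target) −
  mean ΔCt(control). Group aggregation is the arithmetic mean of ΔCt before
  differencing; a per-sample fold-change-averaging variant is provided via
  `per_sample=True` since the aggregation order is a genuine ambiguity.
  ΔΔCt is invariant to any constant shift of one sample's Cts.
* Summary t-tests: the printed "mean ± X" values are SDs (the figure
  legends say so), hence `GroupSummary` takes SD. Default mode is the
  pooled-variance Student test; Welch–Satterthwaite is available. The p
  value is two-sided from the t distribution.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *design* of the experiment: 3 states × 3
replicates; NB counts with Var = μ + αμ² (default dispersion 0.05, typical
of bulk replicates; dispersion 0 falls back to Poisson); baseline means
log₂-uniform on [2, 9] (≈ 4–512 counts); per-sample library-size factors;
8-base tags; PCR copy number 1 + Poisson(mean − 1) so every molecule is read
at least once; per-base tag substitution at 1%; per-base PHRED from a normal
truncated to [2, 40] (mean 32, SD 6 — the distribution is this package's
choice, as only the use of the *mean* PHRED is prescribed); 50 bp single-end
reads. Depth defaults (20 000 molecules standalone, ~7 400 molecules per
sample in the pipeline demo, ≈ 2 × 10⁵ reads in total) are a configuration
choice scaled for a complete run in well under five minutes on one CPU, in
the spirit of the shallow sorted-population libraries being emulated.

Temporal archetypes and their fixed effect sizes: flat (70% of genes by
default); monotone, 2× per step; state-specific, 4× in one state; and
high–low–high, 4× down into Grh then 4× back up into Ey (the generator
guarantees ≥ 2× each way). 30% dynamic genes is deliberately generous so
every archetype is well represented at 2000 genes. The 4× choice for
high–low–high makes its transitions clear the strict |log₂fc| > 1 screen
threshold even at zero noise, whereas 2×-per-step monotone genes sit exactly
*at* the threshold and are excluded noise-free — which is what makes exact
planted-pattern recovery a meaningful test. Archetype labels are assigned by
largest-remainder quotas, so planted fractions are exact, not expected.

Not emulated: read sequences and alignment (reads are generated already
placed; there are no alignment errors, soft clips or introns in the
synthetic models), fragment-length effects, amplification-efficiency biases
in qPCR, or image segmentation. Passing tests therefore demonstrate the
correctness of the *computational* stages under the stated statistical
model, not robustness to upstream artefacts of real data.

Determinism: every generator draws from `numpy` Generators seeded as
`[seed, stream]` with a fixed stream id per stage, so runs are
bit-reproducible and stages are independently perturbable.

## Numerical choices and degenerate inputs

* Dispersion floor 10⁻⁸; Wald z defined as 0 when SE = 0.
* Tag ranking ties: byte-wise lexicographic ascending on tags and read ids
  ("alphanumeric" collation is otherwise undefined).
* Hamming comparison requires equal tag lengths; unequal lengths are an
  error.
* Empty read list → empty grouping; an all-zero count matrix raises in size
  factors unless a pseudocount is supplied; fewer filtered genes than k
  raises in clustering with the count in the message.
* The pipeline funnels all randomness through the run seed; the manifest
  echoes the config and per-stage row counts, and identical config + seed
  reproduce every stage TSV byte for byte (verified by test and by the
  acceptance script).

## Known limitations

* Single-end reads only; no mate-aware position keys, no directional-
  adjacency tag clustering beyond the one-mismatch pool rule.
* The NB stage is a compact Wald test — no independent filtering, no fold
  change shrinkage, no GLM design matrices; counts of differentially
  expressed genes from a full DE framework on real data will differ.
* Three-point profiles limit what correlation distances can express; the
  four-cluster cut is a practical default, not an inference of cluster
  number.
* The screen's thresholds are taken as given; their values (1, 0.5, 50)
  are parameters everywhere they appear.
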