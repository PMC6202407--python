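# Methods

## Study design and data model

The pipeline targets small multi-condition microarray designs: a reference
fibroblast population (MEF), a tissue-derived stem-cell population (MDSC), a
reprogrammed population (iMSC) and its sorted fraction (sort-iMSC), each with
two biological replicates. Expression values are log2 intensities in a plain
genes × samples DataFrame; a `StudyDesign` object maps samples to conditions
and fixes the first condition as the reference of every contrast.

## Synthetic data generator

`simulate_dataset` draws per-gene baselines uniformly on 6–12 log2 units (a
realistic dynamic range for single-channel log2 intensities, and wide enough
that quantile normalization is exercised nontrivially), plants a sign vector
over the contrasts for a chosen fraction of genes (default 10%), shifts every
replicate of a condition by ±effect (default 2.0 log2 units, a clear 4-fold
change) and adds i.i.d. Gaussian noise (default sd 0.25 log2 units, a typical
between-replicate scatter for good-quality arrays). Sign vectors are drawn
uniformly from the 3^C − 1 nonzero patterns so that all clusters and groups
are exercised; effects in the MDSC contrast are independent of the
iMSC/sort-iMSC entries by construction.

What the generator deliberately does **not** emulate: probe-level scanner
artifacts, dye or batch effects, intensity-dependent variance, correlated
genes, and non-Gaussian heavy-tailed noise. Passing tests on this generator
therefore demonstrate the statistical machinery (calibration, power,
bookkeeping) under the model's own assumptions, not robustness to every
pathology of real arrays. The default noise sd is a free parameter of the
generator, not an estimate of any particular dataset.

## Quantile normalization

Each column is replaced by the mean of the sorted columns (the "reference
distribution") in its own rank order. Ties within a column receive the mean
of the reference quantiles they span; this choice is deterministic and
rank-preserving. On tie-free data the map is exactly idempotent and all
post-normalization sorted columns are identical to machine precision; with
ties, tie-averaging necessarily perturbs the shared distribution slightly, so
exact idempotence holds only for the tie-free case (the property the tests
assert). Probe-to-gene collapse keeps the probe with the highest mean
intensity across samples — deterministic, and it preserves fold-change
interpretability better than averaging probes with different dynamic ranges.
Normalization is applied jointly across all arrays before any contrast is
formed; whether it runs at probe or gene level is the caller's choice.

## Differential-expression test

Per gene, the pooled-variance (Student) two-sample T statistic is used rather
than Welch's: with n = 2 per group the Welch degrees of freedom are unstable,
and no parametric reference distribution is used anyway. The null is
empirical: for each contrast, every balanced relabeling of the contrast's
four samples except the identity (C(4,2) − 1 = 5; general group sizes are
enumerated the same way) is applied, T is recomputed for every gene, and all
values are pooled. Because the relabeling space at 2 + 2 is tiny, exhaustive
enumeration replaces random permutation. Genes with exactly zero pooled
variance are excluded from the pool with a logged count; as observations they
receive p = 1 and an `ns` call.

The pooled values are smoothed with a Gaussian KDE using Silverman's
rule-of-thumb bandwidth with the robust scale, `0.9·min(sd, IQR/1.34)·n^(−1/5)`.
The robust scale is essential at n = 2 + 2: a single near-degenerate gene can
contribute a permuted T in the thousands, and a bandwidth proportional to the
plain standard deviation would then oversmooth the entire null and destroy
power. The CDF is obtained by trapezoidal integration on an adaptive grid
spanning [min − 5·bw, max + 5·bw]: 4096 points over the central 99.9% of the
pool, locally refined (33 points over ±6 bw) around each outlier so isolated
kernel bumps still integrate correctly. Two-tailed p-values are
`2·min(F̂(t), 1 − F̂(t))`, floored at `1/(pool size + 1)` so they are strictly
positive.

The "adjusted" p-value is the empirical-null p itself — no further
multiple-testing correction is applied by default, matching the literal
workflow this pipeline reproduces; a Benjamini–Hochberg switch
(`fdr_adjust`) exists but is off by default. Permutations are within-contrast
by default; `permutation_scope: pooled` shares one null across all contrasts.
DEG thresholds are boundary-inclusive: p ≤ α (default 0.05) and
|log2FC| ≥ τ (default 1.0).

On null data (10,000 genes, 2 vs 2, sd 0.25) the measured type-I error at
α = 0.05 is close to nominal because the genome-pooled permutation null is
approximately self-calibrating; with planted 2.0-log2 effects at sd 0.25 the
test recovers over 90% of planted DEGs with every call's direction matching
the planted sign. Both quantities are recomputed by the test suite and by
`scripts/acceptance.py`, which estimates them by Monte-Carlo over replicate
datasets (20 null replicates for calibration, 3 for power) because the
pool-tail quantile — and hence power — shifts coherently across genes within
a replicate.

## Sign-pattern clusters and groups

Each DEG's vector of calls over the three contrasts (+1/−1/0) defines its
cluster, labeled canonically like `+.+.0` in contrast order rather than by
opaque cluster numbers, since only the pattern semantics are reproducible.
Groups project the vector onto the iMSC and sort-iMSC contrasts:
(+,0) → G1, (+,+) → G2, (0,+) → G3, (−,0) → G4, (−,−) → G5, (0,−) → G6;
sign-discordant and (0,0) projections belong to no group. This symmetric
completion is the only assignment under which "up in iMSC only", "up in
both", "up in sort-iMSC only" and their down-regulated mirrors are all
distinct and disjoint; the MDSC entry never affects grouping. Heatmap row
order comes from complete-linkage agglomerative clustering of the DEG × 3
log2FC matrix under Euclidean distance, with scipy's deterministic
tie-breaking; the palette is the conventional red (up) / green (down).

## EASE enrichment

The EASE score is the hypergeometric upper tail of the 2×2 overlap table
with the overlap decremented by one: `p = P[X ≥ max(k − 1, 0)]` for
`X ~ Hypergeom(N, K, n)`. It is always at least the classical one-tailed
Fisher p (the penalization is conservative), equals 1 whenever k ≤ 1, and is
non-increasing in k. The background defaults to all genes on the (collapsed)
array rather than the whole genome, mirroring how array submissions are
normally tested; gene symbols are matched case-insensitively with a logged
unmatched count. Enrichment p-values are not multiplicity-corrected (the
enriched flag is `p < 0.05`, strict); a BH switch exists for callers who want
it. Because curated annotation snapshots differ between tools and over time,
enrichment term lists from any given GMT are not expected to reproduce a
specific historical analysis term-for-term.

## Network reconstruction

The network stage consumes pre-merged interaction tables (KEGG-style typed
edges plus PPIs pooled from whichever databases the caller trusts) — it never
scrapes databases itself, only deduplicates. Gene selection is conjunctive:
a DEG enters the network if it belongs to at least one selected process term
and at least one listed signaling pathway (defaults: Calcium, Jak-STAT, MAPK,
Notch, TGF-beta, VEGF, Wnt, regulation of the actin cytoskeleton). The
network is the induced subgraph on that gene list; isolated nodes are kept
because they still occupy a pathway lane in the display. PPI edges are
undirected and canonicalized (endpoints sorted) so orientation and repetition
in the input collapse to one edge. Genes DE in either annotated contrast are
included even when the two contrasts disagree in sign — the discordance is
visible in the node's two log2FC attributes. Nodes and edges are inserted in
sorted order, so GraphML exports are byte-deterministic; JSON exports are
validated structurally against the schema shipped in
`degnet.network.NETWORK_JSON_SCHEMA` (a self-contained structural check, so
no extra validation dependency is needed). Pathway lanes are node attributes,
not a layout engine.

## Numerical and scale choices

Problem sizes in the tests and the acceptance script were chosen to make the
Monte-Carlo estimates stable: 10,000 genes per replicate gives a 50,000-value
permutation pool (KDE quantiles stable to ~10⁻³), 20 null replicates pin the
type-I error to about ±0.002, and 3 planted-effect replicates average out the
between-replicate drift of the pool tail. The KDE grid size (4096 core
points) keeps CDF interpolation error far below the p-value floor. All
simulation seeds derive from a single integer via `numpy` seed sequences and
stay below 2³¹.

## Known limitations

- With two replicates per group the permutation space is tiny; the empirical
  null leans heavily on pooling across genes and is only approximately
  self-calibrating when many genes are truly differential (the planted
  fraction contaminates the pool's tails and costs a few percent of power).
- The probe-collapse rule and normalization level are under-specified in most
  published array workflows; both are configurable, and different choices
  will change DEG counts at the margin.
- EASE results depend entirely on the supplied GMT and background; no GO DAG
  propagation is performed.
- The synthetic generator's independence and homoscedasticity assumptions are
  idealizations (see above).
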