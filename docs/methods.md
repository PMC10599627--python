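# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of the package. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Synthetic-data generators

The generators exist so that every downstream stage can be validated by
recovering planted effects; their defaults define the study conditions the
acceptance checks run under.

**Single-cell counts** (`simulate.simulate_sc_dataset`). Cells belong to
patient lines (10 by default) and conditions (GM/CSF, 800 cells each per
line). Genes split into disjoint blocks: eight transcriptional programs
(AC/MES1/MES2/NPC/OPC 50 genes each, G1S 43, G2M 54, quiescence 100 —
matching the gene-set sizes the scoring and GSEA stages expect), 13
mitochondrial genes, 98 housekeeping genes, and background genes within a
2,000-gene panel. Per cell, each program has a log2 activity
`A = b(program, patient) + 1[CSF]·e(program) + n(cell)` with patient
baselines `b ~ N(0, 0.15)`, planted condition effects `e` (defaults:
MES +1.0, quiescence +0.5, G1S and G2M −0.5), and cell noise
`n ~ N(0, 0.25)`. Program genes' relative rates are
`exp(base) · 2^A`; planted DE genes (defaults: a NUPR1-like gene at
+1.5 log2 in CSF, one +1.0 and one −1.0 gene) multiply their rate by
`2^fc` in CSF. Rates are renormalized per cell and scaled by a lognormal
library size (ln-scale mean 9.2, sd 0.35; median ≈ 10,000 reads — chosen
as a realistic droplet-protocol depth for a 2,000-gene panel). Counts are
gamma-Poisson (negative binomial) with dispersion 2, i.e.
`var = m + m²/2`. Housekeeping genes sit at the top of the baseline range
so intact cells detect well over 70 of 98; mitochondrial genes are
rescaled to carry 5% of the total rate so the 20% mito-fraction rule has a
clear normal regime. Planted DE genes are pinned near the top of the
baseline range: a lowly expressed gene's fold change is flattened by the
+1 pseudocount of the fold-change convention, and the planted "strongest
up-regulated gene" must be measurable as such. QC outliers (2% of cells)
each violate exactly one rule — library inflated past the read ceiling,
detected genes cut to ~400, 45 housekeeping genes zeroed, or
mitochondrial counts inflated to ~30% — making QC tests deterministic.
Ground truth (program memberships, effects, planted genes, outliers and
their violation types, patient baselines) is returned and serialized as
JSON next to the data.

What this emulates and what it does not: the generator reproduces the
statistical structure the pipeline *assumes* — overdispersed counts,
library-size variation, program-structured condition shifts — but not
ambient RNA, doublets, batch chemistry, gene-gene correlation beyond
program co-regulation, or any distributional claim about the original
biological data. Passing recovery tests therefore demonstrates that the
pipeline's inference is correct under its own model, not that the model
captures every property of real droplet data.

**Plates** (`simulate.simulate_plate`). Treated nuclei counts are
`control_mean · 4PL(dose)/100 · (1+ε)` with multiplicative Gaussian noise
of CV 5% and paired dose-0 vehicle wells; 6 replicates per dose; default
dose series 0, 10, 25, 50, 75, 100 µM (the published TMZ series) with a
4PL of top 100%, bottom 5%, hill 1.5.

**Spike trains** (`simulate.simulate_spike_trains`). Homogeneous Poisson
background per neuron (default 0.5 Hz over a 420-s window — the 7-minute
minimum recording) merged with planted bursts (per-neuron regular trains)
and planted network events (spikes dealt round-robin across participating
neurons). Duplicate timestamps are nudged by 1 µs to keep trains strictly
increasing.

## Single-cell processing

QC applies the prefilter as cells-then-genes passes iterated to a fixed
point (≤ 2 iterations in practice), so the output provably satisfies both
rules simultaneously; the order is a convention, fixed here because it
makes the output contract checkable. Outlier tagging *removes* cells by
default (`keep_flagged` retains them for audit): the four criteria are
OR-combined and every violated criterion is reported as a reason code.
The mitochondrial fraction is mito counts over total counts, computed on
raw counts. Per-line threshold overrides live in configuration, never in
code; the default pipeline config sets the low-complexity gene floor to
1,000 for the simulated 2,000-gene panel (the whole-transcriptome default
of 2,000 detected genes is not meaningful when the panel itself has 2,000
genes — the same override mechanism used for line-specific floors).

Normalization is ln(1 + 10,000·count/total); natural log is the
convention of the standard single-cell toolchains whose behavior the
downstream formulas (expm1-based fold change) assume. Normalization and
highly-variable-gene selection delegate to scanpy
(`normalize_total`/`log1p`, `highly_variable_genes` with the
dispersion-based flavor: 20 mean bins, dispersion z-scored within bin),
with ties broken by gene order for determinism.

Module scores use 24 equal-frequency average-expression bins and 100
control genes per set gene, sampled with replacement when a bin is
smaller than 100; the control pool is drawn once per (set, seed) so
scores are reproducible and invariant to gene-list order. On null data
the score distribution is centered at zero, but any *single* control draw
leaves a residual offset of order `sd_within_bin/√|S|` (~0.02–0.05 here)
that does not shrink with cell count; calibration checks therefore test
the center of the distribution across many random sets rather than each
set's offset.

Cycling labels default to the proliferation-score rule (mean of G1S and
G2M, Cycling iff ≥ 0; the threshold is inclusive). An alternate `max`
mode (Cycling iff G1S > 0 or G2M > 0) is exposed because both conventions
appear in the field; under `max`, cells with one positive and one
negative score are Cycling, a documented asymmetry of that convention.
Quiescent iff quiescence score ≥ 0.

## State classification

Three projection modes are shipped. The default `corrected` mode computes
`D = max(OPC, NPC) − max(AC, MES)`, sets `y = sign(D)·log2(|D|+1)`, and
puts the within-hemifield contrast on x (`sign(NPC−OPC)·log2(|NPC−OPC|+1)`
when D > 0, `sign(MES−AC)·log2(|MES−AC|+1)` otherwise); quadrants then
realize the stated state semantics, and for any cell whose top score
dominates the others the quadrant equals the argmax state. The
`as_written` mode preserves a published branch/formula pairing verbatim
for audit; it is internally inconsistent — dominant NPC or AC cells land
on the x = 0 boundary and log2 arguments can be non-positive — so such
cells are flagged (undefined, or boundary without a state) rather than
silently assigned; neither variant is claimed to be any specific group's
exact code. `argmax` simply takes the largest score. In corrected mode,
exact boundary cells (x = 0 or y = 0) fall back to argmax and are counted
separately. MES1/MES2 scores are carried for density summaries but state
assignment always uses the combined 100-gene MES score.

## Differential expression

Downsampling is uniform without replacement to exactly 700 cells per
condition per line. The rank-sum test enumerates all `C(n1+n2, n1)` rank
assignments when both groups have ≤ 8 cells (midranks for ties; p is the
probability of a rank-sum deviation at least as large as observed);
above that it uses the normal approximation with tie correction and a 0.5
continuity correction, which the oracle-equivalence tests bound against
exact enumeration at the crossover. No expression prefilter is applied:
every gene in the object is tested and Bonferroni-corrected, and the
count of tested genes is recorded. The fold-change convention
(exponentiated means with pseudocount 1) and the rank score
`sign(log2FC)·(−log10 p_adj)` follow the standard single-cell toolchain;
note the rank score is 0 whenever `p_adj` saturates at 1, regardless of
the fold-change sign. Top-k lists sort by fold change with gene-id
tie-breaks.

## GSEA

Ranked lists order by score descending with gene-id tie-breaks. The
weighted statistic uses exponent 1 on |rank score|. The enrichment score
is computed in O(|S|) from the candidate extrema just after each hit and
just before each hit (between hits the running sum is linear, so no other
position can be extremal); exact ties between the positive and negative
extremum are broken by walk order (the extremum reached earliest in the
list wins, with a 1e-12 tolerance). The leading edge is the set genes at
or before the extremum (after it, for negative ES). Null ES values come
from random same-size gene sets; draws whose hits all carry zero rank
score (common when Bonferroni saturates most adjusted p values) fall back
to uniform hit weights rather than aborting the permutation. NES divides
ES by the mean |null ES| of the same sign; p uses the add-one estimator
over same-sign nulls, so it is never exactly 0 and its floor is
`1/(1+n_same)`; FDR q pools sign-normalized null NES across sets
(Benjamini–Hochberg over permutation p when only one set is tested) and
is made monotone in |NES|.

## Assays

Viability is 100 × count / mean(paired vehicle controls), so control
wells average exactly 100 by construction. Stratification cutpoints
follow the two published conventions — (50, 90) for drug assays and
(50, 75) for irradiation/combination — both kept as presets because the
source conventions genuinely differ; the middle interval is closed at
both ends ("<50" strict, ">90" strict). Resistance fold change normalizes
both conditions' per-line survivals by the mean population survival in GM
and reports their ratio. The 4PL fit initializes top/bottom from the
extreme-dose means, IC50 from the first dose crossing the response
midpoint, hill = 1, bounds only IC50 > 0; non-convergence, a
non-decreasing fitted curve (hill ≤ 0 or top < bottom), or an IC50 more
than 10× outside the tested dose range returns a flagged result instead
of raising. At CV 5% with six dose means the per-seed IC50 sampling error
has a heavy tail (the noiseless fit recovers parameters to four
significant figures), so recovery is summarized by the median error over
seeds. qPCR uses comparative-CT only (no efficiency correction):
ΔCt per sample, ΔΔCt as difference of group means, fold `2^−ΔΔCt`.

## MEA metrics

Spike detection thresholds at rolling mean + 6 rolling SD with a 10-ms
noise window and 1-ms refractory hold-off; the window and hold-off are
this package's stand-ins for unstated vendor acquisition parameters and
are exposed as arguments. Active neurons fire strictly more than 5
spikes/min. Bursts and network events are *maximal* runs under their
(min spikes, max ISI) parameters — (5, 100 ms) per neuron, (50, 80 ms) on
the pooled well train — computed by splitting at ISI violations, which is
the unique parameter-faithful definition and is verified against a
sliding-scan oracle; runs are disjoint and non-extendable, and each
network event records its participating neurons. Population vectors
binarize spikes per neuron per frame, sum across neurons, and smooth with
a centered 500-ms rolling mean. Phase AUC uses the trapezoidal rule over
the annotated treatment or recovery window, optionally after a two-point
moving average. Control-normalized percent change defaults to the
ratio-of-ratios form `100·((v(w,t)/v(w,pre))/(v̄c(t)/v̄c(pre)) − 1)`; a
subtraction mode (`pc − pc_ctrl`) is also shipped because the published
phrasing is ambiguous between the two; zero-baseline wells are reported
as missing.

## Pipeline and reproducibility

Stages communicate through files (MTX triplet + TSV, GMT, RNK, CSV) so
each is independently re-runnable; a failure in one arm does not corrupt
the others. The run manifest records the package version, a config hash,
per-file SHA-256 checksums, and the seed; identical config + seed
reproduce identical checksums. Every analysis constant (prefilter
thresholds, outlier rules, scale factor, HVG count, score bins/controls,
downsampling quota, permutation count, burst/network parameters, active
rate, smoothing window, cutpoints) is reachable from the validated YAML
config; unknown keys are rejected.

## Problem sizes

The test suite and acceptance script run the single-cell arm at the
10-line × 800-cells-per-condition scale (≈16,000 cells × 2,000 genes),
null calibrations at 2 × 700 cells, oracle comparisons on 200 rank-sum
toys / 100 ranked lists / 1,000 spike trains, state agreement on 5,000
score vectors, and dose-response recovery on 20 simulated plates — sizes
chosen so the full validation completes in a few minutes on a laptop
while still exercising the exact study-design counts (14,000 / 7,000
cells) where those are the point.

## Known limitations

* The generator's negative-binomial independence model understates
  gene-gene correlation; module-score variances on real data will be
  larger than on synthetic nulls.
* The exact rank-sum path is O(C(n1+n2, n1)) and only used for groups of
  ≤ 8; the asymptotic path's continuity correction can differ from other
  software that omits it, at the third decimal of p for moderate n.
* GSEA uses gene-set permutations only (the published configuration);
  phenotype permutations, which preserve inter-gene correlation, are out
  of scope.
* `as_written` state projection is retained for audit and should not be
  used for inference; see above.
* Spike detection assumes a stationary noise floor within its rolling
  window; electrode drift faster than the window is not handled.
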