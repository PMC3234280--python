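# Methods

## The feature model

`tsog` nominates cancer-gene candidates from the joint state of three
gene-level modalities in a tumor cohort, with copy number as the base
feature. Writing `c_gs` for the mean log2 copy ratio (seg.mean) of gene `g`
in sample `s`, `m_gs` for promoter methylation and `e_gs` for log2
expression, the model behind both the classifier and the simulator is

    e_gs = b_g + β · c_gs − γ · (m_gs − m0) + ε_gs ,

i.e. expression rises with gene dosage (slope `β`) and falls with promoter
methylation above the platform center `m0` (coupling `γ`). An oncogene-like
gene is amplified, hypomethylated and over-expressed; a TS-like gene is the
mirror image; the cross classes (amplified-suppressed, deleted-expressed)
are the states where the methylation term overrides the dosage term. The
model is deliberately linear and additive: it is the minimal structure that
produces the four quadrants, not a claim about transcriptional mechanism.

## Gene-level copy number

A gene receives a seg.mean for a sample only when its whole locus lies
inside exactly one CBS segment of that sample and that segment has at least
`min_num_info = 4` informative markers. Genes split across segments,
uncovered genes and weakly supported segments are *missing*, never zero —
partial coverage must stay distinguishable from copy neutrality, and
missingness propagates through every downstream screen. Assignment uses
binary search over per-(sample, chromosome) segment arrays after validating
that segments are sorted and non-overlapping; a brute-force scan oracle
checks it on random instances.

Near-zero trimming removes, per sign, the `near_zero_trim = 0.05` fraction
of pooled matrix cells closest to seg.mean 0 (so 90% of signed data
survives). Trimming is global over the matrix rather than per sample or per
gene; the alternative readings of the rule are noted as a limitation below.

Two threshold families coexist and must not be conflated:

* **State cuts** — amplified iff `seg.mean ≥ 0.50`, deleted iff
  `seg.mean < 0.00` (strict, so 0.00 is neutral). These define the per-cell
  state matrix and the per-gene amplified/neutral/deleted frequencies.
* **Extreme-CNV cuts** — `extreme_amp_threshold = +0.50`,
  `extreme_del_threshold = −0.50` (one copy gained / at minimum a one-copy
  loss). These gate the feature classifier: a gene enters the
  amplified-class (resp. deleted-class) when ≥ `min_sample_fraction = 0.20`
  of its non-missing tumor samples lie beyond the cut. The permissive
  `< 0.00` state cut would admit copy-neutral noise samples into the
  "deleted" subsets, inflating within-group variance and drowning the
  significance tests; platforms with compressed dynamic range (ratio-based
  deletion-insensitive arrays) can configure the extreme deletion cut back
  toward 0, and `calibrate_platform_threshold` exists to pick such a cut
  from samples shared with a reference platform (objective: sensitivity to
  reference deletions minus false-positive rate over a user grid; ties go
  to the threshold nearest 0).

## Screens

**Rank-sum screen.** Per gene, tumors with `seg.mean <
low_screen_threshold` form the low-copy group and tumors with `seg.mean ≥
high_screen_threshold` the high-copy group; defaults are −0.50 and 1.25
(the stringent operating point for wide-dynamic-range platforms — a
one-copy loss against a strong amplification). The gene is tested only when
each group holds ≥ 20% of tumors, which restricts the screen to recurrently
altered loci and makes the captured gene count a function of the high cut
(`threshold_sweep` reports the curve). The test is the two-sample
Mann–Whitney rank-sum, exact when both groups have ≤ 8 observations and the
pooled values are tie-free, otherwise the tie-corrected normal approximation
with a 0.5 continuity correction. The comparison groups are independent
sample sets, so the two-sample test is the correct form even though such
screens are sometimes loosely called signed-rank tests. BH q-values are
computed within each screen invocation (one test family per call).

**Correlation screens.** Per-gene Pearson r with p from the t-transform on
n−2 df; the methylation–expression screen reports r of (−methylation,
expression) so repressive genes score positive, flagged in the output.
Genes with fewer than `min_pairs` complete pairs or zero variance report
missing r.

**Normal-deviation filter.** A gene passes the CNV gate when ≥ 20% of
tumors have |seg.mean| > 0.50; it is retained when its gated-tumor
expression mean differs from the normal mean by more than one gated-tumor
standard deviation. The retained set is "recurrently altered genes whose
expression departs from tissue normal".

## Feature classification and significance

Tumor:normal expression ratios are means of *linear-scale* expression
(matrices are log2, so values are unlogged first; `linear_ratio` exposes the
choice). When the cohort has no native normal expression, the normal mean is
the average over `bootstrap_reps = 50` bootstrap resamples (with
replacement, resample size = donor count) of a donor cohort's normals,
deterministic given the seed.

Quantile cuts at `q = 0.25` / `1 − q` are taken on the *entire* cohort-wide
distributions: all genes' ratios, and the pooled per-(gene, CNV-class)
methylation means (the methylation value of a call is the mean over the
at-class tumor samples). Classification is a strict quadrant rule per
(gene, CNV class); a gene in both CNV classes yields two calls, and every
call receives exactly one class (possibly `none`).

Each call is tested against the normals on its **at-class** tumor samples
(the samples in the call's CNV state): per-modality Welch t-tests with the
|Δmean| Euclidean distances as effect sizes, and a two-sample Hotelling T²
on the joint (methylation, expression) pairs,

    T² = (n₁n₂/(n₁+n₂)) · d′ S⁻¹ d ,   F = T² (n₁+n₂−p−1)/(p(n₁+n₂−2))

with `F(p, n₁+n₂−p−1)` as reference. Restricting to at-class samples is
what the per-CNV-state analysis calls for: the altered subpopulation
carries the signal, and pooling unaltered tumors both dilutes the mean
shift and inflates the within-group variance. When the pooled covariance is
singular (condition number > 1e12), T² is still computed through the
pseudo-inverse — in the degenerate direction it equals the squared
pooled-variance t — but the multivariate p is reported missing because the
F reference no longer applies; the univariate results stand. BH runs once
across all calls; calls with `q_multi < fdr_level = 0.05` are
percentile-ranked by ascending q: `100 · (1 − (rank−1)/(n−1))`, a single
passing call scoring 100.

## Enrichment

For a feature class of `n` genes in a universe of `N`, a set with `K`
universe members and `k` class members scores the exact upper tail
`P(X ≥ k)` under Hypergeometric(N, K, n), BH-corrected across sets;
over-representation only. The universe is the genes with complete
tri-modal data in the run — enrichment against untestable genes would be
inflated.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
array physics. Genes occupy the middle 2 kb of 10 kb tiles on
`n_chromosomes = 22` chromosomes; per sample each tile is one segment, so
segments partition every chromosome and each gene sits in exactly one
segment — the clean case of the inclusion rules. `inject_edge_cases` then
plants the dirty cases (gene split at its midpoint across two segments;
`num.info` dropped below 4) as positive controls for the exclusion rules.

Defaults mirror the study geometry: 42 tumors, 7 tissue normals, and a
desk-scale 1000 genes standing in for the ~12k-gene arrays. Planted
fractions default to 5% oncogene-like, 5% TS-like and 2% of each cross
class, with counts fixed by round-half-up of fraction × n_genes (remainder
null). For a planted gene, a random `altered_sample_fraction = 0.5` of
tumors carries the alteration: `seg.mean = ±cnv_effect` (1.0, jitter 0.05)
and methylation shifted by `∓meth_effect` (0.3 platform units). Expression
always follows the linear model with `β = expr_dosage_slope = 1.0` and
`γ = meth_coupling = 5.0`; the coupling is set once so that
`γ·meth_effect > β·cnv_effect`, making the cross classes' net expression
shift carry the sign the feature model asserts (an amplified-suppressed
gene really is under-expressed). Noise is Gaussian per modality (seg.mean
0.20 in tumors, 0.02 in normals; methylation 0.05; expression 0.30 log2);
beta-dialect methylation is clipped to [0.01, 0.99] and centered at 0.5,
ratio-dialect at 1.0, higher = more methylated in both. Baselines are
N(7, 1) log2 units, the scale of RMA-processed arrays. One integer seed
drives a single generator; identical configs produce byte-identical files.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: probe-level intensities and CBS itself
(segments are gene-tile-aligned, real breakpoints are not), multi-gene
segments and long-range correlation along chromosomes, batch effects,
subclonal mixtures, non-Gaussian heavy tails, and any realistic effect-size
distribution (no such distribution is published for these aberrations; the
defaults are chosen for testability). Recovery rates on planted cohorts are
upper bounds on real-data performance.

## Numerical and procedural choices

* **Quantile normalization** (for multi-sample ratio-score methylation
  arrays): each column is mapped onto the reference distribution given by
  the row-wise mean of sorted columns; columns with unequal observed counts
  are interpolated onto the target column's rank grid; tied entries receive
  the mean of the reference values across the whole tied run; missing cells
  are excluded and reinserted. Columns need ≥ 2 observed values.
* **MOMA-style probe→gene assignment**: per fragment the maximum probe
  score per sample; the fragment goes to the gene whose TSS (strand-aware)
  is nearest the fragment midpoint, ties broken by distance to the gene
  body then lexicographic id; per gene the maximum over its fragments.
  Whether "closest" meant TSS distance in the original protocol is not
  recoverable; TSS proximity matches the promoter-methylation intent and is
  deterministic. Beta-dialect probes use the same nearest-TSS rule (probe
  records carry no gene id) and a gene's value is the mean over its probes,
  missing unless ≥ 2 probes map to it.
* **Breakpoints**: a boundary between adjacent same-sample segments whose
  CNV states differ; direction is the state of the downstream segment when
  non-neutral, else the direction of the upstream non-neutral segment being
  exited. The rule is one deterministic reading of "regions between each
  segment" with gain/loss coloring.
* **Tumor:normal methylation ranking**: per-gene ratio of tumor to normal
  methylation means; the top and bottom `extreme_fraction = 0.10`
  (round-half-up counts) are flagged hyper-/hypomethylated. Genes with zero
  or missing normal means are skipped with a warning.
* **Tie-breaks and determinism**: stable sorts everywhere a rank or order
  matters; percentile ranking breaks q ties by gene id then class; the
  calibration grid tie-break prefers the threshold nearest 0. All floats
  serialize at `%.6g`, making whole-pipeline reruns byte-identical (the
  manifest records config hash and per-artifact SHA-256, with run-location
  paths relativized so reruns into different directories compare equal).

## Known limitations

* The Euclidean distances are reported as effect sizes next to the t/T²
  p-values; how distances and tests were originally combined is ambiguous,
  and other readings (e.g. testing per-sample distance values directly) are
  possible.
* The 20% group-size gate is applied per group; "a minimum 20% of the tumor
  samples" could also be read as the combined count (`gate_mode =
  "combined"` selects that reading).
* Near-zero trimming is global; a per-sample reading of the rule exists.
* Methylation quantile cuts are cohort-global, not per CNV class; the
  per-class alternative is a one-line change on the pooled series.
* The classifier's recovery depends on the cohort containing enough
  unremarkable genes to anchor the quantile cuts; in cohorts where most
  genes are altered the 25% cuts lose meaning.
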