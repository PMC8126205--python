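# Methods

This note documents the models and procedures `tfakit` implements, the
defaults it ships, and what its synthetic test bench does and does not
establish about real data.

## 1. Panel reduction

**Input.** A module repertoire: `n_modules` co-expression modules, each with
a member gene list, and an *activity* matrix (modules × reference datasets).
Activity is encoded as a single signed percent per module and dataset —
percent of member genes up-regulated minus percent down-regulated, bounded
by ±100 — so the responsiveness rule "at least 25 % of genes up- or
down-regulated" becomes the test `|activity| ≥ 25`.  Member genes carry
profile vectors in the same units.

**Partitioning.** Hartigan's k-means on the activity matrix: k-means++
seeding, nearest-center assignment, then repeated single-point reassignment
sweeps.  Moving module *x* from cluster *c* (size n_c) to *d* (size n_d)
changes the within-cluster sum of squares by
`n_d/(n_d+1)·‖x−μ_d‖² − n_c/(n_c−1)·‖x−μ_c‖²`; a move is taken only when
this is negative, so sweeps never increase the objective (this is asserted
by a test).  The best of `n_restarts` seedings by total within-SS wins; a
fixed seed makes the result deterministic.  K is a required parameter
(default 66, the study's subgroup count); an `elbow()` helper scans
within-SS over K for cases where K is genuinely unknown.

**Retention.** A subgroup is kept iff any member module reaches
`|activity| ≥ threshold` (default 25, inclusive) in any dataset.  An empty
retained set is an explicit error at panel-build time.

**Representatives and genes.** Each retained subgroup contributes the
member module with the smallest Euclidean distance to the subgroup mean
vector (ties → smallest module id).  Within the representative, member
genes are ranked by Euclidean distance of their profile to the same mean
vector, closest first, and the top `min(4, module size)` are selected.
"Highest-ranking" is read as *most representative* (closest), consistent
with the representative-module rule; because the opposite reading
(most extreme) is defensible, both orderings are implemented behind the
`order="closest"|"extreme"` flag.  Euclidean distance is used throughout,
matching the metric used downstream for clustering.

**Uniqueness.** Panel gene symbols must be unique (the real panel's 264
genes are exactly 66 × 4).  When a top-ranked gene was already claimed by
an earlier representative, the module's next-ranked gene is promoted and
flagged in the panel table.

## 2. Ct preprocessing

Stages run in a fixed order; every threshold is a parameter and is echoed
into output provenance.

* **Detectable-range masking.** Ct values above `detect_max_ct` become
  missing.  Default 28 cycles: the PCR protocol runs 30 cycles and the last
  cycles of a dilution series are unreliable, so a 2-cycle guard band is
  kept.  The bound is inclusive (28.0 is kept, 28.01 is not).
* **Sample QC.** A sample fails when its missing fraction over all assays
  exceeds `max_missing_frac` (default 0.5 — the failure mode emulated is
  gross amplification failure, where most assays drop out, so any value
  well inside (0, 1) separates the populations).  If one phase of a
  participant fails, the partner sample simply never forms a pair in the
  paired design; it is retained for unpaired summaries.
* **Housekeeping validation.** The pool is trusted only after checking
  stability: housekeeping genes with cross-sample Ct standard deviation
  above `sd_max` (default 1.5 cycles) are dropped; an empty pool is an
  error reporting each gene's SD.
* **dCt.** `dCt(g, s) = Ct(g, s) − mean(pool Ct in s)`.  The arithmetic
  mean of Ct corresponds to the geometric mean of linear abundances, the
  standard pooled-reference choice.  Samples missing part of the pool use
  the pool genes present (logged); a sample with no pool gene is an error.
* **Imputation.** Regularized iterative PCA: missing cells start at their
  gene means; the matrix is alternately approximated by its
  rank-`n_components` truncated SVD (after row centering) and the missing
  cells refilled until the largest change drops below `tol` (1e-6) or
  `max_iter` (1000).  Observed cells are never altered and complete
  matrices pass through unchanged.  The default rank 2 matches the
  two-component structure examined in the study's ordination; it is a
  parameter.  The procedure recovers exact low-rank completions (tested to
  1e-6 on rank-1 matrices) and beats the row-mean baseline it starts from
  on noisy low-rank data.
* **−dCt.** A tagged elementwise negation used for PCA and clustering so
  that "more transcript" plots as "more"; applying it twice is an error
  caught by the scale tag.

## 3. Paired differential expression

For participants with both phases, `ddCt = dCt(II) − dCt(I)` per gene;
positive ddCt = down-regulation after supplementation.  The signed fold
change is `r = 2^(−mean ddCt)`, reported as +r (r ≥ 1) or −1/r (r < 1), so
magnitudes are symmetric around ±1 and never inside (−1, 1).  The mean is
the default centre (mirroring the ddCt convention); median is an option.

**Wilcoxon signed-rank.** Zero differences are dropped (classic
treatment, the prevailing default of the era's statistical packages, rather
than Pratt's); |differences| are midranked; W = sum of positive ranks.
For n ≤ `exact_n_max` (25) without ties, the two-sided p comes from the
exact null distribution of the rank sum, computed by the standard
subset-sum dynamic program (identical to enumerating all 2ⁿ sign
assignments, which the test suite does up to n = 12); otherwise a normal
approximation with tie correction (−Σ(t³−t)/48 in the variance) and a 0.5
continuity correction is used.  An all-zero gene yields p = 1 with a
warning, not an exception.

**Multiplicity and calling.** Bonferroni over m = genes actually tested
after QC (not the nominal panel size; both are reported).  A gene is
called when `|signed FC| > fc_threshold` (default 2) and `p_adj < alpha`
(default 0.01).  The equivalent nominal threshold `alpha/m` is printed —
for 264 genes this is ≈ 3.8 × 10⁻⁵, which reconciles the two thresholds
quoted for the original analysis (adjusted 0.01 vs nominal 3 × 10⁻⁵).
Stratified re-analysis (`stratum="R"|"NR"`) reruns the identical pipeline
on the stratum's pairs with m = genes tested in that stratum; strata with
fewer than two pairs are refused.

**Ordination/clustering.** PCA on the −dCt matrix (samples as
observations, genes centered; component signs fixed so the largest-
magnitude loading is positive) and complete-linkage hierarchical
clustering on Euclidean distances (scipy's agglomerative implementation;
the merge height of complete linkage — the maximum pairwise distance
between joined clusters — is verified against direct computation in
tests).

## 4. The synthetic study

The generator emulates the study design so the pipeline can be validated
against known truth.

**Repertoire.** 382 modules in 66 planted subgroups across 16 datasets.
Subgroup centroids are i.i.d. Gaussian with per-coordinate scale
`separation` (default 40 activity units; with 16 dimensions typical
centroid pairs are ≈ 40·√32 ≈ 226 apart).  Responsive subgroups
(`responsive_fraction`, default 1.0) get one coordinate forced to magnitude
40–90 so they clear the 25 % rule decisively; non-responsive ones are
squashed under ±15.  Module activity = centroid + N(0, `noise_sd`²)
(default 2 — separation ≫ noise, making partition recovery a property of
the algorithm, not luck); gene profiles add the same noise around their
module.  Module sizes are uniform on 4–30 genes and symbols are globally
unique.

**Cohort.** 80 participants.  Pre-supplementation 25(OH)D ~ truncated
normal (mean 11, sd 4.5, range [2.5, 22.8] ng/mL) — the study's deficient
baseline.  Post levels are a 70/30 · 10 responder/non-responder mixture:
responders truncated normal (37.5, 10) on [20.01, 62.72] (chosen so the
overall post mean lands near the reported 34 ng/mL), non-responders
(9, 4) on [2.96, 19.0] with the highest non-responder pinned at
19.36 ng/mL, emulating the one participant just under the threshold.
Age, BMI and sun-exposure covariates are generated for summaries only; sun
exposure is deliberately *not* wired into expression (the study found no
correlation, and inventing one would plant structure the analysis never
claims).

**Ct matrix.** Additive Gaussian on the cycle (log2) scale, where dCt/ddCt
arithmetic is linear:
`Ct(g,s) = hk_mean + offset(s) + baseline_dCt(g) + shift(g)·[phase II] + ε`.
Housekeeping baselines are uniform on 18–20 cycles with per-assay noise sd
0.2; per-sample loading offsets have sd 0.5 (they cancel exactly in dCt,
which a test asserts); target baselines are uniform on 0–5 dCt units,
keeping nearly all values inside the detectable range.  53 planted down
genes get `shift = +log2(F)` with F uniform on [2.0, 2.6] (the printed
magnitude range of the original down-regulated calls) and 1 up gene gets
`shift = −log2(2.4)`.  Measurement noise has sd `pair_noise_sd/√2` per
assay so the paired difference has sd `pair_noise_sd` (default 0.5 Ct).
Missingness combines right-censoring at `detect_max_ct`, independent
dropout (`missing_rate`, default 0.01 — occasional no-calls), and, in the
QC preset, 2 failing samples with ~85 % of assays missing.

**What passing tests show — and don't.** The generator shares the real
data's design geometry, noise scale and planted effect sizes, but its noise
is Gaussian, homoscedastic and independent across genes; it has no
amplification-efficiency variation, no batch or plate effects, no
correlated co-expression beyond the planted shifts, and no covariate
structure.  Recovery results on it validate the *algorithms* (that the
pipeline finds what its model says it should find at this n and noise
level); they do not certify performance on real qPCR data with efficiency
drift or structured dropout.

## 5. Numerical and design choices

* **Detection vs calling in power checks.**  With planted |FC| drawn
  uniformly from [2.0, 2.6] and a strict |FC| > 2 call gate, genes whose
  true FC sits at the bottom of the range lie *on* the gate: at n = 80 and
  0.5 Ct pair noise the fold-change estimate has sd ≈ 0.08, so a few
  boundary genes per cohort are expected to land just under 2 and the
  called count fluctuates a little below 54.  Recovery is therefore
  quantified as *detection* (adjusted p < α with the correct sign), which
  is essentially 1 at these conditions, while the full called count is
  checked as a count with a tolerance band.  No sign errors are tolerated.
* **Boundary conventions.** Response: level ≥ 20 ng/mL → R (the boundary
  belongs to responders).  Status: deficient ≤ 20 < sufficient ≤ 30 <
  above-sufficient.  The two rules intentionally differ at exactly 20,
  each following its own stated convention; both are tested.
* **Histogram dialect.** Level histograms use width-2 bins centered on
  even integers (a 19.36 value falls in the bin centered at 20).
* **Ties.** k-means representative ties break to the smallest module id;
  gene-distance ties break by symbol; Wilcoxon ties use midranks.
* **Determinism.** Every stochastic component takes a seed and uses an
  isolated `numpy.random.Generator`; identical config + seed gives
  bit-identical output, asserted by tests.
* **Problem sizes.** The shipped validation runs use the study geometry
  (382 modules, 80 pairs, 264 + 8 assays); the family-wise error study
  uses 200 replicates of 1000-gene null cohorts at n = 80, enough to
  resolve a per-gene Bonferroni rejection rate of order 10⁻⁵ against its
  0.01 budget.

## 6. Known limitations

* The choice K = 66 is taken from the study; the elbow helper offers
  within-SS curves but no automatic K selection.
* Imputation can slightly attenuate effects of genes whose direction
  opposes the dominant expression pattern (a single up-regulated gene
  among 53 down-regulated ones), since the low-rank reconstruction pulls
  imputed cells toward the shared structure.  With ~1 % dropout this bias
  is well inside the reported tolerances.
* Inter-/intra-sample variation QC beyond missingness (the original
  instrument-suite checks) is not numerically specified anywhere and is
  not implemented; the pooled-control hook is metadata only.
* Exported gene lists are inputs for external network/enrichment services;
  the package neither calls those services nor reimplements them.
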