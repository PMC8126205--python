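# tfakit

Targeted blood-transcriptome fingerprinting: panel reduction and paired
qPCR differential expression, with a fully synthetic test bench.

## The problem

Whole-blood transcriptome profiling can be compressed into a *transcriptome
fingerprint assay* (TFA): instead of measuring every transcript, a repertoire
of co-expression modules — groups of genes that move together across a
reference collection of blood transcriptome datasets — is reduced to a small
targeted PCR panel that still spans the repertoire's response diversity.
`tfakit` reimplements, as a reusable and tested package, the two bespoke
computational procedures behind such a study of the blood transcriptomic
response to vitamin D3 supplementation in a deficient cohort:

1. **Panel reduction.** A repertoire of 382 modules profiled across 16
   reference datasets is partitioned with Hartigan's k-means; subgroups with
   no module reaching ≥ 25 % of member genes up- or down-regulated in any
   dataset are dropped; each retained subgroup contributes its most central
   module (closest to the subgroup mean vector), and each representative
   contributes its four genes whose profiles lie closest to that mean.
   With 66 retained subgroups this yields a 264-gene panel plus 8
   housekeeping assays.

2. **Paired differential expression.** Threshold-cycle (Ct) matrices from
   the panel are masked beyond the detectable range, QC'd, normalized to a
   validated housekeeping pool (dCt = Ct_gene − mean Ct_pool; higher dCt =
   less transcript), completed by iterative-PCA imputation, and tested per
   gene with the paired Wilcoxon signed-rank statistic over the per-
   participant differences ddCt = dCt(post) − dCt(pre).  The signed fold
   change is `r = 2^(−mean ddCt)` reported as `+r` when r ≥ 1, `−1/r`
   otherwise; a gene is called when |FC| > 2 and the Bonferroni-adjusted
   p-value is below 0.01 (equivalently, nominal p below 0.01/m).

Because the original cohort data live in a controlled repository, the
package ships a first-class synthetic generator that reproduces the study's
statistical structure — 80 participants sampled pre/post, a 264 + 8 assay
panel, 53 planted down-regulated genes and one up-regulated gene with
|FC| ∈ [2.0, 2.6], serum 25(OH)D trajectories with a 70/10
responder/non-responder mixture — with complete ground truth, so every
pipeline stage is testable end to end without any download.

## Worked example

```python
import tfakit as tk

# 1. reduce a synthetic repertoire to a targeted panel
rep, _ = tk.gen_repertoire(tk.repertoire_config("study", seed=42))
panel = tk.PanelReduction(rep, housekeeping=[f"HK{i}" for i in range(1, 9)])
print(panel.fit(K=66, n_restarts=25, seed=42).summary())

# 2. simulate a paired cohort, preprocess, and test
cfg = tk.cohort_config("study", seed=42)
ct, truth, cohort = tk.simulate_study(cfg)
dct, reports = tk.preprocess_pipeline(ct)
model = tk.PairedExpression(dct, tk.PairedDesign.from_meta(dct.meta))
print(model.fit().summary(top=3))
```

prints

```
Panel reduction results
===========================================
subgroups (K):        66
retained subgroups:   66
representatives:      66
target genes:         264
housekeeping genes:   8
retention threshold:  |activity| >= 25.0%
genes per module:     <= 4 (closest-first ranking)
within-subgroup SS:   20638.62

Paired differential expression (Wilcoxon signed-rank)
========================================================
stratum:              all
pairs (participants): 80
genes tested (m):     264
call criteria:        |FC| > 2.0 and Bonferroni p < 0.01
  (nominal p <        3.79e-05)
genes called:         54 (53 down, 1 up)

top genes by |signed FC|:
gene         signed_fc        W       p_adj
G00239           -2.65     3240    2.11e-12
G00153           -2.61     3240    2.11e-12
G00169           -2.61     3240    2.11e-12
```

The reduction recovered all 66 planted responsive subgroups and assembled
the 264-gene panel; the paired test called 54 genes (53 down, 1 up),
matching the planted truth at this seed, at a Bonferroni-equivalent nominal
threshold of about 3.8 × 10⁻⁵.  `DEResults` also exposes `pca()`,
`clustering()` (complete linkage on Euclidean distances of the −dCt
matrix), `volcano_frame()` and fits per response stratum
(`model.fit(stratum="R")`).

The same pipeline is scriptable from a shell:

```sh
tfakit simulate --preset study --seed 42 --out sim/
tfakit preprocess --ct sim/ct.tsv --meta sim/meta.tsv --out dct.tsv
tfakit dge --dct dct.tsv --design sim/meta.tsv --out deg.tsv
tfakit export-genelist --deg deg.tsv --direction down --out down.txt
```

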