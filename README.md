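# ertarget

Discovery of estrogen-receptor (ER) target genes whose binding persists in
endocrine-resistant breast-cancer cells, and prioritization of those genes
by their association with patient survival.

In ER+ breast cancer treated with aromatase inhibitors, resistant cells
(modelled by long-term estrogen-deprived LTEDaro lines) keep recruiting ER
to chromatin even without estrogen. Genes that are (i) bound by ER in the
resistant condition at least as strongly as in the estrogen-stimulated
responsive condition, (ii) near those binding sites, and (iii)
differentially expressed between the two conditions are candidate direct
ER targets of the resistant state; their expression in patient cohorts can
then be tested as a prognostic signal, stratified by ER and HER2 status.

`ertarget` implements that pipeline as a tested library with a synthetic
data generator, so every stage runs with planted ground truth and no
external downloads.

## The pipeline

**Discovery funnel** (`ertarget.peaks`, `ertarget.integration`):

1. keep peaks with peak-level FDR ≤ 0.5% (percent scale) per condition;
2. scale intensities to a common read depth;
3. classify sites *common* when intervals share ≥ 1 bp (0-based half-open;
   abutting intervals do not overlap), else *unique*;
4. keep resistant-condition sites with normalized intensity ratio
   (resistant / responsive) ≥ 0.9, plus resistant-unique sites;
5. annotate each kept site with every gene whose TSS lies within ±20 kb of
   the summit (strand-aware signed distances);
6. keep annotated genes with a two-sided expression change ≥ 1.2-fold at
   Benjamini–Hochberg q < 0.05 (Welch's t on log2 values).

**Survival prioritization** (`ertarget.survival`): genes are ranked by the
univariate Cox partial-likelihood score statistic at β = 0,

    s = U / √I,   U = Σ_{i:event} (x_i − x̄_{R_i}),
                  I = Σ_{i:event} ( mean(x²; R_i) − x̄_{R_i}² ),

with risk sets R_i = {j : t_j ≥ t_i} and Breslow tie handling; expression
is z-scored per gene so the conventional |s| ≥ 2.39 cutoff is comparable
across genes. Patients are stratified by the median expression of a single
gene (ties go low) or by 2-means clustering of a standardized gene panel
(the worse-surviving cluster is labelled high-risk), and groups are
compared with the Kaplan-Meier product-limit estimator and the two-group
log-rank test, optionally within ER/HER2 receptor-status subgroups.

A minimal IUPAC consensus scanner (`scan_ere`, default palindromic core
`GGTCANNNTGACC`) checks candidate sites for the estrogen response element.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data with planted truth:

```sh
python analysis/01_simulate_data.py      # fixtures under results/fixtures
python analysis/02_discover_candidates.py
python analysis/03_survival_analysis.py
python analysis/04_calibration.py
```

The discovery driver prints the funnel (seed 1):

```
Funnel:
  read_inputs                    peaks_a=400, peaks_b=385, genes=500, expr_genes=500
  filter_by_fdr                  peaks_a=362, peaks_b=344
  overlap_peaks                  common_a=245, common_b=245, unique_a=117, unique_b=99
  resistant_associated_sites     peaks=274
  annotate_sites                 sites=274, genes_in_window=65
  candidate_genes                candidates=10

planted recovered: 10/10
false candidates:  0
```

Reading the funnel: of 400 resistant-condition peaks, 362 pass the FDR
filter; 245 are common with the responsive condition and 117 are
resistant-unique; 274 survive the change-ratio rule; 65 genes have a TSS
within 20 kb of a surviving site; and exactly the 10 genes planted to pass
all filters — none of the 40 decoys built to fail exactly one filter —
reach the candidate list.

The survival driver then ranks those candidates in the 570-patient
synthetic cohort. In the ER+ subgroup (417 patients) all 10 planted
prognostic genes pass |s| ≥ 2.39 with positive scores (higher expression,
higher hazard; e.g. G045: s = 5.97, median-split log-rank p ≈ 1e-8), while
smaller subgroups retain fewer. The calibration driver reports (seed 1):

```
                   quantity  value           note
logrank_null_rejection_rate 0.0440   expect ~0.05
      null_cox_tail_at_2.39 0.0164 expect ~0.0169
 planted_top_score_fraction 1.0000   expect ≥0.95
      planted_logrank_power 1.0000   expect ≥0.90
```

i.e. the null type-I error of the median-split log-rank composition is at
its nominal 5% level, the null Cox-score tail matches the two-tailed
normal mass beyond 2.39, and a planted β = −0.5/SD gene among 500 is
recovered essentially always.

A `ertarget` console command wraps the same stages
(`ertarget all --fixture-dir fx --outdir run --seed 1`; see
`ertarget --help`).

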