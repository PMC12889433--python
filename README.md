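# bamscape

Composition, metabolic-penalty and image quantification pipeline for
studying **border-associated macrophage (BAM) decline in Alzheimer's
disease (AD)**, exercised end-to-end on synthetic data with known ground
truth.

BAMs — the macrophages of the meninges, perivascular spaces and choroid
plexus — and in particular the CD206-hi **BAM2** subset appear to protect
against amyloid pathology and cerebral amyloid angiopathy (CAA), and to
decline in number and function as disease progresses. Quantifying that
decline takes three kinds of bespoke computation, all implemented here for
anyone analysing annotated single-cell tables, Compass-style reaction
penalties, or fluorescence micrographs:

* **`bamscape.composition`** — cluster condition-enrichment scores
  (naive score `n_AD,c / n_c`, normalised so the mean over clusters is 1),
  the exponential BAM2:BAM1 score `E = exp((n_CD206 − n_MHCII)/N)`, the
  0.1% capture-quality patient filter, module-score signature ratios,
  Hampel-filter (median ± 3·1.4826·MAD) flagging of per-cluster GWAS-gene
  expression deltas, and OLS models of per-patient BAM frequency on the
  clinical covariates (sex, Braak, PMI, CERAD, education, APOE E2/E4).
* **`bamscape.metabolic`** — random pseudobulking into 10-cell metacells,
  penalty→flux conversion `flux = −log(1 + penalty)` (min-fixed,
  per-reaction z-scored), per-reaction Cohen's d (pooled SD) with
  Benjamini–Hochberg-adjusted rank-sum p-values, median-d subsystem
  summaries (≥3 core reactions, enriched when |median d| > 0.1), and
  healthy→AD transition distances via the Gram expansion
  `‖a−b‖² = ‖a‖² + ‖b‖² − 2a·b`.
* **`bamscape.imaging`** — the particle-analysis chain (max projection,
  rolling-ball background subtraction, disk median filter, fixed-value
  thresholding, erode/dilate, 8-connected particle labeling, % area) and
  the CAA% macro: percent of the vessel mask covered by plaque signal.
* **`bamscape.synthetic_data`** — generates all of the above inputs with
  recorded ground truth (true depletion folds, true subsystem shifts, true
  plaque-on-vessel coverage), so every estimator is tested by recovery.
* **`bamscape.orchestrator`** — config-driven end-to-end runs with a
  deterministic, seed-stamped results bundle.

## Worked example

```python
import bamscape as b

# a synthetic cohort: 40 donors/arm, BAM2 halved in AD donors
cfg = b.SyntheticConfig(seed=1, bam2_ad_depletion_fold=2.0,
                        braak_fold_per_step=1.0)
cells, truth = b.gen_cell_table(cfg)
enr = b.cluster_enrichment(cells, "AD")
print(enr.round(3))
```

```
           n_cells  n_condition_cells  naive_score  normalized_score
cluster
microglia    89482              46625        0.521             1.098
BAM1          6222               3251        0.523             1.101
BAM2          3894               1310        0.336             0.709
DC            4171               2162        0.518             1.092
```

BAM2 is the only cluster whose normalised AD enrichment falls well below 1
— the generated two-fold depletion, recovered from the cell table alone
(0.709 ≈ the AD share of a half-sized cluster after normalisation; the
other clusters sit near 1). Feeding each donor's log BAM2 fraction and
clinical table into `b.clinical_model` then yields a negative Braak
coefficient when the generator couples Braak stage to BAM2 decline, exactly
as a forest plot of a real cohort would show.

The command line mirrors the library
(`bamscape composition enrich|score|filter|model`,
`bamscape metabolic pseudobulk|flux|effects|subsystems|distance`,
`bamscape imaging caa|area|count`), and

```sh
bamscape demo --out demo_out --seed 0
```

generates and analyses the shipped scenario (`configs/demo.yaml`) in a few
seconds, writing per-stage tables and a `results.json` stamped with the
seed and config hash; rerunning it is byte-identical.

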