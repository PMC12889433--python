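# Methods

`bamscape` implements the quantitative tail of a study of border-associated
macrophage (BAM) decline in Alzheimer's disease (AD): composition-shift
statistics on annotated single-cell tables, post-processing of metabolic
reaction penalties from a Compass-style flux-balance step, and the
morphological quantification of amyloid and cerebral amyloid angiopathy
(CAA) in fluorescence micrographs. Everything runs on synthetic data with
recorded ground truth; nothing requires a download.

## The synthetic cohort

`synthetic_data.SyntheticConfig` defines one dataset. A balanced cohort of
healthy and AD donors is generated; each donor receives clinical covariates
(sex ~ Bernoulli(0.5); Braak stage 0–6, uniform in healthy and linearly
up-weighted toward high stages in AD; PMI ~ Gamma(3, 3) hours; CERAD 0–3
with mass reversed between conditions; education ~ round(N(16, 3)) clipped
to [8, 25]; APOE e2 ~ Bin(2, 0.08), e4 ~ Bin(2, 0.15/0.35)). Cells are
multinomial draws from per-donor cell-type proportions over {microglia,
BAM1, BAM2, DC} with healthy baseline {0.85, 0.06, 0.05, 0.04}. The BAM2
baseline of 5% is a convenience default within the plausible range for the
brain immune landscape, not a measured value.

Disease acts on the BAM2 proportion only, multiplicatively:
`p_BAM2 = base / (depletion_fold [if AD]) / (braak_fold ** braak)`, and the
other cell types share the complement `1 - p_BAM2` in their base ratio.
Holding the realized BAM2 proportion exactly log-linear in the fold
parameters (rather than dividing BAM2 and renormalising everything) makes
the generated effects exact: the AD:healthy BAM2 fraction ratio is exactly
`1/depletion_fold` and the per-Braak-step log-fraction slope is exactly
`-log(braak_fold)`. Both folds default to 2, matching the scale of decline
the method is meant to detect.

Reaction penalties are log-normal, `exp(N(location + shift, scale))`, over
90 reactions in nine 10-reaction subsystems; `shift_map[(subsystem,
cell_type)]` adds a signed shift on the log-penalty of AD samples of that
cell type only. Images are two-channel z-stacks (vessel, plaque): vessels
are biased random walks dilated to a 7-pixel width (wide enough that the
quantification macro's erode x2 / dilate x2 step preserves diagonal
segments, as it would for the large penetrating vessels the measure targets);
plaques are uniform disks placed by rejection sampling against the noiseless
vessel mask until the plaque-on-vessel coverage target is met within one
percentage point (candidate centers are screened near the target to avoid
overshoot; an exhausted iteration budget raises rather than silently
missing). Signal amplitude is 200 counts over a smooth sinusoidal background
(~20 counts); each structure has a Gaussian axial profile peaking at 1 so a
maximum projection recovers the full plane. Noise is Poisson shot noise on
the expected signal plus Gaussian read noise with sigma = peak/snr.

All randomness flows from one seed with fixed per-component sub-streams, so
the clinical table is identical whether generated before or after the cell
table, and identical configs give byte-identical serialized outputs.

What the generator does *not* emulate: sequencing depth and UMI noise,
ambient RNA, clustering/annotation error, spatially realistic vessel
topology, or the optics of a real confocal stack. Passing recovery tests
therefore demonstrate estimator correctness under the stated statistical
model, not robustness to the full messiness of real data.

## Composition statistics

* **Cluster enrichment.** Per cluster, the naive score is the fraction of
  its cells from the condition of interest; scores are normalised by their
  mean over clusters (so the normalised scores always average to 1, and a
  value below 1 marks relative depletion in that condition).
* **Exponential BAM2:BAM1 score.** `E = exp((n_CD206 - n_MHCII)/N)` per
  donor, with `N` the donor's total cell count (all cells, not only
  macrophages — the natural reading of the defining formula). `E` is
  reciprocal under swapping the subsets and confined to `[e^-1, e]`.
* **Capture filter.** Donors with fewer than 0.1% of cells carrying a
  target label are dropped; the boundary is inclusive ("at least").
* **Signature ratio.** A deliberately simple module score — mean expression
  of the set minus a size-matched random background set, with the background
  draw keyed on the set contents so identical sets score identically —
  exponentiated, ratioed per cell and averaged within clusters. Bin-matched
  background controls are a tool-specific refinement that is out of scope.
* **Hampel flags.** Per-cluster deltas beyond median ± 3 x (1.4826 x MAD)
  are flagged by sign. With MAD = 0, any delta off the median is flagged
  (degenerate-scale rule); the default k = 3 is the conventional choice.
* **Clinical model.** OLS of a per-donor response on the fixed covariate
  set {sex, Braak, PMI, CERAD, education, E2, E4}, CERAD treated as a
  numeric ordinal, no interactions. A rank-deficient design raises, naming
  the collinear terms. The slope-recovery study condition uses 200 donors
  at 4000–8000 cells each: at shallower capture the high-Braak BAM2
  fractions rest on a handful of cells and the log(count) bias — not the
  estimator — dominates the fit. Per-donor fractions use a half-count
  pseudocount so zero-BAM2 donors remain in the model.

## Metabolic penalty post-processing

Pseudobulking randomly partitions cells into disjoint metacells of exactly
10 within each (cell type, condition) stratum, summing members and dropping
remainders (keeping the metacell size exact). Penalties map to flux as
`-log(1 + penalty)`, shifted so the global minimum is 0 ("min-fixed"), then
z-scored per reaction; since z-scoring is shift-invariant per reaction the
min-fix provably cannot change the output, which the suite asserts as a
pipeline-equality test rather than debating the reading. Constant reactions
are zeroed and flagged.

Per-reaction effects are Cohen's d with the pooled (n-1)-weighted SD —
the conventional resolution of "mean divided by the standard deviation" —
plus a two-sided Wilcoxon rank-sum p-value, Benjamini–Hochberg adjusted
across all reactions of a comparison. Subsystems summarise member d values
by the median, require at least 3 core reactions, and are called enriched
when |median d| > 0.1; reactions at adjusted p < 0.1 are counted as
significant. d is computed on z-scored flux by default (switchable to raw).

Transition distance is the distribution of all healthy x AD pairwise
Euclidean distances within a cell type, computed through the Gram expansion
`||a-b||^2 = ||a||^2 + ||b||^2 - 2 a.b` with negative rounding artifacts
clamped at zero; distributions are compared across cell types by rank-sum
with BH adjustment. Pairs sharing a cell are not independent, so these
p-values describe the pair distribution rather than a donor-level inference
— the computation mirrors the descriptive use it supports, and the caveat
stands.

## Image quantification

The particle-analysis chain is: maximum z-projection; rolling-ball
background subtraction (classical ball estimate, radius 50 px default;
a radius at or above the frame degenerates to global-minimum subtraction
with a warning); disk median filter (radius 2 for % area and counting,
radius 3 in the CAA macro); absolute-intensity thresholding (Otsu as an
explicit opt-in — compared sections are meant to be thresholded
identically, so fixed values are the default and are caller-supplied);
binary erosion/dilation with a 3x3 square, one pass per iteration;
8-connected particle labeling (configurable to 4); area fractions as
100 x object/ROI.

CAA% follows the macro: vessel channel -> project -> background-subtract ->
median(3) -> threshold -> erode x2 -> dilate x2 gives the vessel mask and
its area; the plaque channel is projected, restricted to that mask, and
thresholded raw (no filtering, as in the original); CAA% = 100 x
plaque-on-vessel / vessel area. Because the plaque channel is thresholded
raw, its threshold must clear the *max-projection* noise floor: at snr 5
the projected background reaches ~80 counts plus tails, so 150 counts is
the working default against the 200-count signal. Cell counting applies the
same chain and divides the particle count by the analysed area in um^2.

Numerical notes: coordinates are (z, y, x), 0-based, pixel-centred; areas
are reported in px and um^2; masks are strictly boolean with provenance
strings. The rolling-ball background is the classical ball definition, not
any tool's paraboloid approximation — ground-truth recovery, not
bit-equality with an external program, is the contract. Mask-boundary
discretization (the median filter shifts outlines by ~1 px at corners)
biases coverage by ~1 part in 70 on thin 7-px tubes and becomes negligible
on thick vessels; the full-coverage check accordingly probes 13-px vessels.

## Orchestrated runs

`orchestrator.run` executes composition, metabolic and imaging stages from
one YAML/JSON config, writing per-stage tables and a `results.json` bundle
stamped with the seed and a hash of the scientific configuration (output
location excluded). Stage failures abort with the stage named and keep
completed outputs; config errors and computation errors carry distinct CLI
exit codes (2 and 3). Reruns with the same config are byte-identical,
including the TIFFs. The shipped `configs/demo.yaml` scenario (20 donors
per arm, 300–600 cells each, one down-shifted subsystem, one 20%-coverage
image) completes in a few seconds on one CPU.

## Problem sizes

Repeated-seed calibrations use deliberately desk-scale conditions: null
calibration at 10–30 donors per arm over 100–200 seeds; depletion recovery
at 40 donors per arm over 100 seeds; slope recovery at 100 donors per arm
over 100 seeds; metabolic recovery at 100 metacells per arm over 100 seeds;
image recovery over five coverage targets at 256x256x8 and snr 5. The
acceptance script (`scripts/acceptance.py`) re-runs the same study
conditions at 25–100 replicates.

## Known limitations

* The module score's random background is size-matched but not
  expression-matched; on strongly depth-skewed data it would be biased.
* Rank-sum tests on transition-distance pairs ignore pairwise dependence.
* The Hampel edge rule flags *every* off-median delta when MAD collapses to
  zero, which is aggressive when most deltas tie exactly.
* The image generator's vessels are 2-D tubes replicated across z with an
  axial intensity profile, not 3-D vasculature.
* Cohen's d with zero pooled SD is reported as signed infinity and excluded
  from subsystem medians; a subsystem composed entirely of such reactions
  would disappear from the summary (its exclusion is counted).
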