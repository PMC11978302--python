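# Methods

## Study model

The pipeline targets a two-model, time-resolved liver-fibrosis design:
a hepatotoxic model ("CCl4like") that injures pericentral hepatocytes and
largely heals after challenge withdrawal, and a cholestatic model
("DDClike") with periportal/biliary injury and limited healing. Six mice
are sampled terminally per model and time point (untreated controls, two
progression points T1/T2, two resolution points T3/T4), each contributing
three MS samples: total lysate (Total), detergent-soluble supernatant (S)
and detergent-insoluble ECM-enriched pellet (E). All protein matrices are
log2 MS intensities with an explicit observed/missing mask.

## Quantification

Per-sample proportional coefficients make shared-peptide intensities
comparable across runs and fractions. For every sample pair the median
log2-ratio of peptides observed in both (unique+razor evidence only)
defines one linear equation in the per-sample log-coefficients; the system
is solved by least squares and gauged so each connected component of
samples has geometric-mean coefficient 1. Samples sharing no peptides with
any other sample get coefficient 1 with a warning; a design with no shared
peptides at all is rejected. Protein intensity per sample is the sum of
coefficient-scaled peptide intensities; a protein with no observed peptide
in a sample is missing, never zero. The construction is scale-equivariant
(multiplying one connected sample's intensities by k is absorbed by its
coefficient) and the gauge cancels after log2 transformation and
per-sample centering, so downstream statistics do not depend on it.

## Preprocessing

* **Filtering** keeps proteins with ≥ `min_valid` (default 5) observed
  values in at least one (model, time point) group; a pooled-models scope
  is available. Row order is preserved.
* **Normalization** subtracts each column's observed median and re-adds the
  grand median of the matrix, leaving the missingness mask untouched.
* **Imputation** replaces each missing cell with a draw from
  `N(m − shift·s, (width·s)²)`, `shift = 1.8`, `width = 0.3`, where `m, s`
  are the observed mean and SD of the cell's column (default) or of the
  whole matrix — the scope is a parameter because "the total intensity
  distribution" admits both readings. Draws are consumed in row-major
  order from a single seeded generator, so imputation is reproducible
  cell-for-cell. Observed cells are never altered.
* **z-scoring** uses the population (1/n) SD — the heatmap-tool
  convention; with n = 6 replicates the difference from the sample SD is
  immaterial but a single convention keeps expected values exact in tests.
  Constant rows cannot be scaled and are excluded with a diagnostic.

## Statistics

t-tests are pooled-variance Student tests (Welch available by flag),
matching the convention of the analysis platforms this pipeline mirrors.
One-way ANOVA, Kruskal–Wallis (tie-corrected) and Fisher's exact test
(two-sided, "sum of ≤-probability tables" convention) follow the standard
definitions; Benjamini–Hochberg is the usual step-up with monotone
adjusted p-values. Degenerate inputs never raise inside genome-scale
loops: zero-variance groups yield boundary p-values (1 when means agree,
0 with a warning otherwise) so a constant protein row cannot abort a scan.
Dunn's post-test compares mean joint ranks with the tie-corrected normal
approximation; its multiplicity adjustment defaults to Bonferroni (the
common implementation of the named procedure), BH selectable. The
Bonferroni post-ANOVA test uses the pooled within-group variance of all
groups with N−k degrees of freedom. The slope p-value in the correlation
stages is the two-sided t-test of `slope/SE` with n−2 df, identical to the
test of r = 0.

## Differential and solubility rules

The Total-proteome contrast calls a protein differential when its imputed
log2 mean at T2 minus the control mean is at least `log2 1.5` in magnitude
and the t-test passes BH at q = 0.05; the BH family is all proteins that
survived the valid-value filter in that run. Fold changes are computed on
log2 means (a geometric-mean intensity ratio) after imputation. Induced
proteins are read from the *pre-imputation* detection mask: zero control
detections and detections in ≥ 50% of replicates at both T1 and T2 (the
fraction is a parameter; the detection convention is supplied by the
caller via the mask).

E/S ratios subtract, per protein, the median S-fraction intensity from
each E replicate. The S median is global over all S samples of the model
by default (the singular phrasing of the source protocol), per-time-point
by option. Selection requires a mean per-time-point ratio ≥ log2 3
(inclusive) in at least one time point *and* a BH-significant time-course
ANOVA on the E intensities. Caveat of the global scope: a protein whose S
abundance declines persistently (low-healing model) drags its time-global
S median down and can look "3-fold E-enriched" at control time points;
the per-time-point scope avoids this. Recovery benchmarks therefore use
the high-healing model, where the artifact is absent.

## Correlation stages

Protein deltas are log2 intensities minus the protein's control mean;
fibrosis deltas are sirius-red-positive areas minus the mean control area.
Pairing is by mouse (terminal sampling: one time point per mouse).
Controls are excluded from the regression by default — their deltas are
centered at zero by construction and would act as anchor points; a flag
includes them. Significant correlates are partitioned by slope sign across
the Total and E compartments; "positive in both" is the profile of a
protein tracking scar formation and resolution in both compartments. The
stiffness–proteome correlation averages per-map median moduli per mouse,
subtracts the mean control modulus per region, and regresses protein
deltas on the result through the same vectorized Pearson/slope core.

## AFM processing

The contact point is found by exhaustive two-segment least squares: for
every candidate sample, a straight baseline is fit to the pre-segment and
the Hertz rise `F = a·δ^{3/2}` to the baseline-subtracted post-segment,
with indentation `δ = (z − z_c) − F/k` (piezo travel minus cantilever
deflection, spring constant k from curve metadata); the candidate with the
smallest total squared residual wins. This is deterministic and
noise-stable, unlike derivative thresholding. A curve whose best fit has
non-positive Hertz coefficient raises "no contact detected". The Young's
modulus follows from `E = (3/4)·a·(1−ν²)/√R` with ν = 0.45 and
R = 2.85 µm, fitted on the post-contact segment capped at δ ≤ 0.3·R (the
small-indentation regime; the cap is configurable). Region statistics pool
pixel values (not per-map medians) for Kruskal–Wallis/Dunn, matching a
frequency-distribution analysis; per-map medians are kept for the
correlation stage. Failed fits are flagged and excluded.

## Synthetic-data generator

The generator emulates the full design with planted truth:

* Baseline abundances `log2 x ~ N(23, 2)` — the dynamic range of LFQ
  intensities, chosen so the imputation downshift lands in a meaningful
  region.
* Planted classes: `tracking_pos` (+effect in all fractions), `declining`
  (−effect in all fractions), `solubility_shift` (+effect in E only),
  `null`; default 5% each, with the planted effect 2 log2 units at T2 and
  replicate noise 0.5 log2 — a strong but realistic fibrosis response.
* The temporal profile is piecewise linear 0 → ½ → 1 over Ctrl → T1 → T2,
  then reversed by half the model's healing factor at T3 and the full
  factor at T4 (0.9 for the hepatotoxic model, 0.1 for the cholestatic
  one). No further kinetics are invented.
* Missingness is left-censored: each value is masked with probability
  `1/(1+exp(slope·(x − midpoint)))`, midpoint 18.5 and slope 0.8 by
  default (≈ 6% missing overall, concentrated at low intensities).
* Peptide tables draw 3–8 peptides per protein with lognormal ionization
  shares, per-sample loading factors (log2 SD 0.3) that the proportional
  coefficients must undo, 10% multiplicative peptide noise and
  peptide-level censoring.
* Fibrosis areas per mouse are background (0.6%) + amplitude (12%) ×
  the model's burden profile + N(0, 1%) noise, floored at zero, so
  control-background subtraction is exercised.
* Force curves follow the spherical Hertz model at each pixel's regional
  modulus — defaults are the measured per-region medians (control
  1.6/1.3/1.2 kPa; T1 2.7/1.9/0.8; T2 4.4/2.8/2.0; T4 3.0/2.5/1.4 for
  collagen/injured/interface) — with 5% multiplicative force noise and a
  random tilted pre-contact baseline so contact detection is nontrivial.
* Everything is driven by spawned child generators from one seed:
  identical config + seed gives byte-identical studies.

What the generator does *not* emulate: peptide sequences and spectra,
protein–protein intensity correlations, batch effects, shared latent
per-mouse biology linking proteome noise to fibrosis-area noise, razor
assignment ambiguity, or spatial autocorrelation within AFM maps. Passing
recovery tests therefore demonstrate the pipeline's correctness on an
idealized but structurally faithful study, not performance on any real
dataset.

## Interaction of censoring and imputation (known limitation)

Downshifted imputation draws near the censoring limit of the *column*
(≈ mean − 1.8 SD over all proteins). For a protein whose true values sit
near or below that limit, imputed cells are biased toward the limit,
attenuating planted fold changes, E/S ratios and correlation slopes. The
recovery benchmarks quantify this: with censoring disabled the
differential contrast recovers > 99% of planted effects, while under the
default censoring the sensitivity over *all* planted proteins drops to
≈ 0.85 (and the both-compartment correlation recovery to ≈ 0.8), entirely
attributable to proteins with imputed cells; fully detected proteins are
recovered essentially always, and FDR / global-null error control is
unaffected. This mirrors the behaviour of the same procedure on real
left-censored LFQ data and is reported as measured rather than hidden by
weakening the censoring.

## Problem sizes and numerics

Unit tests and benchmarks run studies of 100–500 proteins (the package's
chosen desk scale; the full design of several thousand proteins runs in
seconds but adds nothing to the assertions), 10 seeds for recovery rates,
100 seeds for global-null rates, and 10 seeds × 7 maps × 10×36-pixel
grids for the AFM power analysis. Ties in clustering follow scipy's
deterministic scan order; cluster labels are renumbered by leaf order so
dendrograms and cuts are reproducible. BH uses statsmodels' step-up;
oracle tests verify exact agreement with a literal enumeration. The
pipeline's per-stage seeds are crc32 hashes of "seed:stage-name", so
inserting a stage never perturbs another stage's randomness. The run
report lists every output file with its sha256; two runs from one config
are byte-identical (the report's wall-time field aside).
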