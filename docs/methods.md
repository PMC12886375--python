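# Methods

`csfnmr` implements the analysis chain used in case–control CSF
¹H-NMR metabolomics of canine neurological disease: spectral quality
control, variable-width binning with representative-bin selection,
univariate and multivariate group discrimination, and pathway
over-representation analysis. A synthetic-cohort generator with full
ground truth makes every stage verifiable without any external data.

## The synthetic cohort

The generator emulates a three-group study — MUO (meningoencephalitis
of unknown origin), SRMA (steroid-responsive meningitis-arteritis) and
IE (idiopathic epilepsy) — sized 20/14/22, with 56 annotated
metabolites (including the three exogenous contaminants ethanol,
isopropyl alcohol and mannitol) mapped to roughly 383 variable-width
peak bins.

Forward model, per sample *i* and metabolite *m*:

* log-concentration `log c_im = μ_m + δ_{g(i),m} + σ √ρ z_im`, with
  `μ_m` a fixed metabolite baseline (uniform on log [0.5, 5]),
  `δ_{g,m}` the group log-fold-change from the effect table, `σ` the
  within-group log-SD (default 0.25) and `ρ` the within-metabolite
  bin correlation (default 0.9). Concentrations are log-normal:
  non-negative, right-skewed, consistent with the routine use of
  non-parametric tests on such data. The CSF concentration
  distribution itself is a modelling choice, not an observed one.
* each metabolite renders as 1–13 Lorentzian singlets (FWHM 0.002 ppm)
  at per-metabolite chemical shifts shared across samples — spectra
  are assumed aligned, so no shift drift is simulated — and each peak
  owns one bin. Per-bin log-normal jitter with SD `σ √(1−ρ)` makes
  same-metabolite bin intensities correlate at ≈ρ across samples.
* a broad residual-water hump (FWHM 0.25 ppm) sits at 4.85 ppm inside
  the 4.52–5.18 ppm exclusion window; a reference singlet at 5.24 ppm
  (the glucose anomeric position, FWHM 0.00243 ppm ≡ 1.70 Hz at
  700 MHz) supports line-width QC; additive Gaussian noise (SD 1.0
  against peak heights of a few hundred) forms the baseline.
* optional "high-protein" outlier samples receive a broad elevated
  baseline and 2.2× line widths; exogenous metabolites get
  concentrations independent of group.

The default effect table plants 29 of the 53 endogenous metabolites as
differential at ±0.5 natural-log units (2 within-group SD),
predominantly elevated in SRMA and depressed in IE relative to MUO,
with myo-inositol and ascorbate running the other way — the direction
pattern reported in comparable clinical cohorts.

**What the generator does not emulate** — and hence what passing tests
do not establish about real data: J-coupling multiplets and peak
overlap, chemical-shift drift, baseline roll, realistic inter-
metabolite biochemical correlations, and clinical effect sizes. The
planted effects are deliberately strong (2 SD) so that recovery is a
sharp pass/fail property; real CSF group differences are far subtler,
and real classification accuracies will be lower than the near-perfect
values the synthetic cohort yields.

**Compositional coupling.** Under total-area normalization, 29 strong
one-sided effects shift every sample's total area, so null metabolites
acquire systematic opposite-direction shifts and also reach formal
significance. On the default cohort the KW-FDR discovery count
therefore exceeds the planted 29 — a property of closure
(constant-sum) data, not a test defect. Calibration is therefore
assessed on global-null cohorts (empty effect table), where the
discovery fraction is controlled well below nominal.

## Spectral QC

Line width at half height of the reference peak: the maximum within
±0.02 ppm of 5.24 ppm is located, the local baseline is the window
minimum, and both half-maximum crossings are found by linear
interpolation between bracketing grid points (deterministic and
resolution-robust; the estimator converges to the true Lorentzian FWHM
as the axis densifies). The ppm width × spectrometer frequency (MHz)
gives Hz. The cohort acceptance window is mean ± k·SD (default k=1,
the 1-SD rule used with reference windows such as 1.43–1.97 Hz).

Residual water is measured the same way over 4.52–5.18 ppm, against a
baseline taken from a 50 %-widened window so a hump that fills the
search window is measured against its true tails; a maximum at the
window edge is the tail of an outside peak and counts as no hump.
Width > 0.4 ppm fails. Signal-to-noise comparability — named as a QC
criterion in practice but never given a formula — is implemented as
max intensity over the SD of a declared signal-free region (default
9.5–10.0 ppm), flagged outside mean ± 2 SD (permissive by intent).

In the original study workflow, out-of-window spectra were *reacquired*
until they passed, so the analyzed cohort kept all animals. With no
instrument in the loop the pipeline's default is to record line-width
flags without excluding (`qc.action: flag`); exclusion mode is one
config switch away. This matters because with identical true line
widths the cohort SD is pure estimator noise and a mean±1SD window
would discard arbitrary spectra.

## Binning and CRS selection

Bins are trapezoid integrals over half-open ppm intervals `[low,
high)` — half-open so adjacent bins never double-count a grid point.
Bins intersecting the water exclusion window are dropped and recorded.

Where several bins carry one metabolite annotation, the correlation
reliability score picks the representative: CRS(b) = mean of bin b's
off-diagonal Pearson correlations with the metabolite's other bins
across samples. The diagonal is excluded — including the constant 1
would shift every score equally and never change the argmax, but the
off-diagonal mean is the cleaner reading of "mean correlation per
bin". Single-bin metabolites score 1 by convention; zero-variance bins
score −∞ over undefined entries and are never selected against a
defined competitor.

Two-bin metabolites are always exact ties (a 2×2 correlation matrix is
symmetric), and ties or low top scores (< 0.3, configurable) fall back
to the bin with the highest SNR, then to the lexicographically
smallest bin id — replacing the manual inspection step with a
deterministic rule. CRS is computed on raw bin integrals, before
normalization (row scaling rescales rows, not columns, so it would
change the correlations; the pre-normalization convention is explicit
and configurable by reordering the calls).

Ethanol, isopropyl alcohol and mannitol — skin-antiseptic and osmotic-
therapy residues, not CSF metabolites — are dropped from the
metabolite table before statistics, leaving 53 of 56.

## Univariate statistics

Each sample row is normalized to its total area, then each metabolite
column is Pareto-scaled: centred and divided by √SD (sample SD, n−1).
Pareto scaling tempers high-abundance dominance without the noise
inflation of full autoscaling; zero-variance columns map to zero with
a warning.

Both test families always run — normality (Shapiro-Wilk) is reported,
not used as a switch, because practice reports both: Kruskal-Wallis
(tie-corrected, χ² reference) plus pairwise two-sided Wilcoxon
rank-sum (exact when both groups ≤ 10 and tie-free, otherwise normal
approximation with tie and continuity correction), and one-way ANOVA
with Tukey HSD. Benjamini-Hochberg step-up FDR is applied across
metabolites within each test family and comparison. Direction arrows
(up = elevated in the pair's second group) are assigned only when the
pair's adjusted p clears α. Tukey runs on the same
normalized+Pareto-scaled matrix as the non-parametric tests; callers
who want raw-scale post hocs can pass the unscaled table.

## Multivariate models

PCA is a column-centred SVD; explained variance fractions are
σ_a²/Σσ². Outliers are samples whose PC1/PC2 scores exceed the
Hotelling T² ellipse: T²_i = z_iᵀS⁻¹z_i > 2(n−1)/(n−2)·F₂,ₙ₋₂(1−α),
α = 0.05. Exclusion is applied once and the model refit once — no
iteration — mirroring the single exclusion pass such studies report.

PLS-DA is PLS1-NIPALS on centred X against centred ±1 class coding
(all models here are two-class):

    w_a = Xᵀy/‖Xᵀy‖   t_a = X w_a   p_a = Xᵀt_a/t_aᵀt_a
    q_a = yᵀt_a/t_aᵀt_a   X ← X − t_a p_aᵀ   (y not deflated)

Prediction ŷ = Σ q_a t_a, class = sign(ŷ) (an exact zero falls to the
negative class). The NIPALS scores are mutually orthogonal, and at
full rank the predictions coincide with ordinary least squares — both
are tested, as is agreement with an independent PLS implementation.

VIP_j = √(p Σ_a SS_a w_ja² / Σ_a SS_a) with SS_a = q_a² t_aᵀt_a, so
Σ_j VIP_j² = p identically; VIP > 1.0 marks a variable as above-average.

Cross-validation is stratified 5-fold with seeded shuffling, repeated
(default 10) because reported single accuracies never disclose fold
seeds: Q²(a) = 1 − PRESS/TSS over pooled out-of-fold predictions,
averaged over repeats; R²(a) = 1 − RSS/TSS from the full-data fit; the
component count is the smallest a maximizing Q² (parsimony on ties).
Out-of-fold sign predictions at the chosen a give one confusion matrix
per repeat; sensitivity, specificity and balanced accuracy =
(sens+spec)/2 are averaged over repeats. The positive class defaults
to the alphabetically first label and is configurable, since which
disease counts as "positive" is a reporting convention.

## Pathway analysis

Hits are the metabolites with VIP > 1.0. Per pathway, the upper-tail
hypergeometric p = P(X ≥ k) with background N (all annotated
non-exogenous metabolites — the detectable-universe convention, not
the full compound universe), pathway size K, hits n, overlap k;
BH-FDR across pathways. Impact is relative betweenness centrality —
Σ centrality of hit nodes / Σ over all nodes, falling back to the hit
fraction when all centralities vanish (e.g. 2-node graphs) — the
standard topology measure reported as "impact" by the usual web tools,
stated here explicitly so it is testable. Both values are reported
side by side rather than combined. Candidate pathways require
FDR < 0.05 and impact > 0.1.

The packaged library format is JSON (id, name, nodes, edges); the
synthetic generator emits random connected graphs, and a real KEGG
export in the same format plugs in directly.

## Pipeline, determinism and problem sizes

One seed drives generation, CV fold shuffling and the pathway library;
a rerun with the same configuration reproduces every output file byte
for byte (checksums in the run report). Per-comparison PLS-DA models
re-normalize and re-scale on the two-group subset, so each model sees
the preprocessing a two-class upload would see.

Test problem sizes: unit tests use reduced ppm axes (2¹¹–2¹³ points) —
bin integrals are linear in peak area at any resolution, so
statistical behaviour is unchanged; only line-shape accuracy tests
need dense axes (2¹⁵–2¹⁶). Calibration and recovery suites use 20
seeded replicates at the full 56-sample design. The acceptance script
runs the complete default cohort at 2¹⁵ axis points.

## Known limitations

* Singlet-only spectra: no multiplets, no peak overlap, so CRS
  tie-breaking by "overlap inspection" reduces to the SNR rule.
* The 0.3 low-CRS threshold and the 2-SD SNR window are conventions;
  the field reports no canonical values.
* Total-area normalization is compositional; strong one-sided effect
  sets induce opposite-direction artefacts in null metabolites (see
  above). Probabilistic-quotient normalization is not implemented.
* The tabular loader (`csfnmr stats` / `csfnmr mva`) reads any
  samples × metabolites CSV with a metadata table, so externally
  quantified matrices (e.g. public-repository exports) can enter the
  chain mid-way; it has not been validated against any specific
  deposit's dialect.
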