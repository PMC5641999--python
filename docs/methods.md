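# Methods

This note records the models, defaults and numerical choices behind
`nmrmetab`, and what the synthetic-cohort tests do and do not establish
about real serum data.

## Spectral processing

The processing chain runs in a fixed order — apodize, zero-fill,
Fourier-transform, phase, baseline-correct, reference, bin, exclude,
align, normalize — enforced by `process_fid` / `preprocess_spectra`.

* **Apodization**: exponential window `exp(-pi * lb * t)` with
  `lb = 1 Hz`; zero filling to 65,536 points ("64k" read as 2¹⁶, the
  standard NMR usage; configurable).
* **Phasing**: acquisition software phasing is interactive; here a
  deterministic surrogate applies the zero-order rotation maximizing the
  integral of the positive real part (1° coarse scan, 0.01° refinement).
  First-order phase is omitted — the synthetic FIDs need none, and
  ingested spectra are expected to arrive phased.
* **Baseline**: asymmetric least squares (Whittaker smoother, roughness
  `lam = 1e7`, asymmetry `p = 1e-3`, 10 reweighting iterations). `lam`
  targets axes sampled at ~1e-3 ppm; the smoother is positively
  homogeneous, so baseline correction preserves the pipeline's overall
  scale invariance.
* **Referencing**: the tallest local maximum within ±0.1 ppm of
  5.236 ppm (the anomeric α-glucose resonance) anchors a rigid axis
  shift; ties break toward higher ppm ("left" peak in NMR convention).
  Shifts below 1e-9 ppm are treated as zero, which also makes
  referencing exactly idempotent. A flat window raises
  `ReferencingError`.
* **Binning**: trapezoidal integrals over half-open `[upper, lower)`
  0.004-ppm intervals anchored at 9.0 ppm and built on a single shared
  edge grid (adjacent bins touch exactly); 0.5–9.0 ppm gives 2125 bins.
  Bin sums telescope, so the total equals the full-range integral to
  machine precision. The printed "2 Hz" equivalent of 0.004 ppm assumes
  ~500 MHz arithmetic; ppm is treated as authoritative at the 599.35 MHz
  default.
* **Water exclusion**: any bin intersecting 4.23–5.18 ppm is dropped
  (238 bins on the default grid).
* **Alignment**: within each drift-prone segment (1.43–1.50, 6.98–7.10,
  7.70–7.84 ppm) every sample is shifted by the integer bin count
  (|shift| ≤ half the segment width) maximizing Pearson correlation with
  the cohort-median segment; vacated bins are edge-padded and shifts are
  logged. Shift decisions are made on per-sample-normalized copies so
  alignment — and hence the whole pipeline — is invariant to each
  sample's overall scale. Candidate shifts are tried in order of
  increasing magnitude, so a zero shift wins all ties.
* **Normalization**: each row is divided by its own total over the
  surviving bins (normalization follows exclusion and alignment, per the
  stated step order); non-positive totals are an error.

## Chemometrics

* **Scaling**: column centering, with unit-variance scaling (sample sd,
  ddof = 1) for the supervised models; zero-variance columns are dropped
  with a warning because autoscaling is undefined for them. Scaling
  parameters are stored so held-out samples are transformed with
  training parameters only.
* **PCA / outlier gating**: SVD-based PCA; Hotelling's
  T² = Σ t_a²/λ_a over A = 2 components against the exact F-based limit
  `A(n-1)(n+1)/(n(n-A)) · F_{1-α}(A, n-A)` at α = 0.05. The pipeline
  gates once on the pooled cohort, before any contrast is fitted, using
  unit-variance scaling.
* **PLS-DA**: single-response NIPALS with X and y deflation; the
  regression vector is `W(PᵀW)⁻¹c`. Predictions carry no intercept
  (classes are encoded ±1; the training-mean row predicts 0), so the
  decision threshold is 0.
* **O-PLS-DA**: single-y orthogonal signal correction with exactly one
  predictive and one orthogonal component. Because the orthogonal score
  is y-orthogonal by construction, the predictive weight is unchanged by
  the deflation; the predictive score and loading are recomputed on the
  filtered matrix. The stored filter (deflation by `w_orth`/`p_orth`) is
  exactly idempotent; note that *re-running the extraction* on filtered
  data would find further orthogonal variation — one component does not
  exhaust the orthogonal subspace, it removes the dominant one. A useful
  identity: with a single response, PLS with 2 components and
  O-PLS(1 + 1) produce identical predictions, so their cross-validated
  Q² coincide; the validation grid reports both columns anyway for
  table compatibility.
* **Class encoding**: +1 for the positive (e.g. patient) class, −1 for
  the reference (controls). "Up" in the significant-bin table means
  higher in the positive class.
* **Back-scaled loadings**: `p_pred * column sd` restores spectral
  lineshape; the colour-coding correlation r is computed between the
  predictive score and the *unscaled* bin columns (correlation is
  scale-invariant; stated for determinism). Significance uses the
  two-tailed critical Pearson correlation
  `r_crit = t_q / sqrt(t_q² + n - 2)` at α = 0.05, with n exposed
  explicitly (0.32 at n = 38, 0.48 at n = 17).

## Validation

* **Cross-validation**: sevenfold, stratified by class (unstratified
  sevenfold can produce single-class folds at realistic group sizes),
  seeded. Scaling and the model are refitted inside each training fold;
  Q² = 1 − PRESS/SS_y with SS_y about the overall mean (SIMCA
  convention).
* **Permutation test**: 200 label permutations drawn uniformly over
  orderings (identity not excluded), full CV-Q² recomputed per
  permutation; pass ⇔ real Q² exceeds the permutation maximum. Under the
  null this passes with probability 1/(n_perm + 1) by exchangeability.
* **CV-ANOVA**: `F = ((SS_y − PRESS)/df1) / (PRESS/df2)` with
  df1 = fitted components (2: predictive + orthogonal),
  df2 = n − df1 − 1; p from the F distribution, and p = 1 whenever
  PRESS ≥ SS_y. Under a global null the statistic is conservative by
  construction — cross-validated predictions cannot beat the overall
  mean in expectation, so E[PRESS] ≥ SS_y and the realized type-I error
  sits below the nominal α (measured ≈ 2–3% at α = 5% for n = 60,
  p = 200). The conjunction verdict (permutation AND CV-ANOVA) is
  therefore conservative as well.
* **ROC/AUC**: Mann–Whitney identity on *cross-validated* scores, ties
  counted half.
* **Verdict**: valid ⇔ permutation pass AND CV-ANOVA p < 0.05; neither
  test alone suffices.

## Synthetic serum cohorts

The generator emulates non-fasting serum CPMG spectra well enough to
give every stage a testable contract:

* **Templates**: ~20 metabolites as Lorentzian line lists with
  literature chemical shifts (lactate doublet 1.33 ppm, alanine
  1.48 ppm, glycine 3.56 ppm, aromatic His/Phe/Tyr, formate 8.45 ppm,
  GPC/choline ~3.2 ppm, …); only the anomeric α-glucose line is pinned
  exactly at 5.236 ppm because referencing anchors on it. Default sharp
  linewidth 2 Hz (serum small molecules after 1-Hz broadening); two
  broad envelopes (25–35 Hz) stand in for VLDL/LDL and HDL lipoprotein
  humps at 0.85/1.27 ppm.
* **Per-sample randomness**: log-normal concentration scatter per
  metabolite (`concentration_cv = 0.12`), optional shared latent factors
  (default: phenylalanine and tyrosine load 0.7 on a common factor, so
  their concentrations correlate ≈ 0.5 as metabolically coupled amino
  acids do); chemical-shift drift `shift_jitter_sd = 0.005 ppm` for the
  pH-sensitive drift metabolites (alanine, histidine — exactly the
  resonances inside the re-aligned segments) and a small
  post-referencing `residual_jitter_sd = 0.0008 ppm` elsewhere; additive
  Gaussian noise `noise_sd = 0.01` (peak SNR ~10², pessimistic for
  128-scan CPMG data); a smooth deterministic baseline distortion shared
  by all samples. Group effects are multiplicative fold changes on
  template intensities. All draws come from one seeded generator in a
  fixed order; a design (including its seed) reproduces its cohort
  bit-identically.
* **What it does not model**: J-coupling multiplet structure beyond
  simple line lists, T₂-editing physics of the CPMG sequence,
  field-dependent lineshape distortions, per-sample baseline variation,
  and vendor raw formats. Consequently, passing recovery tests show the
  *pipeline machinery* is sound at realistic effect and noise scales —
  they do not certify performance on real spectra, where peak overlap
  and baseline behaviour are harsher.
* **Ground truth tooling**: `effect_bins` maps injected metabolites to
  their line-center bins; `true_group_difference` computes the analytic
  noise-free normalized group difference per bin, including the small
  coupling that total-sum normalization induces on unchanged bins
  (largest on the big lipoprotein bins, about an order of magnitude
  below the injected effects at the default design). False-flag rates
  are evaluated against bins whose standardized true effect is < 0.2 —
  far below detectability at n = 50 — because Lorentzian tails and
  factor-correlated metabolites carry genuine signal outside the
  line-center bins.

## Reference problem sizes

The test suite and acceptance script use: oracle checks on 30 × 50
matrices; null calibration at n = 60, p = 200 with 500 Monte-Carlo
replicates (CV-ANOVA) and 400 replicates of a 19-permutation test;
parameter recovery on a 25 + 25 cohort (fold 1.5 on lactate, glycine,
phenylalanine) with 200 permutations, plus five cohort seeds for the
false-flag expectation; Hotelling calibration at n = 2000. These sizes
give Monte-Carlo confidence intervals tight enough for the calibration
claims while keeping the whole suite around a minute.

## Known limitations

* Only two-class contrasts (no multi-class O-PLS or O2-PLS).
* One orthogonal component, fixed; no automatic component selection.
* Zero-order phasing only; curved baselines beyond the AsLS model are
  not corrected.
* Alignment is integer-bin segment shifting; no sub-bin warping
  (icoshift-style interpolation) — adequate for the 0.004-ppm grid.
* The CLI ingests delimited spectra matrices, not vendor raw
  directories.
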