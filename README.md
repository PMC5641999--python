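# nmrmetab

Serum ¹H-NMR metabonomics in Python: spectral processing, O-PLS-DA
chemometrics with back-scaled correlation loadings, model validation and
STOCSY — together with a synthetic serum-cohort generator so the whole
chain can be exercised and tested with known ground truth.

## Who this is for

Metabonomics studies of blood serum record one ¹H NMR (CPMG) spectrum
per sample and ask whether patient groups — disease vs. control,
responder vs. non-responder, successive treatment visits — differ in
their metabolic profiles, and which metabolites carry the difference.
`nmrmetab` implements that workflow end to end for anyone who wants it
scripted, seeded and reproducible rather than driven through vendor GUI
software:

1. **Processing** (`nmrmetab.nmrproc`): exponential apodization (1 Hz),
   zero filling, Fourier transform, zero-order phasing, asymmetric
   least-squares baseline correction, referencing to the anomeric
   α-glucose peak at 5.236 ppm, binning of 0.5–9.0 ppm into 0.004-ppm
   buckets (2125 bins), removal of the residual-water window
   (4.23–5.18 ppm), integer-bin alignment of the drift-prone segments
   1.43–1.50, 6.98–7.10 and 7.70–7.84 ppm, and total-sum normalization.
2. **Chemometrics** (`nmrmetab.chemometrics`): PCA with Hotelling-T²
   outlier gating, NIPALS PLS-DA, single-response O-PLS-DA (one
   predictive + one orthogonal component), and back-scaled loadings with
   correlation colour-coding and significance cutoffs.
3. **Validation** (`nmrmetab.validation`): sevenfold cross-validated
   Q²/R², a 200-permutation overfit test, CV-ANOVA on the
   cross-validated residuals, ROC/AUC on cross-validated scores, and the
   conjunction verdict (a model is valid only if the permutation test
   *and* CV-ANOVA pass together).
4. **STOCSY** (`nmrmetab.stocsy`): statistical total correlation
   spectroscopy traces and targeted region correlations (e.g.
   phenylalanine vs. tyrosine).
5. **Synthetic cohorts** (`nmrmetab.simcohort`): Lorentzian metabolite
   templates, broad lipoprotein envelopes, chemical-shift drift,
   biological concentration scatter with shared latent factors,
   group-wise fold changes, baseline distortion and noise.
6. **Pipeline + CLI** (`nmrmetab.pipeline`, `nmrmetab` command):
   config-driven end-to-end runs with logged provenance.

## The statistics in brief

Binned spectra form an *n × p* matrix **X** (total-sum normalized rows,
unit-variance scaled columns); two-group membership is encoded
*y* ∈ {+1, −1}. O-PLS-DA computes a predictive weight **w** ∝ **X**ᵀ*y*,
splits off one *y*-orthogonal component (**w**ₒ ∝ **p** − (**w**ᵀ**p**)**w**,
with scores t_o = **Xw**ₒ uncorrelated with *y*), deflates it, and
regresses *y* on the filtered predictive score: ŷ = *b*·t. Per-bin
back-scaled loadings p_j·s_j restore the spectral lineshape; each bin's
Pearson correlation r_j = corr(t, x_j) is thresholded at the two-tailed
critical value r_crit = t_q/√(t_q² + n − 2) (0.32 at n = 38 … 0.48 at
n = 17 for P < 0.05). Model validity combines Q² = 1 − PRESS/SS_y from
sevenfold CV, a 200-permutation null for Q², and CV-ANOVA
F = ((SS_y − PRESS)/2)/(PRESS/(n − 3)).

## Worked example

Simulate a 25 + 25 cohort with a 1.5-fold increase of lactate, glycine
and phenylalanine in the cases, preprocess, validate the contrast and
list the significant metabolites:

```python
import nmrmetab as nm

design = nm.CohortDesign(
    groups=(("case", 25), ("ctrl", 25)),
    effects={"lactate": {"case": 1.5}, "glycine": {"case": 1.5},
             "phenylalanine": {"case": 1.5}},
    seed=1,
)
cohort = nm.simulate_cohort(design)
matrix = nm.preprocess_spectra(list(cohort.spectra), list(cohort.sample_ids))
print(f"feature matrix: {matrix.n_samples} samples x {matrix.n_bins} bins")

y, enc = nm.encode_labels(cohort.group_labels, "case", "ctrl")
report = nm.validate_contrast(matrix.values, y, k=7, n_perm=200, seed=1)
print(f"Q2={report.q2:.3f}  R2={report.r2:.3f}  AUC={report.auc:.3f}  "
      f"perm_pass={report.perm_pass}  CV-ANOVA p={report.cv_anova_p:.2g}  "
      f"valid={report.verdict}")

model = nm.fit_opls_da(nm.scale_matrix(matrix), y, enc)
profile = nm.backscaled_loadings(model, matrix)
print(f"significant bins: {int(profile.significant.sum())} "
      f"(|r| >= {profile.r_crit:.3f})")
```

prints

```
feature matrix: 50 samples x 1887 bins
Q2=0.321  R2=0.972  AUC=0.915  perm_pass=True  CV-ANOVA p=0.00011  valid=True
significant bins: 126 (|r| >= 0.279)
```

So the contrast is declared valid (real Q² above all 200 permuted Q²
values *and* CV-ANOVA P < 0.05), cross-validated scores separate the
groups with AUC 0.92, and 126 of 1887 bins exceed the n = 50
correlation cutoff of 0.279 — they cluster on the lactate doublet
(1.33 ppm), glycine singlet (3.56 ppm) and phenylalanine aromatic
multiplets (7.3–7.45 ppm), all flagged "up" in cases, as injected.

The same run from the shell:

```bash
nmrmetab run-all --config examples/recovery.yaml --out-dir out/ --seed 1
```

writes `validation_grid.tsv` (one row per contrast: Q² PLS-DA,
Q² O-PLS-DA, permutation pass, CV-ANOVA p, AUC, verdict), per-contrast
loading profiles, significant-bin tables, serialized models and a
provenance log.

## Layout

```
src/nmrmetab/      nmrproc, simcohort, chemometrics, validation,
                   stocsy, pipeline, io, plotting, cli
tests/             unit + property tests and acceptance checks
docs/methods.md    model assumptions, parameter choices, limitations
scripts/           acceptance.py
examples/          recovery.yaml (CLI demo config)
```
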