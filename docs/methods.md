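# Methods

## Scope and model

`plaquefp` analyses depth-resolved fiber-photometry recordings of a
beta-sheet-binding fluorescent tracer (Methoxy-X04-type) against histological
plaque quantification, for two acquisition geometries:

1. **Flat fiber, acute depth series.** The fiber is lowered in 100-µm steps
   from the brain surface to 4000 µm (41 depths). At each depth the light
   source pulses 10 ms on / 5 ms off for 10 repetitions; detector and sync
   channels are sampled at 5000 Hz. Per-depth fluorescence is the mean of the
   on-window samples (edge-guarded) averaged over repetitions.
2. **Tapered fiber (TF), chronic galvo scans.** A galvo mirror sets the
   light-injection angle and therefore the axial position probed along the
   taper's ~1.6-mm active span. A scan steps the galvo from −1 to 4.5 V
   across consecutive 10-ms pulses; the 41 analysis levels span 0–4.5 V
   (spacing 0.1125 V, ~39.5 µm axially). Scans repeat 3–5 times per timepoint
   every 60 or 300 s.

The analysis model for a TF session is, per galvo level ℓ,

    F(ℓ, t) = a_ℓ·t + b_ℓ + g·d_ℓ·(1 − exp(−(t − t_inj)/τ)),  t ≥ t_inj,

a linear autofluorescence drift plus a saturating tracer term proportional to
the local plaque density d_ℓ. The drift coefficients are estimated per level
on a tracer-free day-0 session by two-fold cross-validated least squares
(folds = interleaved odd/even timepoints; coefficients averaged, held-out MSE
reported) and extrapolated to day 1 on the session clock, assuming identical
session structure across days. The tracer estimate is Fm = F − AF.

Assumptions: the drift is linear over a session; tracer kinetics are a single
saturating exponential; plaque pathology is hemispherically homogeneous (so
the track mirrored about the midline samples equivalent tissue); penetrations
are near-vertical (the 3-D track is parameterized by DV depth, with AP and ML
regressed on DV).

## Key parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| particle diameter band | [11, 20] | µm | plaque size filter for detection |
| detection threshold | 99th percentile of top-hat residual | — | scale-invariant; no absolute threshold is canonical |
| diameter-band tolerance | 1 pixel | µm | absorbs rasterization error at the band edges |
| counting ball radius | 250 | µm | light-sampling volume around the track |
| flat depth step / range | 100 / 0–4000 | µm | 41 stations |
| TF levels / spacing | 41 over 0–4.5 V | 0.1125 V ≈ 39.5 µm | galvo measure resolution |
| TF track shift | 600 (toward surface) | µm | corrects tip-depth overestimation; applied after mirroring |
| z-score baseline (flat) | 0–400 inclusive | µm | 5 superficial depths |
| median filter window | 4 (profiles), 3 (time courses) | samples | see window convention below |
| time bin | 300 | s | 5-min bins |
| extrema window | 30–240 | min | post-injection dynamics |
| profile window | 210–240 | min | near-plateau tracer signal |
| z-score baseline (TF) | first 25 | min | pre-injection bins |
| pulse edge guard | 1 | sample | detector slew; configurable |
| SVM | linear kernel, C = 1 | — | smallest-assumption default for n = 24, d = 3 |
| PCA components | 3 | — | fixed dimensionality of the classifier input |

## Synthetic-data generator

The generator produces every pipeline input with known ground truth:

- **Plaque fields**: inhomogeneous Poisson point process over depth (sampled
  by thinning), diameters i.i.d. uniform on [11, 20] µm so the detection
  filter is not the object under test; out-of-band distractors are opt-in.
  The default affected density is 50 + 400·exp(−((DV − 2800)/500)²)
  plaques/mm³ — a deep (subicular) density peak over a low cortical
  baseline; controls have zero density. No quantitative regional density
  measurements exist to calibrate these numbers; they are stated free
  parameters chosen to give tens of plaques per counting ball at the peak.
- **Section images**: in-slab plaques rendered as filled disks (amplitude 1)
  plus additive Gaussian noise; pixel centres at (i + 0.5)·pixel_µm.
- **Taper fields**: illumination frames are axial Gaussian bands whose
  centres move affinely with galvo voltage (0 V → shallow end of the active
  span; negative voltages off-tissue); frame energy follows a flat-top
  (Tukey) envelope — comparable light delivery at interior angles, cosine
  roll-off to zero over the terminal 15% of the drive range at each end.
  The collection field decays exponentially with radial distance from the
  fiber axis (default length constant 150–400 µm in tests), optionally zero
  inside a fiber footprint.
- **Recordings**: pulse trains with sync and galvo channels at 5000 Hz.
  TF scans step the galvo per pulse (≈9 sub-zero steps, then the 41 levels);
  the per-level model fluorescence is evaluated at the scan start time and
  held constant within the scan, so a noiseless simulate→demodulate round
  trip is exact. Idle time between scan blocks is not materialized (sample
  times are explicit). Default detector noise: sd 0.01 a.u. per sample
  against an autofluorescence intercept of ~1 a.u. and a tracer plateau of
  ~1 a.u. at the density peak (gain 0.0025 a.u. per plaque/mm³); after
  averaging ~240 samples per (level, timepoint), per-value noise is ~7e−4.
  Tracer rise time τ = 30 min reaches ~95% of plateau by 90 min
  post-injection.

What the generator does **not** emulate: optical mode propagation or ray
tracing (fields are phenomenological), tissue absorption and vasculature,
motion or hemodynamic artifacts, photobleaching, registration error between
camera and microscope frames (stacks are consumed pre-aligned; a similarity
transform must be supplied upstream if needed), and non-plaque fluorescent
structures. Passing tests therefore demonstrate correctness of the analysis
given the stated signal model, not robustness to these real-data effects.

## Numerical conventions

- **Even median window.** A window of 4 at index i covers [i−1, i+2],
  truncated at the edges; output length equals input length. An even window
  has no canonical alignment, so the choice is documented and fixed.
- **Z-scores** use the sample standard deviation (ddof = 1). A zero-variance
  baseline raises an explicit degenerate-baseline error rather than emitting
  infinities.
- **Spearman's ρ** uses average ranks for ties; the two-sided p-value is an
  exact permutation enumeration for n ≤ 8 (configurable) and the
  t-approximation above. The exhaustive enumeration bound was set where full
  enumeration stays proportionate (8! = 40320); all analysis-scale uses have
  n = 41.
- **Wilcoxon signed-rank** uses the exact null for n ≤ 25 without zero
  differences; all-zero differences return p = 1 with a warning. The exact
  two-sided p is discrete, hence sub-uniform under the null: calibration
  means P(p ≤ α) ≤ α, not uniformity.
- **PCA** is column-centered SVD with a deterministic sign convention (the
  largest-magnitude loading of each component is positive), so classification
  results cannot depend on solver sign indeterminacy.
- **Ties** in extrema-depth selection break toward the lower level index.
- **Missing galvo level bins** are carried as NaN and excluded from medians
  and means, never interpolated.
- **Counting ball vs cylinder.** Depth-station counting uses 3-D Euclidean
  balls of radius 250 µm ("within 250 µm of each depth measure"), consistent
  with the per-spherical-volume density normalization; the union of balls
  along the track approximates a cylinder. The ex vivo moving ROI is a 2-D
  circle in the slice plane, matching that slice-based context.
- **Terminal-angle baseline** for centroid extraction is the mean of the
  first and last voltage frames (both terminals, symmetric).

## Open design choices

- **Global PCA before leave-one-out.** The published procedure fits PCA once
  on all samples and then runs leave-one-out on the scores; the held-out
  sample therefore contributes to the projection (a mild leakage). This is
  the default for fidelity; `pca_per_fold=True` refits the PCA inside each
  training fold.
- **Galvo sweep direction.** Whether 0 V probes the shallow or deep end of
  the taper is hardware-dependent; the affine galvo→depth map defaults to
  0 V → shallow and is orientation-configurable.
- **Track shift order.** The 600-µm correction is applied after mirroring
  (a pure translation, so the order only matters if the mirror plane is
  re-estimated between the two).
- **Per-depth reduction** over pulse repetitions is the mean by default; the
  median is selectable.
- **Multi-power blocks** are demultiplexed positionally (equal consecutive
  blocks per timepoint, ordered as in the protocol); analysis defaults to
  the last (highest/analysis) power.

## Problem sizes

The test suite and the acceptance script run the study at the cohort sizes
the analyses are designed around: 13 + 11 flat-fiber recordings for the
classification cohort, 20 + 20 for parameter recovery, 12 + 7 TF recordings
(each with a day-0 and a day-1 session). TF sessions are simulated at
250 min with 300-s scan intervals — long enough to cover the 30–240-min
extrema window and the 210–240-min profile window — and stochastic property
checks use 20–1000 seeds depending on the cost of one replicate (e.g.
5 effect-size steps × 25 seeds for the classification-degradation trend).

## Known limitations

- The detection stage's background-subtraction radius and threshold quantile
  are explicit defaults, not derived from any reference implementation;
  real images may need tuning (both are logged in results).
- The autofluorescence model is linear in time; slow nonlinear drifts would
  leak into Fm.
- Correlations between photometry and histology inherit the rigid
  galvo→depth and track models; axial registration error beyond the 600-µm
  correction is not modelled.
- Selecting the extrema levels by argmax/argmin of the windowed medians
  biases the max − min contrast positive even in density-free controls;
  with the generator's low noise the control Wilcoxon p is therefore a
  small discrete value rather than a calibrated null draw. It is reported
  descriptively and should not be read as a calibrated test of the null.
- The classifier is deliberately minimal (3 PCs, linear SVM); no
  hyperparameter search is performed, and accuracy on the synthetic default
  effect size is near ceiling.
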