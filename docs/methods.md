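# Methods

`slnet` implements a complete analysis chain for diagnostic classification
from resting-state EEG functional networks: band filtering, synchronization
likelihood (SL) connectivity, weighted graph characteristics, univariate
group statistics, and a bootstrap-validated random-forest classifier, plus a
synthetic cohort generator that makes the chain testable end to end without
clinical recordings.

## Synthetic cohorts

Each channel is modelled as a damped AR(2) oscillator driven by Gaussian
innovations, with its spectral pole at 10 Hz (an alpha-like rhythm for an
awake, eyes-closed recording) and pole radius 0.97, giving a resonance a few
hertz wide at 512 Hz sampling. Channels are mixed with *shared latent
drivers*: every channel receives a global driver with weight
`base_coupling` (default 0.3 — moderate baseline synchrony, typical of the
mid-range SL values seen in scalp recordings); in the "case" group a focal
driver is additionally mixed, with weight `effect_size`, into a fixed block
of six temporo-central channels (T8, C4, Cz, C3, T7, P8). The
own-signal weight is `sqrt(1 - a² - b²)` so channel variance stays at unity,
and independent white noise with SD `noise_sd` (default 0.5, i.e. a ~4:1
signal-to-noise variance ratio) is added per channel. Defaults reproduce the
recording protocol the package targets: two groups of 35 subjects, 17
channels (the 10-20 montage minus Fp1/Fp2/A1/A2), four 8-s artifact-free
epochs at 512 Hz.

The master seed expands through `numpy.random.SeedSequence` keyed on
(seed, group, subject index), so any one subject's record is bitwise
reproducible regardless of cohort size.

What the generator deliberately does *not* emulate: volume conduction and
reference effects (which inflate zero-lag dependence between neighbouring
electrodes), 1/f background spectra, artifacts, non-stationarity across
epochs, and any disease-specific connectivity topology. Shared-driver mixing
was chosen over phase-coupled oscillator models because it produces
generalized synchronization detectable by SL with a single scalar knob.
Passing tests therefore demonstrate that the *pipeline* recovers planted
coupling differences and stays calibrated under the null — not that any
particular clinical population is separable.

## Band filtering and PSD

Filtering is a 4th-order Butterworth band-pass applied forward-backward
(`sosfiltfilt`), i.e. zero-phase, so band-limiting does not distort the
phase relations SL measures. Canonical bands: broadband 0.5–45 Hz, delta
0.5–4, theta 4–8, alpha 8–12, beta 12–30, gamma 30–45 Hz. PSDs are Welch
estimates with 2-s Hann windows at 50% overlap — 0.5 Hz resolution, matching
the lowest band edge; these are analysis choices, configurable per call.
Relative power is normalized per subject over the in-band grid before
averaging, so group-level relative spectra are convex combinations of
unit-sum spectra.

## Synchronization likelihood

Each channel is delay-embedded (`m` components, lag `lag`). For every
reference time `i` a critical distance `ε_i` is calibrated per channel so
that the fraction of eligible comparison times `j` — those with
`w1 < |i−j| ≤ w2`, where the Theiler window `w1` suppresses autocorrelation
— falling within `ε_i` is the nearest achievable to `p_ref`. SL(x→y) is the
conditional probability that y is recurrent at a time pair given x is,
aggregated over all eligible pairs; the reported value is the mean of the
two directions, giving a symmetric matrix in [0, 1] with SL ≈ `p_ref` for
independent channels and 1 for identical ones. Per-subject networks are the
element-wise mean of per-epoch SL matrices.

Numerical conventions: Euclidean distances in embedding space; `ε_i` is the
k-th smallest eligible distance with `k = round(p_ref · n_eligible)`; ties
at `ε_i` are included as recurrent; recurrence indicators are accumulated in
float32 (counts are exact integers well below 2²⁴) and all distances kept in
float64. A zero-variance channel saturates the recurrence definition; its SL
against every other channel is defined as 0 and a warning is logged.

Default parameters follow the frequency-adaptive prescription
`lag = round(fs/(3 f_hi))`, `m = round(3 f_hi/f_lo) + 1` capped at 16,
`w1 = 2·lag·(m−1)`, `w2 = w1 + floor(10/p_ref)`, `p_ref = 0.05` — the
convention of the measure's software lineage; nothing in the pipeline
depends on these specific values and all are overridable.

## Network characteristics

The subject SL matrix defines a weighted complete graph. Edge *length* for
path-based metrics is `1/w` (high synchronization = short functional
distance); `−log w` and `1−w` are common alternatives but `1/w` is the
convention adopted here. Per node: strength `s_i = Σ_j w_ij`; average
shortest path `L_i` (exact Dijkstra on 1/w lengths); closeness
`cc_i = (N−1)/Σ_j d_ij = 1/L_i`; betweenness as unnormalized ordered-pair
transit counts with endpoints excluded, where shortest-path multiplicity is
counted with an absolute tie tolerance of 1e-12 on path lengths (exact
float comparison would split genuinely degenerate paths arbitrarily);
eigenvector centrality as the Perron vector of W, oriented nonnegative and
normalized to unit Euclidean norm; weighted clustering in the geometric-mean
(Onnela) form on max-rescaled weights, with the Saramäki form available via
a flag. The strength distribution's power-law index is the continuous MLE
`α = 1 + n/Σ ln(d_i/d_min)`.

`d_min` defaults to the smallest strength: with only ~17 node strengths per
network a Kolmogorov–Smirnov cutoff scan (available via `scan_xmin=True`) is
too unstable to be a sensible default, and a 17-point power-law fit is in
any case a fragile feature — it is retained because the feature vector
schema calls for it, not because the tail is well identified. An all-equal
strength sample leaves α undefined and raises a dedicated error, which the
feature assembly propagates (a perfectly uniform graph has no feature
vector).

Each family is summarized over nodes as min/mean/max (mean/max only for
betweenness, whose minimum is almost always 0 on near-complete graphs),
giving 18 features in a fixed, documented order.

## Classifier and internal validation

The classifier is a random forest (500 trees by default, `mtry = 5`
candidate features per split, bootstrap resampling per tree). Scores are
case-vote fractions; trees are grown to purity, so averaged leaf
probabilities coincide with vote fractions.

"Bootstrap-corrected" is implemented as out-of-bag resampling validation:
each of `B` replicates resamples subjects with replacement *stratified by
group* (preserving group sizes), refits the forest, and evaluates ROC/AUC
and Youden-operating-point metrics on the subjects the resample never drew
(on average ~37% of each group). Point estimates are replicate means, 95%
CIs the 2.5th/97.5th percentiles, and the average ROC curve is the vertical
mean of replicate ROCs on a 101-point false-positive-rate grid. Replicates
whose out-of-bag set misses a group are skipped (>20% skipped is an error —
it signals groups too small for this estimator). A Harrell-style
optimism-corrected AUC is available via `method="optimism"`. The operating
point for sensitivity/specificity/PPV/NPV maximizes Youden's J over observed
score thresholds; PPV/NPV are reported as missing (NaN) when their
denominator is empty rather than coerced to 0.

Group statistics are pooled-variance Student t-tests per feature, two-sided,
unadjusted by default (Holm step-down available), and the 18×18 Pearson
feature-correlation matrix with constant features flagged missing.

## Problem sizes used in the shipped checks

The test suite validates SL against a brute-force double-loop oracle on
short epochs (≤ ~250 samples, agreement 1e-12), the graph metrics against
exhaustive path/triangle enumeration on graphs of up to 7 nodes (1e-9), and
AUC against pair counting (1e-12). Cohort-level behaviour is checked at two
scales chosen by this package: a *validation scale* — 6–8 channels, 2–4-s
epochs, 1–2 epochs/subject at 256 Hz, forests of 25–100 trees — used for
the 20-cohort null calibration (B=200) and the three-level planted-effect
recovery (B=100); and one full *protocol scale* run — 70 subjects, 17
channels, four 8-s epochs at 512 Hz, broadband SL, B=100. The null and
planted-effect checks are properties of the estimator (chance-level
corrected AUC without effect; monotone recovery with effect), not claims
about clinical accuracy.

## Known limitations

- SL parameter defaults are conventions, not fitted values; sub-band SL on
  short epochs can leave few embedded vectors for low-frequency bands.
- The 17-node power-law index is statistically fragile (see above).
- Percentile bootstrap CIs on small cohorts are themselves noisy; DeLong-type
  analytic AUC CIs are not implemented.
- The ASCII epoch dialect is the only on-disk recording format; EDF
  interoperability is out of scope for this version.
- `mtry` is fixed by configuration, never tuned inside the validation loop;
  tuning it on the same data that is validated would leak optimism.
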