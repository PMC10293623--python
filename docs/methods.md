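# Methods

This note documents the models, estimators and numerical conventions behind
`mubeta`, the choices that were genuinely open, and what the synthetic-data
validation does and does not establish.

## Generative model of the recordings

A participant's recording is the sum of three independent parts, all in
microvolts and all pure functions of integer seeds:

* **Background noise.** Per-channel Gaussian noise with a `1/f` power
  spectrum (exponent 1, flattened below 1 Hz, no DC), scaled to 5 uV RMS.
* **Rhythms.** Per band (mu/alpha 8-13 Hz, beta 16-24 Hz) and channel,
  band-limited Gaussian noise (white noise through the same zero-phase FIR
  used in analysis, normalised to unit RMS) multiplied by a baseline
  amplitude and a gain envelope. Baseline RMS amplitudes default to 8 uV
  (alpha) / 4 uV (beta) over the ten central channels, 7 / 1.5 uV over
  parieto-occipital channels and 2.5 / 1.5 uV elsewhere — values that give
  realistic epoch peak-to-peak amplitudes well below the 120 uV rejection
  threshold. The envelope is 1 at baseline and `sqrt(g)` on a plateau
  covering exactly the activation window (cue+2 s to cue+6 s); 250 ms
  cosine ramps sit *outside* the plateau so that the expected band-power
  ratio over the window equals `g` with no ramp bias. `g` is looked up per
  (group, task, condition, band, hemisphere); midline channels are never
  modulated. The injected ground truth is therefore `ERDS% = (g-1)*100`.
* **Blinks.** A 300 ms biphasic template at Poisson event times (default
  10/min, 150 uV), projected onto channels with weights decaying
  exponentially with angular distance from Fp1/Fp2 and fixed large weights
  on EOGV/EOGH. This gives the ocular-removal stage a recoverable source.

Trial schedules follow the paradigm exactly: per run, a seeded permutation
of `trials_per_condition` trials of each of LEFT/RIGHT/BOTH; 2 s fixation,
7 s cue, break drawn uniformly from 3-5 s (the jitter distribution is a
choice — only the range is prescribed); 5 s pre-run lead-in; runs alternate
ME and MI. Whether a participant starts with an ME or MI run alternates
across the cohort (configurable), and sex alternates within each
handedness group, mirroring the balanced design.

What the simulator does **not** model: volume-conduction correlations
between channels (rhythms are independent per channel), EMG and line
noise, impedance drift, non-stationary background, or realistic
inter-subject variability of rhythm topographies. Passing recovery tests
therefore shows the estimators are correct and unbiased under the model's
assumptions, not that the pipeline is robust to every artifact of real
recordings.

## Preprocessing conventions

Fixed stage order: spherical-spline interpolation of flat channels ->
average reference (EEG channels only; EOG excluded) -> ocular-component
removal -> 1-40 Hz band-pass -> epoching -> peak-to-peak rejection.

* **Spherical spline** (Perrin-style): kernel
  `g(x) = (1/4pi) * sum_n (2n+1)/(n(n+1))^m P_n(x)` with stiffness `m = 4`,
  series truncated at 50 Legendre terms, ridge `lambda = 1e-5` on the
  diagonal of the augmented system. These are the field-standard values;
  the weights depend only on electrode geometry and reproduce constants
  exactly (rows sum to 1). At least four good electrodes are required.
* **FIR filters**: windowed-sinc (Hamming), transition bandwidth
  `min(max(0.25*edge, 2 Hz), edge)`, odd tap count from the Hamming rule
  `3.3*fs/transition`, applied by centred convolution with edge
  reflection — zero net group delay ("non-causal" in the EEG sense).
* **Ocular removal**: FastICA (20 components, fixed random state, fitted on
  a 1 Hz high-passed copy subsampled to at most 30k time points) with a
  deterministic selection rule: any component whose absolute Pearson
  correlation with an EOG channel reaches 0.7 is subtracted from the
  *unfiltered* data. The decomposition runs on high-passed data because
  slow drifts dominate variance otherwise; the rule replaces manual
  component inspection and is recorded in the preprocessing report. An
  optional kurtosis rule for single-channel-noise components was
  considered and left out: the simulator does not generate that artifact
  class, so the rule would be untestable here.
* **Epochs**: half-open window `[tmin, tmax)` in samples (cue onset =
  sample 0), so an epoch at 500 Hz over -2..7 s has exactly 4500 samples.
  Events too close to a recording edge are dropped with a logged warning.
* **Rejection**: an epoch is rejected when any EEG channel's max-minus-min
  exceeds the threshold (default 120 uV, per-recording configurable; no
  automatic adaptation). EOG channels never enter the criterion.
  Rejection is monotone in the threshold by construction.

## ERD/S estimators — and a deliberate distinction

Two estimators of the relative power change are provided:

* `erds_per_epoch`: band-pass, square, window means, `100*(A-R)/R` per
  epoch, then arithmetic means over trials / conditions / ROI channels /
  participants. This is the estimator used for all tables and the ANOVA.
* `erds_trial_average`: averages `A` and `R` over trials *before* the
  ratio (the classical ERD estimator).

The per-epoch ratio is **biased upward**: with a 1.5 s reference window
and a 5 Hz band, `R` has roughly `2*B*T ~ 15` spectral degrees of freedom,
so `E[A/R] ~ (A/R)*(1+2/dof) ~ 1.14*(A/R)`. Measured on simulated band
noise the bias is +13.6 % (multiplicative), e.g. a true 0 % cell averages
to about +14 %. The bias is condition-independent and multiplicative, so
within-design contrasts (the quantities the ANOVA tests) are preserved;
absolute per-epoch table values carry it, exactly as they do in analyses
that compute the ratio per epoch. Ground-truth recovery is therefore
checked with `erds_trial_average`, whose expectation equals `(g-1)*100`;
residual recovery error (~1-4 pp at 200 trials) comes from in-band
background noise diluting the modulated rhythm and from the analysis
filter's finite rise time at the window edges.

Cells with zero reference power are reported as NaN with a warning rather
than dropped. ERD/S is scale-invariant and bounded below by -100 when
powers are nonnegative.

**Time-frequency maps**: one-sided power spectrograms (Tukey window,
shape 0.25; segment 250 samples, overlap 225 -> 2 Hz frequency resolution,
50 ms hop), averaged over epochs then ROI channels, cropped to 1-35 Hz and
-1.5..7 s, then each frequency row converted to percent change against its
mean over baseline bins (centres in [-1.5, 0) s; a bin belongs to a window
if its centre time is >= start and < end). Averaging before the ratio
avoids the per-epoch division noise discussed above. Rejected epochs are
excluded via the same kept mask as everywhere else.

## Mixed repeated-measures ANOVA

The design is a balanced split-plot: within factors ROI (6) and Condition
(3), between factors Handedness (2) and Sex (2), participants nested in
Handedness x Sex with equal cell sizes (enforced; violations raise an
explicit design error rather than being silently imputed). Sums of squares
use the classical balanced partition, computed by inclusion-exclusion over
marginal means; every within effect is tested against the interaction of
its within part with participants, between effects against participants
within groups. The implementation is validated against base R's
`aov(... + Error(participant/(roi*condition)))` and a brute-force
projection oracle.

* **Greenhouse-Geisser epsilon**: Box sample estimator
  `eps = tr(M)^2 / (d * tr(M^2))`, `M` the covariance of subject-level
  scores (pooled within between-groups) projected on `d` orthonormal
  contrasts; clipped to `[1/d, 1]`. One epsilon per within stratum; for
  the ROI x Condition stratum the contrasts are the Kronecker product of
  the factor contrasts. No Huynh-Feldt fallback is offered. Note the
  correction is guaranteed to *raise* the p-value only for F >= 1; for
  F < 1 it can move either way (irrelevant for significance).
* **Marginal means**: raw means over non-focal factors (exact for the
  balanced design); the reported SE is the standard error of the level
  mean across the participants contributing to it (a descriptive,
  between-subject SE — model-based software may report slightly different
  SEs for within-factor levels).
* **Tukey post-hocs**: `t = diff / sqrt(2*MS_err/n)` with the effect's
  error stratum, `p = P(Q_{k,df} >= |t|*sqrt(2))` from the
  studentized-range distribution (scipy's implementation; numerical
  integration, not table lookup). For k = 2 this reduces exactly to the
  two-sided t-test on the same stratum. The study-specific relevance
  filter (same ROI/different handedness, opposite ROI/same handedness) is
  a reporting-time filter; all pairs enter the correction.

## Validation experiments and problem sizes

The acceptance surface (`mubeta.validation`, exercised by
`tests/test_acceptance.py` and `scripts/acceptance.py`) uses these sizes,
chosen to give stable Monte-Carlo estimates at desk scale:

* parameter recovery: one simulated session per g, 201 trials, mu rhythm
  only, blinks off and ICA skipped so the measurement isolates the ERD/S
  estimator chain; recovered on the five left-central channels;
* type-I calibration: 1000 null tables, 28 participants (7 per
  between-cell), within-cell covariance `kron(AR1(0.5), AR1(0.3))` with
  variances rising 1->2.5 (population epsilon ~0.74 for ROI — the
  moderate nonsphericity regime the correction is meant for);
* stationary TF check: 300 epochs, map interior -1..6.5 s (per-bin
  fluctuations scale as one over the root of epochs x channels, so the
  max over ~2500 bins needs this many epochs to sit comfortably inside
  +-15 %);
* full-chain power: 100 replicates of an 8-participant, one-MI-run,
  9-trial cohort with the default contralateral alpha-ERD profile
  (blinks off, ICA skipped), testing the ROI x Condition interaction at
  alpha = 0.05.

## Known limitations

* Channel rhythms are spatially independent; spatial-filter behaviour
  (average reference, ICA) is exercised but not under realistic
  cross-channel correlation structure.
* The per-epoch ERD/S bias above means absolute table values should not
  be compared against estimators that average power before the ratio.
* The EDF writer emits plain 16-bit EDF (one record per second,
  zero-padded final record, fixed header date for byte-reproducibility);
  EDF+ annotations are not written — events travel in the sidecar TSV.
* `emmeans` SEs are descriptive (see above); F, df, epsilon and p-values
  are the model-based quantities.
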