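# Methods

`seltrack` analyses selective neural speech tracking in a multi-talker
listening paradigm: a target talker at 65 dB SPL masked by an
opposite-gender talker and two-channel background noise, with the target
SNR swept densely over −12…+4 dB. Because raw recordings are not bundled,
a synthetic-experiment generator reproduces the paradigm with explicit
ground truth; every analysis stage is validated by recovering what the
generator planted.

## Acoustic level arithmetic

The masker and each noise channel share one presentation level, so the
competing power is three times the masker power and

SNR = L_target − L_masker − 10·log₁₀ 3  (≈ L_target − L_masker − 4.77 dB).

The constant is kept exact internally; 4.77 is display rounding. A
power-summation oracle on sampled signals (three incoherent equal-RMS
sources) confirms the formula to better than 0.01 dB. Whether a real
experiment's SNR uses realized RMS or nominal calibration levels is
ambiguous; nominal levels are assumed.

## Psychometric model of intelligibility

Word-recall accuracy against SNR is modeled per subject and noise type as
the four-parameter logistic

SI(SNR) = lw + (up − lw) / (1 + exp(−gr·(SNR − ths))),

fitted by maximum binomial likelihood with bounded L-BFGS from several
growth-rate starts (bounds: lw ≤ 0.45, up ≥ 0.55, gr ∈ (0, 20] per dB).
This is a point-estimate substitute for Bayesian psychometric machinery:
downstream analysis only consumes the four parameters. The fitted upper
bound `up` is the subject's *ceiling SI*; a trial counts as at-ceiling when
`up − SI(snr) ≤ tol·(up − lw)` with `tol = 0.02` by default (the notion of
"approaching ceiling" is not quantified anywhere authoritative, so the
tolerance is configurable).

Noise-type curves are combined by averaging *predictions* on a dense SNR
grid and refitting the logistic, rather than averaging parameters — robust
when `gr` and `ths` are poorly identified near ceiling. The refit warns
when its RMSE exceeds 0.02, i.e. when the mean of the two curves is not
logistic-shaped.

## CCA decoding of selective tracking

Envelopes and EEG (both 100 Hz) are causally lag-embedded — 200 ms
(20 lags) for the envelope, 400 ms (40 lags × 64 channels = 2560 columns)
for the EEG; rows are zero-padded at trial starts, and the first 3 s
(lead-in ramp) of every trial are excluded. Per subject, canonical
correlation analysis aligns the two embeddings, trained separately for the
target and masker streams under leave-one-trial-out cross-validation; the
Pearson correlation of the first canonical pair on the held-out trial
gives rT and rM, and rD = rT − rM.

Regularization. The envelope side is whitened by rank truncation (keep
eigencomponents explaining 99.9 % of variance): a band-limited envelope's
lag embedding is severely rank-deficient, and ridge whitening there
promotes numerically meaningless near-null canonical directions (observed
as training correlations of 1.0 that evaporate on application). The EEG
side defaults to ridge whitening, Sxx + γ·mean-eigenvalue·I with γ = 1e-3,
factorized by Cholesky once per fold and shared between the target and
masker models; rank-truncating whitening is available on the EEG side too
(`whiten="truncate"`) and agrees with the ridge default on well-posed
data, but costs a full eigendecomposition per fold. Cross-validation uses
exact leave-one-out covariance downdating from per-trial sufficient
statistics (per-trial Gram matrices are stored in float32, totals
accumulated in float64).

Only the first canonical pair is scored; how many pairs a given study
aggregates is rarely reported, and the first pair carries the dominant
envelope-following component. Swapping stream labels exactly negates rD
(the EEG-side whitener is shared), and breaking the envelope–trial pairing
drives rD to zero — both are tested.

## Temporal response functions

The forward TRF (envelope → EEG, lags 0–390 ms at 100 Hz) is estimated by
ridge regression with the ridge parameter chosen by leave-one-trial-out
predictive correlation over a log grid (1e-2 … 1e2, scaled by the mean
design eigenvalue). Component significance uses a permutation null: each
permutation re-pairs every envelope with the EEG of a different trial (a
random derangement) and refits; a circular-shift scheme is available
behind a flag. At the group level, per-subject channel-averaged TRFs are
compared to their per-subject permutation *means* by a paired t-test across
subjects per lag; testing one dataset's TRF directly against its pooled
permutation samples with a parametric t is invalid (conditional on the
data, the mismatch-null spread underestimates the matched statistic's
sampling variability — measured family-wise errors of 30–95% in
simulation). For a single subject, a two-sided empirical permutation
p-value is used instead, whose floor 1/(n_perm+1) is why ~1000
permutations are needed to clear Bonferroni over 40 lags. Correction is
across lags only — matching a channel-averaged presentation; per-channel
correction is out of scope. Component windows follow the canonical envelope-response
morphology: a point window at 50 ms and windows at 100–150 ms and
200–250 ms; group-average TRFs are normalized to unit maximum absolute
amplitude (idempotent by construction).

## Engagement metrics

Gaze velocity (GV): screen-normalized 60 Hz gaze coordinates are restored
to meters (default 0.53 × 0.30 m panel, eye aligned with screen center at
0.6 m), and the angle between successive eye-to-point 3-D vectors is
computed exactly by arctangent geometry (atan2 of cross and dot products —
no small-angle approximation). Absolute angular velocity is averaged over
pairs of consecutive non-blink samples; a fully blinked trial yields NaN,
never zero. Whether derivatives should be smoothed first is an open
choice; raw sample-to-sample derivatives are used.

Hit rate (HR): each of the three repeated words counts as detected when a
button press falls in (onset + 0.2 s, onset + 2.0 s]; onsets are matched
earliest-first and each press is consumed at most once, so a press inside
two overlapping windows credits the earlier word. Unmatched presses are
ignored, not penalized (false-alarm handling is unreported in the
literature this follows). HR ∈ {0, ⅓, ⅔, 1}.

## Mixed-effects statistics

All models delegate to statsmodels' REML `MixedLM`; the bespoke content is
the model specification and conditioning. Predictors are z-scored within
each analysis set so fixed effects are comparable across predictors. The
rD model (fixed: SNR, SI, GV, HR; random intercept per subject) is fitted
separately for below-ceiling and at-ceiling trials, with SI dropped
automatically where constant; rank-deficient predictor sets abort with a
variance-inflation report. Likelihood-ratio tests against the
intercept-only model refit both models by ML; when the ML likelihood is
degenerate (boundary variance estimates), a joint Wald χ² on the fixed
effects substitutes.

SI-binned SNR slopes use 6 equal-width SI bins from 0 to the ceiling plus
a dedicated ceiling bin, each fitted with a random intercept and random
SNR slope; reported slopes combine fixed and mean random components.
Kruskal–Wallis tests rD across HR groups, followed by Dunn's rank-based
pairwise z-tests with tie correction and Bonferroni multiplication
(implemented in-package). The two-pathway summary fits SI~SNR and GV~SNR
(random slopes), then per-SNR-bin slopes of rD on SI and on GV, and
reports whether the opposing-pathway pattern holds: SI rises with SNR, GV
rises with SNR (effort falls), the positive rD~SI slope weakens and the
negative rD~GV slope strengthens with SNR.

## Synthetic experiment generator

The generator's defaults are the study conditions: 16 target–masker–noise
combinations (4 gendered voices × opposite-gender maskers × {babble,
pedestrian}), trials evenly distributed across them; 80 SNR values evenly
spaced over [−12, +4] dB (the exact grid rule is unspecified upstream and
configurable); ~35-s trials with a 3-s lead-in excluded from analysis;
three repeated words per trial; 14 subjects × 160 trials at full scale.

Envelopes are rectified 8 Hz-low-passed Gaussian noise (modulation
centroid ≈ 3 Hz, inside the 1–8 Hz syllabic band) — a surrogate for
natural speech envelopes, which are out of scope. EEG is generated as

eeg = g_T·conv(env_T, K_T) + g_M·conv(env_M, K_M) + σ·white noise,

where K_T is a triphasic kernel (+50 ms, −110 ms, +210 ms) with smooth
deterministic scalp profiles and K_M a weaker, later kernel. Attention
gains follow g_T = 0.5 + 0.5·SI·(0.5 + 0.5·effort), g_M = 0.5·(1 − g_T);
effort declines logistically with SNR (centered −2 dB, 2 dB slope), so
tracking rises with SI but sags once effort collapses — the mechanism the
mediation analysis is designed to detect. Per-subject true psychometric
curves draw ths ~ N(−6, 1) dB, gr ~ U(0.6, 1), up ~ U(0.93, 1).

Two generator parameters have no authoritative value and were fixed once:

* `eeg_noise_sd = 100` (kernels have unit peak): chosen so held-out
  single-trial rT lands in 0.1–0.3, the magnitude regime of real EEG
  envelope tracking. Spatially *white* noise — deliberately simple; real
  EEG noise is spatially correlated and 1/f — is suppressed by the
  2560-dimensional decoder roughly √(64·40)-fold, so matching realistic
  correlation magnitudes requires a much lower per-channel SNR than real
  EEG exhibits.
* `effort_sd = 0.15`: a latent per-trial attentional-state fluctuation
  around effort(SNR), shared by the attention gains, gaze velocity and
  button-press engagement. Without it, GV would be conditionally
  independent of rD given SNR and every GV→rD analysis would be
  degenerate; 0.15 of the unit effort range is a moderate trial-to-trial
  wander.

Gaze is a reflected random walk near screen center whose exponential
angular step sizes target 30·(1 − 0.8·effort) deg/s, with Poisson blink
bursts; button presses occur per repeated word with probability
SI × (0.6 + 0.3·effort) and gamma-distributed latencies inside the
response window.

What the generator does *not* emulate: real EEG noise structure (1/f,
artifacts, spatial correlation), natural-speech envelope statistics,
saccade/fixation microstructure, listener fatigue or learning. Passing
tests therefore demonstrate that the pipeline recovers the planted
generative structure at realistic signal-to-noise ratios, not that it
reproduces any specific real-data effect size.

## Problem sizes and numerical choices

Simulations are scaled for a single-CPU workflow: the end-to-end mediation
check runs 6 subjects × 48 trials of 35 s (cohort scaled down from
14 × 160, trial structure untouched); decoder sign-test validation uses 50
trials of 12 s, while the null-pairing check keeps the full 35-s duration
(where the finite-sample correlation bias is negligible) over 5 replicate
datasets; permutation calibration uses 100–200 null cohorts of 6 subjects
at 200 permutations per cohort (1000 remains the default for single-subject
TRF analyses). Deterministic seeding flows from a single master seed through
`numpy` SeedSequence-style child seeds; reruns with one configuration are
bit-identical in the deterministic stages. Degenerate inputs fail loudly:
constant envelopes, all-blink gaze, all-correct recall tables, single-trial
permutation requests and majority-bad channel montages all raise with
diagnostics rather than returning silent zeros.

## Known limitations

* The mediation summary is a sign-and-significance report, not a formal
  causal-mediation decomposition.
* Bad-channel repair uses inverse-distance weighting on a standard
  64-channel montage rather than spherical splines.
* The envelope extractor (analytic-signal magnitude + 10 Hz low-pass) is a
  standard substitute for specialized iterative envelope algorithms; the
  decoding pipeline only assumes a slow modulation envelope.
* White-noise EEG makes decoder performance optimistic relative to real
  recordings at matched per-channel SNR; the noise level compensates (see
  above), but spatial-correlation effects on CCA are untested.
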